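"""Generate a synthetic multichannel recording with a planted state schedule.

Builds a small two-file recording (8 channels, 2 x 2 min at 500 Hz) whose
first and third minute are "unconscious" (shared zero-lag slow waves plus
mid-band activity) and whose second and fourth are "conscious" (theta/beta
oscillations, lagged cross-channel coupling, broadband noise), then writes
one file to disk and reads it back.
"""

import tempfile
from pathlib import Path

from ecogstate import SynthConfig, generate, load_raw, save_raw
from ecogstate.synthetic import alternating_schedule

cfg = SynthConfig(n_channels=8, fs=500.0, file_length_s=120.0, n_files=2, seed=1)
schedule = alternating_schedule(2, 120.0, 60.0)
recordings = generate(cfg, schedule)

for rec in recordings:
    print(
        f"{rec.source_file}: {rec.n_channels} channels x {rec.n_samples} samples "
        f"at {rec.fs:g} Hz, starts {rec.start_time}"
    )
print("schedule:", [(s, e, state) for s, e, state in schedule.intervals])

with tempfile.TemporaryDirectory() as d:
    path = save_raw(recordings[0], Path(d) / "hour00.bin")
    back = load_raw(path)
    print(f"round trip: {back.n_channels} channels, fs={back.fs:g} Hz -> lossless header,")
    print("float32 samples (amplitudes in", back.unit + ")")
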