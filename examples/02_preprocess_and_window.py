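"""Band-pass filter, reject noisy channels, and segment into sliding windows.

The numbers to look at: 5 of 64 channels exceed the 200 (header-unit)
amplitude threshold and are dropped, leaving 59; a one-hour file at a 3-s
window and 1-s stride yields 3598 windows, so 24 such files give 86,352
feature rows — windows never span two files.
"""

from ecogstate import (
    PreprocessConfig,
    StateSchedule,
    SynthConfig,
    bandpass,
    generate,
    reject_channels,
    window,
    window_count,
)

cfg = SynthConfig(
    n_channels=64, fs=500.0, file_length_s=20.0, n_files=1, seed=2, noisy_channels=5
)
rec = generate(cfg, StateSchedule(((0.0, 20.0, "conscious"),)))[0]

pp = PreprocessConfig()  # 0.5-45 Hz, order 3, threshold 200, 3-s/1-s windows
kept, rejected = reject_channels(rec, pp)
print(f"rejected {len(rejected)} channels ({', '.join(rejected)}); {kept.n_channels} retained")

filtered = bandpass(kept, pp)
ws = window(filtered, pp)
print(f"{rec.duration_s:g} s file -> {len(ws)} windows of {pp.window_s:g} s every {pp.stride_s:g} s")

per_hour = window_count(3600.0, pp.window_s, pp.stride_s)
print(f"one-hour file -> {per_hour} windows; 24 files -> {24 * per_hour} feature rows")
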