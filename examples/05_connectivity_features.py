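"""Theta-band imaginary coherency and weighted symbolic mutual information.

Two channels driven by a shared theta source with a 50 ms propagation lag
show clearly positive iCOH and wSMI; an identical (zero-lag) copy scores
zero on both — iCOH because zero-lag coherency is purely real, wSMI because
identical symbol pairs carry zero weight.  Independent channels also score
near zero.
"""

import numpy as np

from ecogstate import WsmiParams, icoh_pair, wsmi_pair
from ecogstate.preprocess import downsample_block
from ecogstate.synthetic import _band_noise

fs = 500.0
rng = np.random.default_rng(0)
n = 6000  # 12 s

src = _band_noise(rng, n + 100, fs, 2.0, 4.0)
a = src[:n] + 0.3 * rng.standard_normal(n)
lagged = src[25:25 + n] + 0.3 * rng.standard_normal(n)  # 50 ms lag
independent = rng.standard_normal(n)

p = WsmiParams()  # k=3, tau=8 samples at 200 Hz
for name, other in [("lagged copy", lagged), ("identical copy", a), ("independent", independent)]:
    ic = icoh_pair(a, other, fs)
    w = wsmi_pair(
        downsample_block(a, fs, 200.0), downsample_block(other, fs, 200.0), p
    )
    print(f"{name:15s}: iCOH(theta)={ic:.3f}   wSMI={w:.3f}")
print("only genuinely lagged coupling drives both measures above zero")
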