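"""Compute F, D and Dynamic Complexity on hand-picked windows.

Shows how the fluctuation measure F (slope intensity between turning
points), the distribution measure D (evenness of spread over the scale)
and their product DC react to qualitatively different 7-point windows.
"""

import numpy as np

from dcews import distribution_measure, fluctuation_measure

windows = {
    "constant":            [0.5] * 7,
    "slow drift":          list(np.linspace(0.2, 0.8, 7)),
    "equidistant spread":  list(np.linspace(0.0, 1.0, 7)),
    "mild noise":          [0.45, 0.55, 0.48, 0.52, 0.46, 0.54, 0.50],
    "full alternation":    [0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
    "turbulent":           [0.0, 0.5, 0.25, 0.75, 0.25, 1.0, 0.0],
}

print(f"{'window':<20} {'F':>7} {'D':>7} {'DC':>7}")
for name, w in windows.items():
    f = fluctuation_measure(w, 0.0, 1.0)
    d = distribution_measure(w, 0.0, 1.0)
    print(f"{name:<20} {f:7.3f} {d:7.3f} {f * d:7.3f}")

# DC is high only when values both change direction often (high F) and cover
# the scale evenly (high D): the "turbulent" window scores far above drift or
# noise, and full-scale alternation maximizes F but concentrates values at
# the extremes, capping D.
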