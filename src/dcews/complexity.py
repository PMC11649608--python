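"""The Dynamic Complexity index.

Dynamic Complexity (DC) quantifies turbulent, scattered variability in a
short, coarse-grained time series. Within an overlapping moving window of
``m`` points (default 7, step 1) it multiplies

* a fluctuation measure ``F`` — the normalized sum of mean slope magnitudes
  of the maximal monotone segments between turning points; 0 for a constant
  window, 1 for full-scale alternation at every step — with
* a distribution measure ``D`` — how evenly the sorted window values spread
  across the scale's *theoretical* range ``s``; 1 exactly for an equidistant
  full-range spread, 0 for a constant window.

Both are computed against the theoretical normalized scale range
``s = norm_max - norm_min`` (e.g. 0.7 for a 6–20 category-ratio scale divided
by 20), not the observed range. The window's DC value is assigned to the
window's last occasion, so the series is defined from occasion ``m`` onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import AthleteSeries

__all__ = [
    "DCMatrix",
    "fluctuation_measure",
    "distribution_measure",
    "dynamic_complexity_series",
]

DEFAULT_WINDOW = 7


@dataclass
class DCMatrix:
    """Occasion x factor Dynamic Complexity values for one player.

    ``values`` is indexed by occasion 1..T; occasions before ``window`` are
    NaN (the window is assigned to its trailing edge). ``scale_ranges`` maps
    each factor to its theoretical normalized range ``s``.
    """

    player_id: str
    window: int
    values: pd.DataFrame = field(repr=False)
    scale_ranges: dict[str, float]

    @property
    def defined_from(self) -> int:
        """First occasion (1-based) with a defined DC value."""
        return self.window

    @property
    def factors(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_occasions(self) -> int:
        return len(self.values)


def _segment_boundaries(values: np.ndarray) -> list[int]:
    """Indices bounding the maximal monotone segments of *values*.

    Runs of equal consecutive values are collapsed when determining the
    direction of change; when the direction reverses across such a plateau the
    turning point is the plateau's last index, which keeps every segment's
    mean slope well defined.
    """
    m = len(values)
    diffs = np.diff(values)
    boundaries = [0]
    last_dir = 0
    for i, d in enumerate(diffs):
        if d == 0:
            continue
        direction = 1 if d > 0 else -1
        if last_dir != 0 and direction != last_dir:
            boundaries.append(i)
        last_dir = direction
    if boundaries[-1] != m - 1:
        boundaries.append(m - 1)
    return boundaries


def fluctuation_measure(window, norm_min: float, norm_max: float) -> float:
    """Fluctuation intensity ``F`` of one window, in [0, 1].

    ``F = ( sum over monotone segments of |Δvalue| / Δoccasions )
    / ( s * (m - 1) )`` with ``s = norm_max - norm_min``. The normalizer is
    the value attained by full-scale alternation at every step, so ``F = 1``
    there and ``F = 0`` for a constant window.
    """
    v = np.asarray(window, dtype=float)
    m = v.size
    if m < 2:
        raise ValueError("window must contain at least 2 values")
    s = norm_max - norm_min
    if s <= 0:
        raise ValueError("scale range must be positive")
    b = _segment_boundaries(v)
    total = 0.0
    for a, c in zip(b[:-1], b[1:]):
        total += abs(v[c] - v[a]) / (c - a)
    return total / (s * (m - 1))


def distribution_measure(window, norm_min: float, norm_max: float) -> float:
    """Distribution measure ``D`` of one window, in [0, 1].

    Sort the window ascending as ``y(1..m)``. The ideal equidistant spread
    over the full scale has pairwise gaps ``d_ideal(i,j) = (j-i) * s/(m-1)``;
    each pair contributes the shortfall ``max(0, d_ideal - (y(j) - y(i)))``,
    and ``D = 1 - sum(shortfall) / sum(d_ideal)``.
    """
    v = np.asarray(window, dtype=float)
    m = v.size
    if m < 2:
        raise ValueError("window must contain at least 2 values")
    s = norm_max - norm_min
    if s <= 0:
        raise ValueError("scale range must be positive")
    y = np.sort(v)
    i, j = np.triu_indices(m, k=1)
    ideal = (j - i) * s / (m - 1)
    shortfall = np.clip(ideal - (y[j] - y[i]), 0.0, None)
    return float(1.0 - shortfall.sum() / ideal.sum())


def _distribution_windows(windows: np.ndarray, s: float) -> np.ndarray:
    """Vectorized ``D`` over an (n_windows, m) array."""
    n, m = windows.shape
    y = np.sort(windows, axis=1)
    i, j = np.triu_indices(m, k=1)
    ideal = (j - i) * s / (m - 1)
    shortfall = np.clip(ideal[None, :] - (y[:, j] - y[:, i]), 0.0, None)
    return 1.0 - shortfall.sum(axis=1) / ideal.sum()


def _fluctuation_windows(windows: np.ndarray, s: float) -> np.ndarray:
    n, m = windows.shape
    out = np.empty(n)
    norm = s * (m - 1)
    for k in range(n):
        v = windows[k]
        b = _segment_boundaries(v)
        total = 0.0
        for a, c in zip(b[:-1], b[1:]):
            total += abs(v[c] - v[a]) / (c - a)
        out[k] = total / norm
    return out


def dynamic_complexity_series(series: AthleteSeries,
                              m: int = DEFAULT_WINDOW) -> DCMatrix:
    """Dynamic Complexity of every factor in a trailing moving window.

    For each factor ``v`` and occasion ``t >= m``,
    ``DC[t, v] = F(values[t-m+1 .. t]) * D(values[t-m+1 .. t])`` against the
    factor's theoretical scale range; occasions before ``m`` are undefined.
    """
    if m < 2:
        raise ValueError("window size m must be >= 2")
    T = series.n_occasions
    if T < m:
        raise ValueError(
            f"series of length {T} is shorter than the DC window {m}")
    dc = pd.DataFrame(np.nan, index=series.values.index,
                      columns=series.values.columns)
    ranges: dict[str, float] = {}
    for factor in series.factors:
        spec = series.scale_specs[factor]
        s = spec.scale_range
        ranges[factor] = s
        x = series.values[factor].to_numpy(dtype=float)
        windows = np.lib.stride_tricks.sliding_window_view(x, m)
        f = _fluctuation_windows(windows, s)
        d = _distribution_windows(windows, s)
        dc.iloc[m - 1:, dc.columns.get_loc(factor)] = f * d
    return DCMatrix(player_id=series.player_id, window=m, values=dc,
                    scale_ranges=ranges)
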