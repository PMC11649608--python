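"""Significant Dynamic Complexity peaks and cumulative complexity peaks.

Two stacked one-sided z-tests (one-sided because only *increased* critical
fluctuation is of interest):

1. per factor, standardize the player's defined DC series and flag occasions
   whose z-score exceeds the one-sided critical value (default 1.645,
   alpha = 0.05);
2. count the simultaneous factor peaks per occasion, standardize that count
   series the same way, and flag occasions with a significantly elevated
   count — the cumulative complexity peaks (CCPs) used as warning signals.

Standardization uses the whole defined series by default (the analysis is
post hoc); a trailing running baseline is available as an option. A degenerate
standard deviation of zero yields no peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .complexity import DCMatrix

__all__ = [
    "PeakMatrix",
    "CCPSeries",
    "significant_dc_peaks",
    "cumulative_peak_count",
    "detect_ccp",
    "ccp_from_dc",
]

DEFAULT_ALPHA = 0.05


def _critical_value(alpha: float, z_crit: float | None) -> float:
    if z_crit is not None:
        return float(z_crit)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.norm.ppf(1.0 - alpha))


@dataclass
class PeakMatrix:
    """Occasion x factor flags of significantly elevated DC."""

    player_id: str
    peaks: pd.DataFrame = field(repr=False)   # boolean; False where undefined
    defined: pd.DataFrame = field(repr=False)  # boolean; where DC was defined
    alpha: float
    z_crit: float

    @property
    def factors(self) -> list[str]:
        return list(self.peaks.columns)


@dataclass
class CCPSeries:
    """Per-occasion simultaneous-peak counts and CCP flags."""

    player_id: str
    count: pd.Series = field(repr=False)  # float; NaN where undefined
    ccp: pd.Series = field(repr=False)    # boolean; False where undefined
    alpha: float
    z_crit: float

    @property
    def defined_occasions(self) -> pd.Index:
        return self.count.index[self.count.notna()]

    @property
    def n_occasions(self) -> int:
        return len(self.count)


def _one_sided_flags(x: np.ndarray, z_crit: float,
                     baseline: str, baseline_window: int) -> np.ndarray:
    """Flag entries of *x* exceeding mean + z_crit * sd (NaN-aware)."""
    flags = np.zeros(x.shape, dtype=bool)
    defined = ~np.isnan(x)
    if defined.sum() < 2:
        return flags
    if baseline == "full":
        mu = np.nanmean(x)
        sd = np.nanstd(x, ddof=1)
        if sd > 0:
            flags[defined] = (x[defined] - mu) / sd > z_crit
    elif baseline == "running":
        s = pd.Series(x)
        mu = s.rolling(baseline_window, min_periods=2).mean()
        sd = s.rolling(baseline_window, min_periods=2).std(ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (s - mu) / sd
        flags = (z > z_crit).fillna(False).to_numpy() & defined & (sd > 0).to_numpy()
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return flags


def significant_dc_peaks(dc: DCMatrix, alpha: float = DEFAULT_ALPHA,
                         z_crit: float | None = None,
                         baseline: str = "full",
                         baseline_window: int = 28) -> PeakMatrix:
    """First-stage test: flag per-factor DC values with ``z > z_crit``.

    z-scores use the factor's mean and sample (n-1) standard deviation over
    its defined DC values; a factor with zero spread yields no peaks.
    """
    zc = _critical_value(alpha, z_crit)
    defined = dc.values.notna()
    if not defined.to_numpy().any():
        raise ValueError("all DC values are undefined")
    flags = pd.DataFrame(False, index=dc.values.index, columns=dc.values.columns)
    for factor in dc.values.columns:
        x = dc.values[factor].to_numpy(dtype=float)
        flags[factor] = _one_sided_flags(x, zc, baseline, baseline_window)
    return PeakMatrix(player_id=dc.player_id, peaks=flags, defined=defined,
                      alpha=alpha, z_crit=zc)


def cumulative_peak_count(peaks: PeakMatrix) -> pd.Series:
    """Second-stage input: number of factors flagged per occasion.

    Occasions where DC was undefined for every factor are NaN.
    """
    count = peaks.peaks.sum(axis=1).astype(float)
    any_defined = peaks.defined.any(axis=1)
    count[~any_defined] = np.nan
    count.name = "peak_count"
    return count


def detect_ccp(count: pd.Series, alpha: float = DEFAULT_ALPHA,
               z_crit: float | None = None, baseline: str = "full",
               baseline_window: int = 28,
               player_id: str = "") -> CCPSeries:
    """Second-stage test: flag occasions with significantly many peaks."""
    zc = _critical_value(alpha, z_crit)
    x = count.to_numpy(dtype=float)
    if np.sum(~np.isnan(x)) < 2:
        raise ValueError("need at least 2 defined occasions in the count series")
    flags = _one_sided_flags(x, zc, baseline, baseline_window)
    ccp = pd.Series(flags, index=count.index, name="ccp")
    return CCPSeries(player_id=player_id, count=count, ccp=ccp,
                     alpha=alpha, z_crit=zc)


def ccp_from_dc(dc: DCMatrix, alpha: float = DEFAULT_ALPHA,
                z_crit: float | None = None,
                baseline: str = "full",
                baseline_window: int = 28) -> tuple[PeakMatrix, CCPSeries]:
    """Run both test stages on a DC matrix."""
    peaks = significant_dc_peaks(dc, alpha, z_crit, baseline, baseline_window)
    count = cumulative_peak_count(peaks)
    ccp = detect_ccp(count, alpha, z_crit, baseline, baseline_window,
                     player_id=dc.player_id)
    return peaks, ccp
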