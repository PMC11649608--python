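"""Synthetic athlete-monitoring cohorts.

The real study data (daily self-reports plus GPS / heart-rate sensor output of
youth football players over two seasons) is access-restricted, so this module
generates cohorts with the statistical shape the analysis assumes:

* per player, each factor follows a bounded stationary AR(1) process mapped
  onto its raw scale (VAS 0–100, CRS 6–20, non-negative sensor counts);
* sparse injuries with a time-loss period, placed uniformly at random away
  from the series edges so every generated injury is analysis-eligible;
* optionally, a short pre-onset window of injected "critical fluctuation"
  turbulence — high-amplitude, sign-alternating oscillations in a subset of
  factors — emulating the destabilization an early-warning signal should see;
* missing-completely-at-random gaps.

Values before missingness are complete and in raw units; preprocessing applies
inclusion criteria, imputation, daily aggregation and normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scales import RAW_FACTORS, SESSION_FACTORS

__all__ = [
    "SimConfig",
    "RawPlayerTable",
    "InjuryEvent",
    "generate_cohort",
    "inject_destabilization",
    "apply_missingness",
]


# Raw-scale marginal moments and simulation clip bounds, per factor.
# Chosen once as field-realistic values for elite youth football monitoring:
# self-reports cluster in the upper-middle of their scales, a field session
# lasts 60–90 min, covers ~5–6 km with a dozen sprints, and time in the
# highest heart-rate zone is a few minutes.
_FACTOR_MODELS: dict[str, tuple[float, float, float, float]] = {
    # factor: (mean, sd, clip_lo, clip_hi)
    "recovery": (13.5, 2.5, 6.0, 20.0),
    "self_efficacy": (68.0, 12.0, 0.0, 100.0),
    "motivation": (72.0, 12.0, 0.0, 100.0),
    "mood": (70.0, 12.0, 0.0, 100.0),
    "distance": (5500.0, 1500.0, 0.0, 12000.0),
    "sprints": (12.0, 5.0, 0.0, 40.0),
    "duration": (75.0, 15.0, 30.0, 120.0),
    "hr_zone5": (300.0, 150.0, 0.0, 1800.0),
    "exertion": (13.0, 2.5, 6.0, 20.0),
    "perceived_performance": (65.0, 12.0, 0.0, 100.0),
    "enjoyment": (70.0, 12.0, 0.0, 100.0),
}

#: Margin kept clear of injury onsets at both series edges, in occasions.
EDGE_MARGIN = 7


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic cohort.

    Defaults emulate the study cohort: ~23 players observed 155–430 times,
    11 factors, roughly 0.8 injuries per 100 occasions (64 injuries over
    ~7800 player-occasions), time-loss of a few occasions up to three weeks,
    and mild missingness well under the 20 % inclusion cap.
    """

    n_players: int = 23
    series_length_range: tuple[int, int] = (155, 430)
    factor_set: tuple[str, ...] = RAW_FACTORS
    injury_rate: float = 0.8          # expected injuries per 100 occasions
    time_loss_range: tuple[int, int] = (2, 21)
    destabilization_fraction: float = 0.5
    destabilization_lead: int = 6
    destabilization_gain: float = 5.0
    affected_factor_count: int = 8
    missing_rate: float = 0.05
    baseline_autocorr: float = 0.4
    multi_session_prob: float = 0.1   # chance of a second session on an occasion
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.series_length_range
        if lo < 15:
            raise ValueError(
                "series_length_range minimum must be >= 15: the series must "
                "exceed the DC window plus the edge margins kept clear of "
                "injury onsets"
            )
        if lo > hi:
            raise ValueError("series_length_range must be (min, max) with min <= max")
        if self.n_players < 1:
            raise ValueError("n_players must be positive")
        for name in ("destabilization_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.missing_rate >= 1.0:
            raise ValueError("missing_rate must be < 1")
        if self.destabilization_gain < 1.0:
            raise ValueError("destabilization_gain must be >= 1")
        if not -1.0 < self.baseline_autocorr < 1.0:
            raise ValueError("baseline_autocorr must lie in (-1, 1)")
        if self.injury_rate < 0:
            raise ValueError("injury_rate must be non-negative")
        if self.destabilization_lead < 1:
            raise ValueError("destabilization_lead must be >= 1")
        if not 0 <= self.affected_factor_count <= len(self.factor_set):
            raise ValueError("affected_factor_count must be within the factor set")
        tl_lo, tl_hi = self.time_loss_range
        if tl_lo < 0 or tl_lo > tl_hi:
            raise ValueError("time_loss_range must be (min, max) with 0 <= min <= max")
        unknown = set(self.factor_set) - set(_FACTOR_MODELS)
        if unknown:
            raise ValueError(f"no generative model for factors {sorted(unknown)}")


@dataclass(frozen=True)
class InjuryEvent:
    """One injury: onset occasion, contiguous time-loss occasions, mechanism."""

    player_id: str
    onset_occasion: int
    time_loss_occasions: int
    mechanism: str  # "traumatic" | "overuse"

    def __post_init__(self) -> None:
        if self.onset_occasion < 1:
            raise ValueError("onset_occasion must be >= 1")
        if self.time_loss_occasions < 0:
            raise ValueError("time_loss_occasions must be >= 0")
        if self.mechanism not in ("traumatic", "overuse"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def period(self) -> range:
        """Occasions flagged as injured: ``[onset, onset + time_loss - 1]``."""
        return range(self.onset_occasion,
                     self.onset_occasion + self.time_loss_occasions)


@dataclass
class RawPlayerTable:
    """Long-format monitoring table of one player.

    ``data`` columns: ``occasion`` (1-based), ``session`` (>= 1), ``factor``,
    ``value`` (raw scale, NaN when missing).
    """

    player_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"occasion", "session", "factor", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"raw table missing columns {sorted(missing)}")
        if len(self.data) and int(self.data["occasion"].min()) < 1:
            raise ValueError("occasion indices must be strictly positive")

    @property
    def n_occasions(self) -> int:
        return int(self.data["occasion"].max()) if len(self.data) else 0

    @property
    def factors(self) -> list[str]:
        return sorted(self.data["factor"].unique())

    def copy(self) -> "RawPlayerTable":
        return RawPlayerTable(self.player_id, self.data.copy())


def _ar1_series(rng: np.random.Generator, n: int, mean: float, sd: float,
                phi: float, lo: float, hi: float) -> np.ndarray:
    """Stationary AR(1) with marginal (mean, sd), clipped to [lo, hi]."""
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(mean, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = mean + phi * (x[t - 1] - mean) + eps[t - 1]
    return np.clip(x, lo, hi)


def _place_injuries(rng: np.random.Generator, T: int, config: SimConfig,
                    player_id: str) -> list[InjuryEvent]:
    """Place a Poisson number of non-overlapping injuries away from the edges.

    Onsets fall in ``[EDGE_MARGIN + 1, T - EDGE_MARGIN]`` and the pre-onset
    destabilization lead window is kept clear of earlier injury periods
    (turbulence belongs to the healthy phase before an onset). If the series
    is too crowded to place every drawn event, the surplus is dropped.
    """
    lam = config.injury_rate / 100.0 * T
    k = int(rng.poisson(lam)) if lam > 0 else 0
    if k == 0:
        return []
    if T < 2 * EDGE_MARGIN + 1:
        raise ValueError(
            f"player {player_id}: series of length {T} is too short to place "
            f"an injury onset outside the first and last {EDGE_MARGIN} occasions"
        )
    events: list[InjuryEvent] = []
    occupied: set[int] = set()
    attempts = 0
    while len(events) < k and attempts < 200 * k:
        attempts += 1
        onset = int(rng.integers(EDGE_MARGIN + 1, T - EDGE_MARGIN + 1))
        time_loss = int(rng.integers(config.time_loss_range[0],
                                     config.time_loss_range[1] + 1))
        period = set(range(onset, min(onset + time_loss, T + 1)))
        guard = set(range(onset - config.destabilization_lead, onset))
        if (period | guard) & occupied:
            continue
        mech = "traumatic" if rng.random() < 0.65 else "overuse"
        events.append(InjuryEvent(player_id, onset, time_loss, mech))
        occupied |= period
    events.sort(key=lambda e: e.onset_occasion)
    return events


def _baseline_table(rng: np.random.Generator, player_id: str, T: int,
                    config: SimConfig) -> RawPlayerTable:
    rows: list[pd.DataFrame] = []
    second_session = rng.random(T) < config.multi_session_prob
    for factor in config.factor_set:
        mean, sd, lo, hi = _FACTOR_MODELS[factor]
        values = _ar1_series(rng, T, mean, sd, config.baseline_autocorr, lo, hi)
        rows.append(pd.DataFrame({
            "occasion": np.arange(1, T + 1),
            "session": 1,
            "factor": factor,
            "value": values,
        }))
        if factor in SESSION_FACTORS:
            occ2 = np.flatnonzero(second_session) + 1
            if occ2.size:
                # Second (shorter) session of the day: fresh draws at ~55 %
                # of the typical session magnitude, same raw bounds.
                v2 = np.clip(rng.normal(0.55 * mean, 0.55 * sd, size=occ2.size),
                             lo, hi)
                rows.append(pd.DataFrame({
                    "occasion": occ2, "session": 2, "factor": factor, "value": v2,
                }))
    data = (pd.concat(rows, ignore_index=True)
            .sort_values(["occasion", "session", "factor"])
            .reset_index(drop=True))
    return RawPlayerTable(player_id, data)


def inject_destabilization(table: RawPlayerTable, event: InjuryEvent,
                           lead: int, gain: float,
                           factors: list[str] | tuple[str, ...]) -> RawPlayerTable:
    """Inject pre-onset critical-fluctuation turbulence into selected factors.

    Within the window ``[onset - lead, onset - 1]`` the selected factors
    receive an additive, sign-alternating perturbation of amplitude
    ``(gain - 1) * sigma_f`` around their running values, where ``sigma_f``
    is the factor's whole-series standard deviation; results are clipped to
    the factor's raw simulation bounds. ``gain = 1`` or an empty factor
    selection leaves the table unchanged. A window reaching before occasion 1
    is truncated with a warning.
    """
    if lead < 1:
        raise ValueError("lead must be >= 1")
    if gain < 1:
        raise ValueError("gain must be >= 1")
    out = table.copy()
    if gain == 1.0 or not list(factors):
        return out
    start = event.onset_occasion - lead
    if start < 1:
        warnings.warn(
            f"destabilization window for onset {event.onset_occasion} extends "
            "before occasion 1; truncating", stacklevel=2)
        start = 1
    window = np.arange(start, event.onset_occasion)
    if window.size == 0:
        return out
    df = out.data
    for factor in factors:
        sel = df["factor"] == factor
        if not sel.any():
            raise KeyError(f"factor {factor!r} not present in table")
        sigma = float(df.loc[sel, "value"].std(ddof=1))
        if not np.isfinite(sigma) or sigma == 0.0:
            _, sd, _, _ = _FACTOR_MODELS.get(factor, (0.0, 1.0, 0.0, 1.0))
            sigma = sd
        amp = (gain - 1.0) * sigma
        lo, hi = _FACTOR_MODELS.get(factor, (0.0, 0.0, -np.inf, np.inf))[2:]
        in_win = sel & df["occasion"].isin(window)
        alt = np.where((df.loc[in_win, "occasion"].to_numpy() - start) % 2 == 0,
                       1.0, -1.0)
        perturbed = df.loc[in_win, "value"].to_numpy() + amp * alt
        df.loc[in_win, "value"] = np.clip(perturbed, lo, hi)
    return out


def apply_missingness(table: RawPlayerTable, rate: float,
                      seed: int) -> RawPlayerTable:
    """Blank each value independently with probability *rate* (MCAR)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(len(out.data)) < rate
    out.data.loc[mask, "value"] = np.nan
    return out


def generate_cohort(
    config: SimConfig,
) -> list[tuple[RawPlayerTable, list[InjuryEvent]]]:
    """Generate a cohort of raw monitoring tables plus injury logs.

    Deterministic given ``config.seed``. For each player: AR(1) baselines per
    factor, Poisson-placed injuries clear of the series edges, turbulence
    injected before a ``destabilization_fraction`` share of injuries, MCAR
    missingness applied last. Returned tables are raw and un-normalized.
    """
    master = np.random.default_rng(config.seed)
    cohort: list[tuple[RawPlayerTable, list[InjuryEvent]]] = []
    lo, hi = config.series_length_range
    for i in range(config.n_players):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        player_id = f"P{i + 1:02d}"
        T = int(rng.integers(lo, hi + 1))
        table = _baseline_table(rng, player_id, T, config)
        injuries = _place_injuries(rng, T, config, player_id)
        for event in injuries:
            if rng.random() < config.destabilization_fraction:
                affected = list(rng.choice(
                    np.asarray(config.factor_set, dtype=object),
                    size=config.affected_factor_count, replace=False))
                table = inject_destabilization(
                    table, event, config.destabilization_lead,
                    config.destabilization_gain, affected)
        table = apply_missingness(table, config.missing_rate,
                                  int(rng.integers(0, 2**31 - 1)))
        cohort.append((table, injuries))
    return cohort


def cohort_with(config: SimConfig, **changes) -> SimConfig:
    """Return a copy of *config* with the given fields replaced."""
    return replace(config, **changes)
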