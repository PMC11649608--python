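"""Inclusion criteria, imputation, daily aggregation and normalization.

Turns raw long-format monitoring tables into per-player normalized
occasion x factor matrices ready for the Dynamic Complexity analysis:

1. ``select_players`` — keep players with at least one analysis-eligible
   injury (onset between occasion 7 and the last 7 occasions) and no factor
   missing more than 20 % of its values;
2. ``impute_missing`` — deterministic per-factor linear interpolation over
   occasion order with nearest-edge fill (substitute for the original
   chained-equations multiple imputation, which is out of scope);
3. ``build_daily_factors`` — session RPE x duration -> sRPE, sum session
   factors across a day's sessions, keep self-reports once per occasion;
4. ``normalize_factors`` — VAS / 100, CRS / 20, open-ended factors divided by
   the individual's per-factor maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import (
    ANALYSIS_FACTORS,
    DEFAULT_SCALES,
    SELF_REPORT_ONCE_FACTORS,
    SESSION_FACTORS,
    ScaleSpec,
)
from .simulate import InjuryEvent, RawPlayerTable

__all__ = [
    "AthleteSeries",
    "select_players",
    "impute_missing",
    "build_daily_factors",
    "normalize_factors",
    "preprocess_player",
]

DEFAULT_MAX_MISSING = 0.20
DEFAULT_DC_WINDOW = 7


@dataclass
class AthleteSeries:
    """One player's normalized occasion x factor matrix plus injury log.

    ``values`` is indexed by occasion (1..T) with one column per analysis
    factor; it contains no missing values and every entry lies within its
    factor's normalized bounds. ``injured_mask`` flags the occasions inside
    any injury's time-loss period.
    """

    player_id: str
    values: pd.DataFrame = field(repr=False)
    scale_specs: dict[str, ScaleSpec]
    injuries: list[InjuryEvent]
    injured_mask: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("AthleteSeries must not contain missing values")
        for factor in self.values.columns:
            spec = self.scale_specs[factor]
            col = self.values[factor]
            if (col < spec.norm_min - 1e-9).any() or (col > spec.norm_max + 1e-9).any():
                raise ValueError(
                    f"factor {factor!r} has values outside "
                    f"[{spec.norm_min}, {spec.norm_max}]")

    @property
    def n_occasions(self) -> int:
        return len(self.values)

    @property
    def factors(self) -> list[str]:
        return list(self.values.columns)


def _missing_fractions(table: RawPlayerTable) -> pd.Series:
    return table.data.groupby("factor")["value"].apply(
        lambda v: float(v.isna().mean()))


def select_players(
    cohort: list[tuple[RawPlayerTable, list[InjuryEvent]]],
    max_missing: float = DEFAULT_MAX_MISSING,
    dc_window: int = DEFAULT_DC_WINDOW,
) -> tuple[list[tuple[RawPlayerTable, list[InjuryEvent]]], pd.DataFrame]:
    """Apply the inclusion criteria; return (included, exclusion report).

    A player is retained iff (a) at least one injury has its onset between
    occasion ``dc_window`` and ``T - 7``, and (b) no factor is missing a
    fraction strictly greater than *max_missing* of its values. The report
    lists each excluded player with the rule(s) triggered.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    included = []
    report_rows = []
    for table, injuries in cohort:
        T = table.n_occasions
        reasons = []
        eligible = [e for e in injuries
                    if dc_window <= e.onset_occasion <= T - 7]
        if not eligible:
            reasons.append("no_eligible_injury")
        fractions = _missing_fractions(table)
        too_missing = fractions[fractions > max_missing]
        if len(too_missing):
            worst = too_missing.idxmax()
            reasons.append(
                f"missing_fraction_exceeded:{worst}={too_missing.max():.3f}")
        if reasons:
            report_rows.append({
                "player_id": table.player_id,
                "n_occasions": T,
                "n_injuries": len(injuries),
                "rule": ";".join(reasons),
            })
        else:
            included.append((table, injuries))
    report = pd.DataFrame(
        report_rows, columns=["player_id", "n_occasions", "n_injuries", "rule"])
    return included, report


def impute_missing(table: RawPlayerTable,
                   method: str = "linear") -> RawPlayerTable:
    """Fill missing values; default is per-factor linear interpolation.

    Interpolation runs over (occasion, session) order within each factor,
    with nearest-edge fill at the series boundaries, so the result is
    deterministic and stays inside the observed value hull. A factor with no
    observed value at all cannot be imputed and raises.
    """
    if method != "linear":
        raise ValueError(f"unknown imputation method {method!r}")
    out = table.copy()
    df = out.data.sort_values(["factor", "occasion", "session"])
    filled = []
    for factor, group in df.groupby("factor", sort=False):
        if group["value"].isna().all():
            raise ValueError(
                f"player {table.player_id}: factor {factor!r} is entirely "
                "missing and cannot be imputed")
        v = group["value"].interpolate(method="linear", limit_direction="both")
        filled.append(group.assign(value=v))
    out.data = (pd.concat(filled)
                .sort_values(["occasion", "session", "factor"])
                .reset_index(drop=True))
    return out


def build_daily_factors(table: RawPlayerTable) -> RawPlayerTable:
    """Collapse sessions into one row per (occasion, factor).

    sRPE is built per session as exertion x duration (minutes) and summed
    across the day's sessions, as are the other session factors; self-reports
    answered once per day are averaged if duplicated. The output contains the
    analysis factor set (``exertion`` is consumed into ``srpe``).
    """
    df = table.data
    wide = df.pivot_table(index=["occasion", "session"], columns="factor",
                          values="value", aggfunc="mean")
    if "exertion" in wide.columns:
        if "duration" not in wide.columns:
            raise ValueError("exertion present without duration; cannot build sRPE")
        bad = wide["exertion"].notna() & wide["duration"].isna()
        if bad.any():
            occ = int(wide.index[bad.argmax()][0])
            raise ValueError(
                f"player {table.player_id}: RPE reported without a session "
                f"duration on occasion {occ}")
        wide["srpe"] = wide["exertion"] * wide["duration"]

    rows = []
    for factor in wide.columns:
        if factor == "exertion":
            continue
        per_occ = wide[factor].groupby(level="occasion")
        if factor in SESSION_FACTORS or factor == "srpe":
            daily = per_occ.sum(min_count=1)
        else:
            daily = per_occ.mean()
        rows.append(pd.DataFrame({
            "occasion": daily.index, "session": 1,
            "factor": factor, "value": daily.to_numpy(),
        }))
    data = (pd.concat(rows, ignore_index=True)
            .sort_values(["occasion", "factor"])
            .reset_index(drop=True))
    return RawPlayerTable(table.player_id, data)


def normalize_factors(
    table: RawPlayerTable,
    scale_specs: dict[str, ScaleSpec] | None = None,
    injuries: list[InjuryEvent] | None = None,
) -> AthleteSeries:
    """Normalize a complete daily table onto the analysis scales.

    VAS factors are divided by 100, CRS factors by 20, and open-ended factors
    by the player's own maximum for that factor (which must be positive).
    """
    specs = dict(scale_specs or DEFAULT_SCALES)
    injuries = list(injuries or [])
    wide = table.data.pivot_table(index="occasion", columns="factor",
                                  values="value", aggfunc="mean")
    wide = wide.reindex(np.arange(1, table.n_occasions + 1))
    if wide.isna().any().any():
        raise ValueError(
            f"player {table.player_id}: table has missing values; impute first")
    for factor in wide.columns:
        if factor not in specs:
            raise KeyError(f"no scale specification for factor {factor!r}")
        spec = specs[factor]
        if spec.normalization == "divide_by_100":
            wide[factor] = wide[factor] / 100.0
        elif spec.normalization == "divide_by_20":
            wide[factor] = wide[factor] / 20.0
        else:  # divide_by_individual_max
            fmax = float(wide[factor].max())
            if fmax <= 0:
                raise ValueError(
                    f"player {table.player_id}: factor {factor!r} has no "
                    "positive value; individual maximum is undefined")
            wide[factor] = wide[factor] / fmax
    order = [f for f in ANALYSIS_FACTORS if f in wide.columns]
    order += [f for f in wide.columns if f not in order]
    wide = wide[order]
    wide.columns.name = None

    mask = pd.Series(False, index=wide.index, name="injured")
    for event in injuries:
        occ = [o for o in event.period if o in mask.index]
        mask.loc[occ] = True
    return AthleteSeries(
        player_id=table.player_id,
        values=wide,
        scale_specs={f: specs[f] for f in wide.columns},
        injuries=injuries,
        injured_mask=mask,
    )


def preprocess_player(
    table: RawPlayerTable,
    injuries: list[InjuryEvent],
    scale_specs: dict[str, ScaleSpec] | None = None,
    imputation: str = "linear",
) -> AthleteSeries:
    """Impute, aggregate to daily factors and normalize one player."""
    imputed = impute_missing(table, method=imputation)
    daily = build_daily_factors(imputed)
    return normalize_factors(daily, scale_specs, injuries)
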