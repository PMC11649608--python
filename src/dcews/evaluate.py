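"""Explanatory-performance evaluation of CCP warning signals against injuries.

Implements the proof-of-concept counting rules:

* an injury is analysis-eligible when its onset lies between occasion ``m``
  (the DC window, default 7) and the last 7 occasions;
* for each eligible injury, the ``W`` occasions immediately before onset form
  its pre-injury window (onset itself excluded); at least one CCP inside the
  window counts the injury as one true positive, none as one false negative —
  never more than one either way;
* window occasions are removed from the false-positive / true-negative pool in
  both cases, as are all injured (time-loss) occasions and the first ``m - 1``
  occasions where DC is undefined; every remaining occasion with a CCP is a
  false positive, without one a true negative;
* sensitivity, specificity and accuracy are computed per player and averaged
  across players; precision, recall and F1 are pooled over the summed counts
  (the data are heavily imbalanced, so F1 complements the per-player rates);
* the pre-injury window length is optimized stepwise over 1..10: stop at the
  first W that does not improve on its predecessor and keep the previous one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import CCPSeries, PeakMatrix
from .scales import DEFAULT_SCALES, ScaleSpec
from .simulate import InjuryEvent

__all__ = [
    "InjuryOutcome",
    "ConfusionCounts",
    "MetricsSummary",
    "WindowSearchResult",
    "AttributionTable",
    "eligible_injuries",
    "classify_occasions",
    "player_metrics",
    "cohort_summary",
    "optimize_ews_window",
    "attribute_factors",
]

DEFAULT_DC_WINDOW = 7
TAIL_MARGIN = 7
DEFAULT_W_RANGE = range(1, 11)


@dataclass(frozen=True)
class InjuryOutcome:
    """Per-injury classification detail."""

    event: InjuryEvent
    window: tuple[int, ...]          # occasions scanned (after exclusions)
    hit: bool
    ccp_occasions: tuple[int, ...]   # CCP occasions inside the window


@dataclass
class ConfusionCounts:
    """Per-player confusion counts under the stated counting rules."""

    player_id: str
    tp: int
    fp: int
    tn: int
    fn: int
    window_w: int
    eligible_injuries: int
    excluded_occasions: int
    unevaluable: list[InjuryEvent] = field(default_factory=list)
    outcomes: list[InjuryOutcome] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fn != self.eligible_injuries:
            raise ValueError("TP + FN must equal the evaluated eligible injuries")


@dataclass
class MetricsSummary:
    """Cohort metrics: per-player means plus pooled precision / recall / F1."""

    per_player: pd.DataFrame = field(repr=False)
    mean_sensitivity: float       # percent
    mean_specificity: float       # percent
    mean_accuracy: float          # percent
    pooled_precision: float       # in [0, 1]
    pooled_recall: float          # in [0, 1]
    pooled_f1: float              # in [0, 1]
    window_w: int
    total_tp: int
    total_fp: int
    total_tn: int
    total_fn: int
    mean_injuries_per_player: float


@dataclass
class WindowSearchResult:
    """Outcome of the stepwise pre-injury-window search."""

    table: pd.DataFrame = field(repr=False)  # one row per W in the range
    chosen_w: int
    trace: list[str] = field(default_factory=list)


@dataclass
class AttributionTable:
    """Which factors drive the true-positive warning signals."""

    factor_counts: pd.Series = field(repr=False)
    injury_labels: pd.DataFrame = field(repr=False)


def eligible_injuries(injuries: list[InjuryEvent], T: int,
                      m: int = DEFAULT_DC_WINDOW) -> list[InjuryEvent]:
    """Injuries with onset in ``[m, T - 7]`` (others cannot be evaluated)."""
    return [e for e in injuries
            if m <= e.onset_occasion <= T - TAIL_MARGIN]


def classify_occasions(ccp: CCPSeries, injuries: list[InjuryEvent],
                       injured_mask: pd.Series, W: int,
                       m: int = DEFAULT_DC_WINDOW) -> ConfusionCounts:
    """Confusion counts of one player for pre-injury window length *W*.

    The window of an injury is ``[onset - W, onset - 1]`` minus occasions
    belonging to an earlier injury's time-loss period; a window that is
    swallowed entirely by a previous injury period makes that injury
    unevaluable (reported, not counted). Window occasions leave the FP/TN
    pool whether or not the injury was detected.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    T = ccp.n_occasions
    ccp_flags = ccp.ccp
    injured = set(injured_mask.index[injured_mask])

    eligibles = sorted(eligible_injuries(injuries, T, m),
                       key=lambda e: e.onset_occasion)
    tp = fn = 0
    window_occasions: set[int] = set()
    unevaluable: list[InjuryEvent] = []
    outcomes: list[InjuryOutcome] = []
    for event in eligibles:
        onset = event.onset_occasion
        raw = [o for o in range(onset - W, onset) if o >= 1]
        effective = [o for o in raw if o not in injured]
        if not effective:
            unevaluable.append(event)
            continue
        window_occasions.update(raw)
        hits = tuple(o for o in effective
                     if o >= m and bool(ccp_flags.get(o, False)))
        if hits:
            tp += 1
        else:
            fn += 1
        outcomes.append(InjuryOutcome(event, tuple(effective), bool(hits), hits))

    pool = [o for o in range(m, T + 1)
            if o not in window_occasions and o not in injured]
    fp = sum(bool(ccp_flags.get(o, False)) for o in pool)
    tn = len(pool) - fp
    return ConfusionCounts(
        player_id=ccp.player_id, tp=tp, fp=fp, tn=tn, fn=fn, window_w=W,
        eligible_injuries=tp + fn, excluded_occasions=T - len(pool),
        unevaluable=unevaluable, outcomes=outcomes)


def player_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity and accuracy (percent) of one player.

    Ratios with a zero denominator are NaN and are excluded from cohort
    averaging rather than imputed.
    """
    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    total = counts.tp + counts.tn + counts.fp + counts.fn
    return {
        "player_id": counts.player_id,
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn),
        "specificity": ratio(counts.tn, counts.tn + counts.fp),
        "accuracy": ratio(counts.tp + counts.tn, total),
    }


def cohort_summary(all_counts: list[ConfusionCounts]) -> MetricsSummary:
    """Per-player means plus pooled precision / recall / F1 over summed counts."""
    if not all_counts:
        raise ValueError("need at least one player")
    ws = {c.window_w for c in all_counts}
    if len(ws) > 1:
        raise ValueError("confusion counts use different window lengths")
    per_player = pd.DataFrame([player_metrics(c) for c in all_counts])
    tp = sum(c.tp for c in all_counts)
    fp = sum(c.fp for c in all_counts)
    tn = sum(c.tn for c in all_counts)
    fn = sum(c.fn for c in all_counts)
    precision = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    recall = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    if tp == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    with np.errstate(invalid="ignore"):
        means = per_player[["sensitivity", "specificity", "accuracy"]].mean(
            skipna=True)
    return MetricsSummary(
        per_player=per_player,
        mean_sensitivity=float(means["sensitivity"]),
        mean_specificity=float(means["specificity"]),
        mean_accuracy=float(means["accuracy"]),
        pooled_precision=float(precision),
        pooled_recall=float(recall),
        pooled_f1=float(f1),
        window_w=ws.pop(),
        total_tp=tp, total_fp=fp, total_tn=tn, total_fn=fn,
        mean_injuries_per_player=(tp + fn) / len(all_counts),
    )


_OBJECTIVES = {
    "sensitivity": lambda s: s.mean_sensitivity,
    "f1": lambda s: s.pooled_f1,
    "accuracy": lambda s: s.mean_accuracy,
}


def _search_key(summary: MetricsSummary, objective: str) -> tuple[float, float]:
    v = _OBJECTIVES[objective](summary)
    spec = summary.mean_specificity
    return (-math.inf if math.isnan(v) else v,
            -math.inf if math.isnan(spec) else spec)


def optimize_ews_window(
    players: list[tuple[CCPSeries, list[InjuryEvent], pd.Series]],
    w_range: range = DEFAULT_W_RANGE,
    objective: str = "sensitivity",
    m: int = DEFAULT_DC_WINDOW,
) -> WindowSearchResult:
    """Stepwise search for the optimal pre-injury window length.

    Cohort metrics are evaluated for W = 1, 2, ...; the search stops at the
    first W whose objective does not improve on its predecessor and keeps the
    previous W. Improvement is a strictly higher objective (default: cohort
    mean sensitivity), with equal objectives decided by strictly higher
    cohort mean specificity; otherwise the smaller W wins. The returned table
    covers the whole range regardless of where the search stopped.
    """
    if objective not in _OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    if len(w_range) == 0:
        raise ValueError("w_range must be non-empty")

    summaries: dict[int, MetricsSummary] = {}
    for W in w_range:
        counts = [classify_occasions(ccp, inj, mask, W, m)
                  for ccp, inj, mask in players]
        summaries[W] = cohort_summary(counts)

    ws = list(w_range)
    chosen = ws[0]
    trace = [f"W={ws[0]}: start"]
    for prev, cur in zip(ws[:-1], ws[1:]):
        if _search_key(summaries[cur], objective) > _search_key(summaries[prev],
                                                                objective):
            chosen = cur
            trace.append(f"W={cur}: improved, continue")
        else:
            trace.append(f"W={cur}: no improvement, keep W={prev}")
            chosen = prev
            break

    rows = []
    for W, s in summaries.items():
        rows.append({
            "W": W,
            "mean_sensitivity": s.mean_sensitivity,
            "mean_specificity": s.mean_specificity,
            "mean_accuracy": s.mean_accuracy,
            "pooled_f1": s.pooled_f1,
            "tp": s.total_tp, "fp": s.total_fp,
            "tn": s.total_tn, "fn": s.total_fn,
        })
    return WindowSearchResult(table=pd.DataFrame(rows), chosen_w=chosen,
                              trace=trace)


def _label(categories: set[str], sources: set[str]) -> str:
    if not categories:
        return "none"
    if categories == {"psychological"}:
        return "psychological-only"
    if sources == {"sensor"}:
        return "sensor-only"
    if categories == {"physiological"}:
        return "physiological-only"
    if sources == {"self_report"}:
        return "self-report-only"
    return "combination"


def attribute_factors(
    peaks_by_player: dict[str, PeakMatrix],
    counts_by_player: dict[str, ConfusionCounts],
    scale_specs: dict[str, ScaleSpec] | None = None,
) -> AttributionTable:
    """Attribute true-positive warning signals to the factors behind them.

    For each true-positive injury, the factors with a significant DC peak on
    the CCP occasion(s) inside its pre-injury window are collected; each
    appearance increments that factor's count, and the injury is labelled by
    the categories its contributing factors span (psychological-only,
    physiological-only, self-report-only, sensor-only, or combination).
    """
    specs = scale_specs or DEFAULT_SCALES
    factor_counts: dict[str, int] = {}
    label_rows = []
    for player_id, counts in counts_by_player.items():
        peaks = peaks_by_player[player_id]
        for outcome in counts.outcomes:
            if not outcome.hit:
                continue
            contributing: set[str] = set()
            for occ in outcome.ccp_occasions:
                row = peaks.peaks.loc[occ]
                contributing.update(row.index[row])
            for factor in contributing:
                factor_counts[factor] = factor_counts.get(factor, 0) + 1
            cats = {specs[f].category for f in contributing}
            srcs = {specs[f].source for f in contributing}
            label_rows.append({
                "player_id": player_id,
                "onset_occasion": outcome.event.onset_occasion,
                "mechanism": outcome.event.mechanism,
                "label": _label(cats, srcs),
                "factors": ",".join(sorted(contributing)),
            })
    counts_series = pd.Series(factor_counts, dtype=int,
                              name="tp_ccp_appearances").sort_values(
                                  ascending=False)
    labels = pd.DataFrame(
        label_rows,
        columns=["player_id", "onset_occasion", "mechanism", "label", "factors"])
    return AttributionTable(factor_counts=counts_series, injury_labels=labels)
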