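"""End-to-end orchestration: simulate -> preprocess -> DC -> CCP -> evaluate.

``run_pipeline`` composes every stage on either a synthetic cohort or CSV
inputs, returns the in-memory results, and (optionally) writes the artifact
set — per-player DC / peak / CCP tables, the per-W window-search table, the
per-player confusion table, cohort metrics JSON, factor attribution, and a run
manifest tying every output to the configuration and seed. Identical
configuration and seed yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .complexity import DCMatrix, dynamic_complexity_series
from .evaluate import (
    AttributionTable,
    ConfusionCounts,
    MetricsSummary,
    WindowSearchResult,
    attribute_factors,
    classify_occasions,
    cohort_summary,
    optimize_ews_window,
)
from .peaks import CCPSeries, PeakMatrix, ccp_from_dc
from .preprocess import AthleteSeries, preprocess_player, select_players
from .simulate import InjuryEvent, RawPlayerTable, SimConfig, generate_cohort

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "export_resonance_diagram",
    "write_cohort_csv",
    "load_cohort_csv",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full analysis run.

    Either ``sim`` (a :class:`~dcews.simulate.SimConfig`) or the two input
    CSV paths must be provided. ``ews_window="auto"`` runs the stepwise 1..10
    search; an integer fixes the pre-injury window length.
    """

    sim: SimConfig | None = None
    monitoring_csv: str | Path | None = None
    injuries_csv: str | Path | None = None
    dc_window: int = 7
    alpha: float = 0.05
    ews_window: int | str = "auto"
    objective: str = "sensitivity"
    imputation: str = "linear"
    max_missing: float = 0.20
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.dc_window < 2:
            raise ValueError("dc_window must be >= 2")
        if isinstance(self.ews_window, int) and not 1 <= self.ews_window <= 10:
            raise ValueError("fixed ews_window must lie in 1..10")
        if isinstance(self.ews_window, str) and self.ews_window != "auto":
            raise ValueError("ews_window must be 'auto' or an integer in 1..10")
        if self.sim is None and (self.monitoring_csv is None
                                 or self.injuries_csv is None):
            raise ValueError("provide either a SimConfig or input CSV paths")


@dataclass
class PipelineResult:
    """Everything a run computed, keyed by player where applicable."""

    config: PipelineConfig
    exclusion_report: pd.DataFrame = field(repr=False)
    series: dict[str, AthleteSeries] = field(repr=False, default_factory=dict)
    dc: dict[str, DCMatrix] = field(repr=False, default_factory=dict)
    peaks: dict[str, PeakMatrix] = field(repr=False, default_factory=dict)
    ccp: dict[str, CCPSeries] = field(repr=False, default_factory=dict)
    window_search: WindowSearchResult | None = None
    confusion: dict[str, ConfusionCounts] = field(default_factory=dict)
    summary: MetricsSummary | None = None
    attribution: AttributionTable | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def chosen_w(self) -> int | None:
        if self.summary is not None:
            return self.summary.window_w
        return None


def write_cohort_csv(cohort: list[tuple[RawPlayerTable, list[InjuryEvent]]],
                     out_dir: str | Path) -> tuple[Path, Path]:
    """Write a cohort as ``monitoring.csv`` + ``injuries.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    monitoring = pd.concat(
        [t.data.assign(player_id=t.player_id) for t, _ in cohort],
        ignore_index=True,
    )[["player_id", "occasion", "session", "factor", "value"]]
    injuries = pd.DataFrame(
        [{"player_id": e.player_id, "onset_occasion": e.onset_occasion,
          "time_loss_occasions": e.time_loss_occasions,
          "mechanism": e.mechanism}
         for _, events in cohort for e in events],
        columns=["player_id", "onset_occasion", "time_loss_occasions",
                 "mechanism"])
    mon_path = out / "monitoring.csv"
    inj_path = out / "injuries.csv"
    monitoring.to_csv(mon_path, index=False)
    injuries.to_csv(inj_path, index=False)
    return mon_path, inj_path


def load_cohort_csv(monitoring_csv: str | Path, injuries_csv: str | Path,
                    ) -> list[tuple[RawPlayerTable, list[InjuryEvent]]]:
    """Read a cohort from the long-format monitoring and injury CSVs."""
    monitoring = pd.read_csv(monitoring_csv)
    injuries = pd.read_csv(injuries_csv)
    cohort = []
    for player_id, group in monitoring.groupby("player_id", sort=True):
        table = RawPlayerTable(
            str(player_id),
            group[["occasion", "session", "factor", "value"]].reset_index(
                drop=True))
        events = [
            InjuryEvent(str(r.player_id), int(r.onset_occasion),
                        int(r.time_loss_occasions), str(r.mechanism))
            for r in injuries[injuries["player_id"] == player_id].itertuples()
        ]
        events.sort(key=lambda e: e.onset_occasion)
        cohort.append((table, events))
    return cohort


def export_resonance_diagram(dc: DCMatrix, peaks: PeakMatrix, ccp: CCPSeries,
                             image_path: str | Path | None = None,
                             ) -> pd.DataFrame:
    """Long-format table behind the complexity-resonance / instability plots.

    One row per defined (occasion, factor): the DC value, whether that
    factor's DC was a significant peak, and whether the occasion was a CCP.
    Optionally renders a heat-map image (cosmetic; the table is the artifact).
    """
    if not dc.values.columns.equals(peaks.peaks.columns) or \
            not dc.values.index.equals(peaks.peaks.index) or \
            not dc.values.index.equals(ccp.count.index):
        raise ValueError("DC, peak and CCP tables are misaligned")
    long = dc.values.rename_axis("occasion").reset_index().melt(
        id_vars="occasion", var_name="factor", value_name="dc")
    long = long.dropna(subset=["dc"])
    peak_long = peaks.peaks.rename_axis("occasion").reset_index().melt(
        id_vars="occasion", var_name="factor", value_name="peak")
    table = long.merge(peak_long, on=["occasion", "factor"])
    table["ccp"] = table["occasion"].map(ccp.ccp).astype(bool)
    table = table.sort_values(["occasion", "factor"]).reset_index(drop=True)

    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax0, ax1) = plt.subplots(
            2, 1, figsize=(10, 6), sharex=True,
            gridspec_kw={"height_ratios": [4, 1]})
        grid = dc.values.T
        ax0.imshow(grid, aspect="auto", cmap="inferno",
                   extent=(1, dc.n_occasions, len(dc.factors), 0))
        ax0.set_yticks(np.arange(len(dc.factors)) + 0.5)
        ax0.set_yticklabels(dc.factors)
        ax0.set_title(f"Complexity resonance diagram — {dc.player_id}")
        ax1.plot(ccp.count.index, ccp.count, lw=0.8, color="grey")
        flagged = ccp.ccp[ccp.ccp]
        ax1.plot(flagged.index, ccp.count[flagged.index], "k.", ms=6)
        ax1.set_xlabel("occasion")
        ax1.set_ylabel("# peaks")
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
    return table


def _stage(name: str, player: str | None = None):
    where = f"stage {name!r}" + (f", player {player!r}" if player else "")
    return where


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order and (optionally) write the artifact set."""
    # --- inputs -----------------------------------------------------------
    try:
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            cohort = generate_cohort(sim)
        else:
            cohort = load_cohort_csv(config.monitoring_csv, config.injuries_csv)
    except Exception as err:
        raise RuntimeError(f"{_stage('input')}: {err}") from err

    manifest = {
        "package": "dcews",
        "version": __version__,
        "seed": config.seed,
        "dc_window": config.dc_window,
        "alpha": config.alpha,
        "ews_window": config.ews_window,
        "objective": config.objective,
        "imputation": config.imputation,
        "max_missing": config.max_missing,
        "simulated": config.sim is not None,
    }
    if config.sim is not None:
        manifest["sim_config"] = dataclasses.asdict(sim)

    included, report = select_players(cohort, config.max_missing,
                                      config.dc_window)
    result = PipelineResult(config=config, exclusion_report=report,
                            manifest=manifest)
    manifest["n_players_input"] = len(cohort)
    manifest["n_players_included"] = len(included)
    if not included:
        manifest["status"] = "empty_cohort_after_inclusion_filter"
        warnings.warn("no player passed the inclusion criteria", stacklevel=2)
        _write_outputs(result)
        return result
    manifest["status"] = "ok"

    # --- per-player stages ------------------------------------------------
    eval_inputs = []
    for table, injuries in included:
        pid = table.player_id
        try:
            series = preprocess_player(table, injuries,
                                       imputation=config.imputation)
            dc = dynamic_complexity_series(series, config.dc_window)
            peaks, ccp = ccp_from_dc(dc, alpha=config.alpha)
        except Exception as err:
            raise RuntimeError(f"{_stage('per-player', pid)}: {err}") from err
        result.series[pid] = series
        result.dc[pid] = dc
        result.peaks[pid] = peaks
        result.ccp[pid] = ccp
        eval_inputs.append((ccp, injuries, series.injured_mask))

    # --- evaluation -------------------------------------------------------
    try:
        if config.ews_window == "auto":
            search = optimize_ews_window(eval_inputs,
                                         objective=config.objective,
                                         m=config.dc_window)
            result.window_search = search
            W = search.chosen_w
        else:
            W = int(config.ews_window)
        confusions = [classify_occasions(ccp, inj, mask, W, config.dc_window)
                      for ccp, inj, mask in eval_inputs]
        result.confusion = {c.player_id: c for c in confusions}
        result.summary = cohort_summary(confusions)
        result.attribution = attribute_factors(result.peaks, result.confusion)
    except Exception as err:
        raise RuntimeError(f"{_stage('evaluation')}: {err}") from err
    manifest["chosen_w"] = W

    _write_outputs(result)
    return result


def _summary_dict(s: MetricsSummary) -> dict:
    return {
        "window_w": s.window_w,
        "mean_sensitivity_pct": s.mean_sensitivity,
        "mean_specificity_pct": s.mean_specificity,
        "mean_accuracy_pct": s.mean_accuracy,
        "pooled_precision": s.pooled_precision,
        "pooled_recall": s.pooled_recall,
        "pooled_f1": s.pooled_f1,
        "total_tp": s.total_tp, "total_fp": s.total_fp,
        "total_tn": s.total_tn, "total_fn": s.total_fn,
        "mean_injuries_per_player": s.mean_injuries_per_player,
    }


def _write_outputs(result: PipelineResult) -> None:
    out_dir = result.config.out_dir
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.exclusion_report.to_csv(out / "exclusions.csv", index=False)
    for pid, dc in result.dc.items():
        dc.values.to_csv(out / f"dc_{pid}.csv")
        table = export_resonance_diagram(dc, result.peaks[pid],
                                         result.ccp[pid])
        table.to_csv(out / f"resonance_{pid}.tsv", sep="\t", index=False)
    if result.window_search is not None:
        result.window_search.table.to_csv(out / "window_search.csv",
                                          index=False)
    if result.confusion:
        rows = []
        for pid, c in result.confusion.items():
            series = result.series[pid]
            rows.append({
                "player_id": pid,
                "n_measurements": series.n_occasions,
                "n_eligible_injuries": c.eligible_injuries,
                "time_loss_occasions": sum(e.time_loss_occasions
                                           for e in series.injuries),
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                **{k: v for k, v in player_metrics_row(c).items()
                   if k != "player_id"},
            })
        pd.DataFrame(rows).to_csv(out / "confusion.csv", index=False)
    if result.summary is not None:
        (out / "metrics.json").write_text(
            json.dumps(_summary_dict(result.summary), indent=2,
                       allow_nan=True))
    if result.attribution is not None:
        result.attribution.factor_counts.rename_axis("factor").to_csv(
            out / "attribution_factors.csv")
        result.attribution.injury_labels.to_csv(
            out / "attribution_injuries.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def player_metrics_row(counts: ConfusionCounts) -> dict[str, float]:
    from .evaluate import player_metrics
    return player_metrics(counts)
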