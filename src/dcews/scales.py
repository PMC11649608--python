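"""Measurement-scale metadata for the monitored factors.

Each monitored factor lives on one of three raw scales:

* VAS — visual analogue scale, 0–100 (self-reports such as motivation or mood);
* CRS — category-ratio scale, 6–20 (recovery, perceived exertion);
* open-ended non-negative sensor counts (distance in metres, number of sprints,
  duration in minutes, seconds spent in heart-rate zone 5) and the derived
  internal-load factor sRPE (exertion x duration).

Analysis happens on a normalized scale: VAS values are divided by 100, CRS
values by 20, and open-ended factors by the individual's per-factor maximum.
The *theoretical* normalized range (``norm_max - norm_min``) is the scale
range ``s`` used by the distribution measure downstream — 0.7 for CRS
(6/20 .. 20/20), 1.0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ScaleSpec",
    "DEFAULT_SCALES",
    "RAW_FACTORS",
    "ANALYSIS_FACTORS",
    "SESSION_FACTORS",
    "SELF_REPORT_ONCE_FACTORS",
    "scale_spec",
]

VALID_NORMALIZATIONS = frozenset(
    {"divide_by_100", "divide_by_20", "divide_by_individual_max"}
)
VALID_CATEGORIES = frozenset({"psychological", "physiological"})
VALID_SOURCES = frozenset({"self_report", "sensor"})


@dataclass(frozen=True)
class ScaleSpec:
    """Per-factor measurement metadata.

    Parameters
    ----------
    factor
        Factor name as used in long-format tables.
    raw_min, raw_max
        Theoretical raw bounds. ``raw_max=None`` marks an open-ended factor
        normalized by the individual's observed maximum.
    normalization
        One of ``divide_by_100``, ``divide_by_20``, ``divide_by_individual_max``.
    norm_min, norm_max
        Theoretical bounds after normalization.
    category
        ``psychological`` or ``physiological`` (attribution axis 1).
    source
        ``self_report`` or ``sensor`` (attribution axis 2).
    """

    factor: str
    raw_min: float
    raw_max: float | None
    normalization: str
    norm_min: float
    norm_max: float
    category: str
    source: str

    def __post_init__(self) -> None:
        if self.normalization not in VALID_NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if not self.norm_min < self.norm_max:
            raise ValueError("norm_min must be strictly below norm_max")
        if self.raw_max is not None and not self.raw_min < self.raw_max:
            raise ValueError("raw_min must be strictly below raw_max")

    @property
    def scale_range(self) -> float:
        """Theoretical normalized range ``s = norm_max - norm_min``."""
        return self.norm_max - self.norm_min


def _vas(factor: str) -> ScaleSpec:
    return ScaleSpec(factor, 0.0, 100.0, "divide_by_100", 0.0, 1.0,
                     "psychological", "self_report")


def _crs(factor: str) -> ScaleSpec:
    return ScaleSpec(factor, 6.0, 20.0, "divide_by_20", 0.3, 1.0,
                     "physiological", "self_report")


def _sensor(factor: str) -> ScaleSpec:
    return ScaleSpec(factor, 0.0, None, "divide_by_individual_max", 0.0, 1.0,
                     "physiological", "sensor")


#: Scale metadata for every factor appearing in raw or daily tables.
#: ``exertion`` (session RPE, CRS) only exists pre-aggregation; ``srpe``
#: (exertion x duration, open-ended) replaces it in the analysis set.
DEFAULT_SCALES: dict[str, ScaleSpec] = {
    s.factor: s
    for s in [
        _crs("recovery"),
        _vas("self_efficacy"),
        _vas("motivation"),
        _vas("mood"),
        _sensor("distance"),
        _sensor("sprints"),
        _sensor("duration"),
        _sensor("hr_zone5"),
        _crs("exertion"),
        ScaleSpec("srpe", 0.0, None, "divide_by_individual_max", 0.0, 1.0,
                  "physiological", "self_report"),
        _vas("perceived_performance"),
        _vas("enjoyment"),
    ]
}

#: Factors present in raw monitoring tables (one row per occasion/session).
RAW_FACTORS: tuple[str, ...] = (
    "recovery", "self_efficacy", "motivation", "mood",
    "distance", "sprints", "duration", "hr_zone5",
    "exertion", "perceived_performance", "enjoyment",
)

#: The 11 factors entering the Dynamic Complexity analysis.
ANALYSIS_FACTORS: tuple[str, ...] = (
    "recovery", "self_efficacy", "motivation", "mood",
    "distance", "sprints", "duration", "hr_zone5",
    "srpe", "perceived_performance", "enjoyment",
)

#: Session-level factors: measured per training session / match and summed
#: into a daily value when there is more than one session on an occasion.
SESSION_FACTORS: tuple[str, ...] = (
    "distance", "sprints", "duration", "hr_zone5", "exertion",
)

#: Self-reports answered once per occasion (averaged if duplicated).
SELF_REPORT_ONCE_FACTORS: tuple[str, ...] = (
    "recovery", "self_efficacy", "motivation", "mood",
    "perceived_performance", "enjoyment",
)


def scale_spec(factor: str) -> ScaleSpec:
    """Look up the default :class:`ScaleSpec` for *factor*."""
    try:
        return DEFAULT_SCALES[factor]
    except KeyError:
        raise KeyError(f"no scale specification for factor {factor!r}") from None
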