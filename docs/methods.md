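# Methods

This note records the model, the measurement conventions, the defaults and
the numerical choices behind `dcews`, and what the synthetic-data tests do
and do not establish.

## Model and assumptions

The package treats an athlete as a complex dynamic system observed through
11 daily factors: six self-reports on visual-analogue scales (self-efficacy,
motivation, mood, perceived performance, enjoyment) or category-ratio scales
(recovery, exertion), four sensor-derived load factors (distance, sprints,
session duration, seconds in heart-rate zone 5), and the internal-load
composite sRPE = exertion × duration, summed over a day's sessions. Injuries
are modeled as phase transitions preceded — sometimes — by a short period of
critical fluctuations. The analysis does not assume stationarity, a
parametric noise model, or linear factor interactions; it only assumes that
destabilization expresses itself as increased, scattered variability that
the Dynamic Complexity index can pick up within a 7-occasion window.

## Measurement scales and normalization

Analysis happens on normalized scales: VAS / 100, CRS / 20, open-ended
factors divided by the individual's per-factor maximum. Two consequences
matter downstream:

* the *theoretical* normalized range `s = norm_max − norm_min` enters both F
  and D. For CRS factors `s = 0.7` (6/20 … 20/20), not the observed range;
  using the observed range would make DC drift with the athlete's answering
  style.
* dividing open-ended factors by the individual maximum makes DC comparable
  across athletes but ties the normalization to the realized data; a single
  extreme session compresses the rest of that factor's series.

## Dynamic Complexity: formulas and edge rules

`F = [Σ_segments |Δvalue| / Δoccasions] / (s · (m − 1))`, summed over the
maximal monotone segments between turning points. Plateau rule: runs of
equal consecutive values are collapsed when determining direction; when the
direction reverses across a plateau, the turning point is the plateau's
*last* index. This keeps every segment's mean slope well defined and is
deterministic and oracle-checkable. It is the one place where F is not
time-reversal symmetric (a direction-reversing multi-point plateau splits
differently when read backwards); for continuous-valued data ties have
probability zero, and the invariance suite therefore fuzzes continuous
windows.

`D = 1 − Σ_{i<j} max(0, d_ideal − (y(j) − y(i))) / Σ_{i<j} d_ideal` over the
sorted window, with `d_ideal(i,j) = (j−i)·s/(m−1)`. Only shortfalls count:
gaps wider than ideal are not rewarded. D = 1 exactly when adjacent sorted
gaps all equal `s/(m−1)` (telescoping forces equality), i.e. an equidistant
full-range spread; D = 0 for a constant window.

DC = F × D is assigned to the window's **last** occasion (trailing
alignment), so the series is defined from occasion m = 7 onward — matching
an analysis that "starts on day seven". Both measures are exactly bounded in
[0, 1] by construction.

## Significance testing

Both test stages standardize over the player's entire defined series
(sample SD, n − 1) and flag one-sidedly at z > 1.645 (α = 0.05). Whole-series
standardization matches the post-hoc design and is deterministic; a
trailing running-baseline mode (`baseline="running"`) is available for
pseudo-prospective use but is measurably worse here: short baselines produce
spurious early flags that both overshoot the window search and cost
sensitivity. A zero standard deviation (constant DC or constant counts)
yields no peaks rather than an error. No multiple-testing correction is
applied across factors, deliberately: the second-stage count test is the
aggregation step.

## Evaluation rules and their edge cases

* Eligibility: onset in `[m, T − 7]`. Both margins follow from the 7-point
  window — earlier injuries have no defined DC before them, later ones no
  room for the post-onset exclusion.
* The pre-injury window `[onset − W, onset − 1]` excludes the onset itself.
  Occasions inside an *earlier* injury's time-loss period are dropped from
  the window (not shifted); a window swallowed whole is reported as
  unevaluable rather than silently counted.
* Window occasions leave the FP/TN pool whether or not the injury was
  detected (symmetric exclusion keeps the pool independent of the outcome).
* Per-player ratios with zero denominators are NaN and excluded from cohort
  means, not imputed as zero. Pooled F1 is defined as 0 when ΣTP = 0.
* The stepwise window search compares (objective, mean specificity)
  lexicographically and stops at the first W that does not strictly improve;
  the objective defaults to cohort mean sensitivity and is configurable
  (sensitivity | f1 | accuracy).

## Synthetic cohort: what it emulates and what it does not

Defaults state a cohort of 23 players observed 155–430 times on 11 factors,
~0.8 injuries per 100 occasions (≈ 2.5 per player over a season pair),
time-loss of 2–21 occasions, ≤ 5 % missing values (MCAR), AR(1) baselines
with coefficient 0.4, and field-plausible marginals (e.g. VAS self-reports
≈ 65–72 ± 12, sessions 75 ± 15 min, 5.5 ± 1.5 km, 12 ± 5 sprints, 300 ±
150 s in zone 5). None of these marginals is calibrated against the
restricted study data — they are stated, reasonable values, and tests built
on them establish *mechanical* correctness and parameter recovery, not
empirical injury statistics.

Destabilization is injected into the `lead` occasions before an onset as an
additive, sign-alternating perturbation of amplitude `(gain − 1) · σ_f`
around the running values, clipped to scale bounds (`gain = 1` is exactly
the identity). It raises both F (alternation) and D (spread) and is
controlled by a single effect-size knob. Real pre-injury destabilization, if
it exists, has unknown shape, lead and factor loading; a green parameter-
recovery test says the pipeline finds *this* kind of signal, not that
injuries emit it.

Injury placement keeps onsets out of the first and last 7 occasions (every
generated injury is analysis-eligible) and keeps each pre-onset lead window
clear of earlier injury periods, since the injected turbulence belongs to
the healthy phase. Poisson-drawn events that no longer fit a crowded series
are dropped rather than forced.

## Window recovery is attenuated by one occasion

With trailing windows and whole-series z-thresholds, the first turbulent
occasion (`onset − lead`) contributes exactly one turbulent point to its DC
window. Its DC elevation is capped (≈ 0.1 under full-scale alternation,
since one extreme point yields two short segments and a modest spread) while
the turbulence itself inflates the series SD and pushes the critical value
far above that. Detection therefore needs at least two turbulent points in a
window, and the stepwise search recovers `W = lead − 1`, not `lead` — stably
so (9 of 10 seeds at lead 6, gain 10). An idealized detector flagging any
window that covers ≥ k turbulent points recovers `lead − (k − 1)`, confirming
the mechanism. The acceptance test asserting exact lead recovery is left
failing on purpose; the search logic itself, tested on directly constructed
CCP flags covering the full pre-onset band, recovers the lead exactly.

## Imputation

Per-factor linear interpolation over (occasion, session) order with
nearest-edge fill: deterministic, bounded by the observed hull, and recorded
in the run manifest. This replaces chained-equations multiple imputation,
whose between-imputation variance the downstream z-tests could not use
anyway. The interface is pluggable (`method=` parameter) for alternatives.

## Known limitations

* Interpolation smooths through missing turbulent occasions and mildly
  damps DC right where it matters most; at ≤ 5 % missingness the effect is
  negligible, near the 20 % inclusion cap it is not.
* The attribution labels depend on the category/source tags of the factor
  set; sRPE is tagged physiological / self-report, which is a convention.
* Calendar structure (matches vs. trainings, weekends, congested fixture
  periods) is not emulated; occasions are treated as equally spaced.
* The evaluation is explanatory, not predictive: thresholds are standardized
  on the full series, and no out-of-sample validation is attempted.
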