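# dcews — Dynamic Complexity early-warning signals for athlete monitoring

`dcews` detects *critical fluctuations* — short windows of turbulent,
scattered variability — in multivariate athlete-monitoring time series and
evaluates them as early warning signals (EWS) of sports injuries. The idea
comes from complex dynamic systems theory: an athlete's psychophysiological
state is a system with relatively stable attractor states, and an injury is a
phase transition out of a healthy state. Right before such a transition the
system destabilizes, and its observable factors fluctuate more heavily than
usual. If that destabilization can be measured, it can warn the practitioner
days before the injury.

The package is a library for sports scientists and methodologists who want to
run, probe or extend this analysis. Because the kind of monitoring data it
targets (daily self-reports plus GPS / heart-rate sensor output of team-sport
athletes) is typically access-restricted, `dcews` ships a synthetic-cohort
generator that reproduces the statistical shape of such data — including,
optionally, injected pre-injury turbulence with a known lead time, so the
whole pipeline can be validated by parameter recovery.

## The method

**Dynamic Complexity.** Each monitored factor is normalized to its scale
(visual-analogue 0–100 scales divided by 100, category-ratio 6–20 scales
divided by 20, open-ended sensor factors divided by the individual's
maximum). In an overlapping moving window of m = 7 occasions (step 1) the
Dynamic Complexity index is

```
DC = F × D
F  = [ Σ over monotone segments |Δvalue| / Δoccasions ] / ( s · (m − 1) )
D  = 1 − Σ_{i<j} max(0, d_ideal(i,j) − (y(j) − y(i))) / Σ_{i<j} d_ideal(i,j)
```

where `s` is the factor's theoretical normalized range, `y(1..m)` the sorted
window and `d_ideal(i,j) = (j−i)·s/(m−1)` the pairwise gaps of a perfectly
equidistant full-scale spread. F is sensitive to the amplitude and frequency
of change (1 for full-scale alternation at every step), D to how evenly the
values cover the scale (1 exactly for an equidistant full-range spread); both
are 0 for a constant window. DC is assigned to the window's last occasion.

**Cumulative complexity peaks.** Two stacked one-sided z-tests (one-sided
because only *increased* fluctuation matters): occasions where a factor's DC
exceeds its series mean by more than 1.645 standard deviations are factor
peaks; the per-occasion count of simultaneous factor peaks is standardized
the same way, and significantly elevated counts are cumulative complexity
peaks (CCPs) — the warning signals.

**Evaluation.** For every analysis-eligible injury (onset between occasion 7
and the last 7 occasions), the W occasions before onset form its pre-injury
window: at least one CCP there counts one true positive, none counts one
false negative. Window and injury-period occasions leave the false-positive /
true-negative pool; every remaining occasion is classified by its CCP flag.
Sensitivity, specificity and accuracy are computed per player and averaged;
precision, recall and F1 are pooled over summed counts because the data are
heavily imbalanced. W itself is found by a stepwise search over 1..10 that
stops as soon as the cohort objective stops improving.

## Worked example

```python
from dcews import PipelineConfig, SimConfig, run_pipeline

sim = SimConfig(n_players=20, series_length_range=(300, 300), injury_rate=0.8,
                destabilization_fraction=1.0, destabilization_gain=10.0,
                destabilization_lead=6)
result = run_pipeline(PipelineConfig(sim=sim, seed=3))
s = result.summary
print(f"chosen W = {s.window_w}")
print(f"sensitivity {s.mean_sensitivity:.1f} %  "
      f"specificity {s.mean_specificity:.1f} %  F1 {s.pooled_f1:.3f}")
```

prints

```
chosen W = 5
sensitivity 100.0 %  specificity 99.8 %  F1 0.932
```

Every injury in this cohort is preceded by six occasions of high-gain
injected turbulence, so every one is detected (sensitivity 100 %); the
near-perfect specificity says warning signals rarely fire elsewhere; and the
stepwise search recovers the turbulence lead up to the structural
one-occasion attenuation (W = 5 for a lead of 6). On a null cohort
(`destabilization_fraction=0`) the same pipeline yields a mean per-player
specificity around 94–95 %: the ~5 % false-alarm rate implied by the
one-sided tests. The `examples/` scripts walk through each stage —
simulation, the DC measures on hand-picked windows, peak detection, the
window search and the full pipeline with its artifact export.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch on the default synthetic cohort
(23 players, 155–430 occasions each, 11 factors, sparse injuries, half of
them preceded by injected turbulence): generation, inclusion filtering,
imputation, daily aggregation, normalization, Dynamic Complexity, both
z-test stages, the stepwise window search and the cohort metrics. It prints
the headline numbers and writes the result JSON to `--out`.
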