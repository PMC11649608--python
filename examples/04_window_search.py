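"""Stepwise search for the optimal pre-injury warning window.

Builds a strongly destabilized cohort with a known 6-occasion turbulence
lead, evaluates the cohort confusion metrics for W = 1..10 and shows the
stepwise stopping rule at work.
"""

from dcews import SimConfig, generate_cohort, optimize_ews_window
from dcews.complexity import dynamic_complexity_series
from dcews.peaks import ccp_from_dc
from dcews.preprocess import preprocess_player, select_players

sim = SimConfig(n_players=12, series_length_range=(250, 300), injury_rate=0.8,
                destabilization_fraction=1.0, destabilization_gain=10.0,
                destabilization_lead=6, seed=21)
included, _ = select_players(generate_cohort(sim))

players = []
for table, injuries in included:
    series = preprocess_player(table, injuries)
    dc = dynamic_complexity_series(series, m=7)
    _, ccp = ccp_from_dc(dc)
    players.append((ccp, injuries, series.injured_mask))

result = optimize_ews_window(players, objective="sensitivity")
cols = ["W", "mean_sensitivity", "mean_specificity", "pooled_f1"]
print(result.table[cols].round(3).to_string(index=False))
print("\nstopping trace:")
for line in result.trace:
    print(" ", line)
print(f"\nchosen W = {result.chosen_w} (injected lead was "
      f"{sim.destabilization_lead})")

# Sensitivity saturates early, so the search advances on the specificity
# tie-break while the growing excluded window absorbs pre-onset warning
# signals. The recovered W sits one occasion below the injected lead: the
# first turbulent occasion contributes a single point to its trailing DC
# window and stays below the series-wide z-threshold.
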