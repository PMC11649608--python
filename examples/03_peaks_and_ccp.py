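"""From one player's series to cumulative complexity peaks.

Preprocesses a single simulated player, computes the DC matrix, runs the
two stacked one-sided z-tests and prints where warning signals fall
relative to the player's injuries.
"""

from dcews import SimConfig, generate_cohort
from dcews.complexity import dynamic_complexity_series
from dcews.peaks import ccp_from_dc
from dcews.preprocess import preprocess_player

config = SimConfig(n_players=1, series_length_range=(200, 200),
                   injury_rate=1.5, destabilization_fraction=1.0,
                   destabilization_gain=8.0, seed=13)
table, injuries = generate_cohort(config)[0]
series = preprocess_player(table, injuries)
dc = dynamic_complexity_series(series, m=7)
peaks, ccp = ccp_from_dc(dc, alpha=0.05)

print(f"{series.player_id}: {series.n_occasions} occasions, "
      f"{len(series.factors)} factors")
print(f"injury onsets: {[e.onset_occasion for e in injuries]}")
flagged = list(ccp.ccp[ccp.ccp].index)
print(f"cumulative complexity peaks at occasions: {flagged}")
for occ in flagged:
    row = peaks.peaks.loc[occ]
    print(f"  occasion {occ:3d}: {int(ccp.count.loc[occ])} simultaneous "
          f"factor peaks ({', '.join(row.index[row])})")

# With every injury preceded by injected turbulence, the CCPs cluster in the
# handful of occasions just before each onset; the factor list names which
# monitored signals carried the destabilization.
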