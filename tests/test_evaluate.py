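"""Counting rules, per-player and pooled metrics, window search, attribution."""

import math

import numpy as np
import pandas as pd
import pytest

from dcews import (
    ConfusionCounts,
    InjuryEvent,
    SimConfig,
    attribute_factors,
    classify_occasions,
    cohort_summary,
    dynamic_complexity_series,
    eligible_injuries,
    generate_cohort,
    optimize_ews_window,
    player_metrics,
    preprocess_player,
    select_players,
)
from dcews.peaks import PeakMatrix, ccp_from_dc

from _oracles import classify_oracle
from conftest import make_ccp


def injured_mask(T, injuries):
    idx = pd.RangeIndex(1, T + 1)
    mask = pd.Series(False, index=idx)
    for e in injuries:
        occ = [o for o in e.period if o <= T]
        mask.loc[occ] = True
    return mask


class TestEligibleInjuries:
    @pytest.mark.parametrize("onset, expected", [
        (5, False),    # before data point seven
        (96, False),   # within the last seven
        (50, True),
        (7, True),     # boundary: exactly at the DC window
        (93, True),    # boundary: T - 7
    ])
    def test_onset_eligibility(self, onset, expected):
        events = [InjuryEvent("P", onset, 2, "traumatic")]
        kept = eligible_injuries(events, T=100, m=7)
        assert bool(kept) is expected


class TestClassifyOccasions:
    def test_worked_example(self):
        """T=30, CCPs at 10 and 20, injury at 23 (time-loss 3), W=6.

        Window 17-22 contains the CCP at 20 -> one TP; the pool is occasions
        7-30 minus the window (6) and the injured period 23-25 (3), i.e. 15
        occasions, of which the CCP at 10 is the single FP.
        """
        injuries = [InjuryEvent("P", 23, 3, "traumatic")]
        ccp = make_ccp(30, [10, 20])
        counts = classify_occasions(ccp, injuries, injured_mask(30, injuries), W=6)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 0, 1, 14)
        assert counts.eligible_injuries == 1

    def test_no_ccp_counts_one_false_negative_not_six(self):
        injuries = [InjuryEvent("P", 23, 3, "traumatic")]
        ccp = make_ccp(30, [])
        counts = classify_occasions(ccp, injuries, injured_mask(30, injuries), W=6)
        assert (counts.tp, counts.fn, counts.fp) == (0, 1, 0)
        assert counts.tn == 15  # pool unchanged by the miss

    def test_saturated_ccp_series(self):
        injuries = [InjuryEvent("P", 23, 3, "traumatic")]
        ccp = make_ccp(30, list(range(7, 31)))
        counts = classify_occasions(ccp, injuries, injured_mask(30, injuries), W=6)
        assert (counts.tp, counts.fn, counts.tn) == (1, 0, 0)
        assert counts.fp == 15

    def test_window_drops_occasions_of_earlier_injury(self):
        # Earlier injury occupies 18-20; the W=6 window of the later injury
        # (18-23) shrinks to 21-23 and its CCP at 19 must not count.
        injuries = [InjuryEvent("P", 18, 3, "traumatic"),
                    InjuryEvent("P", 24, 2, "traumatic")]
        ccp = make_ccp(40, [19])
        counts = classify_occasions(ccp, injuries, injured_mask(40, injuries), W=6)
        # earlier injury window 12-17 has no CCP -> FN; later window 21-23
        # loses 18-20 (injured) so its CCP at 19 must not count -> FN
        assert (counts.tp, counts.fn) == (0, 2)

    def test_window_swallowed_by_previous_injury_is_unevaluable(self):
        injuries = [InjuryEvent("P", 15, 12, "overuse"),
                    InjuryEvent("P", 27, 2, "traumatic")]
        ccp = make_ccp(60, [])
        counts = classify_occasions(ccp, injuries, injured_mask(60, injuries), W=2)
        assert len(counts.unevaluable) == 1
        assert counts.unevaluable[0].onset_occasion == 27
        assert counts.eligible_injuries == 1  # only the evaluable one

    def test_conservation_identity(self):
        injuries = [InjuryEvent("P", 20, 4, "overuse"),
                    InjuryEvent("P", 40, 2, "traumatic")]
        ccp = make_ccp(60, [15, 36, 50])
        c = classify_occasions(ccp, injuries, injured_mask(60, injuries), W=5)
        assert c.tp + c.fn == c.eligible_injuries
        assert c.fp + c.tn == 60 - c.excluded_occasions


class TestMetrics:
    def test_sensitivity_19_of_64(self):
        c = ConfusionCounts("P", tp=19, fp=0, tn=0, fn=45, window_w=6,
                            eligible_injuries=64, excluded_occasions=0)
        m = player_metrics(c)
        assert m["sensitivity"] == pytest.approx(100 * 19 / 64)
        assert round(m["sensitivity"]) == 30

    def test_fifty_percent_and_undefined_specificity(self):
        c = ConfusionCounts("P", tp=1, fp=0, tn=0, fn=1, window_w=6,
                            eligible_injuries=2, excluded_occasions=0)
        m = player_metrics(c)
        assert m["sensitivity"] == 50.0
        assert math.isnan(m["specificity"])

    def test_undefined_metrics_excluded_from_cohort_means(self):
        a = ConfusionCounts("A", tp=1, fp=0, tn=0, fn=0, window_w=6,
                            eligible_injuries=1, excluded_occasions=0)
        b = ConfusionCounts("B", tp=0, fp=5, tn=5, fn=1, window_w=6,
                            eligible_injuries=1, excluded_occasions=0)
        s = cohort_summary([a, b])
        assert s.mean_sensitivity == pytest.approx((100.0 + 0.0) / 2)
        assert s.mean_specificity == pytest.approx(50.0)  # only player B defined

    def test_pooled_f1_from_study_scale_counts(self):
        counts = [ConfusionCounts("A", tp=19, fp=380, tn=5000, fn=45,
                                  window_w=6, eligible_injuries=64,
                                  excluded_occasions=0)]
        s = cohort_summary(counts)
        assert s.pooled_precision == pytest.approx(19 / 399)
        assert s.pooled_recall == pytest.approx(19 / 64)
        assert s.pooled_f1 == pytest.approx(38 / 463)
        assert round(s.pooled_f1, 2) == 0.08

    def test_f1_limits(self):
        perfect = ConfusionCounts("A", tp=3, fp=0, tn=10, fn=0, window_w=1,
                                  eligible_injuries=3, excluded_occasions=0)
        assert cohort_summary([perfect]).pooled_f1 == 1.0
        empty = ConfusionCounts("A", tp=0, fp=2, tn=10, fn=3, window_w=1,
                                eligible_injuries=3, excluded_occasions=0)
        assert cohort_summary([empty]).pooled_f1 == 0.0


class TestOptimizeWindow:
    def test_flat_metrics_choose_w1(self):
        injuries = [InjuryEvent("P", 30, 2, "overuse")]
        ccp = make_ccp(60, [29])  # hit for every W >= 1; pool never changes rank
        res = optimize_ews_window([(ccp, injuries, injured_mask(60, injuries))])
        assert res.chosen_w == 1

    def test_recovers_exact_lead_from_constructed_flags(self):
        """CCPs at every occasion of the 1..lead pre-onset band -> W = lead.

        Sensitivity saturates at W=1; the specificity tie-break advances the
        search while the excluded window absorbs pre-onset flags, and stops
        one step past the band.
        """
        lead = 4
        rng = np.random.default_rng(0)
        players = []
        for p in range(5):
            T = 120
            onsets = [30 + 40 * k + int(rng.integers(0, 5)) for k in range(2)]
            injuries = [InjuryEvent(f"P{p}", o, 3, "overuse") for o in onsets]
            flags = [o - off for o in onsets for off in range(1, lead + 1)]
            ccp = make_ccp(T, sorted(set(flags)), player_id=f"P{p}")
            players.append((ccp, injuries, injured_mask(T, injuries)))
        res = optimize_ews_window(players)
        assert res.chosen_w == lead
        assert (res.table["W"] == range(1, 11)).all()

    def test_end_to_end_recovery_is_attenuated_by_one_occasion(self):
        """Full pipeline on a strongly destabilized cohort recovers lead-1.

        The first turbulent occasion contributes a single point to its
        trailing DC window and stays below the series-wide z-threshold, so
        the stepwise search stops one occasion short of the injected lead.
        """
        chosen = []
        for seed in (0, 1, 2):
            sim = SimConfig(n_players=10, series_length_range=(250, 250),
                            injury_rate=0.8, destabilization_fraction=1.0,
                            destabilization_gain=10.0, destabilization_lead=4,
                            seed=seed)
            included, _ = select_players(generate_cohort(sim))
            players = []
            for table, injuries in included:
                series = preprocess_player(table, injuries)
                dc = dynamic_complexity_series(series, 7)
                _, ccp = ccp_from_dc(dc)
                players.append((ccp, injuries, series.injured_mask))
            chosen.append(optimize_ews_window(players).chosen_w)
        assert sum(w == 3 for w in chosen) >= 2


class TestAttribution:
    def _peaks(self, T, flags_by_factor):
        idx = pd.RangeIndex(1, T + 1)
        factors = list(flags_by_factor)
        peaks = pd.DataFrame(False, index=idx, columns=factors)
        for f, occs in flags_by_factor.items():
            peaks.loc[occs, f] = True
        defined = pd.DataFrame(True, index=idx, columns=factors)
        return PeakMatrix("P", peaks, defined, 0.05, 1.645)

    def _counts(self, ccp, injuries, T, W=6):
        return classify_occasions(ccp, injuries, injured_mask(T, injuries), W)

    @pytest.mark.parametrize("factors, label", [
        (("motivation", "mood"), "psychological-only"),
        (("sprints",), "sensor-only"),
        (("recovery", "distance"), "physiological-only"),
        (("mood", "recovery"), "self-report-only"),
        (("mood", "sprints"), "combination"),
    ])
    def test_category_labels(self, factors, label):
        T = 40
        injuries = [InjuryEvent("P", 30, 2, "overuse")]
        ccp = make_ccp(T, [27])
        peaks = self._peaks(T, {f: [27] for f in factors})
        counts = self._counts(ccp, injuries, T)
        table = attribute_factors({"P": peaks}, {"P": counts})
        assert table.injury_labels.loc[0, "label"] == label
        for f in factors:
            assert table.factor_counts[f] == 1

    def test_only_tp_windows_counted(self):
        T = 40
        injuries = [InjuryEvent("P", 30, 2, "overuse")]
        ccp = make_ccp(T, [10])  # CCP outside the window: a false positive
        peaks = self._peaks(T, {"sprints": [10]})
        counts = self._counts(ccp, injuries, T)
        table = attribute_factors({"P": peaks}, {"P": counts})
        assert table.injury_labels.empty
        assert table.factor_counts.empty


class TestAgainstOracle:
    def test_fuzzed_small_instances_match_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            T = int(rng.integers(15, 41))
            m = 7
            W = int(rng.integers(1, 11))
            flags = {int(o) for o in rng.choice(np.arange(m, T + 1),
                                                size=rng.integers(0, 8),
                                                replace=False)}
            injuries = []
            used = set()
            for _ in range(int(rng.integers(0, 4))):
                onset = int(rng.integers(1, T + 1))
                tl = int(rng.integers(0, 6))
                period = set(range(onset, min(onset + tl, T + 1)))
                if period & used or onset in used:
                    continue
                used |= period or {onset}
                injuries.append(InjuryEvent("P", onset, tl, "overuse"))
            injuries.sort(key=lambda e: e.onset_occasion)
            ccp = make_ccp(T, sorted(flags))
            mask = injured_mask(T, injuries)
            counts = classify_occasions(ccp, injuries, mask, W)
            ref = classify_oracle(flags, [(e.onset_occasion,
                                           e.time_loss_occasions)
                                          for e in injuries],
                                  set(mask[mask].index), W, m, T)
            got = {"tp": counts.tp, "fp": counts.fp, "tn": counts.tn,
                   "fn": counts.fn, "unevaluable": len(counts.unevaluable),
                   "pool": counts.fp + counts.tn}
            assert got == ref
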