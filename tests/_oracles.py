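"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: the fluctuation oracle
enumerates monotone segments from the list of non-zero steps, the
distribution oracle sums pairwise shortfalls in an explicit double loop, and
the classification oracle walks the time axis occasion by occasion.
"""

from __future__ import annotations


def fluctuation_oracle(window, norm_min: float, norm_max: float) -> float:
    """Sum of mean slope magnitudes of monotone segments, normalized."""
    v = [float(x) for x in window]
    m = len(v)
    s = norm_max - norm_min
    steps = [(i, v[i + 1] - v[i]) for i in range(m - 1)]
    nonzero = [(i, d) for i, d in steps if d != 0]
    if not nonzero:
        return 0.0
    bounds = [0]
    for (_, d1), (i2, d2) in zip(nonzero[:-1], nonzero[1:]):
        if (d1 > 0) != (d2 > 0):
            # first index of the reversing step == last index of the plateau
            bounds.append(i2)
    bounds.append(m - 1)
    total = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        total += abs(v[b] - v[a]) / (b - a)
    return total / (s * (m - 1))


def distribution_oracle(window, norm_min: float, norm_max: float) -> float:
    """Pairwise shortfall against the equidistant full-scale spread."""
    y = sorted(float(x) for x in window)
    m = len(y)
    s = norm_max - norm_min
    ideal_sum = 0.0
    shortfall_sum = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            ideal = (j - i) * s / (m - 1)
            actual = y[j] - y[i]
            ideal_sum += ideal
            if actual < ideal:
                shortfall_sum += ideal - actual
    return 1.0 - shortfall_sum / ideal_sum


def classify_oracle(ccp_occasions: set[int], injuries, injured: set[int],
                    W: int, m: int, T: int) -> dict:
    """Occasion-by-occasion reference for the confusion counting rules.

    *injuries* is a list of (onset, time_loss) tuples sorted by onset; only
    eligible ones (m <= onset <= T - 7) are evaluated.
    """
    eligible = [(o, tl) for o, tl in injuries if m <= o <= T - 7]
    tp = fn = unevaluable = 0
    in_window: set[int] = set()
    for onset, _ in eligible:
        raw = [o for o in range(onset - W, onset) if o >= 1]
        usable = [o for o in raw if o not in injured]
        if not usable:
            unevaluable += 1
            continue
        in_window.update(raw)
        if any(o in ccp_occasions and o >= m for o in usable):
            tp += 1
        else:
            fn += 1
    fp = tn = 0
    pool = 0
    for occ in range(1, T + 1):
        if occ < m or occ in injured or occ in in_window:
            continue
        pool += 1
        if occ in ccp_occasions:
            fp += 1
        else:
            tn += 1
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "unevaluable": unevaluable, "pool": pool}
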