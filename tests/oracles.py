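"""Independent brute-force oracles used to cross-check the implementations.

Each function re-derives a statistic by the most literal route available
(explicit loops, exhaustive enumeration, hand-worked tables) and stays
deliberately independent of the package's vectorized code paths.
"""

import itertools
import math


def ssgsea_brute(values, gene_ids, members, weight=0.25):
    """Literal single-sample running-sum enrichment for one sample."""
    n = len(gene_ids)
    order = sorted(range(n), key=lambda i: (-values[i], gene_ids[i]))
    in_set = [gene_ids[i] in members for i in order]
    rank_of_pos = [n - j for j in range(n)]
    denom_in = sum(rank_of_pos[j] ** weight for j in range(n) if in_set[j])
    denom_out = n - sum(in_set)
    es = p_in = p_out = 0.0
    for j in range(n):
        if in_set[j]:
            p_in += rank_of_pos[j] ** weight / denom_in
        else:
            p_out += 1.0 / denom_out
        es += p_in - p_out
    return es


def pearson_textbook(x, y):
    """Covariance over root-variance-product, written out longhand."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def auc_pair_counting(scores, labels):
    """Exhaustive Mann–Whitney count over all (positive, negative) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def fisher_enumeration(table):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def p_of(a_):
        return (
            math.comb(col1, a_)
            * math.comb(n - col1, row1 - a_)
            / math.comb(n, row1)
        )

    p_obs = p_of(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    return sum(
        p_of(a_) for a_ in range(lo, hi + 1) if p_of(a_) <= p_obs * (1 + 1e-9)
    )


def logrank_hand_table(time, event, group):
    """Event-by-event worked log-rank chi-square table."""
    times = sorted({t for t, e in zip(time, event) if e})
    O1 = E1 = V = 0.0
    for t in times:
        at_risk = [i for i, ti in enumerate(time) if ti >= t]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if group[i])
        d = sum(1 for i, ti in enumerate(time) if ti == t and event[i])
        d1 = sum(
            1 for i, ti in enumerate(time) if ti == t and event[i] and group[i]
        )
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


def hubs_sort_and_cut(degree_map, frac=0.05):
    """Top-fraction hub extraction by explicit sort with boundary ties."""
    k = math.ceil(frac * len(degree_map) - 1e-9)
    cut = sorted(degree_map.values(), reverse=True)[max(k, 1) - 1]
    return {n for n, d in degree_map.items() if d >= cut}
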