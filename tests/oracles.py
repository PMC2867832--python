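"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately share no code with the package implementations they check.
"""

from itertools import combinations
from math import comb

import numpy as np


def rank_sum_exact_p(treatment, control, alternative="greater"):
    """Exact rank-sum p by enumerating all rank assignments (no ties)."""
    treatment = list(treatment)
    control = list(control)
    pooled = sorted(treatment + control)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n, m = len(treatment), len(control)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in treatment)
    total = comb(n + m, n)
    all_ranks = list(range(1, n + m + 1))
    count_ge = sum(1 for c in combinations(all_ranks, n) if sum(c) >= observed)
    count_le = sum(1 for c in combinations(all_ranks, n) if sum(c) <= observed)
    if alternative == "greater":
        return count_ge / total
    if alternative == "less":
        return count_le / total
    return min(1.0, 2 * min(count_ge, count_le) / total)


def fisher_two_sided_p(table):
    """Two-sided Fisher p by full hypergeometric enumeration (point-prob rule)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = pmf(a)
    return sum(
        p for x in range(0, min(r1, c1) + 1) if (p := pmf(x)) <= p_obs * (1 + 1e-7)
    )


def brute_force_medoids(d, k):
    """Globally optimal medoid set and objective by exhaustive enumeration."""
    n = d.shape[0]
    best_obj, best_set = np.inf, None
    for medoids in combinations(range(n), k):
        obj = d[list(medoids)].min(axis=0).sum()
        if obj < best_obj - 1e-12:
            best_obj, best_set = obj, medoids
    return best_set, float(best_obj)


def is_swap_optimal(d, medoids):
    """No single medoid/non-medoid exchange strictly improves the objective."""
    medoids = list(medoids)
    n = d.shape[0]
    current = d[medoids].min(axis=0).sum()
    for i in range(len(medoids)):
        for h in range(n):
            if h in medoids:
                continue
            cand = medoids.copy()
            cand[i] = h
            if d[cand].min(axis=0).sum() < current - 1e-9:
                return False
    return True


def max_window_share(level1, window_nt=4):
    """Max share of tags in any window of ``window_nt`` consecutive bases."""
    positions = [p for p, _ in level1]
    tags = {p: t for p, t in level1}
    total = sum(tags.values())
    best = 0
    for start in range(min(positions) - window_nt + 1, max(positions) + 1):
        s = sum(t for p, t in tags.items() if start <= p <= start + window_nt - 1)
        best = max(best, s)
    return best / total


def pwm_best_score_brute(sequence, pwm):
    """Best raw PWM sum over all offsets, by explicit loops."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = pwm.shape[1]
    best = -np.inf
    for off in range(len(sequence) - m + 1):
        s = 0.0
        for j in range(m):
            s += pwm[idx[sequence[off + j]], j]
        best = max(best, s)
    return best


def bin_counts_brute(midpoints, rep, n_bins=11, bin_size=400):
    """Probe midpoints per bin around ``rep``, by explicit loops."""
    half = n_bins * bin_size // 2
    counts = [0] * n_bins
    for mid in midpoints:
        for i in range(n_bins):
            lo = rep - half + i * bin_size
            if lo <= mid < lo + bin_size:
                counts[i] += 1
    return counts


def chi_square_textbook(table):
    """Pearson chi-square statistic via N·Σ(p_ij − p_i·p_j)²/(p_i·p_j)."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    p = t / n
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = pr[i] * pc[j]
            stat += n * (p[i, j] - e) ** 2 / e
    return stat
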