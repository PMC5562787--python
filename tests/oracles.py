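"""Independent brute-force oracles for the numerical core.

Every function here is a literal, loop-based transcription of the textbook
formula it checks, sharing no code path with the package: trimmed-mean
normalization factors, quantile normalization by sort/average/remap,
Savitzky-Golay least-squares kernels, the pooled t statistic, the one-way
ANOVA sum-of-squares decomposition, exact rational hypergeometric tails,
and the step-by-step concordance recipe.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import stats


def _avg_ranks(values):
    """1-based ranks with ties averaged, by explicit enumeration."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j + 1) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_factor_oracle(counts, ref_col, logratio_trim=0.30, abundance_trim=0.05):
    """Per-sample TMM factors against a fixed reference column (geo-mean 1)."""
    counts = [[float(v) for v in row] for row in counts]
    n_genes = len(counts)
    n_samples = len(counts[0])
    lib = [sum(counts[g][s] for g in range(n_genes)) for s in range(n_samples)]
    log_f = []
    for s in range(n_samples):
        m_vals, a_vals, w_vals = [], [], []
        for g in range(n_genes):
            y_k, y_r = counts[g][s], counts[g][ref_col]
            if y_k > 0 and y_r > 0:
                p_k, p_r = y_k / lib[s], y_r / lib[ref_col]
                m_vals.append(math.log2(p_k / p_r))
                a_vals.append(0.5 * math.log2(p_k * p_r))
                w_vals.append((lib[s] - y_k) / (lib[s] * y_k)
                              + (lib[ref_col] - y_r) / (lib[ref_col] * y_r))
        if not m_vals or max(abs(m) for m in m_vals) < 1e-6:
            log_f.append(0.0)
            continue
        n = len(m_vals)
        rank_m = _avg_ranks(m_vals)
        rank_a = _avg_ranks(a_vals)
        lo_m = math.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * abundance_trim) + 1
        hi_a = n + 1 - lo_a
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += m_vals[i] / w_vals[i]
                den += 1.0 / w_vals[i]
        log_f.append(num / den if den > 0 else 0.0)
    factors = [2.0 ** f for f in log_f]
    geo = math.exp(sum(math.log(f) for f in factors) / n_samples)
    return [f / geo for f in factors]


def quantile_normalize_oracle(matrix):
    """Sort each column, average order statistics, remap by (tied) rank."""
    mat = [list(map(float, row)) for row in matrix]
    n, m = len(mat), len(mat[0])
    sorted_cols = [sorted(mat[i][j] for i in range(n)) for j in range(m)]
    target = [sum(sorted_cols[j][r] for j in range(m)) / m for r in range(n)]
    out = [[0.0] * m for _ in range(n)]
    for j in range(m):
        col = [mat[i][j] for i in range(n)]
        for i in range(n):
            below = sum(1 for v in col if v < col[i])
            ties = sum(1 for v in col if v == col[i])
            span = range(below + 1, below + ties + 1)  # tied rank positions
            out[i][j] = sum(target[p - 1] for p in span) / ties
    return out


def savgol_weights_oracle(window=5, order=2, eval_at=0):
    """Least-squares polynomial smoothing weights for a centered window.

    Solves the order-``order`` polynomial fit over offsets -h..h and returns
    the linear weights giving the fitted value at offset ``eval_at``.
    """
    h = window // 2
    offsets = list(range(-h, h + 1))
    X = np.array([[x ** p for p in range(order + 1)] for x in offsets], dtype=float)
    # fitted value at eval_at = row of the hat-like matrix
    beta_map = np.linalg.inv(X.T @ X) @ X.T
    eval_row = np.array([eval_at ** p for p in range(order + 1)], dtype=float)
    return eval_row @ beta_map


def smooth_oracle(series, window=5, order=2):
    """Endpoint-extrapolating Savitzky-Golay by explicit window fits."""
    y = [float(v) for v in series]
    n = len(y)
    h = window // 2
    out = []
    for i in range(n):
        start = min(max(i - h, 0), n - window)
        xs = np.arange(start, start + window, dtype=float)
        coef = np.polyfit(xs, y[start:start + window], order)
        out.append(float(np.polyval(coef, i)))
    return out


def median_pcc_oracle(profiles):
    """Median of the 3 pairwise Pearson correlations, from the raw formula."""
    def pcc(a, b):
        n = len(a)
        ma, mb = sum(a) / n, sum(b) / n
        num = sum((a[i] - ma) * (b[i] - mb) for i in range(n))
        da = math.sqrt(sum((a[i] - ma) ** 2 for i in range(n)))
        db = math.sqrt(sum((b[i] - mb) ** 2 for i in range(n)))
        return num / (da * db)
    vals = sorted([pcc(profiles[0], profiles[1]), pcc(profiles[1], profiles[2]),
                   pcc(profiles[2], profiles[0])])
    return vals[1]


def pooled_t_p_oracle(a, b):
    """Two-sided pooled-variance two-sample t-test by the textbook formula."""
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    ss1 = sum((x - m1) ** 2 for x in a)
    ss2 = sum((x - m2) ** 2 for x in b)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2.0 * stats.t.sf(abs(t), n1 + n2 - 2), t


def anova_p_oracle(table):
    """One-way ANOVA p by the explicit sum-of-squares decomposition."""
    groups = [list(map(float, row)) for row in table]
    all_vals = [v for row in groups for v in row]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return stats.f.sf(f, df_b, df_w), f


def ease_oracle(k, n, K, N):
    """Exact rational EASE p: sum of hypergeometric masses for X >= k - 1."""
    if k == 0:
        return Fraction(1)
    total = Fraction(0)
    for x in range(max(k - 1, 0), min(n, K) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
    return total


def trapezoid_oracle(values, times):
    total = 0.0
    for i in range(len(times) - 1):
        total += 0.5 * (values[i] + values[i + 1]) * (times[i + 1] - times[i])
    return total


def concordance_oracle(seq_profiles, qpcr_profiles, times):
    """Step-by-step execution of the weighted multi-method recipe."""
    def _pearson(a, b):
        n = len(a)
        ma, mb = sum(a) / n, sum(b) / n
        num = sum((a[i] - ma) * (b[i] - mb) for i in range(n))
        da = math.sqrt(sum((x - ma) ** 2 for x in a))
        db = math.sqrt(sum((x - mb) ** 2 for x in b))
        return num / (da * db)

    def spearman(a, b):
        return _pearson(_avg_ranks(a), _avg_ranks(b))

    def kendall(a, b):
        n = len(a)
        concordant = discordant = 0
        ties_a = ties_b = 0
        for i in range(n):
            for j in range(i + 1, n):
                da, db = a[i] - a[j], b[i] - b[j]
                if da == 0 and db == 0:
                    continue
                if da == 0:
                    ties_a += 1
                elif db == 0:
                    ties_b += 1
                elif da * db > 0:
                    concordant += 1
                else:
                    discordant += 1
        denom = math.sqrt((concordant + discordant + ties_a)
                          * (concordant + discordant + ties_b))
        return (concordant - discordant) / denom

    leaves = sorted(seq_profiles)
    smoothed_seq = {lf: smooth_oracle(seq_profiles[lf]) for lf in leaves}
    smoothed_q = {lf: smooth_oracle(qpcr_profiles[lf]) for lf in leaves}
    weights = {}
    for lf in leaves:
        w_seq = max(trapezoid_oracle(smoothed_seq[lf], times), 0.0)
        w_q = max(trapezoid_oracle(smoothed_q[lf], times), 0.0)
        weights[lf] = math.sqrt(w_seq * w_q)
    total = sum(weights.values())
    norm = {lf: weights[lf] / total for lf in leaves}
    per_method = []
    for fn in (_pearson, spearman, kendall):
        per_method.append(sum(norm[lf] * fn(smoothed_seq[lf], smoothed_q[lf])
                              for lf in leaves))
    combined = math.exp(sum(math.log(v) for v in per_method) / 3.0)
    return per_method, combined, norm
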