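"""Perturbation and cross-platform concordance metrics.

The FL-SL expression gap of a gene is summarized as the trapezoidal
integral of the mean-expression difference over the 4-44 DAH grid; a
sink-removal intervention (panicle removal) is scored by the relative
change of that integrated difference.  Sequencing/qPCR agreement is a
leaf-weighted geometric-mean combination of Pearson, Spearman and Kendall
correlations between smoothed platform profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sag import smooth_profile

log = logging.getLogger(__name__)


def integrated_difference(fl_means, sl_means, times) -> float:
    """Trapezoidal integral of (FL - SL) mean expression over real DAH spacing."""
    fl = np.asarray(fl_means, dtype=float)
    sl = np.asarray(sl_means, dtype=float)
    t = np.asarray(times, dtype=float)
    if fl.shape != sl.shape or fl.shape != t.shape:
        raise ValueError("profiles and time grid must align")
    return float(np.trapezoid(fl - sl, t))


def relative_change(d_pr: float, d_con: float) -> float:
    """(Diff_PR - Diff_Con) / Diff_Con; NaN (logged) when the control is 0."""
    if d_con == 0:
        log.warning("relative change undefined: control integrated difference is 0")
        return float("nan")
    return (d_pr - d_con) / d_con


def absolute_relative_change(d_pr: float, d_con: float) -> float:
    out = relative_change(d_pr, d_con)
    return abs(out) if np.isfinite(out) else out


@dataclass
class ConcordanceScore:
    """Leaf-weighted multi-method correlation between platforms."""

    pearson_w: float
    spearman_w: float
    kendall_w: float
    combined: float
    leaf_weights: tuple[float, float]
    flagged: bool = False


def _area_weight(profile: np.ndarray, times: np.ndarray) -> float:
    area = float(np.trapezoid(profile, times))
    if area < 0:
        log.warning("negative area under smoothed profile; weight floored at 0")
        return 0.0
    return area


def platform_concordance(seq_profiles: dict[str, np.ndarray],
                         qpcr_profiles: dict[str, np.ndarray],
                         times, smooth: bool = True) -> ConcordanceScore:
    """Weighted sequencing-vs-qPCR concordance for one gene.

    ``seq_profiles`` and ``qpcr_profiles`` map leaf -> 6-point mean profile.
    Both platforms are smoothed, then per leaf and method the correlation is
    computed; each platform weighs a leaf by the area under its smoothed
    profile, the leaf's final weight is the geometric mean of the two
    platform weights normalized over leaves, per-method scores are the
    weighted sums, and the combined score is the geometric mean of the three
    methods.  When any per-method score is non-positive, the combined score
    is sign(min score) x geometric mean of absolute values and the result is
    flagged.
    """
    times = np.asarray(times, dtype=float)
    leaves = sorted(seq_profiles)
    if sorted(qpcr_profiles) != leaves:
        raise ValueError("platforms must cover the same leaves")
    smoothed_seq, smoothed_q, weights = {}, {}, {}
    for leaf in leaves:
        s = np.asarray(seq_profiles[leaf], dtype=float)
        q = np.asarray(qpcr_profiles[leaf], dtype=float)
        if s.shape != times.shape or q.shape != times.shape:
            raise ValueError("profiles must match the time grid")
        if smooth:
            s, q = smooth_profile(s), smooth_profile(q)
        smoothed_seq[leaf], smoothed_q[leaf] = s, q
        weights[leaf] = np.sqrt(_area_weight(s, times) * _area_weight(q, times))
    total = sum(weights.values())
    if total == 0:
        norm = {leaf: 1.0 / len(leaves) for leaf in leaves}
    else:
        norm = {leaf: w / total for leaf, w in weights.items()}
    methods = {
        "pearson": lambda a, b: stats.pearsonr(a, b).statistic,
        "spearman": lambda a, b: stats.spearmanr(a, b).statistic,
        "kendall": lambda a, b: stats.kendalltau(a, b).statistic,
    }
    scores = {}
    for name, fn in methods.items():
        scores[name] = sum(
            norm[leaf] * float(fn(smoothed_seq[leaf], smoothed_q[leaf])) for leaf in leaves
        )
    vals = np.array([scores["pearson"], scores["spearman"], scores["kendall"]])
    flagged = bool(np.any(vals <= 0))
    if flagged:
        log.warning("non-positive per-method score; signed |geometric mean| reported")
        magnitude = float(np.exp(np.mean(np.log(np.abs(vals[vals != 0]))))) if np.any(vals != 0) else 0.0
        combined = float(np.sign(vals.min()) * magnitude)
    else:
        combined = float(np.exp(np.mean(np.log(vals))))
    w = tuple(norm[leaf] for leaf in leaves)
    return ConcordanceScore(scores["pearson"], scores["spearman"], scores["kendall"],
                            combined, w, flagged)


def group_change_test(changes_a, changes_b) -> float:
    """Two-sided t-test between two groups of |relative change| values."""
    a = np.asarray(changes_a, dtype=float)
    b = np.asarray(changes_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
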