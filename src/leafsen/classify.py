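"""Shared vs differential classification of SAGs between the two leaves.

Per time point the FL-SL contrast is the difference of replicate medians of
log2 abundance, tested with a pooled-variance two-sample t-test.  A SAG is
Shared when |difference| < 0.58 (1.5-fold) at all six time points, and
Differential when enough time points show both |difference| above the
criterion's fold-change threshold and t-test p < 0.05; the criteria ladder
tightens the threshold (0.58 -> 1.0) and the number of required time points
(1 -> 3).  A moderated Hotelling-T2 statistic with permutation p-values is
provided as the alternative multivariate route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import TimeCourseExperiment

SHARED_FC = 0.58  # log2(1.5); the Shared rule always uses this threshold


@dataclass(frozen=True)
class CriteriaSpec:
    """One rung of the stringency ladder for Differential calls."""

    id: int
    fc_threshold: float
    min_timepoints: int


#: the published ladder: (fold-change threshold, minimum time points)
CRITERIA: dict[int, CriteriaSpec] = {
    1: CriteriaSpec(1, 0.58, 1),
    2: CriteriaSpec(2, 0.58, 2),
    3: CriteriaSpec(3, 0.58, 3),
    4: CriteriaSpec(4, 1.0, 1),
    5: CriteriaSpec(5, 1.0, 2),
}


def pooled_t_test(a, b, equal_var: bool = True) -> float:
    """Two-sided two-sample t-test p-value with degenerate-variance rules."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def diff_profiles(experiment: TimeCourseExperiment, gene_ids=None,
                  equal_var: bool = True) -> pd.DataFrame:
    """FL-SL difference profile and per-time-point t-test p for each gene.

    diff_t columns hold median(FL replicates) - median(SL replicates) of
    log2 abundance at each time point; p_t columns the corresponding
    two-sample p-values on the 3-vs-3 replicate values.
    """
    sub = experiment.expressed_subset()
    if gene_ids is not None:
        wanted = set(gene_ids)
        keep = np.array([g in wanted for g in sub.gene_ids])
        genes = [g for g in sub.gene_ids if g in wanted]
        fl = sub.leaf_values("FL")[keep]
        sl = sub.leaf_values("SL")[keep]
    else:
        genes = list(sub.gene_ids)
        fl = sub.leaf_values("FL")
        sl = sub.leaf_values("SL")
    diffs = np.median(fl, axis=2) - np.median(sl, axis=2)  # (gene, time)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant replicate rows are expected and handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(fl, sl, axis=2, equal_var=equal_var)
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero pooled variance: p = 1 when means agree, 0 (flagged by NaN->rule) otherwise
    degenerate = np.isnan(pvals)
    if np.any(degenerate):
        equal_means = np.isclose(fl.mean(axis=2), sl.mean(axis=2))
        pvals[degenerate & equal_means] = 1.0
        pvals[degenerate & ~equal_means] = 0.0
    out = {"gene_id": genes}
    for ti, t in enumerate(sub.times):
        out[f"diff_{t}"] = diffs[:, ti]
    for ti, t in enumerate(sub.times):
        out[f"p_{t}"] = pvals[:, ti]
    return pd.DataFrame(out)


def classify(profile: pd.Series | dict, criteria: CriteriaSpec = CRITERIA[1],
             t_alpha: float = 0.05) -> str:
    """Label one difference profile Shared / Diff / Neither.

    The Shared rule always uses the 0.58 threshold regardless of the
    criterion; Diff requires >= min_timepoints time points where both the
    fold-change and significance conditions hold simultaneously.
    """
    diffs = np.array([v for k, v in _items(profile) if k.startswith("diff_")])
    pvals = np.array([v for k, v in _items(profile) if k.startswith("p_")])
    if np.all(np.abs(diffs) < SHARED_FC):
        return "Shared"
    hits = np.sum((np.abs(diffs) >= criteria.fc_threshold) & (pvals < t_alpha))
    return "Diff" if hits >= criteria.min_timepoints else "Neither"


def _items(profile):
    if isinstance(profile, pd.Series):
        return profile.items()
    return profile.items()


def classify_all(profiles: pd.DataFrame, criteria: CriteriaSpec = CRITERIA[1],
                 t_alpha: float = 0.05) -> pd.Series:
    """Vectorized Shared/Diff/Neither labels for a diff_profiles frame."""
    diff_cols = [c for c in profiles.columns if c.startswith("diff_")]
    p_cols = [c for c in profiles.columns if c.startswith("p_")]
    diffs = profiles[diff_cols].to_numpy()
    pvals = profiles[p_cols].to_numpy()
    shared = np.all(np.abs(diffs) < SHARED_FC, axis=1)
    hits = np.sum((np.abs(diffs) >= criteria.fc_threshold) & (pvals < t_alpha), axis=1)
    labels = np.where(shared, "Shared", np.where(hits >= criteria.min_timepoints, "Diff", "Neither"))
    return pd.Series(labels, index=profiles.index, name=f"label_c{criteria.id}")


def direction_split(experiment: TimeCourseExperiment, gene_ids) -> pd.Series:
    """Up/down direction from each gene's own temporal trend.

    Sign of [mean log2 over the late half of the course (28-44 DAH) minus
    the early half (4-20 DAH)], averaged over both leaves; an exactly zero
    trend breaks to "down".
    """
    sub = experiment.expressed_subset()
    idx = {g: i for i, g in enumerate(sub.gene_ids)}
    missing = [g for g in gene_ids if g not in idx]
    if missing:
        raise KeyError(f"genes not in the expressed set: {missing[:5]}")
    rows = np.array([idx[g] for g in gene_ids])
    tensor = sub.log2_cpm[rows]  # (gene, leaf, time, rep)
    n_t = tensor.shape[2]
    half = n_t // 2
    rep_mean = tensor.mean(axis=3)
    trend = (rep_mean[:, :, half:].mean(axis=2) - rep_mean[:, :, :half].mean(axis=2)).mean(axis=1)
    return pd.Series(np.where(trend > 0, "up", "down"), index=list(gene_ids), name="direction")


# ---------------------------------------------------------------------------
# Hotelling-T2 alternative route


def pooled_shrunk_covariance(fl: np.ndarray, sl: np.ndarray, ridge: float = 0.5) -> np.ndarray:
    """Gene-shared pooled within-group covariance, shrunk toward its diagonal.

    With n = 3 replicates and 6 time points a per-gene covariance is
    singular, so the within-group scatter is pooled across all genes and
    both leaves and then shrunk: (1 - ridge) * S + ridge * diag(S).
    """
    if not (0.0 <= ridge <= 1.0):
        raise ValueError("ridge weight must be in [0, 1]")
    n_genes, n_times, _ = fl.shape
    centered_fl = fl - fl.mean(axis=2, keepdims=True)
    centered_sl = sl - sl.mean(axis=2, keepdims=True)
    scatter = np.einsum("gtr,gsr->ts", centered_fl, centered_fl)
    scatter += np.einsum("gtr,gsr->ts", centered_sl, centered_sl)
    df = n_genes * (fl.shape[2] - 1 + sl.shape[2] - 1)
    pooled = scatter / df
    shrunk = (1.0 - ridge) * pooled + ridge * np.diag(np.diag(pooled))
    # numerical floor so the statistic stays defined on degenerate inputs
    shrunk += 1e-10 * np.eye(n_times)
    return shrunk


def hotelling_t2(fl_reps: np.ndarray, sl_reps: np.ndarray,
                 shrink_cov: np.ndarray) -> float:
    """Two-sample Hotelling-T2 on the 6-dimensional mean difference.

    t2 = (n1 n2 / (n1 + n2)) d' Sigma^-1 d with d the FL-SL mean profile
    difference and Sigma the gene-shared shrunken covariance.
    """
    fl_reps = np.asarray(fl_reps, dtype=float)  # (time, rep)
    sl_reps = np.asarray(sl_reps, dtype=float)
    d = fl_reps.mean(axis=1) - sl_reps.mean(axis=1)
    n1, n2 = fl_reps.shape[1], sl_reps.shape[1]
    sol = np.linalg.solve(shrink_cov, d)
    return float(n1 * n2 / (n1 + n2) * d @ sol)


def _t2_block(fl: np.ndarray, sl: np.ndarray, sigma_inv: np.ndarray) -> np.ndarray:
    d = fl.mean(axis=2) - sl.mean(axis=2)  # (gene, time)
    n1, n2 = fl.shape[2], sl.shape[2]
    return n1 * n2 / (n1 + n2) * np.einsum("gt,ts,gs->g", d, sigma_inv, d)


def hotelling_permutation_p(experiment: TimeCourseExperiment, n_perm: int = 1000,
                            seed: int = 0, ridge: float = 0.5,
                            gene_ids=None) -> pd.DataFrame:
    """Per-gene empirical Hotelling-T2 p-values from time-column permutations.

    Each round permutes the time columns of every replicate matrix of both
    leaves (one permutation per replicate, shared across genes), recomputes
    the shared covariance and the statistic, and the one-sided add-one
    empirical p compares each gene's observed t2 with its own null draws.
    """
    import warnings

    if n_perm < 19:
        warnings.warn("n_perm < 19: empirical p floor is coarser than 0.05")
    sub = experiment.expressed_subset()
    if gene_ids is not None:
        wanted = set(gene_ids)
        keep = np.array([g in wanted for g in sub.gene_ids])
        genes = [g for g in sub.gene_ids if g in wanted]
    else:
        keep = np.ones(len(sub.gene_ids), dtype=bool)
        genes = list(sub.gene_ids)
    fl_all = sub.leaf_values("FL")
    sl_all = sub.leaf_values("SL")
    sigma = pooled_shrunk_covariance(fl_all, sl_all, ridge)
    sigma_inv = np.linalg.inv(sigma)
    observed = _t2_block(fl_all[keep], sl_all[keep], sigma_inv)

    rng = np.random.default_rng(seed)
    n_times = fl_all.shape[1]
    exceed = np.zeros(observed.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        fl_p = np.empty_like(fl_all)
        sl_p = np.empty_like(sl_all)
        for r in range(fl_all.shape[2]):
            fl_p[:, :, r] = fl_all[:, rng.permutation(n_times), r]
            sl_p[:, :, r] = sl_all[:, rng.permutation(n_times), r]
        sigma_null = pooled_shrunk_covariance(fl_p, sl_p, ridge)
        null_t2 = _t2_block(fl_p[keep], sl_p[keep], np.linalg.inv(sigma_null))
        exceed += null_t2 >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(
        {"gene_id": genes, "t2": observed, "p_empirical": p, "n_permutations": n_perm}
    )


def compare_classifiers(criteria_set: set[str], alternative_set: set[str]) -> dict:
    """Overlap of the criteria-based and Hotelling-based Diff sets.

    Reports |A intersect B| and its percentage of |B| to two decimals; the
    percentage is undefined (None) for an empty B.
    """
    overlap = len(criteria_set & alternative_set)
    pct = None if not alternative_set else round(100.0 * overlap / len(alternative_set), 2)
    return {
        "overlap": overlap,
        "n_criteria": len(criteria_set),
        "n_alternative": len(alternative_set),
        "overlap_pct_of_alternative": pct,
    }
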