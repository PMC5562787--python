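"""Senescence-associated gene (SAG) detection for one leaf.

A gene is a SAG when its three replicate trajectories are reproducible
(median pairwise Pearson correlation of Savitzky-Golay-smoothed profiles
above a permutation-derived cutoff), its time effect is significant
(one-way ANOVA, Bonferroni-adjusted across the tested genes), and its
maximum absolute log2 fold-change from the 4 DAH baseline reaches 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter

from .normalize import TimeCourseExperiment


def smooth_profile(values, window: int = 5, order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing along the last (time) axis.

    Interior points use the least-squares kernel; the edge points are filled
    by fitting the order-``order`` polynomial to the nearest ``window``
    points and evaluating at the edge, so exact polynomials up to that order
    pass through unchanged.
    """
    arr = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("frame size must be odd")
    if arr.shape[-1] < window:
        raise ValueError(
            f"series length {arr.shape[-1]} shorter than frame size {window}"
        )
    return savgol_filter(arr, window_length=window, polyorder=order, axis=-1, mode="interp")


_PAIRS = ((0, 1), (1, 2), (2, 0))


def _pairwise_pcc(profiles: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations for (..., replicate, time) arrays.

    Returns (..., 3) correlations for replicate pairs (1-2, 2-3, 3-1); a pair
    involving a zero-variance profile is NaN (undefined).
    """
    centered = profiles - profiles.mean(axis=-1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=-1))
    out = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for i, j in _PAIRS:
            num = (centered[..., i, :] * centered[..., j, :]).sum(axis=-1)
            den = norms[..., i] * norms[..., j]
            out.append(np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan))
    return np.stack(out, axis=-1)


def replicate_pcc(replicate_profiles) -> float:
    """Median of the three pairwise PCCs between smoothed replicate profiles.

    NaN when any pairwise correlation is undefined (a constant smoothed
    profile carries no age-dependent signal, so the gene fails the
    reproducibility filter).
    """
    profiles = np.asarray(replicate_profiles, dtype=float)
    if profiles.shape[0] != 3:
        raise ValueError("exactly 3 replicate profiles required")
    pccs = _pairwise_pcc(profiles)
    if np.any(np.isnan(pccs)):
        return float("nan")
    return float(np.median(pccs))


def median_pcc_profile_block(block: np.ndarray, window: int = 5, order: int = 2) -> np.ndarray:
    """Vectorized median smoothed-replicate PCC for a (gene, time, rep) block."""
    smoothed = smooth_profile(np.swapaxes(block, 1, 2), window, order)  # (gene, rep, time)
    pccs = _pairwise_pcc(smoothed)
    med = np.median(pccs, axis=-1)
    med[np.any(np.isnan(pccs), axis=-1)] = np.nan
    return med


@dataclass
class PermutationNull:
    """Empirical null distribution of replicate reproducibility PCCs."""

    pcc_samples: np.ndarray
    n_permutations: int
    percentile_95: float
    seed: int

    @property
    def operative_cutoff(self) -> float:
        """95th percentile floored to one decimal (0.71 -> 0.7)."""
        return float(np.floor(self.percentile_95 * 10.0) / 10.0)


def permutation_pcc_cutoff(block: np.ndarray, n_perm: int = 100, seed: int = 0,
                           window: int = 5, order: int = 2) -> PermutationNull:
    """Permutation null for the median replicate PCC.

    Per round the time columns of each replicate's gene x time matrix are
    permuted independently (one permutation per replicate, shared by all
    genes, destroying the common temporal signal), profiles are re-smoothed
    and the per-gene median pairwise PCC pooled across rounds.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    block = np.asarray(block, dtype=float)
    n_genes, n_times, n_reps = block.shape
    rng = np.random.default_rng(seed)
    pool = []
    for _ in range(n_perm):
        permuted = np.empty_like(block)
        for r in range(n_reps):
            permuted[:, :, r] = block[:, rng.permutation(n_times), r]
        med = median_pcc_profile_block(permuted, window, order)
        pool.append(med[np.isfinite(med)])
    samples = np.concatenate(pool)
    return PermutationNull(samples, n_perm, float(np.quantile(samples, 0.95)), seed)


def anova_time(values) -> float:
    """One-way fixed-effects ANOVA p-value across time groups.

    ``values`` is (time, replicate); a table with no variance at all is
    defined to have p = 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 time groups with >= 2 replicates")
    if np.all(arr == arr.flat[0]):
        return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(*[arr[t] for t in range(arr.shape[0])])
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def _anova_block(block: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA p for a (gene, time, rep) block."""
    groups = [block[:, t, :] for t in range(block.shape[1])]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(*groups, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    flat = np.all(block == block[:, :1, :1], axis=(1, 2))
    p[np.isnan(p) & flat] = 1.0
    p[np.isnan(p)] = 1.0  # residual degenerate tables carry no evidence
    return p


def max_abs_log2fc(block: np.ndarray, baseline_profile: np.ndarray | None = None) -> np.ndarray:
    """Max over time of |mean log2 at t - mean log2 at the first time point|.

    ``baseline_profile`` substitutes an external per-gene baseline (e.g. the
    flag leaf's 4 DAH mean) for the leaf's own first-time-point mean.
    """
    means = block.mean(axis=2)  # (gene, time)
    base = means[:, 0] if baseline_profile is None else np.asarray(baseline_profile)
    return np.max(np.abs(means - base[:, None]), axis=1)


def call_sags(experiment: TimeCourseExperiment, leaf: str, pcc_cutoff: float = 0.7,
              alpha: float = 0.05, fc_min: float = 1.0,
              fc_baseline: str = "own_4dah", anova_on_smoothed: bool = False,
              window: int = 5, order: int = 2) -> pd.DataFrame:
    """Per-gene SAG calls for one leaf on the expressed gene set.

    Returns a frame with columns gene_id, leaf, median_pcc, anova_p,
    anova_p_adjusted (Bonferroni across the tested genes), max_abs_log2fc
    and is_sag.
    """
    sub = experiment.expressed_subset()
    block = sub.leaf_values(leaf)  # (gene, time, rep)
    med_pcc = median_pcc_profile_block(block, window, order)
    anova_input = block
    if anova_on_smoothed:
        anova_input = np.swapaxes(smooth_profile(np.swapaxes(block, 1, 2), window, order), 1, 2)
    p = _anova_block(anova_input)
    n_tested = len(sub.gene_ids)
    p_adj = np.minimum(p * n_tested, 1.0)
    if fc_baseline == "own_4dah":
        fc = max_abs_log2fc(block)
    elif fc_baseline == "fl_4dah":
        fl_base = sub.leaf_values("FL")[:, 0, :].mean(axis=1)
        fc = max_abs_log2fc(block, fl_base)
    else:
        raise ValueError(f"unknown fold-change baseline {fc_baseline!r}")
    with np.errstate(invalid="ignore"):
        is_sag = (med_pcc >= pcc_cutoff) & (p_adj < alpha) & (fc >= fc_min)
    is_sag[np.isnan(med_pcc)] = False
    return pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            "leaf": leaf,
            "median_pcc": med_pcc,
            "anova_p": p,
            "anova_p_adjusted": p_adj,
            "max_abs_log2fc": fc,
            "is_sag": is_sag,
        }
    )


def sag_sets(fl_calls: pd.DataFrame, sl_calls: pd.DataFrame) -> dict[str, set[str]]:
    """FL-only / SL-only / common / union set algebra over identical universes."""
    if set(fl_calls["gene_id"]) != set(sl_calls["gene_id"]):
        raise ValueError("FL and SL calls must cover the same gene universe")
    fl = set(fl_calls.loc[fl_calls["is_sag"], "gene_id"])
    sl = set(sl_calls.loc[sl_calls["is_sag"], "gene_id"])
    return {
        "FL": fl,
        "SL": sl,
        "FL_only": fl - sl,
        "SL_only": sl - fl,
        "common": fl & sl,
        "union": fl | sl,
    }


def sag_set_summary(sets: dict[str, set[str]]) -> pd.DataFrame:
    return pd.DataFrame(
        {"set": list(sets), "count": [len(v) for v in sets.values()]}
    )
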