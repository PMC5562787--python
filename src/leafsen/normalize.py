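"""Two-stage normalization of raw counts into the log2 abundance tensor.

Counts are scaled to CPM with trimmed-mean-of-M-values (TMM) factors to
remove composition bias, then quantile-normalized on log2(CPM + 1) jointly
across all samples so every library shares one abundance distribution.
An expressed-gene mask (replicate-mean CPM > threshold in at least one
time point) gates all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LEAVES, CountMatrix


def _tmm_pair_factor(obs, ref, lib_obs, lib_ref, logratio_trim, abundance_trim):
    """log2 TMM factor of one sample against the reference sample."""
    keep = (obs > 0) & (ref > 0)
    if not np.any(keep):
        return 0.0
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    m = np.log2(o / r)                      # log-ratio
    a = 0.5 * np.log2(o * r)                # absolute abundance
    # asymptotic (delta-method) variance of M, used as inverse weights
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (
        lib_ref - ref[keep]
    ) / (lib_ref * ref[keep])
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        return 0.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(counts: np.ndarray, reference: int | None = None,
                logratio_trim: float = 0.30, abundance_trim: float = 0.05) -> np.ndarray:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    ``reference`` picks the reference column; by default the sample whose
    75th percentile of library-scaled counts is closest to the mean across
    samples (the edgeR convention).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 1:
        raise ValueError("counts must be genes x samples with >= 1 sample")
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have positive library size")
    n_samples = counts.shape[1]
    if n_samples == 1:
        return np.ones(1)
    if reference is None:
        f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(n_samples)])
        reference = int(np.argmin(np.abs(f75 - f75.mean())))
    log_f = np.array(
        [
            _tmm_pair_factor(
                counts[:, j], counts[:, reference], lib[j], lib[reference],
                logratio_trim, abundance_trim,
            )
            for j in range(n_samples)
        ]
    )
    factors = 2.0 ** log_f
    return factors / np.exp(np.mean(np.log(factors)))


def tmm_cpm(cm: CountMatrix, reference: int | None = None,
            logratio_trim: float = 0.30, abundance_trim: float = 0.05) -> pd.DataFrame:
    """Counts per million on TMM-adjusted effective library sizes."""
    factors = tmm_factors(cm.counts, reference, logratio_trim, abundance_trim)
    lib = cm.counts.sum(axis=0)
    cpm = cm.counts / (lib * factors) * 1e6
    return pd.DataFrame(cpm, index=cm.gene_ids, columns=cm.sample_ids)


def quantile_normalize(matrix) -> pd.DataFrame | np.ndarray:
    """Force every column onto the across-column mean of order statistics.

    Ranks within each column are preserved; tied values receive the mean of
    the target values at the tied rank positions.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    values = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if values.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    if np.any(~np.isfinite(values)):
        raise ValueError("matrix contains missing or non-finite values")
    n, m = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    target = np.mean(np.take_along_axis(values, order, axis=0), axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        idx = order[:, j]
        assigned = np.empty(n)
        start = 0
        while start < n:
            stop = start
            while stop + 1 < n and col[idx[stop + 1]] == col[idx[start]]:
                stop += 1
            assigned[start : stop + 1] = target[start : stop + 1].mean()
            start = stop + 1
        out[idx, j] = assigned
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def log2_offset(cpm):
    """log2(CPM + 1); the +1 keeps zero counts at zero abundance."""
    arr = np.asarray(cpm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("CPM values must be non-negative")
    out = np.log2(arr + 1.0)
    if isinstance(cpm, pd.DataFrame):
        return pd.DataFrame(out, index=cpm.index, columns=cpm.columns)
    return out


def filter_expressed(abundance: pd.DataFrame, meta: pd.DataFrame,
                     threshold: float = 1.0, scope: str = "timepoint_mean") -> pd.Series:
    """Expressed-gene mask on linear-scale abundance (CPM).

    ``timepoint_mean`` keeps a gene whose replicate-mean abundance exceeds
    ``threshold`` at >= 1 (leaf, time) combination; ``replicate`` applies the
    rule to individual samples instead.
    """
    if scope == "replicate":
        return (abundance > threshold).any(axis=1)
    if scope != "timepoint_mean":
        raise ValueError(f"unknown expression filter scope {scope!r}")
    keys = np.array([f"{l}|{t}" for l, t in zip(meta["leaf"], meta["time_dah"])])
    means = abundance.T.groupby(keys).mean().T
    return (means > threshold).any(axis=1)


@dataclass
class TimeCourseExperiment:
    """Normalized log2 abundances as a gene x leaf x time x replicate tensor."""

    gene_ids: list[str]
    times: list[int]
    replicates: list[int]
    log2_cpm: np.ndarray          # (gene, leaf, time, replicate); leaf axis = (FL, SL)
    expressed_mask: np.ndarray    # boolean per gene
    cpm: pd.DataFrame | None = None

    leaves: tuple = LEAVES

    def __post_init__(self):
        expect = (len(self.gene_ids), 2, len(self.times), len(self.replicates))
        if self.log2_cpm.shape != expect:
            raise ValueError(f"tensor shape {self.log2_cpm.shape}, expected {expect}")
        if np.any(~np.isfinite(self.log2_cpm)):
            raise ValueError("tensor contains missing cells")
        if np.any(self.log2_cpm < 0):
            raise ValueError("log2(CPM+1) must be non-negative")

    def leaf_index(self, leaf: str) -> int:
        return self.leaves.index(leaf)

    def leaf_values(self, leaf: str) -> np.ndarray:
        """(gene, time, replicate) block for one leaf."""
        return self.log2_cpm[:, self.leaf_index(leaf), :, :]

    def expressed_subset(self) -> "TimeCourseExperiment":
        mask = self.expressed_mask
        return TimeCourseExperiment(
            [g for g, k in zip(self.gene_ids, mask) if k],
            self.times,
            self.replicates,
            self.log2_cpm[mask],
            np.ones(int(mask.sum()), dtype=bool),
            self.cpm.loc[mask] if self.cpm is not None else None,
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for gi, gene in enumerate(self.gene_ids):
            for li, leaf in enumerate(self.leaves):
                for ti, t in enumerate(self.times):
                    for ri, rep in enumerate(self.replicates):
                        rows.append((gene, leaf, t, rep, self.log2_cpm[gi, li, ti, ri]))
        return pd.DataFrame(rows, columns=["gene_id", "leaf", "time_dah", "replicate", "log2_cpm"])


def build_experiment(cm: CountMatrix, expression_threshold: float = 1.0,
                     expression_scope: str = "timepoint_mean",
                     logratio_trim: float = 0.30, abundance_trim: float = 0.05,
                     quantile: bool = True) -> TimeCourseExperiment:
    """Full two-stage normalization of a count matrix into the tensor.

    TMM-CPM -> expressed mask (on linear CPM) -> log2(CPM+1) -> quantile
    normalization jointly across all samples of both leaves.
    """
    meta = cm.meta_frame()
    cpm = tmm_cpm(cm, logratio_trim=logratio_trim, abundance_trim=abundance_trim)
    mask = filter_expressed(cpm, meta, expression_threshold, expression_scope)
    log2cpm = log2_offset(cpm)
    if quantile:
        log2cpm = quantile_normalize(log2cpm)
    times = sorted(meta["time_dah"].unique())
    reps = sorted(meta["replicate"].unique())
    tensor = np.full((len(cm.gene_ids), 2, len(times), len(reps)), np.nan)
    for j, s in enumerate(cm.samples):
        li = LEAVES.index(s.leaf)
        ti = times.index(s.time_dah)
        ri = reps.index(s.replicate)
        tensor[:, li, ti, ri] = log2cpm.iloc[:, j]
    if np.any(~np.isfinite(tensor)):
        raise ValueError("incomplete design: some (leaf, time, replicate) cell missing")
    return TimeCourseExperiment(
        list(cm.gene_ids), [int(t) for t in times], [int(r) for r in reps],
        tensor, mask.to_numpy(), cpm,
    )
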