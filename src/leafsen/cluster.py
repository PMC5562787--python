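"""Expression-pattern discovery: k-means clusters -> merged patterns -> groups.

Shared and differential SAG tracks are each clustered into k = 30 clusters
with correlation similarity (realized as row standardization + Euclidean
k-means, since squared Euclidean distance of standardized rows is a
monotone function of 1 - r).  Clusters split into up/down strata by the
sign of their mean profile's largest excursion, strata merge into patterns
by complete-linkage Euclidean hierarchical clustering of the cluster mean
profiles, and differential patterns merge further into major groups by the
similarity of their FL-SL difference profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans


def standardize_rows(matrix: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance rows; constant rows map to all zeros."""
    arr = np.asarray(matrix, dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (arr - mu) / sd


def cluster_kmeans(profiles: np.ndarray, k: int = 30, seed: int = 0,
                   n_restarts: int = 20) -> np.ndarray:
    """Correlation-similarity k-means; returns 1-based cluster ids.

    Rows are standardized, then Euclidean k-means runs ``n_restarts`` times
    keeping the lowest within-cluster sum of squares; empty clusters are
    re-seeded from the farthest points.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < k:
        raise ValueError(f"{profiles.shape[0]} rows < k = {k}")
    std = standardize_rows(profiles)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2**32 - 1))
    return km.fit_predict(std) + 1


def cluster_mean_profiles(profiles: np.ndarray, cluster_ids: np.ndarray) -> pd.DataFrame:
    """Mean (unstandardized) profile per cluster, indexed by cluster id."""
    frame = pd.DataFrame(np.asarray(profiles, dtype=float))
    frame["cluster"] = cluster_ids
    return frame.groupby("cluster").mean()


def split_direction(mean_profiles: pd.DataFrame) -> pd.Series:
    """Up/down per cluster by the sign of the maximum-magnitude excursion.

    Profiles are log2 fold-changes relative to the 4 DAH flag-leaf baseline,
    so the excursion farthest from zero decides the direction; this stays
    correct for peaked, non-monotone patterns.  A zero profile counts down.
    """
    values = mean_profiles.to_numpy()
    extreme = values[np.arange(values.shape[0]), np.argmax(np.abs(values), axis=1)]
    return pd.Series(np.where(extreme > 0, "up", "down"),
                     index=mean_profiles.index, name="direction")


def merge_patterns(mean_profiles: pd.DataFrame, n_patterns: int) -> pd.Series:
    """Complete-linkage Euclidean merge of cluster mean profiles.

    Cuts the tree at ``n_patterns``; returns 1-based pattern ids indexed by
    cluster id.  Requesting more patterns than clusters is an error.
    """
    if n_patterns > len(mean_profiles):
        raise ValueError(
            f"requested {n_patterns} patterns from {len(mean_profiles)} clusters"
        )
    if len(mean_profiles) == 1 or n_patterns == len(mean_profiles):
        ids = np.arange(1, len(mean_profiles) + 1)
        return pd.Series(ids[: len(mean_profiles)], index=mean_profiles.index, name="pattern")
    tree = linkage(mean_profiles.to_numpy(), method="complete", metric="euclidean")
    labels = fcluster(tree, t=n_patterns, criterion="maxclust")
    return pd.Series(labels, index=mean_profiles.index, name="pattern")


def form_groups(pattern_diff_profiles: pd.DataFrame, gene_counts: pd.Series,
                n_groups: int = 5, major_fraction: float = 0.10) -> pd.DataFrame:
    """Major groups from pattern-level FL-SL difference profiles.

    Complete-linkage Euclidean clustering of the per-pattern mean difference
    profiles, cut at ``n_groups``; a group is major when its gene count
    exceeds ceiling(major_fraction x total differential genes).
    """
    if n_groups > len(pattern_diff_profiles):
        raise ValueError(
            f"requested {n_groups} groups from {len(pattern_diff_profiles)} patterns"
        )
    if n_groups == len(pattern_diff_profiles):
        labels = np.arange(1, n_groups + 1)
    else:
        tree = linkage(pattern_diff_profiles.to_numpy(), method="complete", metric="euclidean")
        labels = fcluster(tree, t=n_groups, criterion="maxclust")
    out = pd.DataFrame({"group": labels}, index=pattern_diff_profiles.index)
    totals = out.join(gene_counts.rename("n_genes")).groupby("group")["n_genes"].sum()
    threshold = int(np.ceil(major_fraction * gene_counts.sum()))
    out["group_n_genes"] = out["group"].map(totals)
    out["major"] = out["group_n_genes"] > threshold
    out["major_threshold"] = threshold
    return out


def assign_patterns(track: str, gene_ids: list[str], feature_profiles: np.ndarray,
                    fc_profiles: np.ndarray, diff_profiles: np.ndarray | None = None,
                    k: int = 30, seed: int = 0, n_restarts: int = 20,
                    n_up_patterns: int = 4, n_down_patterns: int = 3,
                    n_groups: int = 5, major_fraction: float = 0.10) -> pd.DataFrame:
    """Full cluster -> direction -> pattern (-> group) assignment for one track.

    ``feature_profiles`` feed k-means (log2-FC profiles for the shared
    track; log2-FC concatenated with FL-SL difference profiles for the
    differential track).  ``fc_profiles`` (vs the 4 DAH FL baseline) drive
    direction and pattern merging; ``diff_profiles`` (differential track
    only) drive group formation.  Pattern ids are SP1.. / DP1.. with
    up-regulated patterns numbered first.
    """
    if track not in ("shared", "diff"):
        raise ValueError("track must be 'shared' or 'diff'")
    clusters = cluster_kmeans(feature_profiles, k=k, seed=seed, n_restarts=n_restarts)
    mean_fc = cluster_mean_profiles(fc_profiles, clusters)
    direction = split_direction(mean_fc)
    prefix = "SP" if track == "shared" else "DP"
    pattern_of_cluster: dict[int, str] = {}
    offset = 0
    for direc, n_pat in (("up", n_up_patterns), ("down", n_down_patterns)):
        members = direction.index[direction == direc]
        if len(members) == 0:
            continue
        n_cut = min(n_pat, len(members))
        merged = merge_patterns(mean_fc.loc[members], n_cut)
        for cid, pat in merged.items():
            pattern_of_cluster[cid] = f"{prefix}{pat + offset}"
        offset += n_cut
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "track": track,
            "cluster_id": clusters,
            "direction": [direction.loc[c] for c in clusters],
            "pattern_id": [pattern_of_cluster[c] for c in clusters],
        }
    )
    out["group"] = "none"
    out["major"] = False
    if track == "diff":
        if diff_profiles is None:
            raise ValueError("differential track requires FL-SL difference profiles")
        per_gene_diff = pd.DataFrame(np.asarray(diff_profiles, dtype=float))
        per_gene_diff["pattern"] = out["pattern_id"].to_numpy()
        pattern_means = per_gene_diff.groupby("pattern").mean()
        counts = per_gene_diff.groupby("pattern").size()
        groups = form_groups(pattern_means, counts, n_groups, major_fraction)
        out["group"] = out["pattern_id"].map(lambda p: f"G{groups.loc[p, 'group']}")
        out["major"] = out["pattern_id"].map(groups["major"]).to_numpy()
    return out
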