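"""EASE-score term enrichment with the study's reporting filters.

The EASE score is DAVID's conservative variant of the one-tailed Fisher
test: one gene is removed from the list hits before taking the
hypergeometric upper tail, so single-hit terms can never score.  A term is
reported when EASE p <= 0.05 and the list hits number at least 5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneAnnotation


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """EASE p-value: P(X >= k - 1) for X ~ Hypergeometric(N, K, n).

    k list hits, n list size, K term total, N universe size; k = 0 gives 1.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts (k={k}, n={n}, K={K}, N={N})")
    if k == 0:
        return 1.0
    # sf(x) = P(X > x), so P(X >= k-1) = sf(k-2)
    return float(stats.hypergeom.sf(k - 2, N, K, n))


def fisher_exact_p(k: int, n: int, K: int, N: int) -> float:
    """Ordinary one-tailed Fisher p, P(X >= k); EASE is never smaller."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts (k={k}, n={n}, K={K}, N={N})")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_group(gene_set, annotation: GeneAnnotation, universe,
                 alpha: float = 0.05, min_hits: int = 5) -> pd.DataFrame:
    """EASE enrichment of one gene set against every intersecting term.

    ``universe`` is the background gene set (the expressed genes by
    default); genes lacking any annotation stay in the universe.  Returns
    one row per term intersecting the set, sorted by EASE p, with a
    Benjamini-Hochberg column emitted for information only (the pass flag
    uses the raw EASE p, matching the reporting rule).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty enrichment universe")
    gene_set = set(gene_set) & universe
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    n = len(gene_set)
    N = len(universe)
    rows = []
    for term, genes in annotation.term_genes.items():
        term_in_universe = genes & universe
        hits = term_in_universe & gene_set
        if not hits:
            continue
        k, K = len(hits), len(term_in_universe)
        p = ease_score(k, n, K, N)
        rows.append(
            {
                "term_id": term,
                "term_name": annotation.term_names.get(term, ""),
                "list_hits": k,
                "list_size": n,
                "term_total": K,
                "universe": N,
                "ease_p": p,
                "passes": (p <= alpha) and (k >= min_hits),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "list_hits", "list_size", "term_total",
                 "universe", "ease_p", "passes"],
    )
    if len(frame):
        frame["bh_fdr"] = multipletests(frame["ease_p"], method="fdr_bh")[1]
        frame = frame.sort_values(["ease_p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        frame["bh_fdr"] = np.array([], dtype=float)
    return frame
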