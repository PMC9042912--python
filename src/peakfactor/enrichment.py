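"""Over-representation analysis (ORA) of gene lists against gene-set
collections: an upper-tail hypergeometric test per term with
Benjamini-Hochberg FDR control across the tested terms.

For a universe of N genes of which K are annotated to a term, and a
query of n genes of which k hit the term, the enrichment p-value is
P(X >= k) for X ~ Hypergeometric(N, K, n), and the fold enrichment is
(k/n) / (K/N).  Finding no significant term is an admissible outcome
and is reported as such, not an error.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_upper", "bh_adjust", "ora"]

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["term_id", "term_size", "hits", "query_size",
                      "universe_size", "p_value", "q_value", "fold"]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``N`` genes in the universe, ``K`` annotated to the term, ``n``
    drawn (the query); the survival function is evaluated at k - 1.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"inconsistent arguments: K={K}, n={n} must not exceed N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n={n}, K={K})")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(query_genes: Iterable[str],
        gene_sets: Mapping[str, Iterable[str]],
        universe: Iterable[str],
        q_threshold: float = 0.05) -> pd.DataFrame:
    """Rank gene sets by over-representation in the query.

    Query genes outside the universe are dropped with a warning.  Every
    term with >= 1 universe gene is tested (the BH family); rows are
    reported for terms with >= 1 query hit, sorted by p-value.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("the gene universe is empty")
    query = set(query_genes)
    dropped = query - universe_set
    if dropped:
        warnings.warn(f"{len(dropped)} query gene(s) outside the universe "
                      "were dropped", stacklevel=2)
        query &= universe_set
    N, n = len(universe_set), len(query)
    rows = []
    for term_id, members in gene_sets.items():
        term = set(members) & universe_set
        if not term:
            continue
        hits = query & term
        rows.append({
            "term_id": term_id,
            "term_size": len(term),
            "hits": len(hits),
            "query_size": n,
            "universe_size": N,
            "p_value": hypergeom_upper(len(hits), len(term), n, N),
            "fold": ((len(hits) / n) / (len(term) / N)) if n else 0.0,
        })
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    table = pd.DataFrame(rows)
    table["q_value"] = np.maximum(bh_adjust(table["p_value"].to_numpy()),
                                  table["p_value"].to_numpy())
    table = table[table["hits"] >= 1]
    table = table.sort_values(["p_value", "term_id"], kind="mergesort")
    table = table.reset_index(drop=True)[ENRICHMENT_COLUMNS]
    n_sig = int((table["q_value"] <= q_threshold).sum()) if len(table) else 0
    if n_sig == 0:
        logger.info("no significant terms at q <= %g", q_threshold)
    table.attrs["n_significant"] = n_sig
    table.attrs["q_threshold"] = q_threshold
    return table
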