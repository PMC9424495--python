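"""Hypergeometric overrepresentation analysis (ORA) over pooled gene sets.

The universe is the set of expressed genes (the analysis background); a
query list (e.g. the kinetic genes of one cluster, or the Independent
hybrid genes) is tested against every gene set for overlap enrichment with
the hypergeometric upper tail, sets of fewer than 3 or more than 1,000
within-universe members are excluded, and p-values are Benjamini-Hochberg
corrected across all tested sets pooled over sources (significance at
FDR < 0.1 by convention).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data_io import GeneSetCollection, benjamini_hochberg

__all__ = ["hypergeom_upper_tail", "run_ora"]


def hypergeom_upper_tail(k: int, m: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, m marked, n drawn).

    k is the observed overlap between a query of size n and a set of size
    m within a universe of size N. Computed via the survival function
    (log-space internally), so small tail probabilities are stable.
    """
    if not (0 <= k <= min(m, n) and m <= N and n <= N):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, m={m}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def run_ora(query: list[str], universe: list[str], sets: GeneSetCollection,
            min_size: int = 3, max_size: int = 1000,
            fdr: float = 0.1) -> pd.DataFrame:
    """Overrepresentation of a query gene list in every eligible gene set.

    Query genes outside the universe are dropped with a warning. Set sizes
    are measured *after* intersection with the universe, and the size
    filter [min_size, max_size] applies to those within-universe sizes.
    Returns one row per tested set, sorted by q-value.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    q_genes = [g for g in dict.fromkeys(query) if g in uni_set]
    dropped = len(set(query)) - len(q_genes)
    if dropped:
        warnings.warn(f"{dropped} query genes outside the universe were dropped")
    if not q_genes:
        raise ValueError("no query genes inside the universe")
    N, n = len(uni_set), len(q_genes)
    q_set = set(q_genes)

    rows = []
    for name, (_desc, members) in sets.sets.items():
        in_universe = [g for g in members if g in uni_set]
        m = len(in_universe)
        if not min_size <= m <= max_size:
            continue
        overlap = [g for g in in_universe if g in q_set]
        k = len(overlap)
        rows.append({
            "set_name": name, "source": sets.source_label,
            "overlap": k, "set_size": m, "query_size": n, "universe_size": N,
            "p_value": hypergeom_upper_tail(k, m, n, N),
            "overlap_genes": ",".join(overlap),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=[
            "set_name", "source", "overlap", "set_size", "query_size",
            "universe_size", "p_value", "q_value", "significant",
            "overlap_genes"])
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < fdr
    out = out.sort_values(["q_value", "p_value", "set_name"],
                          kind="stable").reset_index(drop=True)
    return out[["set_name", "source", "overlap", "set_size", "query_size",
                "universe_size", "p_value", "q_value", "significant",
                "overlap_genes"]]
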