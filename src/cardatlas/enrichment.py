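"""Over-representation analysis (hypergeometric upper tail / one-sided Fisher).

One generic engine backs every enrichment step in the pipeline: pathway
filtering in the crosstalk builder, functional annotation of signature and
differential gene sets. The test asks whether a query gene set overlaps a
named gene set more than chance would allow given a finite background
universe: with k observed overlap, K genes in the set, n in the query and N in
the universe, p = P(X >= k) for X ~ Hypergeometric(N, K, n) — identical to the
one-sided Fisher exact p of the 2x2 table.

Raw p-values are reported (and filtered at raw p < 0.05 by callers); a
Benjamini-Hochberg column is provided for users who want FDR control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_upper_tail", "ora_table", "benjamini_hochberg"]


class EnrichmentError(ValueError):
    pass


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N draws... population N, K successes, n draws).

    Computed via the hypergeometric survival function (log-space internally),
    so small tail probabilities stay accurate. k = 0 gives exactly 1.
    """
    if not (0 <= k <= min(K, n)):
        raise EnrichmentError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise EnrichmentError(f"need K, n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


def ora_table(
    query,
    collection: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Over-representation table: one row per gene set overlapping the query.

    Query genes outside the universe are dropped with a warning; gene sets are
    intersected with the universe before testing. Rows (k >= 1 only) are sorted
    by ascending raw p, ties broken by set name; a ``p_bh`` column carries the
    Benjamini-Hochberg adjustment over the tested sets.
    """
    universe = frozenset(universe)
    if not universe:
        raise EnrichmentError("empty universe")
    query = frozenset(query)
    outside = query - universe
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped: %s ...",
            len(outside), sorted(outside)[:5],
        )
    query &= universe
    N, n = len(universe), len(query)
    rows = []
    for name, genes in collection.items():
        genes = genes & universe
        overlap = genes & query
        k, K = len(overlap), len(genes)
        if k == 0:
            continue
        rows.append(
            {
                "set": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeom_upper_tail(k, K, n, N),
                "genes": ";".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "p_value", "genes"]
    )
    if len(df):
        df["p_bh"] = benjamini_hochberg(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "set"], kind="stable").reset_index(drop=True)
    else:
        df["p_bh"] = pd.Series(dtype=float)
    return df
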