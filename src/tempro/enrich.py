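"""Hypergeometric over-representation analysis against GMT gene sets.

One-sided enrichment of a query feature set within a background universe
(default: all quantified features of the omics layer after QC), with
Benjamini-Hochberg FDR across the tested sets.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection


class EnrichError(ValueError):
    pass


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts the overlap of a size-``n`` draw (query) with the ``K`` members
    of a set inside a background universe of size ``N``.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise EnrichError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_sets(query, background, gmt: GeneSetCollection, alpha: float = 0.05,
                report_empty: bool = False) -> pd.DataFrame:
    """ORA table: one row per gene set with non-empty overlap.

    Sets are intersected with the background universe before testing. Rows
    carry the overlap count k, set size K (within background), query size n,
    background size N, raw p, BH FDR, and a significance flag at ``alpha``.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise EnrichError("empty query set")
    stray = query - background
    if stray:
        raise EnrichError(f"query feature(s) outside the background: {sorted(stray)[:5]}")
    N, n = len(background), len(query)
    rows = []
    for name, members in gmt:
        in_bg = members & background
        K = len(in_bg)
        if K == 0:
            continue
        overlap = sorted(in_bg & query)
        k = len(overlap)
        if k == 0 and not report_empty:
            continue
        rows.append((name, k, K, n, N, hypergeom_p(k, K, n, N), ",".join(overlap)))
    table = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_raw", "overlap_ids"])
    if table.empty:
        table["fdr"] = []
        table["significant"] = []
        return table
    _, fdr, _, _ = multipletests(table["p_raw"], method="fdr_bh")
    table["fdr"] = fdr
    table["significant"] = table["fdr"] <= alpha
    return table.sort_values(["p_raw", "set_name"], kind="stable").reset_index(drop=True)
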