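"""Hypergeometric gene-set over-representation against GMT collections.

Plain over-representation analysis: for a query gene list and a gene
universe, each set's overlap is tested with the upper-tail
hypergeometric distribution, and p values are BH-adjusted across all
tested sets.  Set membership and the universe are opaque gene-id
strings; sets are intersected with the universe before testing, and
empty (within-universe) sets are dropped.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .differential import benjamini_hochberg
from .exceptions import InputError

logger = logging.getLogger(__name__)

__all__ = ["enrich"]


def enrich(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, set],
    universe: Iterable[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in gene sets.

    Returns a DataFrame sorted by p with one row per tested set:
    ``set``, ``K`` (set size within the universe), ``n`` (query size),
    ``k`` (overlap), ``p`` (upper-tail hypergeometric), ``q`` (BH),
    ``significant`` (q < fdr) and ``overlap_genes``.

    Query genes outside the universe are dropped (count logged); an
    empty query or empty collection raises.
    """
    universe = set(universe)
    if not universe:
        raise InputError("empty universe")
    query = set(query_genes)
    if not query:
        raise InputError("empty query gene list")
    if not gene_sets:
        raise InputError("empty gene-set collection")
    outside = query - universe
    if outside:
        logger.info("enrich: dropped %d query genes outside the universe", len(outside))
        query &= universe
    if not query:
        raise InputError("no query gene lies in the universe")

    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        inside = members & universe
        K = len(inside)
        if K == 0:
            continue
        overlap = sorted(inside & query)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, K, n, k, p, ",".join(overlap)))
    if not rows:
        raise InputError("no gene set intersects the universe")
    table = pd.DataFrame(rows, columns=["set", "K", "n", "k", "p", "overlap_genes"])
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    table["significant"] = table["q"] < fdr
    table = table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return table[["set", "K", "n", "k", "p", "q", "significant", "overlap_genes"]]
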