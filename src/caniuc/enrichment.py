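"""Hypergeometric over-representation of a dysregulated-gene list against
GMT gene-set collections, with Benjamini-Hochberg control across sets.

The background universe defaults to the tested (DE) gene universe rather
than all annotated genes, which corrects for expression-detectability
bias; it is a parameter, not a constant.
"""

from __future__ import annotations

import logging

import pandas as pd

from .de import bh_adjust
from .io import GeneSetCollection
from .positional import hypergeometric_enrichment

logger = logging.getLogger("caniuc")


def overrepresentation(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    uppercase: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Set members are restricted to the universe; query genes outside the
    universe are dropped with a warning. Per set, p is the upper tail of
    Hypergeometric(N=|universe|, K=|set n universe|, n=|query|) at
    k=|set n query|; q is BH-adjusted across sets. Rows are sorted by
    (q, p, set_name). ``uppercase`` folds all identifiers to upper case
    before matching (for human-ortholog GMTs).
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query gene list")
    if uppercase:
        query = {g.upper() for g in query}
        universe = {g.upper() for g in universe}
    stray = query - universe
    if stray:
        logger.warning(
            "dropping %d query genes absent from the universe", len(stray)
        )
    query = query & universe
    if not query:
        raise ValueError("no query genes remain inside the universe")

    N, n = len(universe), len(query)
    rows = []
    for name, gs in sets:
        members = {m.upper() for m in gs.members} if uppercase else set(gs.members)
        in_universe = members & universe
        overlap = sorted(in_universe & query)
        rows.append(
            {
                "set_name": name,
                "set_size": len(members),
                "universe_size": N,
                "query_size": n,
                "overlap_size": len(overlap),
                "p_hyper": hypergeometric_enrichment(len(overlap), n, len(in_universe), N),
                "overlap_members": ",".join(overlap),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name", "set_size", "universe_size", "query_size",
            "overlap_size", "p_hyper", "overlap_members",
        ],
    )
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        return out
    out["q"] = bh_adjust(out["p_hyper"].to_numpy())
    out = out.sort_values(["q", "p_hyper", "set_name"], kind="stable").reset_index(drop=True)
    return out[
        [
            "set_name", "set_size", "overlap_size", "universe_size",
            "query_size", "p_hyper", "q", "overlap_members",
        ]
    ]


def top_k(rows: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """First min(k, len) rows of an over-representation table (already
    sorted by q, then p, then name)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return rows.head(k).reset_index(drop=True)
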