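"""Hypergeometric over-representation analysis (ORA) for metabolite sets
and KO pathways.

The test asks whether a hit list (differential metabolites or KOs) lands in
an annotated set more often than chance given the measured universe: with N
universe members, K of them in the set and n hits, the p-value is the exact
hypergeometric upper tail P(X >= k) for the k observed hits in the set. The
enrichment ratio k / (n*K/N) compares observed to expected hits.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DifferentialTable, benjamini_hochberg
from .io_core import SetLibrary

logger = logging.getLogger("guildlink")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), capped at 1."""
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def ora_enrichment(
    hits: list[str],
    universe: list[str],
    library: SetLibrary,
    min_set_size: int = 2,
) -> pd.DataFrame:
    """One-sided hypergeometric ORA of ``hits`` against each library set.

    Set members are intersected with the universe first; sets smaller than
    ``min_set_size`` after intersection are dropped with a warning. Returns
    a table (one row per retained set) with N, K, n, k, enrichment_ratio,
    p and BH q, sorted by p.
    """
    universe_set = set(universe)
    if len(universe_set) != len(universe):
        raise ValueError("universe contains duplicate identifiers")
    offenders = [h for h in hits if h not in universe_set]
    if offenders:
        raise ValueError(f"hits not in universe: {offenders[:10]}")
    hit_set = set(hits)
    N = len(universe_set)
    n = len(hit_set)
    rows = []
    for name, members in library.items():
        in_universe = sorted(set(members) & universe_set)
        K = len(in_universe)
        if K < min_set_size:
            logger.warning("set %r has %d members in universe (< %d); dropped",
                           name, K, min_set_size)
            continue
        k = len(hit_set & set(in_universe))
        expected = n * K / N
        ratio = k / expected if expected > 0 else 0.0
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append({"set": name, "N": N, "K": K, "n": n, "k": k,
                     "enrichment_ratio": ratio, "p": p})
    df = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k",
                                     "enrichment_ratio", "p"])
    if len(df):
        df["q"] = benjamini_hochberg(df["p"].to_numpy())
        df = df.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df.set_index("set")


def split_hits_by_direction(diff: DifferentialTable) -> tuple[list[str], list[str]]:
    """Selected features split into (case-depleted, case-enriched) id lists."""
    sel = diff.table[diff.table["selected"]]
    depleted = sel.index[sel["direction"] == "case_depleted"].tolist()
    enriched = sel.index[sel["direction"] == "case_enriched"].tolist()
    return depleted, enriched
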