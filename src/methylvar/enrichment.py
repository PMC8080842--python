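"""Genomic-context over-representation of probe lists (Fisher's exact test).

For a probe list against the background of all analyzed probes, each
annotation category (CpG-island relation, gene-region group, enhancer
flag) is tested with a 2x2 table

    a = in list & in category      b = in list & out of category
    c = background & in category   d = background & out of category

where the background is the universe minus the list. The reported odds
ratio is the sample odds ratio (a*d)/(b*c); the p-value is the standard
two-sided Fisher exact probability (sum of hypergeometric probabilities
no larger than the observed table's).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ISLAND_RELATIONS, REGION_GROUPS
from .variability import bh_adjust


def fisher_exact(a: int, b: int, c: int, d: int, alternative: str = "two-sided"):
    """Sample odds ratio and Fisher exact p-value of a 2x2 table.

    The odds ratio is (a*d)/(b*c): ``inf`` when b*c = 0 with a*d > 0 and
    NaN when both products vanish.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError(f"counts must be non-negative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return odds, float(p)


def enrich_probe_list(probe_list, universe, annotation: pd.DataFrame,
                      alternative: str = "two-sided") -> pd.DataFrame:
    """Enrichment table over all annotation categories.

    ``probe_list`` must be a subset of ``universe``. Probes without
    annotation are excluded from both margins and counted in the
    ``n_unannotated`` DataFrame attribute.
    """
    probe_list = set(probe_list)
    universe = set(universe)
    if not probe_list <= universe:
        raise ValueError("probe list is not a subset of the universe")
    annotated = universe & set(annotation.index)
    n_unannotated = len(universe) - len(annotated)
    hits = probe_list & annotated
    background = annotated - hits
    ann = annotation.loc[sorted(annotated)]
    in_list = ann.index.isin(hits)

    categories = ([("island_relation", lvl) for lvl in ISLAND_RELATIONS]
                  + [("region_group", lvl) for lvl in REGION_GROUPS]
                  + [("enhancer", True)])
    rows = []
    for fieldname, level in categories:
        in_cat = (ann[fieldname] == level).to_numpy()
        a = int((in_cat & in_list).sum())
        b = int((~in_cat & in_list).sum())
        c = int((in_cat & ~in_list).sum())
        d = int((~in_cat & ~in_list).sum())
        odds, p = fisher_exact(a, b, c, d, alternative=alternative)
        rows.append({"field": fieldname, "category": str(level),
                     "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p_value": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy()) if len(table) \
        else np.array([])
    table.attrs["n_unannotated"] = n_unannotated
    return table
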