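"""Over-representation analysis of functional categories among CND genes.

Given a list of copy-number divergent genes, the percentage of list
genes annotated to each functional category (top-level BIN-style bins)
is compared to the percentage among all unmasked nuclear probesets on
the array with a one-sided Fisher's exact test (enrichment direction),
Benjamini-Hochberg corrected across categories.  A gene may belong to
several categories and counts once per category.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .calling import bh_adjust
from .datamodel import ValidationError

ORA_COLUMNS = (
    "category",
    "name",
    "in_list",
    "in_background",
    "pct_list",
    "pct_background",
    "fold",
    "p_raw",
    "p_adj",
    "significant",
)


def _category_sets(categories: pd.DataFrame) -> dict[str, set[str]]:
    for col in ("probeset_id", "category"):
        if col not in categories.columns:
            raise ValidationError(f"category map lacks column {col!r}")
    return {
        cat: set(grp["probeset_id"]) for cat, grp in categories.groupby("category")
    }


def ora(
    gene_list: Iterable[str],
    categories: pd.DataFrame,
    background: Iterable[str],
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-category Fisher's exact over-representation test.

    Parameters
    ----------
    gene_list
        Probeset ids of interest (must be a subset of ``background``).
    categories
        Tidy frame with probeset_id / category (and optional name).
    background
        All unmasked nuclear probesets on the array.
    alpha
        BH-adjusted significance cut-off (default 0.05).
    alternative
        'greater' for the usual enrichment test; 'two-sided' by flag.

    Returns a table sorted by raw p with counts, percentages, fold
    enrichment ((%list)/(%background)), raw and adjusted p-values.
    """
    gene_list = set(gene_list)
    background = set(background)
    if not gene_list or not background:
        raise ValidationError("gene list and background must be non-empty")
    outside = gene_list - background
    if outside:
        raise ValidationError(
            f"{len(outside)} list genes are not in the background (e.g. {sorted(outside)[:3]})"
        )
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unsupported alternative {alternative!r}")

    names = (
        categories.drop_duplicates("category").set_index("category")["name"]
        if "name" in categories.columns
        else pd.Series(dtype=str)
    )
    n_list = len(gene_list)
    n_bg = len(background)
    rows = []
    for cat, members in sorted(_category_sets(categories).items()):
        members = members & background
        a = len(gene_list & members)            # in list, in category
        b = n_list - a                          # in list, outside category
        c = len(members) - a                    # outside list, in category
        d = (n_bg - n_list) - c                 # outside both
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        pct_list = 100.0 * a / n_list
        pct_bg = 100.0 * len(members) / n_bg
        fold = pct_list / pct_bg if pct_bg > 0 else float("nan")
        rows.append(
            {
                "category": cat,
                "name": names.get(cat, ""),
                "in_list": a,
                "in_background": len(members),
                "pct_list": pct_list,
                "pct_background": pct_bg,
                "fold": fold,
                "p_raw": float(p),
            }
        )
    out = pd.DataFrame(rows, columns=[c for c in ORA_COLUMNS if c not in ("p_adj", "significant")])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] <= alpha
    return out.sort_values("p_raw", kind="stable").reset_index(drop=True)
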