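"""Rare-biosphere classification of taxa by relative-abundance thresholds.

Each taxon is assigned to exactly one of six categories from the per-sample
relative-abundance vector ``a``, with an upper threshold (default 1%) and a
lower threshold (default 0.01%):

========  =============================================================
AAT       always abundant: min(a) >= upper
CAT       conditionally abundant: max(a) >= upper, min(a) >= lower, not AAT
ART       always rare: max(a) < lower
CRT       conditionally rare: max(a) < upper and min(a) < lower
MT        moderate: lower <= min(a) and max(a) < upper
CRAT      conditionally rare and abundant: min(a) < lower and max(a) >= upper
========  =============================================================

Boundary semantics follow the printed definitions exactly: the upper
threshold is inclusive (>= 1% counts as abundant), the lower threshold is
exclusive (< 0.01% counts as rare).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORIES = ("AAT", "CAT", "ART", "CRT", "MT", "CRAT")

ABUNDANT_CATEGORIES = ("AAT", "CAT", "CRAT")
RARE_CATEGORIES = ("ART", "CRT")

__all__ = [
    "CATEGORIES",
    "classify_taxa",
    "group_rare_abundant",
    "categorize_profile",
]


def categorize_profile(a: np.ndarray, upper: float = 0.01, lower: float = 0.0001) -> str:
    """Category for one taxon's per-sample relative-abundance vector."""
    lo, hi = float(np.min(a)), float(np.max(a))
    if lo >= upper:
        return "AAT"
    if hi < lower:
        return "ART"
    if hi >= upper and lo < lower:
        return "CRAT"
    if hi >= upper:  # and lo >= lower (not AAT since lo < upper implied)
        return "CAT"
    if lo < lower:  # and hi < upper
        return "CRT"
    return "MT"  # lower <= lo, hi < upper


def classify_taxa(
    rel: pd.DataFrame, upper: float = 0.01, lower: float = 0.0001
) -> pd.DataFrame:
    """Classify every taxon of a samples x taxa proportion table.

    Taxa with zero total abundance are dropped (their profile is undefined
    after rarefaction).  Returns a DataFrame indexed by taxon_id with
    columns ``category`` and ``group``.
    """
    if not lower < upper:
        raise ValueError("lower threshold must be < upper threshold")
    if rel.shape[0] == 0 or rel.shape[1] == 0:
        raise ValueError("empty table")
    arr = rel.to_numpy(dtype=float)
    nonzero = arr.sum(axis=0) > 0
    arr = arr[:, nonzero]
    taxa = rel.columns[nonzero]

    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    cat = np.full(len(taxa), "MT", dtype=object)
    cat[(hi >= upper) & (lo >= lower) & (lo < upper)] = "CAT"
    cat[(hi < upper) & (lo < lower)] = "CRT"
    cat[lo >= upper] = "AAT"
    cat[hi < lower] = "ART"
    cat[(hi >= upper) & (lo < lower)] = "CRAT"

    out = pd.DataFrame({"category": cat}, index=taxa)
    out.index.name = "taxon_id"
    out["group"] = group_labels(out["category"])
    return out


def group_labels(categories: pd.Series, rare_group: str = "art_crt") -> pd.Series:
    """Map categories to the binary rare/abundant grouping.

    abundant = AAT + CAT + CRAT.  rare = ART + CRT by default; the
    ``rare_group="art_cat"`` switch reproduces the alternative ART + CAT
    reading found in parts of the literature (in which case CAT counts as
    both groups is avoided by letting rare win only for non-abundant taxa;
    here it is applied literally, so CAT becomes rare).
    """
    if rare_group == "art_crt":
        rare = set(RARE_CATEGORIES)
        abundant = set(ABUNDANT_CATEGORIES)
    elif rare_group == "art_cat":
        rare = {"ART", "CAT"}
        abundant = {"AAT", "CRAT"}
    else:
        raise ValueError(f"unknown rare_group: {rare_group!r}")
    out = pd.Series("neither", index=categories.index, dtype=object)
    out[categories.isin(abundant)] = "abundant"
    out[categories.isin(rare)] = "rare"
    return out


def group_rare_abundant(
    cls: pd.DataFrame, rare_group: str = "art_crt"
) -> dict[str, list[str]]:
    """Partition taxa into {'abundant', 'rare', 'neither'} identifier lists."""
    groups = group_labels(cls["category"], rare_group=rare_group)
    return {
        name: list(groups.index[groups == name])
        for name in ("abundant", "rare", "neither")
    }
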