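"""Venn-region computation and union/intersection building over DEG lists."""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

__all__ = ["venn_regions", "combine", "write_venn_regions"]


def _check_collection(collection: dict[str, list[str]]) -> dict[str, set[str]]:
    if len(set(collection)) != len(collection):
        raise ValueError("duplicate list names")
    return {name: set(ids) for name, ids in collection.items()}


def venn_regions(collection: dict[str, list[str]]) -> dict[str, set[str]]:
    """Exact membership regions: signature ("&"-joined sorted names) -> genes.

    Signatures partition the union of the lists; only non-empty regions are
    returned.  Works for any number of lists (diagrams are practical up to
    four).
    """
    sets = _check_collection(collection)
    if len(sets) < 2:
        raise ValueError("need >= 2 lists for Venn regions")
    names = sorted(sets)
    regions: dict[str, set[str]] = {}
    for gene in set.union(*sets.values()):
        sig = "&".join(n for n in names if gene in sets[n])
        regions.setdefault(sig, set()).add(gene)
    return regions


def combine(collection: dict[str, list[str]], mode: str = "union") -> list[str]:
    """Union or intersection of the lists, sorted by gene id."""
    sets = _check_collection(collection)
    if not sets:
        raise ValueError("need >= 1 list")
    if mode == "union":
        result = set.union(*sets.values())
    elif mode == "intersection":
        result = set.intersection(*sets.values())
        if not result:
            warnings.warn("intersection of the lists is empty", stacklevel=2)
    else:
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    return sorted(result)


def write_venn_regions(regions: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"signature": sig, "size": len(genes), "ids": ";".join(sorted(genes))}
        for sig, genes in sorted(regions.items())
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
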