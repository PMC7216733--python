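"""Readers, validators and sample filters for the two project input files.

Expected layout mirrors the workspace convention: ``Data/<project>/`` holds
``<project>_COUNTS.csv`` (first column gene ids, one column per sample) and
``<project>_TARGET.csv`` (first column sample ids, one column per declared
factor).  Separators ``,``, ``;`` and tab are auto-detected on the header
line; decimals use ``.``; encoding UTF-8.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import Annotation, CountMatrix, DesignTable, Project, ProjectError

__all__ = [
    "read_counts",
    "write_counts",
    "read_target",
    "align_and_validate",
    "filter_samples",
    "read_annotation",
]

log = logging.getLogger(__name__)

_SEPARATORS = (",", ";", "\t")


def _sniff_separator(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    counts = {sep: header.count(sep) for sep in _SEPARATORS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def read_counts(path: str | Path, sep: str | None = None) -> CountMatrix:
    """Read a gene x sample count table; first column = gene identifiers.

    Integral-valued floats (``"12.0"``) are accepted and coerced; negative,
    non-numeric or fractional entries raise :class:`ProjectError` naming the
    offending gene and sample.
    """
    path = Path(path)
    if not path.exists():
        raise ProjectError(f"count file not found: {path}")
    sep = sep or _sniff_separator(path)
    df = pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                gene = df.index[coerced.isna()][0]
                raise ProjectError(
                    f"non-numeric count at gene {gene!r}, sample {col!r}"
                )
            df[col] = coerced
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path: str | Path, sep: str = ",") -> None:
    df = cm.counts.copy()
    df.index.name = df.index.name or "Gene_ID"
    df.to_csv(Path(path), sep=sep, encoding="utf-8")


def read_target(
    path: str | Path,
    factor_names: Sequence[str],
    replicate_name: str | None = None,
    sep: str | None = None,
) -> DesignTable:
    """Read the target (design) table; first column = sample identifiers.

    Modality order is the order of first appearance, which fixes the
    reference level of each factor in the GLM coding downstream.
    """
    path = Path(path)
    if not path.exists():
        raise ProjectError(f"target file not found: {path}")
    sep = sep or _sniff_separator(path)
    df = pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8", dtype=str)
    df.index = df.index.astype(str)
    return DesignTable(df, list(factor_names), replicate_name)


def align_and_validate(
    counts: CountMatrix, design: DesignTable, name: str = "project"
) -> Project:
    """Reorder count columns to the target-table order and validate.

    The two sample-id sets must be equal; the design must be complete
    (every biological condition observed in >= 1 sample), otherwise the
    analysis stops with an error listing the missing combinations.
    """
    cset, dset = set(counts.sample_ids), set(design.sample_ids)
    if cset != dset:
        only_c = sorted(cset - dset)
        only_d = sorted(dset - cset)
        raise ProjectError(
            f"sample-id mismatch: only in counts {only_c}, only in target {only_d}"
        )
    design.check_complete()
    if counts.sample_ids != design.sample_ids:
        counts = counts.reorder_samples(design.sample_ids)
    return Project(counts, design, name)


def filter_samples(
    project: Project, rules: Sequence[tuple[str, str, str]]
) -> Project:
    """Keep/drop samples by (factor, modality, "keep"|"drop") rules.

    Drop rules remove matching samples; keep rules (per factor) retain only
    the named modalities.  Factors reduced to a single modality are removed
    from the design; the filtered design is re-validated for completeness.
    """
    design = project.design
    keep_mask = pd.Series(True, index=design.table.index)
    keeps: dict[str, set[str]] = {}
    for factor, modality, action in rules:
        if factor not in design.factors:
            raise ProjectError(f"unknown factor {factor!r}")
        if modality not in design.levels[factor]:
            raise ProjectError(f"unknown modality {modality!r} of factor {factor!r}")
        if action == "drop":
            keep_mask &= design.table[factor] != modality
        elif action == "keep":
            keeps.setdefault(factor, set()).add(modality)
        else:
            raise ProjectError(f"rule action must be 'keep' or 'drop', got {action!r}")
    for factor, modalities in keeps.items():
        keep_mask &= design.table[factor].isin(modalities)
    kept = design.table.index[keep_mask].tolist()
    if len(kept) < 2:
        raise ProjectError(f"filtering left {len(kept)} sample(s); need >= 2")
    new_design = design.subset(kept)
    new_design.check_complete()
    new_counts = project.counts.reorder_samples(kept)
    return Project(new_counts, new_design, project.name)


def read_annotation(path: str | Path, sep: str | None = None) -> Annotation:
    """Read a two-column gene/term file; duplicated pairs are removed.

    Pairs for genes absent from the count table are retained here — the
    universe restriction happens at enrichment-test time.
    """
    path = Path(path)
    if not path.exists():
        raise ProjectError(f"annotation file not found: {path}")
    sep = sep or _sniff_separator(path)
    rows: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ProjectError(f"malformed annotation row at line {lineno}: {line!r}")
            rows.append((parts[0].strip(), parts[1].strip()))
    # drop a header row if present (exact common header names only)
    if rows and rows[0][0].lower() in {"gene", "gene_id", "geneid"}:
        rows = rows[1:]
    if not rows:
        warnings.warn(f"annotation file {path} is empty", stacklevel=2)
    return Annotation(pd.DataFrame(rows, columns=["gene", "term"]))
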