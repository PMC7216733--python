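"""Core containers for a project: counts, design, annotation.

A project couples a gene x sample integer count matrix with a design
(target) table describing up to two biological factors and an optional
replicate factor.  The design must be *complete*: every combination of
biological-factor modalities is observed in at least one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "DesignTable",
    "Project",
    "Annotation",
    "ProjectError",
]


class ProjectError(ValueError):
    """Raised when an input file or project violates a structural constraint."""


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ProjectError(f"duplicate gene identifier(s): {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ProjectError(f"duplicate sample identifier(s): {dup}")
        if df.shape[1] < 2:
            raise ProjectError("a count matrix needs at least 2 samples")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = np.argwhere(~np.vectorize(np.isreal)(values))
            raise ProjectError(f"non-numeric count entries, first at {bad[:1]}")
        if not np.isfinite(values).all():
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ProjectError(
                f"non-finite count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ProjectError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if not np.allclose(values, np.round(values)):
            g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ProjectError(
                f"non-integral count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        self.counts = df.round().astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def reorder_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)])


@dataclass
class DesignTable:
    """Sample-level description of the experimental factors.

    ``table`` holds one row per sample (index = sample id) and one column
    per factor.  Modality order within a factor is the order of first
    appearance in the file; the first modality is the reference level of
    the GLM coding downstream.
    """

    table: pd.DataFrame
    biological_factors: list[str]
    replicate_factor: str | None = None
    levels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= len(self.biological_factors) <= 2:
            raise ProjectError("need 1 or 2 biological factors")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ProjectError(f"duplicate sample identifier(s): {dup}")
        for f in self.factors:
            if f not in self.table.columns:
                raise ProjectError(f"declared factor {f!r} missing from target table")
            col = self.table[f]
            if col.isna().any() or (col.astype(str).str.strip() == "").any():
                bad = self.table.index[
                    col.isna() | (col.astype(str).str.strip() == "")
                ].tolist()
                raise ProjectError(f"missing {f!r} value for sample(s) {bad}")
        self.table = self.table[self.factors].astype(str)
        if not self.levels:
            self.levels = {
                f: list(dict.fromkeys(self.table[f])) for f in self.factors
            }
        for f in self.biological_factors:
            if len(self.levels[f]) < 2:
                raise ProjectError(
                    f"biological factor {f!r} needs >= 2 modalities, "
                    f"found {self.levels[f]}"
                )

    @property
    def factors(self) -> list[str]:
        fs = list(self.biological_factors)
        if self.replicate_factor is not None:
            fs.append(self.replicate_factor)
        return fs

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    def condition_of(self, sample: str) -> tuple[str, ...]:
        return tuple(self.table.loc[sample, f] for f in self.biological_factors)

    @property
    def conditions(self) -> list[tuple[str, ...]]:
        """All combinations of biological-factor modalities, in level order."""
        return list(product(*(self.levels[f] for f in self.biological_factors)))

    def samples_in_condition(self, condition: tuple[str, ...]) -> list[str]:
        mask = np.ones(len(self.table), dtype=bool)
        for f, mod in zip(self.biological_factors, condition):
            mask &= (self.table[f] == mod).to_numpy()
        return self.table.index[mask].tolist()

    def check_complete(self) -> None:
        missing = [c for c in self.conditions if not self.samples_in_condition(c)]
        if missing:
            raise ProjectError(
                "incomplete design: no sample for condition(s) "
                + ", ".join("x".join(c) for c in missing)
            )

    def subset(self, sample_ids: Sequence[str]) -> "DesignTable":
        sub = self.table.loc[list(sample_ids)]
        bio, rep = [], self.replicate_factor
        for f in self.biological_factors:
            if sub[f].nunique() >= 2:
                bio.append(f)
        if rep is not None and sub[rep].nunique() < 2:
            rep = None
        if not bio:
            raise ProjectError("filtering left no biological factor with 2 modalities")
        levels = {
            f: [m for m in self.levels[f] if m in set(sub[f])]
            for f in bio + ([rep] if rep else [])
        }
        return DesignTable(sub, bio, rep, levels)


@dataclass
class Project:
    """Validated pairing of a count matrix with its design table."""

    counts: CountMatrix
    design: DesignTable
    name: str = "project"

    def __post_init__(self) -> None:
        if self.counts.sample_ids != self.design.sample_ids:
            raise ProjectError(
                "count columns and target rows disagree; "
                "use align_and_validate to reorder"
            )

    @property
    def n_genes(self) -> int:
        return len(self.counts.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.counts.sample_ids)


@dataclass
class Annotation:
    """Set of (gene, term) pairs; genes may carry any number of terms."""

    pairs: pd.DataFrame  # columns: gene, term (deduplicated)

    def __post_init__(self) -> None:
        self.pairs = (
            self.pairs[["gene", "term"]].astype(str).drop_duplicates().reset_index(drop=True)
        )

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.pairs["term"].unique())

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.pairs["gene"].unique())

    def genes_for_term(self, term: str) -> set[str]:
        return set(self.pairs.loc[self.pairs["term"] == term, "gene"])

    def __len__(self) -> int:
        return len(self.pairs)
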