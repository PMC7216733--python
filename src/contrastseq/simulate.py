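"""Synthetic factorial RNA-seq datasets with known ground truth.

Counts are drawn NB with ``variance = mu + phi mu^2``; per-gene condition
means are built additively in log2 space from a baseline plus planted
main-factor and interaction effects, and scaled by per-sample library-size
multipliers.  The generator emits the same CSV dialect the readers accept
(counts table + Table-1-style target table) and returns the planted truth:
condition mean matrix, per-effect gene sets and (via the contrast weights)
the exact per-contrast differentially expressed sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd

from .contrasts import Contrast
from .datatypes import Annotation, CountMatrix, DesignTable

__all__ = [
    "SimulationSpec",
    "SyntheticTruth",
    "simulate_counts",
    "simulate_coexpression",
    "simulate_annotation",
    "write_simulated_project",
]


@dataclass
class SimulationSpec:
    """Parameters of a complete (possibly unbalanced) factorial simulation."""

    n_genes: int = 2000
    factor_names: tuple[str, ...] = ("FactorA", "FactorB")
    modalities: tuple[tuple[str, ...], ...] = (("A1", "A2"), ("B1", "B2"))
    replicates: int | dict[tuple[str, ...], int] = 3
    replicate_name: str = "Replicate"
    baseline_log2_range: tuple[float, float] = (3.0, 12.0)
    library_sigma: float = 0.1
    dispersion: float = 0.1
    frac_de_a: float = 0.0
    frac_de_b: float = 0.0
    frac_de_interaction: float = 0.0
    effect_log2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need >= 1 gene")
        if len(self.factor_names) != len(self.modalities):
            raise ValueError("one modality tuple per factor required")
        if not 1 <= len(self.factor_names) <= 2:
            raise ValueError("1 or 2 biological factors supported")
        for frac in (self.frac_de_a, self.frac_de_b, self.frac_de_interaction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("DE fractions must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def conditions(self) -> list[tuple[str, ...]]:
        return list(product(*self.modalities))

    def n_replicates(self, condition: tuple[str, ...]) -> int:
        if isinstance(self.replicates, dict):
            return self.replicates[condition]
        return int(self.replicates)


@dataclass
class SyntheticTruth:
    """Planted structure: condition log2 means and per-effect gene sets."""

    condition_log2_means: pd.DataFrame  # genes x conditions ("a|b" labels)
    effect_genes: dict[str, list[str]]  # "main_a" / "main_b" / "interaction"
    cluster_labels: pd.Series | None = None
    enriched_terms: dict[str, list[str]] = field(default_factory=dict)

    def true_de_genes(self, contrast: Contrast) -> set[str]:
        """Genes whose planted condition means give this contrast a
        non-zero value (exact, from the contrast's condition weights)."""
        value = np.zeros(len(self.condition_log2_means))
        for cond, w in contrast.weights_on_conditions.items():
            value += float(w) * self.condition_log2_means["|".join(cond)].to_numpy()
        mask = np.abs(value) > 1e-9
        return set(self.condition_log2_means.index[mask])

    def to_json(self) -> str:
        payload = {
            "condition_log2_means": {
                "genes": self.condition_log2_means.index.tolist(),
                "conditions": self.condition_log2_means.columns.tolist(),
                "values": self.condition_log2_means.to_numpy().tolist(),
            },
            "effect_genes": self.effect_genes,
            "cluster_labels": (
                self.cluster_labels.to_dict() if self.cluster_labels is not None else None
            ),
            "enriched_terms": self.enriched_terms,
        }
        return json.dumps(payload)


def _design_from_spec(spec: SimulationSpec) -> DesignTable:
    rows, index = [], []
    for cond in spec.conditions:
        for r in range(1, spec.n_replicates(cond) + 1):
            index.append("_".join(cond) + f"_R{r}")
            rows.append(list(cond) + [f"R{r}"])
    table = pd.DataFrame(
        rows, index=index, columns=list(spec.factor_names) + [spec.replicate_name]
    )
    replicate = spec.replicate_name
    if all(spec.n_replicates(c) == 1 for c in spec.conditions):
        table = table.drop(columns=[replicate])
        replicate = None
    return DesignTable(table, list(spec.factor_names), replicate)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def simulate_counts(
    spec: SimulationSpec,
) -> tuple[CountMatrix, DesignTable, SyntheticTruth]:
    """NB counts for a complete factorial design with planted DE genes.

    Effect gene sets (main A, main B, interaction) are disjoint; each
    affected gene receives ``+-effect_log2`` on one randomly chosen
    non-reference modality (or non-reference cell for interactions).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    design = _design_from_spec(spec)
    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    conditions = spec.conditions
    cond_labels = ["|".join(c) for c in conditions]

    baseline = rng.uniform(*spec.baseline_log2_range, size=spec.n_genes)
    log2_mu = np.tile(baseline[:, None], (1, len(conditions)))

    n_a = round(spec.frac_de_a * spec.n_genes)
    n_b = round(spec.frac_de_b * spec.n_genes) if len(spec.factor_names) == 2 else 0
    n_ab = (
        round(spec.frac_de_interaction * spec.n_genes)
        if len(spec.factor_names) == 2
        else 0
    )
    perm = rng.permutation(spec.n_genes)
    idx_a = perm[:n_a]
    idx_b = perm[n_a : n_a + n_b]
    idx_ab = perm[n_a + n_b : n_a + n_b + n_ab]

    def add_main(indices: np.ndarray, axis: int) -> None:
        mods = spec.modalities[axis]
        for g in indices:
            target = mods[rng.integers(1, len(mods))]
            sign = rng.choice([-1.0, 1.0])
            for ci, cond in enumerate(conditions):
                if cond[axis] == target:
                    log2_mu[g, ci] += sign * spec.effect_log2

    add_main(idx_a, 0)
    if len(spec.factor_names) == 2:
        add_main(idx_b, 1)
        mods_a, mods_b = spec.modalities
        for g in idx_ab:
            ta = mods_a[rng.integers(1, len(mods_a))]
            tb = mods_b[rng.integers(1, len(mods_b))]
            sign = rng.choice([-1.0, 1.0])
            ci = conditions.index((ta, tb))
            log2_mu[g, ci] += sign * spec.effect_log2

    samples = design.sample_ids
    lib_mult = np.exp(rng.normal(0.0, spec.library_sigma, size=len(samples)))
    cond_of = [conditions.index(design.condition_of(s)) for s in samples]
    mu = (2.0 ** log2_mu)[:, cond_of] * lib_mult[None, :]
    counts = _nb_draw(rng, mu, spec.dispersion)
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    truth = SyntheticTruth(
        condition_log2_means=pd.DataFrame(log2_mu, index=genes, columns=cond_labels),
        effect_genes={
            "main_a": [genes[i] for i in sorted(idx_a)],
            "main_b": [genes[i] for i in sorted(idx_b)],
            "interaction": [genes[i] for i in sorted(idx_ab)],
        },
    )
    return cm, design, truth


def _cluster_patterns(n_clusters: int, n_conditions: int) -> np.ndarray:
    """Distinct condition-weight patterns: most of the mass on a subset of
    conditions (singletons first, then pairs, triples, ...)."""
    subsets: list[tuple[int, ...]] = []
    for size in range(1, n_conditions + 1):
        subsets.extend(combinations(range(n_conditions), size))
        if len(subsets) >= n_clusters:
            break
    if len(subsets) < n_clusters:
        raise ValueError(
            f"cannot build {n_clusters} distinct patterns over {n_conditions} conditions"
        )
    patterns = np.full((n_clusters, n_conditions), np.nan)
    major = 0.85
    for c, subset in enumerate(subsets[:n_clusters]):
        w = np.full(n_conditions, (1.0 - major) / (n_conditions - len(subset))
                    if len(subset) < n_conditions else 0.0)
        w[list(subset)] = major / len(subset)
        patterns[c] = w / w.sum()
    return patterns


def simulate_coexpression(
    n_clusters: int = 7,
    genes_per_cluster: int | list[int] = 100,
    spec: SimulationSpec | None = None,
    total_log2_range: tuple[float, float] = (10.0, 13.0),
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[CountMatrix, DesignTable, pd.Series]:
    """Counts whose genes share cluster-specific condition profiles.

    Each cluster concentrates a fixed fraction of a gene's expression on a
    cluster-specific subset of conditions; genes differ in total abundance
    but share the relative profile up to NB noise, so profile
    normalization aligns cluster members.  Returns (counts, design,
    labels 1..n_clusters).
    """
    if n_clusters < 2:
        raise ValueError("need >= 2 clusters")
    spec = spec or SimulationSpec(seed=seed)
    rng = np.random.default_rng(seed)
    design = _design_from_spec(spec)
    conditions = spec.conditions
    sizes = (
        [genes_per_cluster] * n_clusters
        if isinstance(genes_per_cluster, int)
        else list(genes_per_cluster)
    )
    if len(sizes) != n_clusters:
        raise ValueError("one size per cluster required")
    patterns = _cluster_patterns(n_clusters, len(conditions))
    samples = design.sample_ids
    cond_of = np.array([conditions.index(design.condition_of(s)) for s in samples])
    reps = np.array([spec.n_replicates(conditions[c]) for c in cond_of])

    genes, labels, mu_rows = [], [], []
    g = 0
    for c, size in enumerate(sizes):
        total = 2.0 ** rng.uniform(*total_log2_range, size=size)
        per_sample_weight = patterns[c][cond_of] / reps
        for t in total:
            genes.append(f"G{g + 1:05d}")
            labels.append(c + 1)
            mu_rows.append(t * per_sample_weight)
            g += 1
    mu = np.vstack(mu_rows)
    counts = _nb_draw(rng, mu, dispersion)
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    return cm, design, pd.Series(labels, index=genes, name="cluster")


def simulate_annotation(
    genes: list[str],
    n_terms: int = 20,
    planted: dict[str, list[str]] | None = None,
    background_rate: float = 0.02,
    seed: int = 0,
) -> Annotation:
    """Annotation with planted (term -> gene set) pairs plus background noise.

    Background pairs attach each background term to each gene independently
    with probability ``background_rate``.  Deterministic given ``seed``.
    """
    if not 0.0 <= background_rate <= 1.0:
        raise ValueError("background_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    for term, members in (planted or {}).items():
        rows.extend((g, term) for g in members)
    for t in range(n_terms):
        term = f"T{t + 1:04d}"
        hits = rng.random(len(genes)) < background_rate
        rows.extend((g, term) for g, hit in zip(genes, hits) if hit)
    return Annotation(pd.DataFrame(rows, columns=["gene", "term"]))


def write_simulated_project(
    outdir: str | Path,
    name: str,
    counts: CountMatrix,
    design: DesignTable,
    truth: SyntheticTruth | None = None,
    spec: SimulationSpec | None = None,
) -> None:
    """Write ``<name>_COUNTS.csv`` / ``<name>_TARGET.csv`` (+ truth/spec)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = counts.counts.copy()
    df.index.name = "Gene_ID"
    df.to_csv(outdir / f"{name}_COUNTS.csv")
    target = design.table.copy()
    target.index.name = "Sample"
    target.to_csv(outdir / f"{name}_TARGET.csv")
    if truth is not None:
        (outdir / f"{name}_truth.json").write_text(truth.to_json())
    if spec is not None:
        payload = asdict(spec)
        payload["replicates"] = (
            {"|".join(k): v for k, v in spec.replicates.items()}
            if isinstance(spec.replicates, dict)
            else spec.replicates
        )
        (outdir / f"{name}_simspec.json").write_text(json.dumps(payload, indent=1))
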