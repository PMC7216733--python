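"""Low-count filtering and between-sample normalization (TMM / RLE).

Filtering happens on CPM computed from the *raw* library sizes and precedes
normalization; the normalization factors are then computed on the filtered
matrix.  Both factor methods are rescaled so their geometric mean is 1, so
``effective size = library size x factor`` keeps the count scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import CountMatrix, Project, ProjectError

__all__ = [
    "NormalizationResult",
    "FilterReport",
    "compute_cpm",
    "filter_low_expressed",
    "tmm_factors",
    "rle_factors",
    "normalization_factors",
    "normalized_counts",
]


@dataclass
class NormalizationResult:
    """Per-sample scaling factors with geometric mean 1."""

    method: str  # "TMM" | "RLE"
    sample_ids: list[str]
    factors: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.library_sizes * self.factors


@dataclass
class FilterReport:
    strategy: str
    cpm_cutoff: float
    kept_genes: list[str]
    removed_genes: list[str]


def compute_cpm(counts: CountMatrix, effective_sizes: np.ndarray) -> np.ndarray:
    """counts per million: ``cpm_gj = y_gj * 1e6 / effective_size_j``."""
    sizes = np.asarray(effective_sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("effective sizes must be > 0")
    return counts.values * 1e6 / sizes[np.newaxis, :]


def filter_low_expressed(
    project: Project,
    strategy: str = "NbConditions",
    cpm_cutoff: float = 1.0,
) -> tuple[Project, FilterReport]:
    """Remove unexpressed / low-count genes before normalization.

    ``NbConditions`` keeps gene g iff its mean CPM within at least one
    biological condition reaches the cutoff.  ``NbReplicates`` keeps g iff
    its CPM reaches the cutoff in at least r samples, r being the minimum
    number of replicates over the conditions.  CPM uses raw library sizes.
    """
    if strategy not in ("NbConditions", "NbReplicates"):
        raise ValueError(f"unknown filter strategy {strategy!r}")
    if cpm_cutoff < 0:
        raise ValueError("cpm_cutoff must be >= 0")
    counts = project.counts
    design = project.design
    cpm = compute_cpm(counts, counts.library_sizes.astype(float))
    sample_pos = {s: i for i, s in enumerate(counts.sample_ids)}
    cond_samples = [
        [sample_pos[s] for s in design.samples_in_condition(c)]
        for c in design.conditions
    ]
    if strategy == "NbConditions":
        keep = np.zeros(cpm.shape[0], dtype=bool)
        for idx in cond_samples:
            keep |= cpm[:, idx].mean(axis=1) >= cpm_cutoff
    else:
        r = min(len(idx) for idx in cond_samples)
        keep = (cpm >= cpm_cutoff).sum(axis=1) >= r
    genes = np.asarray(counts.gene_ids)
    kept = genes[keep].tolist()
    removed = genes[~keep].tolist()
    if not kept:
        raise ProjectError("filtering removed every gene; lower the cutoff")
    filtered = Project(counts.subset_genes(kept), design, project.name)
    return filtered, FilterReport(strategy, cpm_cutoff, kept, removed)


def _rescale_geomean(factors: np.ndarray) -> np.ndarray:
    return factors / np.exp(np.mean(np.log(factors)))


def tmm_factors(
    counts: CountMatrix,
    log_ratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
    weighted: bool = True,
) -> NormalizationResult:
    """Trimmed mean of M-values scaling factors.

    For each sample k against the reference r, over genes positive in both:
    ``M_g = log2((y_gk/N_k)/(y_gr/N_r))`` and
    ``A_g = 0.5*log2((y_gk/N_k)*(y_gr/N_r))``.  Genes in the upper/lower
    ``log_ratio_trim`` tail of M or ``abundance_trim`` tail of A are
    dropped; the factor is ``2**(weighted mean of the remaining M)`` with
    inverse asymptotic-binomial-variance weights.  The reference sample is
    the one whose upper-quartile/total ratio is closest to the mean of that
    ratio across samples.  Factors are rescaled to geometric mean 1.
    """
    y = counts.values.astype(float)
    n_samples = y.shape[1]
    if n_samples < 2:
        raise ProjectError("TMM needs >= 2 samples")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = [counts.sample_ids[j] for j in np.where(lib == 0)[0]]
        raise ProjectError(f"sample(s) with all-zero counts: {bad}")
    # reference: upper-quartile/total closest to the across-sample mean
    uq = np.array([np.quantile(y[y[:, j] > 0, j], 0.75) if (y[:, j] > 0).any() else 0.0
                   for j in range(n_samples)])
    ratio = uq / lib
    ref = int(np.argmin(np.abs(ratio - ratio.mean())))

    factors = np.ones(n_samples)
    yr, nr = y[:, ref], lib[ref]
    for k in range(n_samples):
        if k == ref:
            continue
        yk, nk = y[:, k], lib[k]
        both = (yk > 0) & (yr > 0)
        if not both.any():
            continue
        pk, pr = yk[both] / nk, yr[both] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        if np.allclose(m, m[0]):  # identical profiles up to scale
            factors[k] = 2 ** m[0]
            continue
        n = m.size
        lo_m, hi_m = np.floor(n * log_ratio_trim) + 1, n - np.floor(n * log_ratio_trim)
        lo_a, hi_a = np.floor(n * abundance_trim) + 1, n - np.floor(n * abundance_trim)
        rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
        rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        if weighted:
            w = 1.0 / (
                (1.0 - yk[both] / nk) / yk[both] + (1.0 - yr[both] / nr) / yr[both]
            )
            factors[k] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
        else:
            factors[k] = 2 ** np.mean(m[keep])
    return NormalizationResult(
        "TMM", counts.sample_ids, _rescale_geomean(factors), lib
    )


def rle_factors(counts: CountMatrix) -> NormalizationResult:
    """Relative log expression (median-of-ratios) scaling factors.

    ``s_j = median_g y_gj / (prod_k y_gk)^(1/m)`` over genes positive in
    every sample; converted to factors ``s_j / N_j`` rescaled to geometric
    mean 1, so effective sizes are proportional to ``s_j``.
    """
    y = counts.values.astype(float)
    lib = y.sum(axis=0)
    all_pos = (y > 0).all(axis=1)
    if not all_pos.any():
        raise ProjectError("RLE needs >= 1 gene with non-zero counts in all samples")
    sub = y[all_pos]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    size = np.median(sub / geo[:, np.newaxis], axis=0)
    factors = _rescale_geomean(size / lib)
    return NormalizationResult("RLE", counts.sample_ids, factors, lib)


def normalization_factors(counts: CountMatrix, method: str = "TMM") -> NormalizationResult:
    if method == "TMM":
        return tmm_factors(counts)
    if method == "RLE":
        return rle_factors(counts)
    raise ValueError(f"unknown normalization method {method!r}")


def normalized_counts(counts: CountMatrix, norm: NormalizationResult) -> np.ndarray:
    """Counts rescaled to the mean effective size (stays on the count scale)."""
    eff = norm.effective_sizes
    return counts.values * (eff.mean() / eff)[np.newaxis, :]
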