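"""Quality-control summaries: library sizes, count distributions, sample
clustering (Ward on Euclidean distances) and PCA.

All panels are emitted as machine-readable tables; the transform used for
the multivariate panels is ``log2(normalized count + 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .datatypes import Project
from .normalization import NormalizationResult, normalized_counts

__all__ = ["QCReport", "qc_summaries", "pca_samples", "write_qc_report"]


@dataclass
class QCReport:
    library_sizes: pd.Series  # per sample
    boxplot_stats: pd.DataFrame  # quartiles of raw and normalized log2 counts
    dendrogram: np.ndarray  # scipy linkage matrix over samples
    sample_order: list[str]
    pca_coordinates: pd.DataFrame  # samples x PCs
    percent_variance: np.ndarray


def pca_samples(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centered (unscaled) PCA of the rows of ``x`` via SVD.

    Returns (coordinates, percent variance per axis); axes are ordered by
    decreasing variance and signs are fixed so each axis' largest-magnitude
    loading is positive (determinism).
    """
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    coords = u * s
    # deterministic sign: largest |coordinate| positive per axis
    for a in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, a])))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    var = s**2
    pct = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return coords, pct


def _quartiles(mat: np.ndarray, prefix: str, samples: list[str]) -> pd.DataFrame:
    qs = np.quantile(mat, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0)
    return pd.DataFrame(
        qs.T,
        index=samples,
        columns=[f"{prefix}_{q}" for q in ("min", "q25", "median", "q75", "max")],
    )


def qc_summaries(project: Project, norm: NormalizationResult) -> QCReport:
    """Summaries before/after normalization on log2(count + 1) scale."""
    samples = project.counts.sample_ids
    if norm.sample_ids != samples:
        raise ValueError("normalization result does not match project samples")
    raw = project.counts.values.astype(float)
    normed = normalized_counts(project.counts, norm)
    log_raw = np.log2(raw + 1.0)
    log_norm = np.log2(normed + 1.0)

    box = pd.concat(
        [_quartiles(log_raw, "raw", samples), _quartiles(log_norm, "norm", samples)],
        axis=1,
    )
    # Ward linkage on Euclidean distances between sample profiles
    z = linkage(pdist(log_norm.T, metric="euclidean"), method="ward")
    coords, pct = pca_samples(log_norm.T)
    pcs = pd.DataFrame(
        coords,
        index=samples,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return QCReport(
        library_sizes=pd.Series(project.counts.library_sizes, index=samples),
        boxplot_stats=box,
        dendrogram=z,
        sample_order=samples,
        pca_coordinates=pcs,
        percent_variance=pct,
    )


def write_qc_report(report: QCReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.library_sizes.rename("library_size").to_csv(outdir / "library_sizes.csv")
    report.boxplot_stats.to_csv(outdir / "boxplot_stats.csv")
    pcs = report.pca_coordinates.copy()
    pcs.to_csv(outdir / "pca_coordinates.csv")
    pd.Series(
        report.percent_variance,
        index=[f"PC{i + 1}" for i in range(len(report.percent_variance))],
        name="percent_variance",
    ).to_csv(outdir / "pca_variance.csv")
    merges = [
        {
            "left": int(row[0]),
            "right": int(row[1]),
            "height": float(row[2]),
            "size": int(row[3]),
        }
        for row in report.dendrogram
    ]
    (outdir / "dendrogram.json").write_text(
        json.dumps({"samples": report.sample_order, "merges": merges}, indent=1)
    )
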