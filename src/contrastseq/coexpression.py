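"""Gaussian-mixture co-expression clustering with two-loop ICL selection.

Genes are represented by their normalized expression *profile* (the row-
normalized vector of normalized counts across samples, summing to 1) and
transformed by ``arcsin(sqrt(p))`` to stabilize variances.  A
multidimensional Gaussian mixture with unequal proportions and general
(full) covariance matrices is fitted by EM for a range of subpopulation
counts K; the number of clusters is chosen by minimizing the Integrated
Completed Likelihood, ``ICL = -2 logL + nu_K log n + 2 Ent`` with ``Ent``
the posterior entropy.

EM is sensitive to its starting point, so each K uses a small-EM strategy:
many short (10-iteration) runs from k-means++-seeded responsibilities, the
best of which is run to convergence.  Model selection runs in two loops: a
coarse grid (5, 10, ..., 30 by default, few starts each) locates an
interval, which a second loop re-estimates with many starts.  Genes below
the mean-normalized-count filter are assigned to Cluster 0.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus

from .datatypes import CountMatrix
from .normalization import NormalizationResult, normalized_counts

__all__ = [
    "expression_profiles",
    "arcsine_transform",
    "CoexpressionGMM",
    "CoexpressionModel",
    "icl",
    "select_model",
    "CoexpressionResults",
]

_EM_TOL = 1e-8
_EM_MAX_ITER = 1000
_SHORT_EM_ITERS = 10
_COV_REG = 1e-6


def expression_profiles(
    counts: CountMatrix,
    norm: NormalizationResult,
    mean_filter_cutoff: float = 50.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Row-normalized profiles of the genes passing the low-mean filter.

    Genes whose mean normalized count is below the cutoff (and all-zero
    genes) go to Cluster 0 and are returned separately.
    """
    if len(counts.gene_ids) == 0:
        raise ValueError("empty gene list")
    normed = normalized_counts(counts, norm)
    means = normed.mean(axis=1)
    keep = (means >= mean_filter_cutoff) & (normed.sum(axis=1) > 0)
    genes = np.asarray(counts.gene_ids)
    cluster0 = genes[~keep].tolist()
    if not keep.any():
        raise ValueError(
            "every gene fell below the mean normalized count cutoff; "
            "lower mean_filter_cutoff"
        )
    sub = normed[keep]
    profiles = sub / sub.sum(axis=1, keepdims=True)
    return (
        pd.DataFrame(profiles, index=genes[keep], columns=counts.sample_ids),
        cluster0,
    )


def arcsine_transform(profiles: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Variance-stabilizing ``arcsin(sqrt(p))`` on proportions in [0, 1]."""
    p = np.asarray(profiles, dtype=float)
    if (p < -1e-12).any() or (p > 1 + 1e-12).any():
        raise ValueError("profile entries must lie in [0, 1]")
    return np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# EM machinery


def _regularize(cov: np.ndarray, reg: float) -> np.ndarray:
    """Symmetrize, add the dataset-scaled ridge, escalate until Cholesky
    succeeds (the constant ridge keeps EM effectively monotone; the
    escalation is a rare numerical fallback)."""
    d = cov.shape[0]
    out = (cov + cov.T) / 2.0 + reg * np.eye(d)
    bump = max(reg, 1e-12)
    for _ in range(20):
        try:
            np.linalg.cholesky(out)
            return out
        except np.linalg.LinAlgError:
            out = out + bump * np.eye(d)
            bump *= 10.0
    raise np.linalg.LinAlgError("covariance could not be regularized")


def _log_gauss(data: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = data.shape[1]
    chol = np.linalg.cholesky(cov)
    diff = data - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


@dataclass
class CoexpressionModel:
    """Fitted Gaussian mixture over transformed profiles."""

    K: int
    proportions: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    posteriors: np.ndarray  # (n, K) responsibilities tau
    loglik: float
    n_obs: int
    converged: bool
    loglik_history: list[float] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    @property
    def n_free_parameters(self) -> int:
        d = self.dim
        return (self.K - 1) + self.K * d + self.K * d * (d + 1) // 2

    @property
    def entropy(self) -> float:
        tau = np.clip(self.posteriors, 1e-300, 1.0)
        return float(-np.sum(self.posteriors * np.log(tau)))

    @property
    def icl(self) -> float:
        return icl(self, self.n_obs)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_free_parameters * np.log(self.n_obs)

    def hard_labels(self) -> np.ndarray:
        """argmax-posterior component index per gene (0-based, unrelabeled)."""
        return np.argmax(self.posteriors, axis=1)


def icl(model: CoexpressionModel, n: int) -> float:
    """Integrated completed likelihood, soft-entropy form (= BIC + 2 Ent)."""
    return float(
        -2.0 * model.loglik + model.n_free_parameters * np.log(n) + 2.0 * model.entropy
    )


def _e_step(
    data: np.ndarray, pi: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> tuple[np.ndarray, float]:
    log_comp = np.stack(
        [np.log(max(pi[k], 1e-300)) + _log_gauss(data, means[k], covs[k])
         for k in range(len(pi))],
        axis=1,
    )
    m = log_comp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.sum(np.exp(log_comp - m), axis=1))
    tau = np.exp(log_comp - lse[:, None])
    return tau, float(np.sum(lse))


def _m_step(
    data: np.ndarray, tau: np.ndarray, reg: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = data.shape
    nk = tau.sum(axis=0)
    nk = np.clip(nk, 1e-10, None)
    pi = nk / nk.sum()
    means = (tau.T @ data) / nk[:, None]
    covs = np.empty((tau.shape[1], d, d))
    for k in range(tau.shape[1]):
        diff = data - means[k]
        cov = (tau[:, k][:, None] * diff).T @ diff / nk[k]
        covs[k] = _regularize(cov, reg)
    return pi, means, covs


def _init_responsibilities(data: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding: hard assignment to K seeded centers."""
    seed = int(rng.integers(0, 2**31 - 1))
    centers, _ = kmeans_plusplus(data, n_clusters=K, random_state=seed)
    d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    # softened assignment: keeps every initial covariance well-conditioned
    tau = np.full((data.shape[0], K), 0.1 / max(K - 1, 1))
    tau[np.arange(data.shape[0]), np.argmin(d2, axis=1)] = 0.9
    return tau


def _run_em(
    data: np.ndarray,
    tau0: np.ndarray,
    max_iter: int,
    tol: float = _EM_TOL,
) -> CoexpressionModel:
    n, _ = data.shape
    K = tau0.shape[1]
    reg = _COV_REG * float(np.mean(np.var(data, axis=0)))
    pi, means, covs = _m_step(data, tau0, reg)
    history: list[float] = []
    prev = -np.inf
    converged = False
    tau = tau0
    for _ in range(max_iter):
        tau, ll = _e_step(data, pi, means, covs)
        # EM guarantees a non-decreasing likelihood (up to the covariance
        # regularization); enforced as an internal consistency check
        if history and ll < history[-1] - 1e-6 * (abs(history[-1]) + 1.0):
            raise AssertionError(
                f"EM log-likelihood decreased: {history[-1]} -> {ll}"
            )
        history.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll
        pi, means, covs = _m_step(data, tau, reg)
    return CoexpressionModel(
        K=K,
        proportions=pi,
        means=means,
        covariances=covs,
        posteriors=tau,
        loglik=history[-1] if history else -np.inf,
        n_obs=n,
        converged=converged,
        loglik_history=history,
    )


class CoexpressionGMM:
    """Gaussian-mixture model over arcsine-transformed profiles.

    ``fit(K, ...)`` runs the small-EM strategy for a single K;
    :func:`select_model` performs the full two-loop ICL selection.
    """

    def __init__(self, data: np.ndarray, gene_ids: list[str] | None = None) -> None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be genes x samples")
        self.data = data
        self.gene_ids = (
            list(gene_ids) if gene_ids is not None else [str(i) for i in range(len(data))]
        )

    def fit(self, K: int, n_inits: int = 10, seed: int = 0, loop_tag: int = 0) -> CoexpressionModel:
        """Best-of-``n_inits`` small-EM runs followed by EM to convergence.

        Deterministic given ``seed``: every (loop, K, init) triple derives
        its own child seed, so serial and parallel execution agree.
        """
        n, d = self.data.shape
        if K < 1:
            raise ValueError("K must be >= 1")
        if K >= n:
            raise ValueError(f"K={K} must be smaller than the number of genes {n}")
        if d > n:
            warnings.warn(f"dimension {d} exceeds number of genes {n}", stacklevel=2)
        best_short: CoexpressionModel | None = None
        best_tau0: np.ndarray | None = None
        for init in range(n_inits):
            rng = np.random.Generator(
                np.random.PCG64(np.random.SeedSequence((seed, loop_tag, K, init)))
            )
            tau0 = _init_responsibilities(self.data, K, rng)
            model = _run_em(self.data, tau0, max_iter=_SHORT_EM_ITERS)
            if best_short is None or model.loglik > best_short.loglik:
                best_short, best_tau0 = model, tau0
        assert best_tau0 is not None
        return _run_em(self.data, best_tau0, max_iter=_EM_MAX_ITER)


# ---------------------------------------------------------------------------
# two-loop model selection


def _relabel_by_size(labels: np.ndarray, K: int) -> np.ndarray:
    """Map component indices to 1..K by decreasing size (ties: lowest index)."""
    sizes = np.bincount(labels, minlength=K)
    order = sorted(range(K), key=lambda k: (-sizes[k], k))
    mapping = {orig: rank + 1 for rank, orig in enumerate(order)}
    return np.array([mapping[l] for l in labels])


def _data_digest(data: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(np.round(data, 12)).tobytes()).hexdigest()[:16]


def _checkpoint_path(directory: Path, K: int) -> Path:
    return directory / f"model_K{K}.json"


def _save_checkpoint(
    directory: Path, K: int, model: CoexpressionModel, key: dict
) -> None:
    payload = {
        "key": key,
        "K": model.K,
        "proportions": model.proportions.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "loglik": model.loglik,
        "converged": model.converged,
    }
    directory.mkdir(parents=True, exist_ok=True)
    _checkpoint_path(directory, K).write_text(json.dumps(payload))


def _load_checkpoint(
    directory: Path, K: int, key: dict, data: np.ndarray
) -> CoexpressionModel | None:
    path = _checkpoint_path(directory, K)
    if not path.exists():
        return None
    payload = json.loads(path.read_text())
    if payload.get("key") != key:
        return None
    pi = np.asarray(payload["proportions"])
    means = np.asarray(payload["means"])
    covs = np.asarray(payload["covariances"])
    tau, ll = _e_step(data, pi, means, covs)
    return CoexpressionModel(
        K=payload["K"],
        proportions=pi,
        means=means,
        covariances=covs,
        posteriors=tau,
        loglik=payload["loglik"],
        n_obs=data.shape[0],
        converged=payload["converged"],
    )


@dataclass
class CoexpressionResults:
    """Selected mixture, cluster assignment and the ICL curves."""

    model: CoexpressionModel
    assignments: pd.Series  # gene -> cluster label, 0 = low-mean filtered
    max_posterior: pd.Series
    icl_loop1: pd.Series  # K -> ICL
    icl_loop2: pd.Series
    convex: bool

    @property
    def K(self) -> int:
        return self.model.K

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def summary(self) -> pd.DataFrame:
        sizes = self.cluster_sizes()
        rows = [
            {
                "cluster": int(c),
                "size": int(sizes[c]),
                "mean_max_posterior": float(
                    self.max_posterior[self.assignments == c].mean()
                )
                if c != 0
                else np.nan,
            }
            for c in sizes.index
        ]
        return pd.DataFrame(rows).set_index("cluster")

    def __str__(self) -> str:
        return (
            f"Gaussian-mixture co-expression: K={self.K}, "
            f"ICL={self.model.icl:.2f}, convex ICL curve={self.convex}\n"
            + self.summary().to_string()
        )


def _single_minimum(values: np.ndarray) -> bool:
    """True iff the sequence decreases then increases (one local minimum)."""
    k = int(np.argmin(values))
    return bool(
        np.all(np.diff(values[: k + 1]) <= 0) and np.all(np.diff(values[k:]) >= 0)
    )


def select_model(
    data: np.ndarray,
    gene_ids: list[str] | None = None,
    cluster0: list[str] | None = None,
    grid: tuple[int, ...] = (5, 10, 15, 20, 25, 30),
    loop1_inits: int = 5,
    loop2_inits: int = 40,
    seed: int = 0,
    interval_halfwidth: int = 4,
    checkpoint_dir: str | Path | None = None,
) -> CoexpressionResults:
    """Two-loop ICL model selection over the number of subpopulations.

    Loop 1 estimates each grid K with ``loop1_inits`` starts to locate the
    ICL-minimizing grid point K*; loop 2 re-estimates every K in
    ``[K*-4, K*+4]`` (clipped to [2, max grid]) with ``loop2_inits``
    starts.  The returned model is the loop-2 ICL minimizer; genes are
    assigned to their argmax-posterior component, components relabeled
    1..K by decreasing size, with filtered genes in Cluster 0.  Loop-2
    fits are checkpointed per K so an interrupted run resumes.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    gmm = CoexpressionGMM(data, gene_ids)
    grid = tuple(sorted(k for k in grid if 1 <= k < n))
    if not grid:
        raise ValueError("grid empty after truncation to K < number of genes")
    if grid[-1] < max(5, 2):
        warnings.warn("few genes: grid truncated", stacklevel=2)
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    digest = _data_digest(data)

    icl1 = {}
    for K in grid:
        model = gmm.fit(K, n_inits=loop1_inits, seed=seed, loop_tag=1)
        icl1[K] = icl(model, n)
    k_star = min(icl1, key=icl1.get)
    lo = max(2, k_star - interval_halfwidth)
    hi = min(grid[-1], k_star + interval_halfwidth)
    interval = [k for k in range(lo, hi + 1) if k < n]

    icl2 = {}
    best: CoexpressionModel | None = None
    for K in interval:
        key = {"seed": seed, "n_inits": loop2_inits, "K": K, "data": digest}
        model = _load_checkpoint(ckpt, K, key, data) if ckpt else None
        if model is None:
            model = gmm.fit(K, n_inits=loop2_inits, seed=seed, loop_tag=2)
            if ckpt:
                _save_checkpoint(ckpt, K, model, key)
        icl2[K] = icl(model, n)
        if best is None or icl2[K] < icl(best, n):
            best = model
    assert best is not None
    convex = _single_minimum(np.array([icl2[k] for k in sorted(icl2)]))
    if not convex:
        warnings.warn(
            "ICL curve is not convex on the refinement interval; consider "
            "removing genes with flat normalized profiles",
            stacklevel=2,
        )
    labels = _relabel_by_size(best.hard_labels(), best.K)
    ids = gmm.gene_ids
    assignments = pd.Series(labels, index=ids, name="cluster")
    max_post = pd.Series(best.posteriors.max(axis=1), index=ids, name="max_posterior")
    if cluster0:
        assignments = pd.concat(
            [assignments, pd.Series(0, index=list(cluster0), name="cluster")]
        )
        max_post = pd.concat(
            [max_post, pd.Series(np.nan, index=list(cluster0), name="max_posterior")]
        )
    return CoexpressionResults(
        model=best,
        assignments=assignments,
        max_posterior=max_post,
        icl_loop1=pd.Series(icl1).sort_index(),
        icl_loop2=pd.Series(icl2).sort_index(),
        convex=convex,
    )
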