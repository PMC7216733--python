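"""Negative-binomial GLM inference for contrast-driven differential analysis.

Per-gene counts y_gj are modelled as NB with mean ``mu_gj = exp(o_j + x_j'
beta_g)`` (offset o_j = log effective library size) and variance ``mu +
phi mu^2``.  Fitting is iteratively reweighted least squares with weights
``mu/(1 + phi mu)``; dispersion is estimated by maximizing the Cox-Reid
adjusted profile likelihood (APL), either a single common value or
tagwise values shrunk toward the common one with a prior-degrees-of-
freedom weight.  Each contrast is tested by a likelihood-ratio chi-square
with 1 df: the null fit constrains ``c' beta = 0`` by restricting the
coefficient space to the null space of c, dispersions held fixed.

The user-facing surface is ``NBDifferentialModel(project, glm_design,
norm).fit()`` returning an :class:`NBDifferentialResults` with per-contrast
test tables, p-value diagnostics and a summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .contrasts import Contrast, GLMDesign
from .datatypes import Project
from .normalization import NormalizationResult

__all__ = [
    "GeneFitResult",
    "ContrastTestResult",
    "PValueDiagnostic",
    "fit_gene_glm",
    "fit_glm_batch",
    "nb_loglik",
    "estimate_common_dispersion",
    "estimate_tagwise_dispersions",
    "lrt_contrast",
    "adjust_bh",
    "pvalue_histogram",
    "top_degs",
    "NBDifferentialModel",
    "NBDifferentialResults",
]

log = logging.getLogger(__name__)

_BETA_CLIP = 50.0
_RIDGE = 1e-10
_MAX_IRLS = 100
_IRLS_TOL = 1e-8


@dataclass
class GeneFitResult:
    beta: np.ndarray
    mu: np.ndarray
    deviance: float
    dispersion: float
    converged: bool
    loglik: float


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray | float) -> np.ndarray:
    """NB log-likelihood per gene (rows); Poisson when phi == 0.

    ``y``/``mu``: (G, n); ``phi``: scalar or (G,).  Returns (G,).
    """
    y = np.atleast_2d(y)
    mu = np.clip(np.atleast_2d(mu), 1e-12, None)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],)).copy()
    ll = np.empty(y.shape[0])
    pois = phi_arr <= 0
    if pois.any():
        yp, mp = y[pois], mu[pois]
        ll[pois] = np.sum(yp * np.log(mp) - mp - gammaln(yp + 1.0), axis=1)
    if (~pois).any():
        yn, mn = y[~pois], mu[~pois]
        r = 1.0 / phi_arr[~pois][:, None]
        ll[~pois] = np.sum(
            gammaln(yn + r)
            - gammaln(r)
            - gammaln(yn + 1.0)
            + r * np.log(r / (r + mn))
            + yn * np.log(mn / (r + mn)),
            axis=1,
        )
    return ll


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray | float) -> np.ndarray:
    """2*(saturated - fitted) log-likelihood per gene; rows of (G, n)."""
    y = np.atleast_2d(y).astype(float)
    mu = np.clip(np.atleast_2d(mu), 1e-12, None)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        pois = phi_arr[:, None] <= 0
        r = 1.0 / np.clip(phi_arr[:, None], 1e-300, None)
        nbpart = (y + r) * np.log((mu + r) / (y + r))
        poispart = -(y - mu)
        term2 = np.where(pois, poispart, nbpart)
    dev = 2.0 * np.sum(term1 + term2, axis=1)
    return np.clip(dev, 0.0, None)


def fit_glm_batch(
    y: np.ndarray,
    design_matrix: np.ndarray,
    offsets: np.ndarray,
    dispersions: np.ndarray | float,
    max_iter: int = _MAX_IRLS,
    tol: float = _IRLS_TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS over genes.

    ``y``: (G, n) counts; returns (beta (G,p), mu (G,n), deviance (G,),
    converged (G,)).  Step-halving guards against deviance increase; beta
    is clipped to |beta| <= 50 (all-zero genes land on the floor).
    """
    y = np.atleast_2d(y).astype(float)
    x = np.asarray(design_matrix, dtype=float)
    n_genes, n = y.shape
    p = x.shape[1]
    if not np.isfinite(x).all():
        raise ValueError("non-finite design matrix entries")
    phi = np.broadcast_to(np.asarray(dispersions, dtype=float), (n_genes,)).copy()
    offsets = np.asarray(offsets, dtype=float)

    # start from OLS on log counts
    z0 = np.log(np.clip(y, 0.5, None)) - offsets[None, :]
    beta, *_ = np.linalg.lstsq(x, z0.T, rcond=None)
    beta = np.clip(beta.T, -_BETA_CLIP, _BETA_CLIP)  # (G, p)

    # all-zero genes: pin the linear predictor at the floor, never converged
    zero_rows = y.sum(axis=1) == 0
    if zero_rows.any():
        floor, *_ = np.linalg.lstsq(x, -_BETA_CLIP - offsets, rcond=None)
        beta[zero_rows] = np.clip(floor, -_BETA_CLIP, _BETA_CLIP)

    def mean_of(b: np.ndarray) -> np.ndarray:
        eta = np.clip(offsets[None, :] + b @ x.T, -700, 700)
        return np.clip(np.exp(eta), 1e-10, 1e12)

    mu = mean_of(beta)
    dev = nb_deviance(y, mu, phi)
    converged = np.zeros(n_genes, dtype=bool)
    active = ~zero_rows
    eye = np.eye(p)

    for _ in range(max_iter):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        ya, mua, ba, phia = y[idx], mu[idx], beta[idx], phi[idx]
        w = mua / (1.0 + phia[:, None] * mua)
        eta = np.log(mua)
        z = (eta - offsets[None, :]) + (ya - mua) / mua
        xtwx = np.einsum("gn,np,nq->gpq", w, x, x) + _RIDGE * eye[None, :, :]
        xtwz = np.einsum("gn,np->gp", w * z, x)
        try:
            new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.stack(
                [np.linalg.lstsq(a, b_, rcond=None)[0] for a, b_ in zip(xtwx, xtwz)]
            )
        new_beta = np.clip(new_beta, -_BETA_CLIP, _BETA_CLIP)
        # step-halving where deviance would increase
        step = new_beta - ba
        frac = np.ones(idx.size)
        cur_dev = dev[idx]
        for _half in range(12):
            cand = np.clip(ba + frac[:, None] * step, -_BETA_CLIP, _BETA_CLIP)
            cand_mu = mean_of(cand)
            cand_dev = nb_deviance(ya, cand_mu, phia)
            bad = cand_dev > cur_dev * (1 + 1e-12) + 1e-12
            if not bad.any():
                break
            frac[bad] *= 0.5
        beta[idx] = cand
        mu[idx] = cand_mu
        rel = np.abs(cand_dev - cur_dev) / (np.abs(cur_dev) + 0.1)
        dev[idx] = cand_dev
        done = rel < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    return beta, mu, dev, converged


def fit_gene_glm(
    y: np.ndarray,
    design_matrix: np.ndarray,
    offsets: np.ndarray,
    dispersion: float = 0.0,
) -> GeneFitResult:
    """Single-gene NB GLM fit (see :func:`fit_glm_batch`)."""
    beta, mu, dev, conv = fit_glm_batch(
        y[np.newaxis, :], design_matrix, offsets, dispersion
    )
    ll = float(nb_loglik(y[np.newaxis, :], mu, dispersion)[0])
    return GeneFitResult(beta[0], mu[0], float(dev[0]), dispersion, bool(conv[0]), ll)


# ---------------------------------------------------------------------------
# dispersion estimation: Cox-Reid adjusted profile likelihood


def _apl(
    y: np.ndarray,
    x: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray | float,
) -> np.ndarray:
    """Per-gene Cox-Reid adjusted profile log-likelihood at dispersion phi."""
    n_genes = y.shape[0]
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (n_genes,))
    beta, mu, _, _ = fit_glm_batch(y, x, offsets, phi_arr)
    ll = nb_loglik(y, mu, phi_arr)
    w = mu / (1.0 + phi_arr[:, None] * mu)
    xtwx = np.einsum("gn,np,nq->gpq", w, x, x) + 1e-10 * np.eye(x.shape[1])
    _, logdet = np.linalg.slogdet(xtwx)
    return ll - 0.5 * logdet


def _phi_grid(lo: float = 1e-4, hi: float = 10.0, size: int = 25) -> np.ndarray:
    return np.exp(np.linspace(np.log(lo), np.log(hi), size))


_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


def estimate_common_dispersion(
    counts: np.ndarray,
    design_matrix: np.ndarray,
    offsets: np.ndarray,
    grid: np.ndarray | None = None,
) -> float:
    """Common dispersion maximizing the summed Cox-Reid APL over genes.

    Deterministic: coarse log-scale grid on [1e-4, 10] then golden-section
    refinement between the grid neighbours of the maximizer.
    """
    y = np.atleast_2d(counts).astype(float)
    x = np.asarray(design_matrix, dtype=float)
    if y.shape[1] - x.shape[1] < 1:
        raise ValueError(
            "no residual degrees of freedom for dispersion estimation; "
            "use a simpler model"
        )
    grid = _phi_grid() if grid is None else np.asarray(grid, dtype=float)

    def objective(phi: float) -> float:
        return float(np.sum(_apl(y, x, offsets, phi)))

    vals = np.array([objective(g) for g in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    if lo == hi:
        return float(grid[k])
    # golden-section on log scale
    a, b = np.log(lo), np.log(hi)
    c = b - _GOLD * (b - a)
    d = a + _GOLD * (b - a)
    fc, fd = objective(np.exp(c)), objective(np.exp(d))
    for _ in range(40):
        if b - a < 1e-6:
            break
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLD * (b - a)
            fc = objective(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + _GOLD * (b - a)
            fd = objective(np.exp(d))
    return float(np.exp((a + b) / 2.0))


def estimate_tagwise_dispersions(
    counts: np.ndarray,
    design_matrix: np.ndarray,
    offsets: np.ndarray,
    common_dispersion: float | None = None,
    prior_df: float = 10.0,
    grid_size: int = 31,
) -> np.ndarray:
    """Per-gene dispersions with empirical-Bayes shrinkage.

    Each gene maximizes ``APL_g(phi) + w * mean_g' APL_g'(phi)`` with
    ``w = prior_df / residual_df``; the shared term is interpolated from a
    dense log-scale grid and the per-gene term refined by a batched
    golden-section between the gene's grid neighbours.  ``prior_df = 0``
    gives the per-gene maximizer; ``prior_df -> inf`` returns the common
    value for every gene.
    """
    if prior_df < 0:
        raise ValueError("prior_df must be >= 0")
    y = np.atleast_2d(counts).astype(float)
    x = np.asarray(design_matrix, dtype=float)
    n_genes, n = y.shape
    resid_df = n - x.shape[1]
    if resid_df < 1:
        raise ValueError("no residual degrees of freedom; use a simpler model")
    if not np.isfinite(prior_df):
        if common_dispersion is None:
            common_dispersion = estimate_common_dispersion(y, x, offsets)
        return np.full(n_genes, common_dispersion)
    w = prior_df / resid_df

    grid = _phi_grid(size=grid_size)
    apl_mat = np.stack([_apl(y, x, offsets, g) for g in grid], axis=1)  # (G, K)
    mean_apl = apl_mat.mean(axis=0)  # shared term on the grid
    from scipy.interpolate import CubicSpline

    shared = CubicSpline(np.log(grid), mean_apl)
    obj_grid = apl_mat + w * mean_apl[None, :]
    k = np.argmax(obj_grid, axis=1)
    a = np.log(grid[np.maximum(k - 1, 0)])
    b = np.log(grid[np.minimum(k + 1, grid.size - 1)])

    def objective(log_phi: np.ndarray) -> np.ndarray:
        phi = np.exp(log_phi)
        return _apl(y, x, offsets, phi) + w * shared(log_phi)

    c = b - _GOLD * (b - a)
    d = a + _GOLD * (b - a)
    fc, fd = objective(c), objective(d)
    for _ in range(25):
        if np.all(b - a < 1e-5):
            break
        left = fc >= fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c_new = np.where(left, b - _GOLD * (b - a), d)
        d_new = np.where(left, c, a + _GOLD * (b - a))
        f_eval = objective(np.where(left, c_new, d_new))
        fc, fd = np.where(left, f_eval, fd), np.where(left, fc, f_eval)
        c, d = c_new, d_new
    return np.exp((a + b) / 2.0)


# ---------------------------------------------------------------------------
# contrast testing


@dataclass
class ContrastTestResult:
    contrast: Contrast
    table: pd.DataFrame  # index gene, columns log2FC, LR, pvalue, adj_pvalue, is_deg
    alpha: float

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["is_deg"]]

    @property
    def n_up(self) -> int:
        return int((self.table["is_deg"] & (self.table["log2FC"] > 0)).sum())

    @property
    def n_down(self) -> int:
        return int((self.table["is_deg"] & (self.table["log2FC"] < 0)).sum())


def adjust_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def lrt_contrast(
    counts: np.ndarray,
    glm_design: GLMDesign,
    offsets: np.ndarray,
    dispersions: np.ndarray | float,
    contrast: Contrast,
    gene_ids: list[str] | None = None,
    alpha: float = 0.05,
    full_fit: tuple[np.ndarray, np.ndarray] | None = None,
) -> ContrastTestResult:
    """Likelihood-ratio test of a single contrast for every gene.

    The null model restricts beta to the null space of the contrast vector
    (a rank p-1 basis completion), dispersions held fixed; LR is referred
    to chi-square with 1 df and BH-adjusted across genes.
    """
    y = np.atleast_2d(counts).astype(float)
    x = glm_design.design_matrix
    c = np.asarray(contrast.vector, dtype=float)
    if not np.any(c):
        raise ValueError(f"contrast {contrast.name} is zero on the coefficient basis")
    # estimability: c must lie in the row space of x
    u, *_ = np.linalg.lstsq(x.T, c, rcond=None)
    if np.linalg.norm(x.T @ u - c) > 1e-8 * max(1.0, np.linalg.norm(c)):
        raise ValueError(f"contrast {contrast.name} is not estimable")

    z = null_space(c[np.newaxis, :])  # (p, p-1)
    phi = np.broadcast_to(np.asarray(dispersions, dtype=float), (y.shape[0],))
    if full_fit is None:
        beta_full, mu_full, _, _ = fit_glm_batch(y, x, offsets, phi)
    else:
        beta_full, mu_full = full_fit
    _, mu_null, _, _ = fit_glm_batch(y, x @ z, offsets, phi)
    ll_full = nb_loglik(y, mu_full, phi)
    ll_null = nb_loglik(y, mu_null, phi)
    lr = 2.0 * (ll_full - ll_null)
    lr = np.where(lr < 0, np.where(lr > -1e-8, 0.0, lr), lr)
    lr = np.clip(lr, 0.0, None)
    pvals = chi2.sf(lr, df=1)
    log2fc = (beta_full @ c) / np.log(2.0)
    adj = adjust_bh(pvals)
    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "LR": lr,
            "pvalue": pvals,
            "adj_pvalue": adj,
            "is_deg": adj <= alpha,
        },
        index=pd.Index(
            gene_ids if gene_ids is not None else range(y.shape[0]), name="gene"
        ),
    )
    return ContrastTestResult(contrast, table, alpha)


@dataclass
class PValueDiagnostic:
    bin_counts: np.ndarray
    n_bins: int
    uniform_tail: bool


def pvalue_histogram(pvals: np.ndarray, n_bins: int = 20) -> PValueDiagnostic:
    """Raw p-value histogram with a uniformity check on the last quintile.

    A spike near 1 usually means insufficient low-count filtering; the
    tail flag is false when any of the last 4 bins deviates from the
    uniform expectation m/n_bins by more than 3*sqrt(m/n_bins).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed bins: (e_{i}, e_{i+1}], first bin includes 0
    idx = np.clip(np.ceil(p * n_bins).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    expected = p.size / n_bins
    tol = 3.0 * np.sqrt(expected)
    tail_ok = bool(np.all(np.abs(counts[-4:] - expected) <= tol))
    if not tail_ok:
        log.warning(
            "p-value histogram tail departs from uniformity; consider "
            "repeating the analysis with a more stringent filtering cut-off"
        )
    del edges
    return PValueDiagnostic(counts, n_bins, tail_ok)


def top_degs(result: ContrastTestResult, k: int = 50) -> list[str]:
    """Top-k DEGs by ascending raw p (ties: |log2FC| desc, then gene id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    degs = result.degs.copy()
    degs["_absfc"] = -degs["log2FC"].abs()
    degs = degs.sort_values(["pvalue", "_absfc", "gene"], kind="stable")
    return degs.index[:k].tolist()


# ---------------------------------------------------------------------------
# model / results surface


class NBDifferentialModel:
    """NB-GLM differential-expression model for a filtered project.

    Parameters
    ----------
    project : Project
        Filtered counts + design (samples aligned).
    glm_design : GLMDesign
        Treatment-coded design basis (see :mod:`contrastseq.contrasts`).
    norm : NormalizationResult
        Scaling factors; offsets are log effective library sizes.
    contrasts : list of Contrast, optional
        Defaults to the automatically generated full list.
    """

    def __init__(
        self,
        project: Project,
        glm_design: GLMDesign,
        norm: NormalizationResult,
        contrasts: list[Contrast] | None = None,
    ) -> None:
        from .contrasts import generate_contrasts

        self.project = project
        self.glm_design = glm_design
        self.norm = norm
        self.contrasts = contrasts if contrasts is not None else generate_contrasts(glm_design)
        self.counts = project.counts.values.astype(float)
        self.offsets = np.log(norm.effective_sizes)

    def fit(
        self,
        dispersion: str | float | np.ndarray = "tagwise",
        prior_df: float = 10.0,
        alpha: float = 0.05,
    ) -> "NBDifferentialResults":
        """Estimate dispersions, fit per-gene GLMs and test every contrast.

        ``dispersion`` may be "common", "tagwise" (default), or an explicit
        scalar / per-gene array.
        """
        x = self.glm_design.design_matrix
        common = None
        if isinstance(dispersion, str):
            common = estimate_common_dispersion(self.counts, x, self.offsets)
            if dispersion == "common":
                phi = np.full(self.counts.shape[0], common)
            elif dispersion == "tagwise":
                phi = estimate_tagwise_dispersions(
                    self.counts, x, self.offsets, common, prior_df=prior_df
                )
            else:
                raise ValueError(f"unknown dispersion mode {dispersion!r}")
        else:
            phi = np.broadcast_to(
                np.asarray(dispersion, dtype=float), (self.counts.shape[0],)
            ).copy()
        beta, mu, dev, conv = fit_glm_batch(self.counts, x, self.offsets, phi)
        tests = {}
        for c in self.contrasts:
            tests[c.name] = lrt_contrast(
                self.counts,
                self.glm_design,
                self.offsets,
                phi,
                c,
                gene_ids=self.project.counts.gene_ids,
                alpha=alpha,
                full_fit=(beta, mu),
            )
        return NBDifferentialResults(
            model=self,
            common_dispersion=common,
            dispersions=phi,
            beta=beta,
            fitted_means=mu,
            deviance=dev,
            converged=conv,
            tests=tests,
            alpha=alpha,
        )


@dataclass
class NBDifferentialResults:
    """Estimates, per-contrast LRT tables and diagnostics from a fit."""

    model: NBDifferentialModel
    common_dispersion: float | None
    dispersions: np.ndarray
    beta: np.ndarray
    fitted_means: np.ndarray
    deviance: np.ndarray
    converged: np.ndarray
    tests: dict[str, ContrastTestResult]
    alpha: float
    diagnostics: dict[str, PValueDiagnostic] = field(init=False)

    def __post_init__(self) -> None:
        self.diagnostics = {
            name: pvalue_histogram(t.table["pvalue"].to_numpy())
            for name, t in self.tests.items()
        }

    def deg_lists(self) -> dict[str, list[str]]:
        return {name: t.degs.index.tolist() for name, t in self.tests.items()}

    def summary(self) -> pd.DataFrame:
        """One row per contrast: DEG counts and the tail-uniformity flag."""
        rows = []
        for name, t in self.tests.items():
            rows.append(
                {
                    "contrast": name,
                    "kind": t.contrast.kind,
                    "n_deg": int(t.table["is_deg"].sum()),
                    "n_up": t.n_up,
                    "n_down": t.n_down,
                    "uniform_tail": self.diagnostics[name].uniform_tail,
                }
            )
        return pd.DataFrame(rows).set_index("contrast")

    def __str__(self) -> str:
        header = (
            f"NB differential analysis: {self.model.project.name}\n"
            f"genes={self.beta.shape[0]} samples={self.model.counts.shape[1]} "
            f"coefficients={self.model.glm_design.n_coefficients} "
            f"alpha={self.alpha}\n"
            f"common dispersion={self.common_dispersion}\n"
        )
        return header + self.summary().to_string()
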