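"""Global population structure and the ancestry-height relationship.

PCA on frequency-scaled genotypes, maximum-likelihood admixture proportions
(the deterministic EM counterpart of the usual Bayesian clustering point
estimates), and the linear regression of height on sex and genome-wide
ancestry with its sequential r-squared decomposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_qc import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "AdmixtureFit", "RegressionResult",
           "pca_genotypes", "admixture_em", "ancestry_height_regression"]


@dataclass
class PCAResult:
    scores: np.ndarray               # samples x components
    variance_explained: np.ndarray   # fraction of total variance per component
    loadings: np.ndarray             # SNPs x components


@dataclass
class AdmixtureFit:
    """Q (samples x K ancestry proportions), F (SNPs x K cluster frequencies)."""

    Q: np.ndarray
    F: np.ndarray
    loglik: float
    n_restarts: int
    converged: bool
    loglik_path: np.ndarray

    def relabel(self, populations, anchor_label: str) -> "AdmixtureFit":
        """Reorder clusters so column 0 has the highest mean Q among samples
        labelled ``anchor_label`` (post-hoc majority relabelling)."""
        populations = np.asarray(populations)
        mask = populations == anchor_label
        order = np.argsort(-self.Q[mask].mean(axis=0))
        return AdmixtureFit(self.Q[:, order], self.F[:, order], self.loglik,
                            self.n_restarts, self.converged, self.loglik_path)


@dataclass
class RegressionResult:
    params: pd.Series
    pvalues: pd.Series
    r2_full: float
    r2_sex: float
    r2_ancestry: float
    n: int


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_genotypes(geno: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of mean-imputed genotypes scaled by sqrt(2p(1-p)).

    Scores are ordered by decreasing eigenvalue; ``variance_explained`` is
    each component's share of the total variance (so the returned entries
    sum to <= 1).
    """
    if geno.n_samples < 3:
        raise ValueError("PCA needs >= 3 samples")
    g = geno.matrix.astype(np.float64)
    miss = g < 0
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(np.where(miss, np.nan, g), axis=0)
    x = np.where(miss, mu, g)
    p = mu / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    x = (x[:, ok] - mu[ok]) / scale[ok]
    n_components = min(n_components, geno.n_samples - 1, int(ok.sum()))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s ** 2).sum())
    scores = u[:, :n_components] * s[:n_components]
    return PCAResult(scores=scores,
                     variance_explained=(s[:n_components] ** 2) / total,
                     loadings=vt[:n_components].T)


# ---------------------------------------------------------------------------
# admixture proportions by EM
# ---------------------------------------------------------------------------

def _admixture_loglik(g, w, Q, F) -> float:
    theta = np.clip(Q @ F.T, 1e-12, 1.0 - 1e-12)
    return float(np.sum(w * (g * np.log(theta) + (2.0 - g) * np.log1p(-theta))))


def admixture_em(geno: GenotypeMatrix, K: int = 2, n_restarts: int = 5,
                 tol: float = 1e-6, max_iter: int = 2000, seed=None) -> AdmixtureFit:
    """Maximum-likelihood admixture proportions via EM.

    Maximizes the binomial admixture log-likelihood
    ``sum_i sum_s [g log(sum_k q_ik f_ks) + (2-g) log(sum_k q_ik (1-f_ks))]``
    by alternating EM updates of Q and F; the best of ``n_restarts`` random
    starts is kept.  Missing genotypes contribute nothing to the
    likelihood.  The log-likelihood is non-decreasing across iterations.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    g = geno.matrix.astype(np.float64)
    w = (g >= 0).astype(np.float64)
    g = np.where(g >= 0, g, 0.0)
    n, m = g.shape

    best = None
    for _ in range(n_restarts):
        Q = rng.dirichlet(np.ones(K), size=n)
        F = rng.uniform(0.05, 0.95, size=(m, K))
        path = []
        prev = -np.inf
        converged = False
        wg = w * g
        w2g = w * (2.0 - g)
        for _it in range(max_iter):
            theta = np.clip(Q @ F.T, 1e-12, 1.0 - 1e-12)       # n x m
            # responsibility sums collapse to 2-D matmuls:
            #   E[alt draws from k]  = q_ik f_sk * (w g / theta)
            #   E[ref draws from k]  = q_ik (1-f_sk) * (w (2-g) / (1-theta))
            A = wg / theta
            B = w2g / (1.0 - theta)
            Qa = Q * (A @ F)                                   # n x K
            Qb = Q * (B @ (1.0 - F))
            Fa = F * (A.T @ Q)                                 # m x K
            Fb = (1.0 - F) * (B.T @ Q)
            Q = Qa + Qb
            Q /= Q.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                F = np.where(Fa + Fb > 0, Fa / np.maximum(Fa + Fb, 1e-300), 0.5)
            F = np.clip(F, 1e-6, 1.0 - 1e-6)
            ll = _admixture_loglik(g, w, Q, F)
            path.append(ll)
            if ll - prev < tol and _it > 0:
                converged = True
                break
            prev = ll
        fit = AdmixtureFit(Q, F, path[-1], n_restarts, converged, np.asarray(path))
        if best is None or fit.loglik > best.loglik:
            best = fit
    if not best.converged:
        logger.warning("admixture EM did not converge in %d iterations", max_iter)
    return best


# ---------------------------------------------------------------------------
# ancestry-height regression
# ---------------------------------------------------------------------------

def ancestry_height_regression(sample_table: pd.DataFrame,
                               ancestry_col: str = "pygmy_fraction") -> RegressionResult:
    """OLS of height on sex and global ancestry with sequential r-squared.

    ``r2_sex`` comes from the sex-only model and ``r2_ancestry`` is the
    increment to the full model, so ``r2_sex + r2_ancestry = r2_full``
    exactly.  Rows without height are dropped.
    """
    df = sample_table.dropna(subset=["height_cm", "sex", ancestry_col]).copy()
    if len(df) < 10:
        raise ValueError("regression needs >= 10 samples with phenotype")
    y = df["height_cm"].astype(float)
    male = (df["sex"] == "M").astype(float)
    p = df[ancestry_col].astype(float)

    X_sex = sm.add_constant(pd.DataFrame({"sex_M": male}))
    fit_sex = sm.OLS(y, X_sex).fit()

    drop_ancestry = float(p.std()) == 0.0
    if drop_ancestry:
        warnings.warn("ancestry is constant; ancestry term dropped")
        fit_full = fit_sex
    else:
        X_full = sm.add_constant(pd.DataFrame({"sex_M": male, "ancestry": p}))
        fit_full = sm.OLS(y, X_full).fit()

    r2_full = float(fit_full.rsquared)
    r2_sex = float(fit_sex.rsquared)
    return RegressionResult(
        params=fit_full.params,
        pvalues=fit_full.pvalues,
        r2_full=r2_full,
        r2_sex=r2_sex,
        r2_ancestry=r2_full - r2_sex,
        n=len(df),
    )
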