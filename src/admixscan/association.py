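"""Mixed-model association and admixture mapping.

Implements the variance-component association machinery used with
structured, admixed cohorts: REML estimation of the polygenic and residual
variance on an identity-by-state kinship (one eigendecomposition plus a
one-dimensional search over the variance ratio), generalized-least-squares
Wald tests per marker with the variance components fixed from the null
model, per-ancestry-window admixture-mapping tests on local-ancestry
dosages, analysis-specific Benjamini-Hochberg FDR, and targeted SNP-set
testing with subset-specific FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["MixedModelFit", "fit_null_mixed_model", "marker_scan",
           "ancestry_scan", "targeted_subset", "bh_fdr", "genomic_inflation",
           "ancestry_dosage_matrix"]


@dataclass
class MixedModelFit:
    sigma_g2: float
    sigma_e2: float
    delta: float               # sigma_e2 / sigma_g2
    reml_loglik: float
    eigenvalues: np.ndarray    # of the centered kinship (full spectrum)
    eigenvectors: np.ndarray
    X: np.ndarray              # covariates including intercept
    y: np.ndarray
    sample_ids: list

    def v_inv_sqrt_transform(self) -> np.ndarray:
        """Whitening matrix T with T V T' = I for V = sg^2 (K_c + delta I)."""
        lam = np.maximum(self.eigenvalues, 0.0)
        d = 1.0 / np.sqrt(self.sigma_g2 * (lam + self.delta))
        return d[:, None] * self.eigenvectors.T

    def covariance(self) -> np.ndarray:
        lam = np.maximum(self.eigenvalues, 0.0)
        return (self.eigenvectors * (self.sigma_g2 * (lam + self.delta))) \
            @ self.eigenvectors.T


def _center_kinship(K: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    return H @ K @ H


def _reml_loglik(log_delta, lam, eta2):
    """Profile REML log-likelihood in log10(delta) (EMMA parameterization)."""
    delta = 10.0 ** log_delta
    q = lam.size
    denom = lam + delta
    s = np.sum(eta2 / denom)
    return 0.5 * (q * np.log(q / (2 * np.pi)) - q - q * np.log(s)
                  - np.sum(np.log(denom)))


def fit_null_mixed_model(y, covariates, K, sample_ids=None,
                         add_intercept: bool = True) -> MixedModelFit:
    """REML variance components for y = X b + u + e, Var(u) = sg^2 K_c.

    The kinship is centered; after projecting out the covariates the REML
    profile likelihood is a function of delta = se^2/sg^2 alone, searched
    on a log10 grid over [-10, 10] and refined by bounded Brent.  Flat
    stretches of the profile (unidentifiable delta, e.g. K = I) resolve
    toward the largest delta, i.e. variance assigned to the residual.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.asarray(covariates, dtype=float) if covariates is not None \
        else np.empty((n, 0))
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariates are rank deficient")
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship must be symmetric")
    Kc = _center_kinship(K)
    w = np.linalg.eigvalsh(Kc)
    if w.min() < -1e-6 * max(1.0, w.max()):
        raise ValueError("kinship is not positive semidefinite; recompute it")

    # eigendecomposition of the covariate-projected kinship
    Q, _ = np.linalg.qr(X)
    S = np.eye(n) - Q @ Q.T
    lam_s, U_s = np.linalg.eigh(S @ Kc @ S)
    q = n - X.shape[1]
    lam = np.maximum(lam_s[-q:], 0.0)
    eta = U_s[:, -q:].T @ y
    eta2 = eta ** 2

    grid = np.linspace(-10, 10, 81)
    lls = np.array([_reml_loglik(g, lam, eta2) for g in grid])
    # prefer the largest delta among near-maximal grid points (flat profiles)
    best_ll = lls.max()
    i = int(np.flatnonzero(lls >= best_ll - 1e-9)[-1])
    lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(lambda g: -_reml_loglik(g, lam, eta2),
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    log_delta = float(res.x) if -res.fun > lls[i] + 1e-12 else float(grid[i])
    delta = 10.0 ** log_delta
    sigma_g2 = float(np.sum(eta2 / (lam + delta)) / q)
    sigma_e2 = delta * sigma_g2

    lam_full, U_full = np.linalg.eigh(Kc)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return MixedModelFit(sigma_g2, sigma_e2, delta,
                         float(_reml_loglik(log_delta, lam, eta2)),
                         lam_full, U_full, X, y, list(sample_ids))


# ---------------------------------------------------------------------------
# GLS marker tests
# ---------------------------------------------------------------------------

def _gls_scan_transformed(yt, Xt, Mt, ids):
    """Wald t-tests of each column of Mt added to the model Xt (whitened)."""
    n, p = Xt.shape
    Q, _ = np.linalg.qr(Xt)
    y_res = yt - Q @ (Q.T @ yt)
    M_res = Mt - Q @ (Q.T @ Mt)
    xx = np.einsum("ij,ij->j", M_res, M_res)
    xy = M_res.T @ y_res
    ok = xx > 1e-12
    beta = np.where(ok, xy / np.where(ok, xx, 1.0), np.nan)
    df = n - p - 1
    rss = np.maximum(y_res @ y_res - beta ** 2 * xx, 0.0)
    sigma2 = rss / df
    se = np.sqrt(np.where(ok, sigma2 / np.where(ok, xx, 1.0), np.nan))
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    out = pd.DataFrame({"id": ids, "beta": beta, "se": se, "stat": tstat,
                        "p": pvals})
    out.loc[~ok, ["beta", "se", "stat", "p"]] = np.nan
    return out


def marker_scan(markers, y, fit: MixedModelFit, marker_ids=None,
                maf_min: float = 0.01, call_min: float = 0.9) -> pd.DataFrame:
    """GLS Wald tests per marker with variance components fixed at the null
    REML estimates.

    ``markers`` is samples x markers dosage (0/1/2 SNP dosages or 0..2
    local-ancestry dosages; negative or NaN = missing).  Markers below the
    call-rate or MAF thresholds, or constant, are skipped (NaN results,
    ``skipped`` flag).  BH q-values are appended over the tested markers.
    """
    M = np.asarray(markers, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n, m = M.shape
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(m)]
    miss = ~np.isfinite(M) | (M < 0)
    call = 1.0 - miss.mean(axis=0)
    Mimp = np.where(miss, np.nan, M)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(Mimp, axis=0)
        sd = np.nanstd(Mimp, axis=0)
    freq = mean / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    testable = (call >= call_min) & (maf >= maf_min) & (sd > 0)
    Mimp = np.where(miss, mean, M)

    T = fit.v_inv_sqrt_transform()
    yt = T @ fit.y
    Xt = T @ fit.X
    res = _gls_scan_transformed(yt, Xt, T @ Mimp, list(marker_ids))
    res.loc[~testable, ["beta", "se", "stat", "p"]] = np.nan
    res["skipped"] = ~testable
    tested = res["p"].notna()
    res["q"] = np.nan
    if tested.any():
        res.loc[tested, "q"] = bh_fdr(res.loc[tested, "p"].to_numpy())
    logger.info("marker_scan: tested %d of %d markers", int(tested.sum()), m)
    return res


def ancestry_dosage_matrix(am, sample_ids) -> np.ndarray:
    """Diploid local-ancestry dosage per sample and window.

    Dosage = number of the sample's two haplotypes hard-called Pygmy, kept
    only where both haplotypes pass the confidence mask (else NaN).
    Haplotype ids are expected as ``{sample}_h0`` / ``{sample}_h1``.
    """
    idx = {h: i for i, h in enumerate(am.hap_ids)}
    W = am.posterior.shape[1]
    out = np.full((len(sample_ids), W), np.nan)
    for s_i, sid in enumerate(sample_ids):
        rows = [idx[f"{sid}_h{k}"] for k in range(2)]
        calls = (am.hard_call[rows] == "P").sum(axis=0).astype(float)
        both_conf = am.confident[rows].all(axis=0)
        out[s_i] = np.where(both_conf, calls, np.nan)
    return out


def ancestry_scan(am, sample_ids, y, fit: MixedModelFit,
                  min_callable: float = 0.8) -> pd.DataFrame:
    """Admixture mapping: GLS tests of per-window local-ancestry dosage.

    Windows with fewer than ``min_callable`` callable samples are dropped;
    for the rest the test runs on the callable subset with the null-model
    covariance restricted to those samples.
    """
    D = ancestry_dosage_matrix(am, sample_ids)
    n, W = D.shape
    V = fit.covariance()
    rows = []
    for w in range(W):
        d = D[:, w]
        ok = np.isfinite(d)
        frac = ok.mean()
        rec = {"id": f"window{w}", "window": w,
               "chrom": am.windows.loc[w, "chrom"],
               "start_bp": am.windows.loc[w, "start_bp"],
               "end_bp": am.windows.loc[w, "end_bp"],
               "beta": np.nan, "se": np.nan, "stat": np.nan, "p": np.nan,
               "skipped": True}
        if frac >= min_callable and np.nanstd(d) > 0:
            sub = np.flatnonzero(ok)
            from scipy.linalg import solve_triangular
            L = np.linalg.cholesky(V[np.ix_(sub, sub)]
                                   + 1e-10 * np.eye(sub.size))
            yt = solve_triangular(L, fit.y[sub], lower=True)
            Xt = solve_triangular(L, fit.X[sub], lower=True)
            dt = solve_triangular(L, d[sub][:, None], lower=True)
            r = _gls_scan_transformed(yt, Xt, dt, [f"window{w}"])
            if np.isfinite(r.loc[0, "p"]):
                rec.update(beta=r.loc[0, "beta"], se=r.loc[0, "se"],
                           stat=r.loc[0, "stat"], p=r.loc[0, "p"], skipped=False)
        rows.append(rec)
    res = pd.DataFrame(rows)
    if res.empty or res["p"].notna().sum() == 0:
        logger.warning("ancestry_scan: no callable windows")
        res["q"] = np.nan
        return res
    tested = res["p"].notna()
    res["q"] = np.nan
    res.loc[tested, "q"] = bh_fdr(res.loc[tested, "p"].to_numpy())
    return res


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def targeted_subset(results: pd.DataFrame, marker_ids) -> pd.DataFrame:
    """Restrict an association result to an a-priori marker set and
    recompute the FDR within the subset (p-values unchanged)."""
    wanted = set(marker_ids)
    sub = results[results["id"].isin(wanted)].copy()
    if sub.empty:
        raise ValueError("no scanned markers in the requested subset")
    tested = sub["p"].notna()
    sub["q"] = np.nan
    if tested.any():
        sub.loc[tested, "q"] = bh_fdr(sub.loc[tested, "p"].to_numpy())
    return sub.reset_index(drop=True)


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median association chi-square over its
    null expectation (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
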