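"""Window-based local ancestry inference for admixed haplotypes.

The approach mirrors machine-learning local-ancestry painting with a single
available ancestral reference panel: the genome is cut into consecutive
50-SNP windows; in each window a linear support-vector classifier separates
the admixed (Pygmy-labelled) haplotypes from the reference (Bantu) panel;
the admixed haplotypes furthest from the hyperplane on the Pygmy side are
taken as window-specific "ancestral" proxies and a second classifier trained
on proxies vs. reference produces calibrated per-window ancestry scores.
The proxy fraction rho is one global constant, chosen by bisection so the
genome-wide mean Pygmy call fraction matches a target global ancestry
proportion.  A two-state hidden Markov chain over windows (forward-backward
posteriors, optional Baum-Welch re-estimation of the switch probability)
smooths the scores; high-confidence hard calls and ancestry tracts follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

__all__ = ["AncestryMatrix", "TractSet", "window_partition", "classify_windows",
           "hmm_posteriors", "call_tracts"]


@dataclass
class AncestryMatrix:
    """Per-haplotype, per-window posterior P(Pygmy) with hard calls and a
    high-confidence mask (max posterior >= threshold)."""

    posterior: np.ndarray      # haplotypes x windows
    hard_call: np.ndarray      # 'P'/'B'
    confident: np.ndarray      # bool
    windows: pd.DataFrame
    hap_ids: list
    threshold: float


@dataclass
class TractSet:
    """Inferred ancestry tracts per haplotype plus per-ancestry length summaries."""

    tracts: dict               # hap_id -> list of (start_bp, end_bp, ancestry)
    summary: pd.DataFrame      # ancestry, n, mean_bp, sd_bp


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def window_partition(variant_table: pd.DataFrame, window_snps: int = 50) -> pd.DataFrame:
    """Consecutive non-overlapping windows of ``window_snps`` SNPs.

    Windows never span chromosomes; a terminal remainder shorter than the
    window is dropped (logged).  Returns one row per window with the global
    SNP index range (``start_idx`` inclusive, ``end_idx`` exclusive) and the
    bp span of its first/last SNP.
    """
    rows = []
    dropped = 0
    vt = variant_table.reset_index(drop=True)
    for chrom, grp in vt.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        n_win = len(idx) // window_snps
        dropped += len(idx) - n_win * window_snps
        for w in range(n_win):
            sel = idx[w * window_snps:(w + 1) * window_snps]
            rows.append({
                "window": len(rows),
                "chrom": chrom,
                "start_idx": int(sel[0]),
                "end_idx": int(sel[-1]) + 1,
                "start_bp": int(vt.loc[sel[0], "pos_bp"]),
                "end_bp": int(vt.loc[sel[-1], "pos_bp"]),
                "n_snps": window_snps,
            })
    if dropped:
        logger.info("window_partition dropped %d terminal SNPs", dropped)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# windowed SVM classification with single-panel self-training
# ---------------------------------------------------------------------------

def _window_stage1(X_adm, X_ref, seed):
    """First-pass classifier: admixed-labelled vs reference haplotypes.
    Returns signed distances of the admixed haplotypes from the hyperplane
    (positive = admixed side), or None when degenerate."""
    X = np.vstack([X_adm, X_ref]).astype(np.float64)
    y = np.concatenate([np.ones(len(X_adm)), np.zeros(len(X_ref))])
    if np.ptp(X, axis=0).max() == 0:
        return None
    svm = LinearSVC(C=1.0, random_state=seed, max_iter=5000, dual="auto")
    svm.fit(X, y)
    w = svm.coef_.ravel()
    norm = np.linalg.norm(w)
    if norm == 0:
        return None
    return (X_adm @ w + svm.intercept_[0]) / norm


def _window_stage2(X_adm, X_ref, proxy_rows, seed):
    """Second-pass classifier: proxy-ancestral vs reference; returns
    calibrated P(Pygmy) for all admixed haplotypes (None when degenerate)."""
    X_proxy = X_adm[proxy_rows]
    X = np.vstack([X_proxy, X_ref]).astype(np.float64)
    y = np.concatenate([np.ones(len(X_proxy)), np.zeros(len(X_ref))])
    if np.ptp(X, axis=0).max() == 0:
        return None
    svm = LinearSVC(C=1.0, random_state=seed, max_iter=5000, dual="auto")
    svm.fit(X, y)
    dec_train = X @ svm.coef_.ravel() + svm.intercept_[0]
    if np.ptp(dec_train) < 1e-12:
        return None
    # Platt-style calibration of decision values -> probabilities
    lr = LogisticRegression(C=1e3)
    lr.fit(dec_train[:, None], y)
    dec_adm = X_adm @ svm.coef_.ravel() + svm.intercept_[0]
    return lr.predict_proba(dec_adm[:, None])[:, 1]


def classify_windows(panel, sample_table, variant_table, windows=None,
                     admixed_label: str = "pygmy", reference_label: str = "bantu",
                     target_global_P: float | None = None, rho: float | None = None,
                     window_snps: int = 50, seed: int = 0, tol: float = 0.01,
                     max_bisect: int = 25):
    """Per-window per-haplotype Pygmy-ancestry scores via two-stage SVM.

    Stage 1 ranks the admixed haplotypes by signed Euclidean distance from
    the hyperplane separating them from the reference panel; the top
    fraction ``rho`` become window-specific ancestral proxies for stage 2,
    whose calibrated scores are returned for every admixed haplotype.
    When ``rho`` is None it is chosen by bisection so the genome-wide mean
    Pygmy call fraction (score > 0.5) matches ``target_global_P`` within
    ``tol``.  Degenerate windows yield 0.5 scores and a flag.

    Returns ``(scores, windows, info)`` where scores is haplotypes x
    windows and info records rho, the achieved call fraction, and the
    per-window degenerate flags.
    """
    if windows is None:
        windows = window_partition(variant_table, window_snps)
    adm_ids = list(sample_table.loc[sample_table["population"] == admixed_label,
                                    "sample_id"])
    ref_ids = list(sample_table.loc[sample_table["population"] == reference_label,
                                    "sample_id"])
    if not adm_ids or not ref_ids:
        raise ValueError("need both admixed and reference samples")
    H_adm = panel.for_samples(adm_ids)
    H_ref = panel.for_samples(ref_ids)
    hap_ids = [f"{s}_h{i}" for s in adm_ids for i in range(2)]
    n_adm = H_adm.shape[0]
    W = len(windows)

    # stage-1 rankings are rho-independent: compute once per window
    rankings = []
    feats = []
    for w in range(W):
        cols = np.arange(windows.loc[w, "start_idx"], windows.loc[w, "end_idx"])
        Xa, Xr = H_adm[:, cols], H_ref[:, cols]
        feats.append((Xa, Xr))
        dist = _window_stage1(Xa, Xr, seed)
        rankings.append(None if dist is None else np.argsort(-dist))

    def run(rho_val):
        scores = np.full((n_adm, W), 0.5)
        degenerate = np.zeros(W, dtype=bool)
        n_proxy = max(2, int(np.ceil(rho_val * n_adm)))
        for w in range(W):
            if rankings[w] is None:
                degenerate[w] = True
                continue
            Xa, Xr = feats[w]
            sc = _window_stage2(Xa, Xr, rankings[w][:n_proxy], seed)
            if sc is None:
                degenerate[w] = True
            else:
                scores[:, w] = sc
        return scores, degenerate

    if rho is None:
        if target_global_P is None:
            raise ValueError("need target_global_P when rho is not fixed")
        lo, hi = 2.0 / n_adm, 1.0
        best = None
        for _ in range(max_bisect):
            mid = (lo + hi) / 2.0
            scores, degenerate = run(mid)
            frac = float((scores > 0.5).mean())
            if best is None or abs(frac - target_global_P) < abs(best[3] - target_global_P):
                best = (mid, scores, degenerate, frac)
            if abs(frac - target_global_P) <= tol:
                best = (mid, scores, degenerate, frac)
                break
            if frac < target_global_P:
                lo = mid
            else:
                hi = mid
        rho, scores, degenerate, frac = best
    else:
        scores, degenerate = run(rho)
        frac = float((scores > 0.5).mean())

    info = {"rho": float(rho), "call_fraction": frac,
            "degenerate": degenerate, "hap_ids": hap_ids}
    logger.info("classify_windows: rho=%.3f call_fraction=%.3f (%d degenerate windows)",
                rho, frac, int(degenerate.sum()))
    return scores, windows, info


# ---------------------------------------------------------------------------
# HMM smoothing
# ---------------------------------------------------------------------------

def _fb_chain(em_p, em_b, init_p, trans):
    """Scaled forward-backward for one two-state chain.

    ``trans[k]`` is the 2x2 transition matrix into step k+1.  Returns
    posterior P(state = P) per step and the expected transition-count
    matrix (for Baum-Welch).
    """
    T = em_p.size
    alpha = np.empty((T, 2))
    beta = np.empty((T, 2))
    scale = np.empty(T)
    e = np.stack([em_p, em_b], axis=1)
    alpha[0] = np.array([init_p, 1.0 - init_p]) * e[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ trans[t - 1]) * e[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = trans[t] @ (e[t + 1] * beta[t + 1])
        beta[t] /= scale[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    xi = np.zeros((2, 2))
    for t in range(T - 1):
        m = (alpha[t][:, None] * trans[t]) * (e[t + 1] * beta[t + 1])[None, :]
        xi += m / m.sum()
    return post[:, 0], xi


def hmm_posteriors(scores: np.ndarray, windows: pd.DataFrame,
                   switch_prob: float = 0.1, stationary_p: float | None = None,
                   estimate_switch: bool = False, max_bw_iter: int = 20,
                   threshold: float = 0.9, hap_ids=None) -> AncestryMatrix:
    """Forward-backward smoothing of window ancestry scores.

    Window scores s (calibrated P(Pygmy) under a symmetric prior) act as
    emission likelihood ratios s : (1-s).  The hidden chain uses the
    crossover-thinning parameterization: with probability ``switch_prob``
    per window step an ancestry redraw occurs, landing on Pygmy with the
    stationary probability, so the prior equals the stationary
    distribution.  Chains restart at chromosome boundaries.  When
    ``estimate_switch`` is set, the switch probability is re-estimated by
    up to ``max_bw_iter`` Baum-Welch iterations, bounded in [1e-6, 0.2].
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    H, W = scores.shape
    if len(windows) != W:
        raise ValueError("windows must align with score columns")
    pi = float(np.clip(stationary_p if stationary_p is not None else scores.mean(),
                       1e-3, 1 - 1e-3))
    c = float(switch_prob)
    s = np.clip(scores, 1e-3, 1 - 1e-3)

    chrom_groups = [grp.index.to_numpy() for _, grp in windows.groupby("chrom", sort=False)]

    def trans_mat(cv):
        return np.array([[1.0 - cv * (1.0 - pi), cv * (1.0 - pi)],
                         [cv * pi, 1.0 - cv * pi]])

    for _bw in range(max_bw_iter if estimate_switch else 1):
        post = np.empty_like(s)
        xi_total = np.zeros((2, 2))
        tm = trans_mat(c)
        for idx in chrom_groups:
            if idx.size == 1:
                # single-window chromosome: posterior is the calibrated emission
                j = idx[0]
                num = s[:, j] * pi
                post[:, j] = num / (num + (1 - s[:, j]) * (1 - pi))
                continue
            trans = np.repeat(tm[None, :, :], idx.size - 1, axis=0)
            for h in range(H):
                p, xi = _fb_chain(s[h, idx], 1.0 - s[h, idx], pi, trans)
                post[h, idx] = p
                xi_total += xi
        if not estimate_switch:
            break
        row_p, row_b = xi_total[0].sum(), xi_total[1].sum()
        denom = row_p * (1.0 - pi) + row_b * pi
        if denom <= 0:
            break
        c_new = float(np.clip((xi_total[0, 1] + xi_total[1, 0]) / denom, 1e-6, 0.2))
        if abs(c_new - c) < 1e-6:
            c = c_new
            break
        c = c_new

    hard = np.where(post >= 0.5, "P", "B")
    confident = np.maximum(post, 1.0 - post) >= threshold
    if hap_ids is None:
        hap_ids = [f"hap{i}" for i in range(H)]
    logger.info("hmm_posteriors: switch_prob=%.4f, %.1f%% confident windows",
                c, 100 * confident.mean())
    return AncestryMatrix(post, hard, confident, windows.reset_index(drop=True),
                          list(hap_ids), threshold)


# ---------------------------------------------------------------------------
# tract calling
# ---------------------------------------------------------------------------

def call_tracts(am: AncestryMatrix) -> TractSet:
    """Merge consecutive same-call windows into ancestry tracts.

    Tract boundaries sit at the bp midpoint between the flanking windows of
    opposite call; chromosome ends close tracts at the first/last window
    edge.  Returns per-haplotype tracts plus mean +/- SD lengths per
    ancestry.
    """
    tracts = {}
    lengths = {"P": [], "B": []}
    win = am.windows
    for h, hid in enumerate(am.hap_ids):
        out = []
        for chrom, grp in win.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            calls = am.hard_call[h, idx]
            starts_bp = grp["start_bp"].to_numpy().astype(float)
            ends_bp = grp["end_bp"].to_numpy().astype(float)
            run_start = 0
            for k in range(1, idx.size + 1):
                if k == idx.size or calls[k] != calls[run_start]:
                    left = starts_bp[run_start] if run_start == 0 else \
                        0.5 * (ends_bp[run_start - 1] + starts_bp[run_start])
                    right = ends_bp[k - 1] if k == idx.size else \
                        0.5 * (ends_bp[k - 1] + starts_bp[k])
                    anc = str(calls[run_start])
                    out.append((float(left), float(right), anc))
                    lengths[anc].append(right - left)
                    run_start = k
        tracts[hid] = out
    rows = []
    for anc in ("P", "B"):
        arr = np.asarray(lengths[anc], dtype=float)
        rows.append({
            "ancestry": anc,
            "n": arr.size,
            "mean_bp": arr.mean() if arr.size else np.nan,
            "sd_bp": arr.std() if arr.size else np.nan,
        })
    return TractSet(tracts, pd.DataFrame(rows))
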