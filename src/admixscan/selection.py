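"""Genome scans for positive selection and their clustering statistics.

Implements the four scans used on the admixed hunter-gatherer/agriculturalist
cohorts — per-SNP Weir-Cockerham F_ST, three-way locus-specific branch
lengths (LSBL), the integrated haplotype score (iHS), and cross-population
EHH (XP-EHH) — plus the downstream machinery: empirical-tail thresholds,
physical clusters of high SNPs, 500-SNP-bin binomial enrichment,
ancestral-state assignment from outgroup alleles, sequence diversity
statistics (pi, Watterson's theta, Tajima's D), and haplotype template
matching for visualizing extended haplotypes.

Scan results carry the raw statistic, a standardized score where the test
defines one, the empirical percentile, and a "high" flag for the
empirical-tail cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "weir_cockerham_theta", "fst_scan", "lsbl_scan", "empirical_high_set",
    "detect_blocks", "bin_binomial_enrichment", "assign_ancestral_states",
    "ehh_curve", "integrated_ehh", "ihs_scan", "xpehh_scan",
    "seq_diversity", "SeqDiversity", "haplotype_template_match",
]


# ---------------------------------------------------------------------------
# F_ST and LSBL
# ---------------------------------------------------------------------------

def _pop_summaries(geno: np.ndarray):
    """Per-SNP sample size, alt-allele frequency and het frequency (missing = -1)."""
    valid = geno >= 0
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid, geno, 0).sum(axis=0) / (2.0 * n)
        h = ((geno == 1).sum(axis=0)) / n
    return n, p, h


def weir_cockerham_theta(genoA: np.ndarray, genoB: np.ndarray, clamp: bool = True):
    """Per-SNP Weir-Cockerham (1984) theta-hat for two populations.

    Uses the full diploid variance-component estimator (a, b, c components
    including observed heterozygosity).  Returns ``(theta, defined)``;
    negative estimates are clamped to 0 when ``clamp`` and SNPs that are
    monomorphic across both populations (or missing in a population, or
    with fewer than 2 genotyped samples in a population) are undefined.
    """
    n1, p1, h1 = _pop_summaries(genoA)
    n2, p2, h2 = _pop_summaries(genoB)
    defined = (n1 >= 2) & (n2 >= 2)

    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    defined &= np.isfinite(theta)
    theta = np.where(defined, theta, np.nan)
    if clamp:
        theta = np.clip(theta, 0.0, 1.0)
    return theta, defined


def _scan_frame(variant_table, raw, defined, std=None, tail=0.001):
    pct = np.full(raw.shape, np.nan)
    vals = std if std is not None else raw
    ok = defined & np.isfinite(vals)
    score = np.abs(vals) if std is not None else vals
    if ok.sum() > 0:
        ranks = stats.rankdata(score[ok])
        pct[ok] = ranks / ok.sum()
    high = np.zeros(raw.shape, dtype=bool)
    if ok.sum() >= int(round(1.0 / tail)):
        _thr, flags = empirical_high_set(np.where(ok, score, np.nan), tail=tail)
        high = flags
    out = pd.DataFrame({
        "snp_id": variant_table["snp_id"].to_numpy(),
        "chrom": variant_table["chrom"].to_numpy(),
        "pos_bp": variant_table["pos_bp"].to_numpy(),
        "raw": raw,
        "std": std if std is not None else np.full(raw.shape, np.nan),
        "percentile": pct,
        "high": high,
        "defined": defined,
    })
    return out


def fst_scan(genoA: np.ndarray, genoB: np.ndarray,
             variant_table: pd.DataFrame, tail: float = 0.001) -> pd.DataFrame:
    """Weir-Cockerham F_ST scan between two population genotype blocks."""
    theta, defined = weir_cockerham_theta(genoA, genoB)
    return _scan_frame(variant_table, theta, defined, tail=tail)


def lsbl_scan(fst_AB, fst_AC, fst_BC, clamp: bool = True) -> np.ndarray:
    """Locus-specific branch length for population A:
    ``(d_AB + d_AC - d_BC) / 2`` per SNP; undefined where any input is NaN."""
    fst_AB, fst_AC, fst_BC = map(np.asarray, (fst_AB, fst_AC, fst_BC))
    if not (fst_AB.shape == fst_AC.shape == fst_BC.shape):
        raise ValueError("F_ST vectors must be aligned")
    lsbl = (fst_AB + fst_AC - fst_BC) / 2.0
    if clamp:
        lsbl = np.where(np.isnan(lsbl), np.nan, np.clip(lsbl, 0.0, None))
    return lsbl


# ---------------------------------------------------------------------------
# empirical tails, blocks, bins
# ---------------------------------------------------------------------------

def empirical_high_set(values, tail: float = 0.001):
    """Empirical upper-tail threshold and strictly-greater flags.

    The threshold is the (1 - tail) empirical quantile; values strictly
    greater than it are flagged, so ties at the threshold are excluded.
    NaNs are never flagged.
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    n_def = int(ok.sum())
    if n_def < int(round(1.0 / tail)):
        raise ValueError(f"need >= {int(round(1.0 / tail))} defined values for a {tail} tail")
    defined = values[ok]
    if np.all(defined == defined[0]):
        warnings.warn("all values identical; empty high set")
        return float(defined[0]), np.zeros(values.shape, dtype=bool)
    threshold = float(np.quantile(defined, 1.0 - tail))
    flags = np.zeros(values.shape, dtype=bool)
    flags[ok] = defined > threshold
    return threshold, flags


def detect_blocks(high_positions, chrom=None, min_count: int = 4,
                  max_gap_bp: int = 100_000) -> pd.DataFrame:
    """Cluster high-scoring SNPs into physical signal blocks.

    A block is a maximal run of ``min_count`` or more high SNPs in which
    every adjacent pair is separated by strictly less than ``max_gap_bp``.
    ``high_positions`` is either an array of positions (single chromosome)
    or a DataFrame with ``chrom`` and ``pos_bp`` columns.
    """
    if isinstance(high_positions, pd.DataFrame):
        groups = [(c, g["pos_bp"].to_numpy()) for c, g in
                  high_positions.groupby("chrom", sort=False)]
    else:
        groups = [(chrom if chrom is not None else "1",
                   np.asarray(high_positions))]
    rows = []
    for c, pos in groups:
        pos = np.sort(pos)
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) >= max_gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [pos.size]])
        for s, e in zip(starts, ends):
            if e - s >= min_count:
                span = float(pos[e - 1] - pos[s])
                rows.append({
                    "chrom": c,
                    "start_bp": int(pos[s]),
                    "end_bp": int(pos[e - 1]),
                    "n_high_snps": int(e - s),
                    "length_bp": int(span),
                    "density_per_mb": (e - s) / (span / 1e6) if span > 0 else np.inf,
                })
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                       "n_high_snps", "length_bp", "density_per_mb"])


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    return float(stats.binom.sf(k - 1, n, p))


def bin_binomial_enrichment(variant_table: pd.DataFrame, high_flags,
                            bin_size: int = 500, alpha: float = 0.01) -> pd.DataFrame:
    """Binomial over-representation of high SNPs in consecutive SNP bins.

    Non-overlapping bins of ``bin_size`` SNPs in genome order (never
    spanning chromosomes; terminal partial bins dropped).  The per-bin
    success probability is the realized genome-wide fraction of high SNPs,
    and the p-value is the upper tail P(X >= k_high).
    """
    high = np.asarray(high_flags, dtype=bool)
    if len(high) != len(variant_table):
        raise ValueError("high_flags must align with variant_table")
    p_success = high.sum() / len(high) if len(high) else 0.0
    rows = []
    dropped = 0
    for chrom, grp in variant_table.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        n_bins = len(idx) // bin_size
        dropped += len(idx) - n_bins * bin_size
        for b in range(n_bins):
            sel = idx[b * bin_size:(b + 1) * bin_size]
            k = int(high[sel].sum())
            pval = 1.0 if p_success == 0.0 else binomial_upper_tail(k, bin_size, p_success)
            rows.append({
                "bin": len(rows),
                "chrom": chrom,
                "start_bp": int(variant_table.loc[sel[0], "pos_bp"]),
                "end_bp": int(variant_table.loc[sel[-1], "pos_bp"]),
                "n_snps": bin_size,
                "k_high": k,
                "p_success": p_success,
                "p_value": pval,
                "enriched": pval < alpha,
            })
    if dropped:
        logger.info("bin_binomial_enrichment dropped %d SNPs in partial bins", dropped)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------

def assign_ancestral_states(variant_table: pd.DataFrame,
                            outgroup_alleles: pd.DataFrame) -> pd.DataFrame:
    """Assign ancestral states from outgroup alleles by priority.

    The highest-priority non-missing outgroup allele (chimp, then orang,
    then macaque; '.' or NaN is missing) decides: if it equals ref or alt,
    that allele is ancestral; otherwise the state is unknown.
    """
    og = outgroup_alleles.set_index("snp_id")
    vt = variant_table.copy()
    states = []
    for row in vt.itertuples():
        state = "unknown"
        if row.snp_id in og.index:
            rec = og.loc[row.snp_id]
            for col in ("chimp", "orang", "macaque"):
                allele = rec.get(col)
                if isinstance(allele, str) and allele not in (".", ""):
                    if allele == row.ref:
                        state = "ref"
                    elif allele == row.alt:
                        state = "alt"
                    break
        states.append(state)
    vt["ancestral_state"] = states
    frac_unknown = np.mean([s == "unknown" for s in states]) if states else 0.0
    logger.info("ancestral states: %.1f%% unassigned", 100 * frac_unknown)
    return vt


# ---------------------------------------------------------------------------
# EHH machinery
# ---------------------------------------------------------------------------

def _ehh_steps(haps: np.ndarray, order) -> np.ndarray:
    """EHH at each marker in ``order`` for the haplotype block ``haps``.

    Group-refinement: haplotypes stay grouped while identical over the
    markers consumed so far; EHH is the probability two random haplotypes
    fall in the same group, sum_h C(n_h,2) / C(n,2).
    """
    n = haps.shape[0]
    denom = n * (n - 1) / 2.0
    ids = np.zeros(n, dtype=np.int64)
    out = np.empty(len(order))
    for k, j in enumerate(order):
        ids = ids * 2 + haps[:, j]
        _, inv, counts = np.unique(ids, return_inverse=True, return_counts=True)
        ids = inv.astype(np.int64)
        out[k] = (counts * (counts - 1)).sum() / 2.0 / denom
    return out


def ehh_curve(haps: np.ndarray, core_idx: int, core_allele: int, direction: str,
              genetic_pos=None):
    """EHH decay away from a core allele.

    Returns ``(distance, ehh)`` arrays starting at the core (distance 0,
    EHH 1) and stepping marker by marker left or right among the carriers
    of ``core_allele``.  Distances are |genetic position - core position|
    when ``genetic_pos`` is given, otherwise marker counts.  Undefined
    (returns None) with fewer than 2 carriers.
    """
    carriers = haps[haps[:, core_idx] == core_allele]
    if carriers.shape[0] < 2:
        return None
    m = haps.shape[1]
    if direction == "left":
        order = range(core_idx - 1, -1, -1)
    elif direction == "right":
        order = range(core_idx + 1, m)
    else:
        raise ValueError("direction must be 'left' or 'right'")
    order = list(order)
    ehh = np.concatenate([[1.0], _ehh_steps(carriers, order)])
    if genetic_pos is not None:
        gp = np.asarray(genetic_pos)
        dist = np.concatenate([[0.0], np.abs(gp[order] - gp[core_idx])])
    else:
        dist = np.arange(len(order) + 1, dtype=float)
    return dist, ehh


def _side_orders(core_idx: int, m: int):
    return (("left", range(core_idx - 1, -1, -1)),
            ("right", range(core_idx + 1, m)))


def _ihh_side(carriers: np.ndarray, core_idx: int, order, gp, bp,
              cutoff: float, max_gap_bp: int, max_steps=None):
    """One-sided truncated trapezoidal iHH with incremental group refinement.

    Steps marker by marker, maintaining haplotype group ids; stops after
    the first marker whose EHH falls below ``cutoff`` (that segment is
    still integrated), before any physical gap >= ``max_gap_bp``, at the
    chromosome end, or after ``max_steps`` markers (used to share pooled
    integration limits across panels).  Returns ``(integral, n_steps)``.
    """
    order = np.fromiter(order, dtype=np.int64)
    if max_steps is not None:
        order = order[:max_steps]
    n = carriers.shape[0]
    denom = n * (n - 1) / 2.0
    if order.size == 0:
        return 0.0, 0

    d = np.abs(gp[order] - gp[core_idx])
    gap = np.abs(np.diff(np.concatenate([[bp[core_idx]], bp[order]]))) >= max_gap_bp
    limit = int(np.argmax(gap)) if gap.any() else order.size

    block = 4
    ids = np.zeros(n, dtype=np.int64)
    n_groups = 1
    ehh = 1.0
    total = 0.0
    k = 0
    while k < limit:
        b_end = min(k + block, limit)
        # flat stretches (no group splits anywhere in the block) are
        # integrated wholesale: find the first marker polymorphic within
        # any current group; the block grows while markers stay flat
        cols = order[k:b_end]
        if n_groups == 1:
            sub = carriers[:, cols]
            poly = (sub.max(axis=0) > sub.min(axis=0))
        else:
            sort_idx = np.argsort(ids, kind="stable")
            sid = ids[sort_idx]
            starts = np.flatnonzero(np.concatenate([[True], sid[1:] != sid[:-1]]))
            sub = carriers[np.ix_(sort_idx, cols)]
            gmin = np.minimum.reduceat(sub, starts, axis=0)
            gmax = np.maximum.reduceat(sub, starts, axis=0)
            poly = (gmax > gmin).any(axis=0)
        has_split = bool(poly.any())
        t = int(np.argmax(poly)) if has_split else (b_end - k)
        if t:
            prev_d = d[k - 1] if k else 0.0
            total += ehh * (d[k + t - 1] - prev_d)
            k += t
        block = max(4, block // 2) if has_split else min(512, block * 2)
        if not has_split or k >= limit:
            continue
        # refine groups at the splitting marker
        key = ids * 2 + carriers[:, order[k]]
        counts = np.bincount(key, minlength=2 * n_groups)
        nz = np.flatnonzero(counts)
        remap = np.zeros(2 * n_groups, dtype=np.int64)
        remap[nz] = np.arange(nz.size)
        ids = remap[key]
        n_groups = nz.size
        cz = counts[nz]
        new_ehh = float((cz * (cz - 1)).sum()) / 2.0 / denom
        prev_d = d[k - 1] if k else 0.0
        total += 0.5 * (ehh + new_ehh) * (d[k] - prev_d)
        ehh = new_ehh
        k += 1
        if ehh < cutoff:
            break
    return total, k


def integrated_ehh(haps: np.ndarray, core_idx: int, core_allele, genetic_pos,
                   pos_bp, ehh_cutoff: float = 0.05, max_gap_bp: int = 200_000,
                   max_steps=None) -> float:
    """Integrated EHH (iHH) for one core, summed over both directions.

    ``core_allele`` of None pools all haplotypes (the cross-population
    variant of the statistic).  ``max_steps``, when given, is a
    ``{'left': k, 'right': k}`` pair bounding the number of markers
    integrated per side — used to share integration limits between
    populations.  Integration is over genetic distance, truncated where
    EHH drops below ``ehh_cutoff``, at chromosome ends, and before any
    physical gap >= ``max_gap_bp``.
    """
    if core_allele is None:
        carriers = haps
    else:
        carriers = haps[haps[:, core_idx] == core_allele]
    if carriers.shape[0] < 2:
        return np.nan
    gp = np.asarray(genetic_pos, dtype=float)
    bp = np.asarray(pos_bp, dtype=float)
    total = 0.0
    for side, order in _side_orders(core_idx, haps.shape[1]):
        lim = None if max_steps is None else max_steps[side]
        part, _ = _ihh_side(carriers, core_idx, order, gp, bp,
                            ehh_cutoff, max_gap_bp, max_steps=lim)
        total += part
    return total


def _standardize_in_bins(values, bin_key, bin_width=0.02, min_bin=50):
    """Zero-mean/unit-SD standardization within bins of ``bin_key``; bins
    with fewer than ``min_bin`` members are merged with their neighbour."""
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values) & np.isfinite(bin_key)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    which = np.clip(np.digitize(bin_key, edges) - 1, 0, len(edges) - 2)
    # merge sparse bins rightward (then leftward at the top end)
    counts = np.bincount(which[ok], minlength=len(edges) - 1)
    merged = np.arange(len(counts))
    for b in range(len(counts)):
        if 0 < counts[b] < min_bin:
            if b + 1 < len(counts):
                target = b + 1
                while target < len(counts) - 1 and counts[target] == 0:
                    target += 1
            else:
                target = b - 1
                while target > 0 and counts[target] == 0:
                    target -= 1
            if target == b or target < 0:
                continue
            counts[target] += counts[b]
            counts[b] = 0
            merged[merged == b] = target
    which = merged[which]
    std = np.full(values.shape, np.nan)
    assignment = np.where(ok, which, -1)
    for b in np.unique(which[ok]):
        sel = ok & (which == b)
        v = values[sel]
        sd = v.std()
        std[sel] = (v - v.mean()) / sd if sd > 0 else 0.0
    return std, assignment


def ihs_scan(haps: np.ndarray, variant_table: pd.DataFrame, min_maf: float = 0.05,
             ehh_cutoff: float = 0.05, max_gap_bp: int = 200_000,
             freq_bin_width: float = 0.02, min_bin: int = 50,
             tail: float = 0.001) -> pd.DataFrame:
    """Integrated haplotype score scan within one population.

    Per SNP with known ancestral state and MAF >= ``min_maf``:
    iHH_A and iHH_D integrate the EHH of the ancestral- and derived-allele
    carriers over genetic distance (0.05 EHH cutoff, 200 kb gap rule,
    chromosome-end truncation); the unstandardized score is
    ln(iHH_A / iHH_D), standardized to zero mean and unit variance within
    2%-wide derived-allele-frequency bins.  The high flag marks the
    empirical 0.1% tail of |standardized iHS|.
    """
    vt = variant_table.reset_index(drop=True)
    gp = vt["cM"].to_numpy(dtype=float)
    bp = vt["pos_bp"].to_numpy(dtype=float)
    anc_state = vt["ancestral_state"].to_numpy()
    freq_alt = haps.mean(axis=0)
    maf = np.minimum(freq_alt, 1 - freq_alt)
    derived_freq = np.where(anc_state == "ref", freq_alt, 1.0 - freq_alt)

    m = len(vt)
    raw = np.full(m, np.nan)
    usable = (maf >= min_maf) & np.isin(anc_state, ("ref", "alt"))
    for chrom, grp in vt.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        sub = haps[:, idx]
        for k, j in enumerate(idx):
            if not usable[j]:
                continue
            anc_allele = 0 if anc_state[j] == "ref" else 1
            ihh_a = integrated_ehh(sub, k, anc_allele, gp[idx], bp[idx],
                                   ehh_cutoff, max_gap_bp)
            ihh_d = integrated_ehh(sub, k, 1 - anc_allele, gp[idx], bp[idx],
                                   ehh_cutoff, max_gap_bp)
            if np.isfinite(ihh_a) and np.isfinite(ihh_d) and ihh_a > 0 and ihh_d > 0:
                raw[j] = np.log(ihh_a / ihh_d)
    std, bin_assignment = _standardize_in_bins(raw, derived_freq,
                                               freq_bin_width, min_bin)
    defined = np.isfinite(raw)
    out = _scan_frame(vt, raw, defined, std=std, tail=tail)
    out["std_bin"] = bin_assignment
    out["derived_freq"] = derived_freq
    return out


def xpehh_scan(hapsA: np.ndarray, hapsB: np.ndarray, variant_table: pd.DataFrame,
               min_maf: float = 0.05, ehh_cutoff: float = 0.05,
               max_gap_bp: int = 200_000, tail: float = 0.001) -> pd.DataFrame:
    """Cross-population EHH scan; positive scores mean longer haplotype
    homozygosity in population A.

    The integration interval per core SNP is set where the EHH of the
    pooled panel falls below ``ehh_cutoff`` (plus gap/end rules) and is
    shared by both populations; the unstandardized score is
    ln(iHH_A / iHH_B), standardized genome-wide to zero mean and unit
    variance.  SNPs with pooled MAF < ``min_maf`` are skipped; the high
    flag marks the empirical 0.1% tail of |standardized score|.
    """
    if hapsA.shape[1] != hapsB.shape[1]:
        raise ValueError("panels must share the variant list")
    vt = variant_table.reset_index(drop=True)
    gp = vt["cM"].to_numpy(dtype=float)
    bp = vt["pos_bp"].to_numpy(dtype=float)
    pooled = np.vstack([hapsA, hapsB])
    freq = pooled.mean(axis=0)
    usable = np.minimum(freq, 1 - freq) >= min_maf

    m = len(vt)
    raw = np.full(m, np.nan)
    for chrom, grp in vt.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        subA, subB, subP = hapsA[:, idx], hapsB[:, idx], pooled[:, idx]
        gpi, bpi = gp[idx], bp[idx]
        for k, j in enumerate(idx):
            if not usable[j]:
                continue
            # pooled panel fixes the integration interval, shared by both pops
            limits = {}
            for side, order in _side_orders(k, subP.shape[1]):
                _tot, steps = _ihh_side(subP, k, order, gpi, bpi,
                                        ehh_cutoff, max_gap_bp)
                limits[side] = steps
            ihh_a = integrated_ehh(subA, k, None, gpi, bpi, 0.0, max_gap_bp,
                                   max_steps=limits)
            ihh_b = integrated_ehh(subB, k, None, gpi, bpi, 0.0, max_gap_bp,
                                   max_steps=limits)
            if np.isfinite(ihh_a) and np.isfinite(ihh_b) and ihh_a > 0 and ihh_b > 0:
                raw[j] = np.log(ihh_a / ihh_b)
    defined = np.isfinite(raw)
    std = np.full(m, np.nan)
    if defined.any():
        v = raw[defined]
        std[defined] = (v - v.mean()) / v.std()
    return _scan_frame(vt, raw, defined, std=std, tail=tail)




# ---------------------------------------------------------------------------
# sequence diversity
# ---------------------------------------------------------------------------

@dataclass
class SeqDiversity:
    n_sequences: int
    n_sites: int
    segregating_sites: int
    pi_per_site: float
    watterson_theta_per_site: float
    tajimas_d: float        # NaN when undefined
    d_defined: bool


def seq_diversity(alignment) -> SeqDiversity:
    """Nucleotide diversity, Watterson's theta and Tajima's D.

    ``alignment`` is a list of equal-length ACGTN strings.  Pairwise
    differences exclude sites with N in either member of a pair; S counts
    sites with >= 2 distinct non-N alleles; D uses the standard
    a1..e2 constants and is undefined when S = 0.
    """
    seqs = [s.upper() for s in alignment]
    n = len(seqs)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal length")
    arr = np.array([list(s) for s in seqs])
    valid = arr != "N"

    seg = 0
    for j in range(L):
        alleles = set(arr[valid[:, j], j])
        if len(alleles) >= 2:
            seg += 1

    diffs = 0.0
    n_pairs = 0
    for i in range(n):
        for k in range(i + 1, n):
            both = valid[i] & valid[k]
            sites = both.sum()
            if sites == 0:
                continue
            d = np.sum(arr[i, both] != arr[k, both])
            diffs += d / sites
            n_pairs += 1
    pi = diffs / n_pairs if n_pairs else 0.0

    a1 = np.sum(1.0 / np.arange(1, n))
    theta_w = seg / a1 / L

    if seg == 0:
        return SeqDiversity(n, L, 0, pi, theta_w, np.nan, False)
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * seg + e2 * seg * (seg - 1.0)
    d = (pi * L - seg / a1) / np.sqrt(var)
    return SeqDiversity(n, L, int(seg), pi, theta_w, float(d), True)


# ---------------------------------------------------------------------------
# haplotype template matching
# ---------------------------------------------------------------------------

def haplotype_template_match(haps: np.ndarray, focal_idx: int, half_window: int,
                             maf_min: float = 0.1) -> pd.DataFrame:
    """Match each haplotype outward from a focal SNP against the 10 most
    frequent window haplotypes ("templates").

    SNPs with MAF < ``maf_min`` are removed first; the window is
    ``half_window`` retained SNPs each side of the focal SNP (truncated at
    chromosome ends).  Matching consumes one SNP at a time, left first then
    right alternately; the live template set shrinks at each step and a
    side's extent ends when no live template matches its extension.  The
    assigned template is the most frequent one still live at the end.

    Returns per-haplotype ``template_rank`` (1 = most frequent, 0 = no
    match beyond the focal SNP), ``left_extent`` and ``right_extent``
    (number of matched SNPs per side).
    """
    freq = haps.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    if maf[focal_idx] <= 0:
        raise ValueError("focal SNP must be polymorphic")
    keep = np.flatnonzero((maf >= maf_min) | (np.arange(haps.shape[1]) == focal_idx))
    sub = haps[:, keep]
    f = int(np.searchsorted(keep, focal_idx))
    lo = max(0, f - half_window)
    hi = min(sub.shape[1], f + half_window + 1)
    win = sub[:, lo:hi]
    fpos = f - lo

    # templates: top-10 most frequent full-window haplotypes, ties by first occurrence
    keys = ["".join(map(str, row)) for row in win]
    order = {}
    counts = {}
    for i, k in enumerate(keys):
        counts[k] = counts.get(k, 0) + 1
        order.setdefault(k, i)
    ranked = sorted(counts, key=lambda k: (-counts[k], order[k]))[:10]
    templates = np.array([list(map(int, k)) for k in ranked])

    # interleaved step order: left first, then right, one SNP at a time
    steps = []
    li, ri = fpos - 1, fpos + 1
    while li >= 0 or ri < win.shape[1]:
        if li >= 0:
            steps.append(("L", li))
            li -= 1
        if ri < win.shape[1]:
            steps.append(("R", ri))
            ri += 1

    rows = []
    for h in win:
        live = np.flatnonzero(templates[:, fpos] == h[fpos])
        left = right = 0
        left_open = right_open = True
        for side, j in steps:
            if not live.size:
                break
            if side == "L" and left_open:
                nxt = live[templates[live, j] == h[j]]
                if nxt.size:
                    live = nxt
                    left += 1
                else:
                    left_open = False
            elif side == "R" and right_open:
                nxt = live[templates[live, j] == h[j]]
                if nxt.size:
                    live = nxt
                    right += 1
                else:
                    right_open = False
            if not (left_open or right_open):
                break
        rank = int(live[0]) + 1 if live.size else 0
        rows.append({"template_rank": rank, "left_extent": left, "right_extent": right})
    return pd.DataFrame(rows)
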