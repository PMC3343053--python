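"""Cohort I/O and genotype quality control.

Reads phased VCF cohorts plus sample and genetic-map tables, and applies
the QC used throughout the pipeline: per-SNP missingness filtering,
method-of-moments relatedness (pi-hat) with greedy relative removal,
identity-by-state kinship, and windowed VIF-based LD pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import HaplotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "read_cohort",
    "snp_missingness_filter",
    "pairwise_pi_hat",
    "remove_relatives",
    "ibs_kinship",
    "vif_prune",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with values {0,1,2} and -1 for missing."""

    matrix: np.ndarray
    sample_ids: list
    snp_ids: list

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("matrix shape inconsistent with id lists")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_fraction_per_snp(self) -> np.ndarray:
        return (self.matrix == MISSING).mean(axis=0)

    def missing_fraction_per_sample(self) -> np.ndarray:
        return (self.matrix == MISSING).mean(axis=1)

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls."""
        m = np.ma.masked_equal(self.matrix, MISSING)
        return np.asarray(m.mean(axis=0) / 2.0)

    def subset_snps(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(self.matrix[:, keep], list(self.sample_ids),
                              [self.snp_ids[i] for i in keep])

    def subset_samples(self, ids) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(self.matrix[idx], list(ids), list(self.snp_ids))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_cohort(vcf_path, sample_tsv, map_tsv=None):
    """Read a cohort from a VCF plus a sample table (and optional genetic map).

    Only biallelic SNPs are used (others are skipped and counted).  A phased
    :class:`HaplotypePanel` is returned only when every genotype in the VCF
    is phased and non-missing; genotypes are returned regardless.  Genetic
    positions are linearly interpolated between map points with constant
    extrapolation beyond the ends.

    Returns ``(genotypes, panel_or_None, variant_table, sample_table)``.
    """
    from cyvcf2 import VCF

    sample_table = pd.read_csv(sample_tsv, sep="\t", dtype={"sample_id": str})
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    tsv_samples = list(sample_table["sample_id"])
    if set(vcf_samples) != set(tsv_samples):
        only_vcf = sorted(set(vcf_samples) - set(tsv_samples))
        only_tsv = sorted(set(tsv_samples) - set(vcf_samples))
        raise ValueError(
            f"sample-id mismatch between VCF and sample table; "
            f"VCF-only: {only_vcf[:10]}, table-only: {only_tsv[:10]}")

    n = len(vcf_samples)
    geno_rows, hapA, hapB, records = [], [], [], []
    all_phased = True
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        gt = np.asarray(v.genotypes, dtype=object)
        a0 = np.array([g[0] for g in gt], dtype=np.int16)
        a1 = np.array([g[1] for g in gt], dtype=np.int16)
        phased = np.array([bool(g[2]) for g in gt])
        miss = (a0 < 0) | (a1 < 0)
        if (~phased).any() or miss.any():
            all_phased = False
        dose = np.where(miss, MISSING, a0 + a1).astype(np.int16)
        geno_rows.append(dose)
        hapA.append(np.where(a0 < 0, 0, a0).astype(np.int8))
        hapB.append(np.where(a1 < 0, 0, a1).astype(np.int8))
        records.append((v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS, v.REF, v.ALT[0]))
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP records", n_skipped)

    variant_table = pd.DataFrame(records,
                                 columns=["snp_id", "chrom", "pos_bp", "ref", "alt"])
    variant_table["ancestral_state"] = "unknown"

    if map_tsv is not None:
        gmap = pd.read_csv(map_tsv, sep="\t")
        cm = np.empty(len(variant_table))
        for chrom, grp in variant_table.groupby("chrom", sort=False):
            mchr = gmap[gmap["chrom"].astype(str) == str(chrom)].sort_values("pos_bp")
            cm[grp.index] = np.interp(grp["pos_bp"], mchr["pos_bp"], mchr["cM"])
        variant_table["cM"] = cm

    matrix = np.stack(geno_rows).T if geno_rows else np.empty((n, 0), dtype=np.int16)
    geno = GenotypeMatrix(matrix, vcf_samples, list(variant_table["snp_id"]))

    panel = None
    if all_phased and geno_rows:
        haps = np.empty((2 * n, len(geno_rows)), dtype=np.int8)
        haps[0::2] = np.stack(hapA).T
        haps[1::2] = np.stack(hapB).T
        panel = HaplotypePanel(haps, vcf_samples)

    sample_table = sample_table.set_index("sample_id").loc[vcf_samples].reset_index()
    return geno, panel, variant_table, sample_table


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def snp_missingness_filter(geno: GenotypeMatrix, max_missing: float = 0.05):
    """Retain SNPs whose missing fraction is <= ``max_missing``.

    Returns ``(filtered_geno, report)`` where report counts removals.
    """
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0,1]")
    frac = geno.missing_fraction_per_snp()
    keep = frac <= max_missing
    report = {
        "n_input": geno.n_snps,
        "n_removed": int((~keep).sum()),
        "n_retained": int(keep.sum()),
        "max_missing": max_missing,
    }
    logger.info("missingness filter: removed %d of %d SNPs at cutoff %.3f",
                report["n_removed"], report["n_input"], max_missing)
    return geno.subset_snps(keep), report


# ---------------------------------------------------------------------------
# relatedness (method-of-moments IBD)
# ---------------------------------------------------------------------------

def pairwise_pi_hat(geno: GenotypeMatrix, allele_freqs=None, min_maf: float = 0.01,
                    min_informative: int = 100) -> pd.DataFrame:
    """Method-of-moments P(IBD=0/1/2) and pi-hat for every sample pair.

    Observed identity-by-state counts (IBS0/1/2 over shared non-missing
    SNPs) are equated with their expectations under each IBD state, solved
    sequentially for P(IBD=0), P(IBD=1), P(IBD=2), clamped to [0,1] and
    renormalized; pi_hat = P1/2 + P2.  SNPs with MAF < ``min_maf`` are
    excluded.  Allele frequencies default to the in-cohort estimates.
    """
    g = geno.matrix
    p = np.asarray(allele_freqs, dtype=float) if allele_freqs is not None \
        else geno.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= min_maf
    if int(keep.sum()) < min_informative:
        raise ValueError(f"only {int(keep.sum())} informative SNPs (need >= {min_informative})")
    g = g[:, keep].astype(np.float32)
    p = p[keep]
    q = 1.0 - p

    valid = (g >= 0)
    vf = valid.astype(np.float32)

    # indicator matrices for the three genotype classes
    a0 = ((g == 0) & valid).astype(np.float32)
    a1 = ((g == 1) & valid).astype(np.float32)
    a2 = ((g == 2) & valid).astype(np.float32)

    n_shared = vf @ vf.T
    ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    ibs0 = a0 @ a2.T + a2 @ a0.T
    ibs1 = n_shared - ibs2 - ibs0

    # per-SNP conditional IBS probabilities given IBD state
    e0_z0 = (2.0 * p**2 * q**2).astype(np.float32)
    e1_z0 = (4.0 * p**3 * q + 4.0 * p * q**3).astype(np.float32)
    e2_z0 = (1.0 - e0_z0 - e1_z0).astype(np.float32)
    e1_z1 = (2.0 * p**2 * q + 2.0 * p * q**2).astype(np.float32)
    e2_z1 = (1.0 - e1_z1).astype(np.float32)

    E0_0 = (vf * e0_z0) @ vf.T
    E1_0 = (vf * e1_z0) @ vf.T
    E2_0 = (vf * e2_z0) @ vf.T
    E1_1 = (vf * e1_z1) @ vf.T
    E2_1 = (vf * e2_z1) @ vf.T

    with np.errstate(divide="ignore", invalid="ignore"):
        z0 = ibs0 / E0_0
        z1 = (ibs1 - z0 * E1_0) / E1_1
        z2 = (ibs2 - z0 * E2_0 - z1 * E2_1) / n_shared
    z = np.stack([z0, z1, z2])
    z = np.clip(np.nan_to_num(z), 0.0, 1.0)
    total = z.sum(axis=0)
    total[total == 0] = 1.0
    z /= total

    ids = geno.sample_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    return pd.DataFrame({
        "id1": [ids[i] for i in iu],
        "id2": [ids[j] for j in ju],
        "Z0": z[0][iu, ju],
        "Z1": z[1][iu, ju],
        "Z2": z[2][iu, ju],
        "pi_hat": (z[1] / 2.0 + z[2])[iu, ju],
        "n_shared": n_shared[iu, ju].astype(int),
    })


def remove_relatives(relatedness: pd.DataFrame, threshold: float = 0.25,
                     missingness_by_sample=None) -> list:
    """Greedy relative removal: drop the highest-degree individual from the
    pi-hat > threshold graph until no related pair remains.

    Ties broken by higher missingness, then lexicographically smaller id,
    so the output is order-stable.  Returns removed ids in removal order.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0,1)")
    miss = dict(missingness_by_sample or {})
    edges = {
        (r.id1, r.id2)
        for r in relatedness.itertuples()
        if r.pi_hat > threshold
    }
    removed = []
    while edges:
        degree = {}
        for a, b in edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        top = max(degree.values())
        cands = [s for s in degree if degree[s] == top]
        top_miss = max(miss.get(s, 0.0) for s in cands)
        victim = min(s for s in cands if miss.get(s, 0.0) == top_miss)
        removed.append(victim)
        edges = {e for e in edges if victim not in e}
    logger.info("relatedness filter removed %d individuals at pi_hat > %.2f",
                len(removed), threshold)
    return removed


# ---------------------------------------------------------------------------
# IBS kinship
# ---------------------------------------------------------------------------

def ibs_kinship(geno: GenotypeMatrix):
    """Pairwise identity-by-state similarity matrix.

    K_ij is the mean over shared non-missing SNPs of (shared allele
    count)/2, i.e. per-SNP IBS in {0, 0.5, 1}.  Returns ``(K, sample_ids)``.
    """
    if geno.n_samples < 2:
        raise ValueError("kinship needs >= 2 samples")
    g = geno.matrix.astype(np.float32)
    valid = (g >= 0).astype(np.float32)

    n_shared = valid @ valid.T
    if (n_shared == 0).any():
        raise ValueError("a sample pair shares zero non-missing SNPs")
    # sum over SNPs of |g_i - g_j| decomposed through squared terms:
    # |gi-gj| in {0,1,2}; |gi-gj| = (gi-gj)^2 - 2*[both het? no] -- use
    # indicator decomposition instead for exactness.
    a0 = ((g == 0) & (valid > 0)).astype(np.float32)
    a1 = ((g == 1) & (valid > 0)).astype(np.float32)
    a2 = ((g == 2) & (valid > 0)).astype(np.float32)
    absdiff = (a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T
               + 2.0 * (a0 @ a2.T + a2 @ a0.T))
    K = 1.0 - absdiff / (2.0 * n_shared)
    return K.astype(np.float64), list(geno.sample_ids)


# ---------------------------------------------------------------------------
# VIF-based LD pruning
# ---------------------------------------------------------------------------

def _window_vif_prune(dose: np.ndarray, active: np.ndarray, threshold: float,
                      ridge: float = 1e-8) -> list:
    """Remove max-VIF SNPs within one window until all VIF <= threshold.

    ``active`` holds the global column indices currently retained in the
    window.  Returns the list of global indices removed.
    """
    removed = []
    idx = list(active)
    while len(idx) >= 2:
        x = dose[:, idx]
        r = np.corrcoef(x, rowvar=False)
        r = np.atleast_2d(r)
        try:
            rinv = np.linalg.inv(r + ridge * np.eye(r.shape[0]))
        except np.linalg.LinAlgError:
            rinv = np.linalg.pinv(r)
        vif = np.diag(rinv)
        worst = int(np.argmax(vif))
        if vif[worst] <= threshold:
            break
        removed.append(idx.pop(worst))
    return removed


def vif_prune(geno: GenotypeMatrix, window: int = 100, step: int = 50,
              vif_threshold: float = 2.0) -> list:
    """Sliding-window LD pruning on the variance inflation factor.

    Within each window (``window`` SNPs, offset ``step``) the SNP with the
    largest VIF = 1/(1-R^2) against the other retained SNPs in the window
    is removed until every VIF is <= ``vif_threshold``.  Removals are
    global: a SNP removed in one window stays removed.  Monomorphic SNPs
    are removed first.  Returns the retained snp_id list.
    """
    if not (window > step > 0):
        raise ValueError("require window > step > 0")
    g = geno.matrix.astype(np.float64)
    miss = g < 0
    col_mean = np.where(miss, np.nan, g)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(col_mean, axis=0)
    dose = np.where(miss, mu, g)

    keep = np.ones(geno.n_snps, dtype=bool)
    mono = np.nanstd(np.where(miss, np.nan, g), axis=0) == 0
    if mono.any():
        logger.info("vif_prune: removing %d monomorphic SNPs first", int(mono.sum()))
        keep[mono] = False

    for start in range(0, geno.n_snps, step):
        cols = np.arange(start, min(start + window, geno.n_snps))
        active = cols[keep[cols]]
        for r in _window_vif_prune(dose, active, vif_threshold):
            keep[r] = False
        if start + window >= geno.n_snps:
            break
    retained = [geno.snp_ids[i] for i in np.flatnonzero(keep)]
    logger.info("vif_prune retained %d of %d SNPs at VIF <= %.2f",
                len(retained), geno.n_snps, vif_threshold)
    return retained
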