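"""Gene-window mapping and pathway enrichment for selection/association scans.

Three complementary procedures:

* hypergeometric over-representation of a candidate gene list against a
  user-supplied pathway database (GMT), with a Bonferroni threshold of
  0.05 divided by the number of pathways holding at least two genes;
* a cumulative pathway statistic CA = sum of per-SNP scan scores over a
  pathway's SNPs, tested against a resampled null (equal-size draws with
  replacement from the genome-wide scores) smoothed by a maximum-likelihood
  skew-normal fit;
* a "top-two" resampling test for whether a given pair of pathways would
  rank as the two most enriched in random gene lists of the observed size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["read_gene_bed", "read_gmt", "genes_near_signals",
           "pathway_overrepresentation", "cumulative_pathway_test",
           "CumulativeTestResult", "top_two_resampling_test"]


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

def read_gene_bed(path) -> pd.DataFrame:
    """Gene intervals from a BED file (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "gene"]
    if (df["start"] >= df["end"]).any() or (df["start"] < 0).any():
        raise ValueError("malformed BED intervals")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene symbols in BED")
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_gmt(path) -> dict:
    """Pathway -> gene-set mapping from a GMT file (name, description, genes...).

    Empty pathways are rejected; the pathway universe is the union of all
    member genes unless the caller supplies one.
    """
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line with no genes: {parts[:1]}")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"empty pathway {name!r}")
            out[name] = set(genes)
    return out


# ---------------------------------------------------------------------------
# gene windows
# ---------------------------------------------------------------------------

def genes_near_signals(signal_snps, gene_table: pd.DataFrame,
                       flank_bp: int = 100_000) -> list:
    """Protein-coding genes within ``flank_bp`` of any signal SNP.

    ``signal_snps`` is a DataFrame with ``chrom`` and ``pos_bp`` (1-based)
    columns.  A gene is included when a signal SNP falls inside its
    interval extended by ``flank_bp`` on both sides (inclusive at the
    boundary).  Returns deduplicated gene symbols in genomic order.
    """
    found = []
    for chrom, grp in signal_snps.groupby("chrom", sort=False):
        pos = np.sort(grp["pos_bp"].to_numpy())
        genes = gene_table[gene_table["chrom"].astype(str) == str(chrom)]
        for g in genes.itertuples():
            lo = g.start + 1 - flank_bp   # 1-based inclusive window
            hi = g.end + flank_bp
            i = np.searchsorted(pos, lo, side="left")
            if i < pos.size and pos[i] <= hi:
                found.append((g.chrom, g.start, g.gene))
    seen = set()
    out = []
    for _, _, gene in sorted(found):
        if gene not in seen:
            seen.add(gene)
            out.append(gene)
    return out


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def pathway_overrepresentation(gene_list, pathway_db: dict,
                               universe=None, alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation per pathway.

    Genes outside the universe are dropped (logged).  The Bonferroni
    threshold divides ``alpha`` by the number of pathways with at least two
    genes in the universe (single-gene pathways are still tested but
    excluded from the correction denominator).
    """
    if universe is None:
        universe = set().union(*pathway_db.values())
    universe = set(universe)
    genes = [g for g in dict.fromkeys(gene_list) if g in universe]
    dropped = len(set(gene_list)) - len(genes)
    if dropped:
        logger.info("pathway_overrepresentation dropped %d genes outside universe",
                    dropped)
    if not genes:
        raise ValueError("gene list is empty after universe filtering")
    N = len(universe)
    n = len(genes)
    gene_set = set(genes)
    rows = []
    n_multi = 0
    for name, members in pathway_db.items():
        members = members & universe
        K = len(members)
        if K >= 2:
            n_multi += 1
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"pathway": name, "n_pathway": K, "overlap": k, "p": p})
    thr = alpha / max(n_multi, 1)
    df = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    df["bonferroni_threshold"] = thr
    df["significant"] = df["p"] < thr
    return df


# ---------------------------------------------------------------------------
# cumulative pathway score test
# ---------------------------------------------------------------------------

@dataclass
class CumulativeTestResult:
    ca_observed: float
    n_snps: int
    n_resample: int
    xi: float                  # skew-normal location
    omega: float               # scale
    alpha: float               # shape
    p: float
    empirical_p: float
    skewnorm_converged: bool


def cumulative_pathway_test(snp_scores, pathway_snp_idx, n_resample: int = 10_000,
                            seed=None) -> CumulativeTestResult:
    """Cumulative pathway statistic against a resampled skew-normal null.

    CA_obs sums the scan scores of the pathway's SNPs; the null resamples
    equally many scores with replacement from the genome-wide set
    ``n_resample`` times; a skew-normal is fit to the null by maximum
    likelihood and the reported p is its upper tail at CA_obs.  When the
    fit fails the empirical resampling p is reported with a flag.
    """
    scores = np.asarray(snp_scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    idx = np.asarray(pathway_snp_idx)
    obs = np.asarray(snp_scores, dtype=float)[idx]
    if not np.all(np.isfinite(obs)):
        raise ValueError("pathway SNP scores must be finite")
    k = obs.size
    if k < 10:
        raise ValueError("pathway must contain >= 10 SNPs")
    ca_obs = float(obs.sum())
    rng = np.random.default_rng(seed)
    null = rng.choice(scores, size=(n_resample, k), replace=True).sum(axis=1)
    emp_p = float((1 + np.sum(null >= ca_obs)) / (n_resample + 1))
    converged = True
    try:
        a, loc, scale = stats.skewnorm.fit(null)
        p = float(stats.skewnorm.sf(ca_obs, a, loc=loc, scale=scale))
        if not (np.isfinite(p) and np.isfinite(a) and scale > 0):
            raise ValueError
    except Exception:
        converged = False
        a, loc, scale = np.nan, np.nan, np.nan
        p = emp_p
        logger.warning("skew-normal fit failed; reporting empirical p")
    return CumulativeTestResult(ca_obs, k, n_resample, float(loc), float(scale),
                                float(a), p, emp_p, converged)


# ---------------------------------------------------------------------------
# top-two pathway resampling
# ---------------------------------------------------------------------------

def _chi2_2x2(a, row1, col1, total):
    """Chi-squared statistic of the 2x2 table with entry ``a`` and the
    given margins, vectorized; no continuity correction."""
    b = col1 - a
    c = row1 - a
    d = total - row1 - col1 + a
    num = total * (a * d - b * c) ** 2
    den = row1 * (total - row1) * col1 * (total - col1)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def top_two_resampling_test(observed_list_size: int, target_pathways,
                            pathway_db: dict, universe=None,
                            n_reps: int = 10_000, seed=None):
    """Probability that any target pathway ranks among the two most
    enriched in random gene lists of the observed size.

    Per repetition a gene list is drawn without replacement from the
    universe; each pathway's 2x2 chi-squared statistic (in-list x
    in-pathway) is computed and the two largest recorded.  The returned p
    is the fraction of repetitions where any target pathway makes the top
    two, floored at 1/n_reps.
    """
    if len(pathway_db) < 2:
        raise ValueError("need at least 2 pathways")
    targets = list(target_pathways)
    unknown = [t for t in targets if t not in pathway_db]
    if unknown:
        raise ValueError(f"unknown target pathways: {unknown}")
    if universe is None:
        universe = sorted(set().union(*pathway_db.values()))
    else:
        universe = sorted(set(universe))
    U = len(universe)
    if observed_list_size > U:
        raise ValueError("list size exceeds universe")
    gidx = {g: i for i, g in enumerate(universe)}
    names = sorted(pathway_db)
    member = np.zeros((len(names), U), dtype=np.float32)
    for r, name in enumerate(names):
        for g in pathway_db[name]:
            if g in gidx:
                member[r, gidx[g]] = 1.0
    col1 = member.sum(axis=1)          # pathway sizes
    t_rows = np.array([names.index(t) for t in targets])

    rng = np.random.default_rng(seed)
    hits = 0
    batch = max(1, min(n_reps, 2_000_000 // max(U, 1)))
    done = 0
    while done < n_reps:
        b = min(batch, n_reps - done)
        masks = np.zeros((b, U), dtype=np.float32)
        for i in range(b):
            masks[i, rng.choice(U, size=observed_list_size, replace=False)] = 1.0
        overlap = masks @ member.T                      # b x pathways
        chi2 = _chi2_2x2(overlap, observed_list_size, col1[None, :], U)
        top2 = np.argsort(-chi2, axis=1, kind="stable")[:, :2]
        hits += int(np.isin(top2, t_rows).any(axis=1).sum())
        done += b
    p = max(hits, 1) / n_reps
    return float(p), {"hits": hits, "n_reps": n_reps, "targets": targets}
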