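"""Synthetic admixed cohorts with known truth.

Generates phased cohorts that emulate the study design this package targets:
two strongly differentiated ancestral populations (a forest hunter-gatherer
"Pygmy-like" ancestry P and an agriculturalist "Bantu-like" ancestry B, plus
an optional East-African "Maasai-like" outgroup M for three-way branch-length
scans), admixed individuals whose genomes are mosaics of short ancestry
tracts, optional planted selective sweeps and ancestry-linked height QTLs,
and a height phenotype driven by sex and genome-wide ancestry.

Model summary
-------------
* Allele frequencies follow the Balding-Nichols construction: an ancestral
  frequency p ~ Uniform(0.05, 0.95) per SNP, and per-population frequencies
  Beta(p(1-F)/F, (1-p)(1-F)/F) for a drift parameter F per population.
* Haplotypes are founder mosaics: each population has a small pool of
  founder haplotypes (independent Bernoulli draws from the population
  frequencies) and every output haplotype copies from a randomly chosen
  founder, switching founders as a Poisson process along the genetic map.
  Shared founder segments are what create linkage disequilibrium and
  extended-haplotype structure.
* Admixed haplotypes additionally carry a two-state ancestry process:
  crossover events arrive as a Poisson process of rate g (generations since
  admixture onset) per Morgan and each event re-draws the ancestry as
  Bernoulli(pi_i), where pi_i is the individual's stationary Pygmy
  proportion drawn from a Beta distribution.  Tract boundaries are recorded
  at every crossover event, so the mean recorded tract length is 1/g Morgan.
* Height (cm) = mu + beta_sex * I[male] + beta_anc * P_i
  + sum_q gamma_q * (local P-ancestry dosage at QTL q) + N(0, sigma_e^2).

Everything is deterministic under a fixed :class:`SimConfig` seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

__all__ = [
    "SimConfig",
    "SimTruth",
    "HaplotypePanel",
    "simulate_frequencies",
    "simulate_cohort",
    "plant_sweep",
    "simulate_phenotype",
    "write_fixture_bundle",
    "genotypes_from_panel",
    "plant_missingness",
    "true_window_ancestry",
    "make_relatedness_cohort",
    "simulate_related_pairs",
]


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the synthetic admixed cohort.

    Defaults reproduce the study conditions the package is tested against:
    67 admixed Pygmy samples, 58 unadmixed Bantu samples, a 30-sample
    unadmixed Pygmy reference panel, g = 50 generations of admixture
    (~2 Mb tracts at 1 cM/Mb), and a phenotype in which sex and genome-wide
    ancestry explain roughly 0.42 and 0.32 of the height variance of the
    125-sample Pygmy+Bantu cohort.
    """

    n_snps: int = 4000
    chrom_length_bp: int = 40_000_000
    chrom: str = "1"
    n_admixed: int = 67
    n_bantu: int = 58
    n_pygmy_anc: int = 30
    n_maasai: int = 0
    fst_targets: dict = field(default_factory=lambda: {"P": 0.1, "B": 0.1, "M": 0.1})
    admix_generations: float = 50.0
    admix_beta: tuple = (6.5, 3.5)
    founder_pool_size: int = 50
    founder_switch_rate: float = 1.0  # per Morgan
    sweep_specs: list = field(default_factory=list)  # (pos_bp, population, carrier_fraction)
    qtl_specs: list = field(default_factory=list)    # (pos_bp, effect_cm_per_P_allele)
    mu_cm: float = 160.0
    beta_sex_cm: float = 11.0
    beta_anc_cm: float = -14.0
    sigma_e_cm: float = 4.3
    map_cM_per_Mb: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        if self.chrom_length_bp <= 0 or self.map_cM_per_Mb <= 0:
            raise ValueError("lengths and map rate must be positive")
        if self.admix_generations < 1:
            raise ValueError("admix_generations must be >= 1")
        if self.n_admixed + self.n_bantu + self.n_pygmy_anc + self.n_maasai <= 0:
            raise ValueError("at least one sample must be requested")
        if self.n_admixed > 0 and (self.n_bantu + self.n_pygmy_anc) == 0:
            raise ValueError("admixed samples need at least one ancestral panel")
        for pop, f in self.fst_targets.items():
            if not (0.0 < f < 1.0):
                raise ValueError(f"fst target for {pop!r} must be in (0,1)")
        a, b = self.admix_beta
        if a <= 0 or b <= 0:
            raise ValueError("admix_beta parameters must be positive")
        if self.founder_pool_size < 1:
            raise ValueError("founder_pool_size must be >= 1")
        for pos, _pop, cf in self.sweep_specs:
            if not (0.0 < cf <= 1.0):
                raise ValueError("carrier_fraction must be in (0,1]")
            if not (0 <= pos <= self.chrom_length_bp):
                raise ValueError("sweep position outside chromosome")

    @property
    def morgan_length(self) -> float:
        return self.chrom_length_bp * self.map_cM_per_Mb / 1e6 / 100.0

    def bp_per_morgan(self) -> float:
        return 1e8 / self.map_cM_per_Mb


@dataclass
class HaplotypePanel:
    """Phased haplotypes, two consecutive rows per sample."""

    haplotypes: np.ndarray            # (2 n_samples, n_snps) int8 in {0,1}
    sample_ids: list                  # length n_samples

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype rows must be 2 per sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def rows_for(self, sample_ids) -> np.ndarray:
        """Row indices of the haplotypes belonging to ``sample_ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = []
        for s in sample_ids:
            i = index[s]
            rows.extend((2 * i, 2 * i + 1))
        return np.asarray(rows, dtype=int)

    def for_samples(self, sample_ids) -> np.ndarray:
        return self.haplotypes[self.rows_for(sample_ids)]

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(self.haplotypes.copy(), list(self.sample_ids))


@dataclass
class SimTruth:
    """Generator ground truth: the acceptance surface for every downstream stage.

    ``tracts[sample_id]`` is a pair of per-haplotype tract lists, each tract a
    ``(start_bp, end_bp, ancestry)`` triple with ancestry in {'P','B','M'}.
    Tract boundaries sit at every recorded crossover event, so adjacent
    tracts may carry the same ancestry; :meth:`merged_blocks` merges them.
    """

    tracts: dict
    global_pygmy_fraction: pd.Series
    sweep_loci: list
    qtl_loci: list
    true_freqs: pd.DataFrame

    def ancestry_at(self, sample_id: str, pos_bp: float) -> tuple:
        out = []
        for hap_tracts in self.tracts[sample_id]:
            anc = None
            for start, end, a in hap_tracts:
                if start <= pos_bp < end or (pos_bp == end == hap_tracts[-1][1]):
                    anc = a
                    break
            out.append(anc)
        return tuple(out)

    def local_dosage(self, sample_id: str, pos_bp: float, ancestry: str = "P") -> int:
        return sum(a == ancestry for a in self.ancestry_at(sample_id, pos_bp))

    def merged_blocks(self, sample_id: str) -> list:
        """Per-haplotype ancestry blocks with adjacent same-ancestry tracts merged."""
        merged = []
        for hap_tracts in self.tracts[sample_id]:
            blocks = []
            for start, end, a in hap_tracts:
                if blocks and blocks[-1][2] == a:
                    blocks[-1] = (blocks[-1][0], end, a)
                else:
                    blocks.append((start, end, a))
            merged.append(blocks)
        return merged


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def simulate_frequencies(n_snps: int, fst_targets: dict, seed=None) -> pd.DataFrame:
    """Balding-Nichols per-population allele frequencies.

    Each SNP gets an ancestral alternate-allele frequency p ~ U(0.05, 0.95);
    each population's frequency is an independent
    Beta(p(1-F)/F, (1-p)(1-F)/F) draw around it, where F is that
    population's drift parameter.

    Returns a DataFrame with an ``ancestral`` column plus one column per
    population key in ``fst_targets``.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    for pop, f in fst_targets.items():
        if not (0.0 < f < 1.0):
            raise ValueError(f"fst target for {pop!r} must be in (0,1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = rng.uniform(0.05, 0.95, n_snps)
    out = {"ancestral": p}
    for pop in sorted(fst_targets):
        f = fst_targets[pop]
        scale = (1.0 - f) / f
        out[pop] = rng.beta(p * scale, (1.0 - p) * scale)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# haplotype machinery
# ---------------------------------------------------------------------------

def _poisson_positions(rate: float, length: float, rng) -> np.ndarray:
    k = rng.poisson(rate * length)
    return np.sort(rng.uniform(0.0, length, k))


def _founder_pools(freqs: pd.DataFrame, pops, pool_size: int, rng) -> dict:
    pools = {}
    for pop in pops:
        f = freqs[pop].to_numpy()
        pools[pop] = (rng.random((pool_size, f.size)) < f).astype(np.int8)
    return pools


def _mosaic_hap(founders: np.ndarray, mpos: np.ndarray, length_m: float,
                switch_rate: float, rng) -> np.ndarray:
    cuts = _poisson_positions(switch_rate, length_m, rng)
    choice = rng.integers(0, founders.shape[0], cuts.size + 1)
    seg = np.searchsorted(cuts, mpos, side="right")
    return founders[choice[seg], np.arange(mpos.size)]


def _admixed_hap(pools: dict, pi: float, g: float, switch_rate: float,
                 mpos: np.ndarray, length_m: float, bp_per_m: float, rng):
    """One admixed haplotype plus its truth tracts.

    Crossover events (rate g/Morgan) re-draw ancestry ~ Bernoulli(pi) and the
    copying template; founder-mosaic events (rate switch_rate/Morgan) re-draw
    the template only.
    """
    a_ev = _poisson_positions(g, length_m, rng)
    states = np.where(rng.random(a_ev.size + 1) < pi, "P", "B")
    s_ev = _poisson_positions(switch_rate, length_m, rng)
    all_ev = np.sort(np.concatenate([a_ev, s_ev]))
    bounds = np.concatenate([[0.0], all_ev, [length_m]])
    hap = np.empty(mpos.size, dtype=np.int8)
    n_founders = {anc: pools[anc].shape[0] for anc in pools}
    cols = np.arange(mpos.size)
    for i in range(bounds.size - 1):
        lo, hi = bounds[i], bounds[i + 1]
        anc = states[np.searchsorted(a_ev, lo, side="right")]
        j0, j1 = np.searchsorted(mpos, [lo, hi])
        if j1 > j0:
            founder = rng.integers(0, n_founders[anc])
            hap[j0:j1] = pools[anc][founder, cols[j0:j1]]
        else:
            rng.integers(0, n_founders[anc])  # keep stream aligned regardless of SNP content
    tract_bounds = np.concatenate([[0.0], a_ev, [length_m]]) * bp_per_m
    tracts = [
        (float(tract_bounds[i]), float(tract_bounds[i + 1]), str(states[i]))
        for i in range(states.size)
    ]
    return hap, tracts


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig):
    """Simulate the full cohort.

    Returns ``(panel, variant_table, sample_table, truth)`` where the sample
    table carries population labels ``pygmy`` (admixed cohort), ``bantu``
    (unadmixed agriculturalist samples), ``pygmy_anc`` (unadmixed reference
    panel) and ``maasai`` (outgroup), sex, simulated height in cm, and the
    true global Pygmy proportion.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    pos = np.sort(rng.choice(config.chrom_length_bp, size=config.n_snps, replace=False)) + 1
    cm = pos * config.map_cM_per_Mb / 1e6
    mpos = cm / 100.0
    length_m = config.morgan_length
    bp_per_m = config.bp_per_morgan()

    ref_idx = rng.integers(0, 4, config.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, config.n_snps)) % 4

    pops = ["P", "B"] + (["M"] if config.n_maasai > 0 else [])
    freqs = simulate_frequencies(config.n_snps, {p: config.fst_targets[p] for p in pops}, rng)
    pools = _founder_pools(freqs, pops, config.founder_pool_size, rng)

    sample_ids, populations, hap_rows = [], [], []
    tracts = {}
    chrom_bp = float(config.chrom_length_bp)

    def add_unadmixed(n, prefix, pop_label, anc):
        for i in range(n):
            sid = f"{prefix}{i + 1:03d}"
            sample_ids.append(sid)
            populations.append(pop_label)
            t = []
            for _ in range(2):
                hap_rows.append(_mosaic_hap(pools[anc], mpos, length_m,
                                            config.founder_switch_rate, rng))
                t.append([(0.0, chrom_bp, anc)])
            tracts[sid] = t

    a, b = config.admix_beta
    pi_all = rng.beta(a, b, config.n_admixed)
    for i in range(config.n_admixed):
        sid = f"PYG{i + 1:03d}"
        sample_ids.append(sid)
        populations.append("pygmy")
        t = []
        for _ in range(2):
            hap, tr = _admixed_hap({k: pools[k] for k in ("P", "B")}, pi_all[i],
                                   config.admix_generations, config.founder_switch_rate,
                                   mpos, length_m, bp_per_m, rng)
            hap_rows.append(hap)
            t.append(tr)
        tracts[sid] = t

    add_unadmixed(config.n_bantu, "BAN", "bantu", "B")
    add_unadmixed(config.n_pygmy_anc, "ANC", "pygmy_anc", "P")
    if config.n_maasai > 0:
        add_unadmixed(config.n_maasai, "MAA", "maasai", "M")

    panel = HaplotypePanel(np.vstack(hap_rows), sample_ids)

    variant_table = pd.DataFrame({
        "snp_id": [f"snp{i + 1:06d}" for i in range(config.n_snps)],
        "chrom": config.chrom,
        "pos_bp": pos.astype(np.int64),
        "ref": _BASES[ref_idx],
        "alt": _BASES[alt_idx],
        "cM": cm,
        "ancestral_state": "ref",
    })

    frac = pd.Series(
        {sid: _pygmy_fraction(tracts[sid], chrom_bp) for sid in sample_ids},
        name="pygmy_fraction",
    )

    truth = SimTruth(
        tracts=tracts,
        global_pygmy_fraction=frac.loc[sample_ids],
        sweep_loci=[],
        qtl_loci=[pos_bp for pos_bp, _ in config.qtl_specs],
        true_freqs=freqs,
    )

    sample_table = pd.DataFrame({
        "sample_id": sample_ids,
        "population": populations,
        "sex": np.where(rng.random(len(sample_ids)) < 0.5, "M", "F"),
        "pygmy_fraction": frac.loc[sample_ids].to_numpy(),
    })

    for pos_bp, pop_label, cf in config.sweep_specs:
        panel, core = plant_sweep(panel, variant_table, sample_table, pos_bp,
                                  pop_label, cf, seed=rng)
        truth.sweep_loci.append(int(variant_table["pos_bp"].iloc[core]))

    sample_table["height_cm"] = simulate_phenotype(sample_table, truth, config, seed=rng)
    return panel, variant_table, sample_table, truth


def _pygmy_fraction(sample_tracts, chrom_bp: float) -> float:
    total = 0.0
    for hap_tracts in sample_tracts:
        for start, end, anc in hap_tracts:
            if anc == "P":
                total += end - start
    return total / (2.0 * chrom_bp)


def genotypes_from_panel(panel: HaplotypePanel) -> np.ndarray:
    """Diploid dosage matrix (samples x SNPs) from a phased panel."""
    h = panel.haplotypes
    return (h[0::2].astype(np.int16) + h[1::2].astype(np.int16))


def plant_missingness(genotypes: np.ndarray, snp_indices, fraction: float, seed=None) -> np.ndarray:
    """Set a ``fraction`` of samples to missing (-1) at the given SNPs."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = genotypes.copy()
    n = g.shape[0]
    k = int(np.ceil(fraction * n))
    for j in snp_indices:
        rows = rng.choice(n, size=k, replace=False)
        g[rows, j] = -1
    return g


# ---------------------------------------------------------------------------
# sweeps and phenotype
# ---------------------------------------------------------------------------

def plant_sweep(panel: HaplotypePanel, variant_table: pd.DataFrame,
                sample_table: pd.DataFrame, position_bp: int, population: str,
                carrier_fraction: float, core_width_morgan: float = 0.005,
                seed=None):
    """Plant a partial sweep: a carrier fraction of one population's
    haplotypes is overwritten with a single sweep haplotype carrying the
    derived (alt) core allele across the core window.

    The core SNP is the nearest SNP to ``position_bp`` whose pre-sweep
    derived (alt) frequency in the target population is at most 0.5 — a
    sweep lifts a low-to-moderate-frequency derived allele — falling back
    to the nearest SNP outright if none qualifies within 250 kb.

    Returns ``(new_panel, core_snp_index)``; other populations untouched.
    """
    if not (0.0 < carrier_fraction <= 1.0):
        raise ValueError("carrier_fraction must be in (0,1]")
    pos = variant_table["pos_bp"].to_numpy()
    if not (pos[0] <= position_bp <= pos[-1]):
        raise ValueError("sweep position outside the genotyped chromosome")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    ids_target = sample_table.loc[sample_table["population"] == population, "sample_id"]
    target_rows = panel.rows_for(ids_target)
    if target_rows.size:
        freq = panel.haplotypes[target_rows].mean(axis=0)
        cand = np.flatnonzero((np.abs(pos - position_bp) <= 250_000) & (freq <= 0.5))
    else:
        cand = np.array([], dtype=int)
    if cand.size:
        core = int(cand[np.argmin(np.abs(pos[cand] - position_bp))])
    else:
        core = int(np.argmin(np.abs(pos - position_bp)))
    mpos = variant_table["cM"].to_numpy() / 100.0
    lo_m = mpos[core] - core_width_morgan / 2.0
    hi_m = mpos[core] + core_width_morgan / 2.0
    if lo_m < mpos[0] or hi_m > mpos[-1]:
        warnings.warn("sweep window extends past chromosome end; truncated")
    j0, j1 = np.searchsorted(mpos, [lo_m, hi_m])
    j1 = min(j1 + 1, pos.size)

    ids = sample_table.loc[sample_table["population"] == population, "sample_id"]
    rows = panel.rows_for(ids)
    if rows.size == 0:
        raise ValueError(f"no samples in population {population!r}")

    new = panel.copy()
    template_row = rows[rng.integers(0, rows.size)]
    template = new.haplotypes[template_row, j0:j1].copy()
    template[core - j0] = 1  # derived core allele
    n_carriers = max(1, int(round(carrier_fraction * rows.size)))
    carriers = rng.choice(rows, size=n_carriers, replace=False)
    new.haplotypes[carriers, j0:j1] = template
    return new, core


def simulate_phenotype(sample_table: pd.DataFrame, truth: SimTruth,
                       config: SimConfig, seed=None) -> np.ndarray:
    """Heights in cm from sex, global ancestry, QTL dosages and noise."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    frac = truth.global_pygmy_fraction
    missing = [s for s in sample_table["sample_id"] if s not in frac.index]
    if missing:
        raise ValueError(f"samples without global ancestry: {missing[:5]}")
    p = frac.loc[sample_table["sample_id"]].to_numpy(dtype=float)
    male = (sample_table["sex"] == "M").to_numpy()
    y = config.mu_cm + config.beta_sex_cm * male + config.beta_anc_cm * p
    for pos_bp, gamma in config.qtl_specs:
        dose = np.array([truth.local_dosage(s, pos_bp) for s in sample_table["sample_id"]],
                        dtype=float)
        y = y + gamma * dose
    if config.sigma_e_cm > 0:
        y = y + rng.normal(0.0, config.sigma_e_cm, y.size)
    return y


# ---------------------------------------------------------------------------
# truth helpers for window-level evaluation
# ---------------------------------------------------------------------------

def true_window_ancestry(truth: SimTruth, windows: pd.DataFrame, sample_ids) -> np.ndarray:
    """Ancestry label at each window midpoint, per haplotype.

    Returns an array of shape ``(2 * len(sample_ids), n_windows)`` of
    'P'/'B'/'M' labels ordered as (sample0 hap0, sample0 hap1, ...).
    """
    mids = ((windows["start_bp"] + windows["end_bp"]) / 2.0).to_numpy()
    out = np.empty((2 * len(sample_ids), len(mids)), dtype="U1")
    for i, sid in enumerate(sample_ids):
        for h in range(2):
            hap_tracts = truth.tracts[sid][h]
            starts = np.array([t[0] for t in hap_tracts])
            labels = np.array([t[2] for t in hap_tracts])
            idx = np.clip(np.searchsorted(starts, mids, side="right") - 1, 0, len(labels) - 1)
            out[2 * i + h] = labels[idx]
    return out


# ---------------------------------------------------------------------------
# relatedness cohorts (gene dropping at unlinked SNPs)
# ---------------------------------------------------------------------------

def _hwe_haplotypes(freqs: np.ndarray, n: int, rng) -> np.ndarray:
    return (rng.random((n, freqs.size)) < freqs).astype(np.int8)


def _offspring(hapA, hapB, rng) -> np.ndarray:
    """One gamete from each parent's pair of haplotype rows (unlinked SNPs)."""
    m = hapA.shape[1]
    ga = np.where(rng.random(m) < 0.5, hapA[0], hapA[1])
    gb = np.where(rng.random(m) < 0.5, hapB[0], hapB[1])
    return np.stack([ga, gb]).astype(np.int8)


def make_relatedness_cohort(n_unrelated: int = 125, n_relatives: int = 7,
                            n_snps: int = 20_000, seed: int = 0):
    """Cohort of ``n_unrelated + n_relatives`` diploids at unlinked HWE SNPs.

    The first ``n_unrelated`` samples are mutually unrelated; each of the
    ``n_relatives`` extra samples is a first-degree relative (offspring with
    an unsampled mate) of one distinct unrelated sample, so planted pairs
    are disjoint.  Returns ``(genotypes, sample_ids, freqs, planted_pairs)``.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.05, 0.95, n_snps)
    haps = [_hwe_haplotypes(freqs, 2, rng) for _ in range(n_unrelated)]
    ids = [f"S{i + 1:04d}" for i in range(n_unrelated)]
    pairs = []
    for j in range(n_relatives):
        mate = _hwe_haplotypes(freqs, 2, rng)
        child = _offspring(haps[j], mate, rng)
        haps.append(child)
        rid = f"R{j + 1:04d}"
        ids.append(rid)
        pairs.append((ids[j], rid))
    geno = np.stack([h.sum(axis=0) for h in haps]).astype(np.int16)
    return geno, ids, freqs, pairs


def simulate_related_pairs(relationship: str, n_pairs: int, n_snps: int = 20_000,
                           seed: int = 0):
    """Gene-dropped pairs of a given relationship at unlinked HWE SNPs.

    ``relationship`` is one of 'unrelated', 'parent_offspring', 'full_sib',
    'half_sib', 'grandparent_grandchild', 'duplicate'.  Returns
    ``(genotypes, sample_ids, freqs, pair_list)`` where the cohort holds the
    2 * n_pairs pair members in order.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.05, 0.95, n_snps)
    genos, ids, pairs = [], [], []
    for k in range(n_pairs):
        a = _hwe_haplotypes(freqs, 2, rng)
        if relationship == "unrelated":
            b = _hwe_haplotypes(freqs, 2, rng)
        elif relationship == "duplicate":
            b = a
        elif relationship == "parent_offspring":
            b = _offspring(a, _hwe_haplotypes(freqs, 2, rng), rng)
        elif relationship == "full_sib":
            m = _hwe_haplotypes(freqs, 2, rng)
            a2 = _hwe_haplotypes(freqs, 2, rng)
            a, b = _offspring(a2, m, rng), _offspring(a2, m, rng)
        elif relationship == "half_sib":
            shared = _hwe_haplotypes(freqs, 2, rng)
            a = _offspring(shared, _hwe_haplotypes(freqs, 2, rng), rng)
            b = _offspring(shared, _hwe_haplotypes(freqs, 2, rng), rng)
        elif relationship == "grandparent_grandchild":
            child = _offspring(a, _hwe_haplotypes(freqs, 2, rng), rng)
            b = _offspring(child, _hwe_haplotypes(freqs, 2, rng), rng)
        else:
            raise ValueError(f"unknown relationship {relationship!r}")
        for tag, h in (("a", a), ("b", b)):
            genos.append(h.sum(axis=0))
            ids.append(f"{relationship[:2].upper()}{k + 1:04d}{tag}")
        pairs.append((ids[-2], ids[-1]))
    return np.stack(genos).astype(np.int16), ids, freqs, pairs


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(directory, panel: HaplotypePanel, variant_table: pd.DataFrame,
                         sample_table: pd.DataFrame, truth: SimTruth,
                         gene_spacing_bp: int = 200_000, gene_length_bp: int = 100_000,
                         n_pathways: int = 20, pathway_seed: int = 0,
                         chrom_length_bp: int | None = None) -> dict:
    """Write the cohort as a plain-text file bundle.

    Produces a phased VCF, sample/phenotype TSV, genetic-map TSV, truth
    TSVs, a gene BED (genes tiled every ``gene_spacing_bp``), a GMT with
    ``n_pathways`` pathways (two of them enriched for genes near the planted
    QTL/sweep loci), and an outgroup-allele TSV consistent with the
    generator's ancestral states.  Byte-identical for identical inputs.
    """
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}

    vt = variant_table.reset_index(drop=True)
    if chrom_length_bp is None:
        chrom_length_bp = int(vt["pos_bp"].max()) + gene_spacing_bp

    # --- phased VCF ---
    vcf = d / "cohort.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={vt['chrom'].iloc[0]},length={chrom_length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        h = panel.haplotypes
        for j in range(len(vt)):
            gts = "\t".join(f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(panel.n_samples))
            row = vt.iloc[j]
            fh.write(f"{row['chrom']}\t{row['pos_bp']}\t{row['snp_id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")
    paths["vcf"] = vcf

    samples = d / "samples.tsv"
    cols = ["sample_id", "population", "sex"]
    if "height_cm" in sample_table:
        cols.append("height_cm")
    sample_table[cols].to_csv(samples, sep="\t", index=False, float_format="%.4f")
    paths["samples"] = samples

    gmap = d / "genetic_map.tsv"
    vt[["chrom", "pos_bp", "cM"]].to_csv(gmap, sep="\t", index=False, float_format="%.6f")
    paths["map"] = gmap

    tracts_path = d / "truth_tracts.tsv"
    with open(tracts_path, "w") as fh:
        fh.write("sample_id\thaplotype\tstart_bp\tend_bp\tancestry\n")
        for sid in panel.sample_ids:
            for hidx, hap_tracts in enumerate(truth.tracts[sid]):
                for start, end, anc in hap_tracts:
                    fh.write(f"{sid}\t{hidx}\t{start:.1f}\t{end:.1f}\t{anc}\n")
    paths["tracts"] = tracts_path

    ganc = d / "truth_global_ancestry.tsv"
    truth.global_pygmy_fraction.rename("pygmy_fraction").to_csv(
        ganc, sep="\t", index_label="sample_id", float_format="%.6f")
    paths["global_ancestry"] = ganc

    loci = d / "truth_loci.tsv"
    with open(loci, "w") as fh:
        fh.write("kind\tpos_bp\n")
        for p in truth.sweep_loci:
            fh.write(f"sweep\t{p}\n")
        for p in truth.qtl_loci:
            fh.write(f"qtl\t{p}\n")
    paths["loci"] = loci

    # --- genes tiled along the chromosome (BED: 0-based half-open) ---
    chrom = str(vt["chrom"].iloc[0])
    starts = np.arange(0, chrom_length_bp - gene_length_bp, gene_spacing_bp, dtype=np.int64)
    genes = [f"GENE{i + 1:04d}" for i in range(starts.size)]
    bed = d / "genes.bed"
    with open(bed, "w") as fh:
        for g, s in zip(genes, starts):
            fh.write(f"{chrom}\t{s}\t{s + gene_length_bp}\t{g}\t0\t+\n")
    paths["genes"] = bed

    # --- GMT: random pathways plus two enriched near planted loci ---
    rng = np.random.default_rng(pathway_seed)
    target_loci = list(truth.qtl_loci) or list(truth.sweep_loci)
    near = set()
    for p in target_loci:
        for g, s in zip(genes, starts):
            if s - 300_000 <= p <= s + gene_length_bp + 300_000:
                near.add(g)
    if not near:
        near = set(genes[:4])
    near = sorted(near)
    gmt = d / "pathways.gmt"
    with open(gmt, "w") as fh:
        for k in range(n_pathways):
            if k < 2:
                extra = [g for g in genes if g not in near]
                pick = sorted(near + [extra[i] for i in
                                      rng.choice(len(extra), size=3, replace=False)])
                name = f"ENRICHED_PATHWAY_{k + 1}"
            else:
                size = int(rng.integers(8, 25))
                pick = sorted(np.array(genes)[rng.choice(len(genes), size=size, replace=False)])
                name = f"PATHWAY_{k + 1:02d}"
            fh.write(name + "\tsynthetic pathway\t" + "\t".join(pick) + "\n")
    paths["gmt"] = gmt

    # --- outgroup alleles (priority chimp > orang > macaque), ~5% unassignable ---
    og = d / "outgroups.tsv"
    u = rng.random(len(vt))
    with open(og, "w") as fh:
        fh.write("snp_id\tchimp\torang\tmacaque\n")
        for j, row in vt.iterrows():
            anc = row["ref"] if row["ancestral_state"] == "ref" else row["alt"]
            if u[j] < 0.90:
                fh.write(f"{row['snp_id']}\t{anc}\t{anc}\t{anc}\n")
            elif u[j] < 0.95:
                fh.write(f"{row['snp_id']}\t.\t{anc}\t.\n")
            else:
                fh.write(f"{row['snp_id']}\t.\t.\t.\n")
    paths["outgroups"] = og

    logger.info("fixture bundle written to %s (%d files)", d, len(paths))
    return paths
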