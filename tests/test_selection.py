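"""Selection scans against independent oracles, plus tail/cluster machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_

from admixscan import selection as sel, synthetic_data as sd


# ---------------------------------------------------------------------------
# independent oracles (scalar, straight from the published algebra)
# ---------------------------------------------------------------------------

def wc_theta_oracle(gA, gB):
    """Scalar Weir-Cockerham theta for one SNP, coded independently."""
    def summarize(g):
        g = [x for x in g if x >= 0]
        n = len(g)
        p = sum(g) / (2 * n)
        h = sum(1 for x in g if x == 1) / n
        return n, p, h
    n1, p1, h1 = summarize(gA)
    n2, p2, h2 = summarize(gB)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    if a + b + c == 0:
        return None
    return a / (a + b + c)


def ehh_oracle(haps, core, allele, marker_order):
    """Pair-counting EHH: enumerate all carrier pairs explicitly."""
    carriers = [h for h in haps if h[core] == allele]
    n = len(carriers)
    out = []
    for stop in range(1, len(marker_order) + 1):
        js = marker_order[:stop]
        same = sum(1 for i in range(n) for k in range(i + 1, n)
                   if all(carriers[i][j] == carriers[k][j] for j in js))
        out.append(same / (n * (n - 1) / 2))
    return out


def tajima_oracle(n, S, pi_total):
    """Tajima's D from the published constants, term by term."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def binom_tail_oracle(k, n, p):
    """Direct upper-tail summation of the binomial pmf."""
    return sum(math.comb(n, j) * p ** j * (1 - p) ** (n - j)
               for j in range(k, n + 1))


# ---------------------------------------------------------------------------
# F_ST / LSBL
# ---------------------------------------------------------------------------

class TestFst:
    def test_equal_frequencies_clamped_to_zero(self):
        g = np.array([[0], [1], [2], [1]], dtype=np.int16)
        theta, defined = sel.weir_cockerham_theta(g, g.copy())
        assert defined[0] and theta[0] == 0.0

    def test_fixed_difference_is_one(self):
        theta, _ = sel.weir_cockerham_theta(np.full((50, 1), 2, dtype=np.int16),
                                            np.zeros((50, 1), dtype=np.int16))
        assert theta[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_oracle_on_random_configurations(self):
        rng = np.random.default_rng(12)
        mismatches = 0
        for _ in range(1000):
            nA, nB = rng.integers(2, 21, 2)
            gA = rng.integers(0, 3, nA).astype(np.int16)
            gB = rng.integers(0, 3, nB).astype(np.int16)
            theta, defined = sel.weir_cockerham_theta(gA[:, None], gB[:, None],
                                                      clamp=False)
            expect = wc_theta_oracle(gA.tolist(), gB.tolist())
            if expect is None:
                assert not defined[0]
            else:
                assert theta[0] == pytest.approx(expect, abs=1e-12)
        assert mismatches == 0

    def test_population_fully_missing_undefined(self):
        gA = np.full((5, 1), sel.np.int16(-1))
        gB = np.array([[0], [1], [2]], dtype=np.int16)
        _, defined = sel.weir_cockerham_theta(gA, gB)
        assert not defined[0]


class TestLsbl:
    def test_star_symmetry(self):
        d = np.array([0.3, 0.1])
        assert np.allclose(sel.lsbl_scan(d, d, d), d / 2)

    def test_forced_arithmetic(self):
        assert sel.lsbl_scan([0.3], [0.25], [0.15])[0] == pytest.approx(0.2)

    def test_additivity_identity_preclamp(self):
        rng = np.random.default_rng(3)
        ab, ac, bc = rng.uniform(0, 0.6, (3, 200))
        la = sel.lsbl_scan(ab, ac, bc, clamp=False)
        lb = sel.lsbl_scan(ab, bc, ac, clamp=False)
        assert np.allclose(la + lb, ab, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sel.lsbl_scan([0.1], [0.1, 0.2], [0.1])


# ---------------------------------------------------------------------------
# tails, blocks, bins
# ---------------------------------------------------------------------------

class TestEmpiricalHighSet:
    def test_strict_tail_on_integers(self):
        thr, flags = sel.empirical_high_set(np.arange(1, 1001, dtype=float), 0.001)
        assert flags.sum() == 1 and flags[-1]

    def test_half_tail(self):
        rng = np.random.default_rng(0)
        _, flags = sel.empirical_high_set(rng.normal(size=10_001), 0.5)
        assert flags.mean() == pytest.approx(0.5, abs=0.02)

    def test_identical_values_warn_empty(self):
        with pytest.warns(UserWarning):
            _, flags = sel.empirical_high_set(np.ones(2000), 0.001)
        assert flags.sum() == 0

    def test_flag_fraction_calibrated_on_fst_scan(self, cohort):
        from conftest import pop_haplotypes
        gA = pop_haplotypes(cohort, "pygmy_anc")
        gB = pop_haplotypes(cohort, "bantu")
        gA = gA[0::2] + gA[1::2]
        gB = gB[0::2] + gB[1::2]
        scan = sel.fst_scan(gA.astype(np.int16), gB.astype(np.int16),
                            cohort["variants"])
        frac = scan.high.sum() / scan.defined.sum()
        assert 0.0008 <= frac <= 0.0012


class TestBlocks:
    def test_single_block_span(self):
        blocks = sel.detect_blocks([1_000_000, 1_050_000, 1_090_000, 1_150_000])
        assert len(blocks) == 1
        assert blocks.loc[0, "length_bp"] == 150_000
        assert blocks.loc[0, "n_high_snps"] == 4

    def test_three_snps_no_block(self):
        assert sel.detect_blocks([1_000_000, 1_050_000, 1_090_000]).empty

    def test_exact_gap_breaks_run(self):
        pos = [1_000_000, 1_100_000, 1_150_000, 1_200_000, 1_250_000]
        blocks = sel.detect_blocks(pos)     # first gap is exactly 100 kb
        assert len(blocks) == 1 and blocks.loc[0, "start_bp"] == 1_100_000

    def test_input_order_invariant(self):
        rng = np.random.default_rng(1)
        pos = rng.choice(10_000_000, 200, replace=False)
        a = sel.detect_blocks(pos)
        b = sel.detect_blocks(rng.permutation(pos))
        pd.testing.assert_frame_equal(a, b)


class TestBinEnrichment:
    def test_zero_high_gives_unit_pvalue(self):
        assert sel.binomial_upper_tail(0, 500, 0.001) == 1.0

    def test_headline_bins_below_1e12(self):
        # the two most extreme 500-SNP bins of the genome-wide scans
        assert sel.binomial_upper_tail(83, 500, 947 / 960_497) < 1e-12
        assert sel.binomial_upper_tail(92, 500, 912 / 960_497) < 1e-12

    def test_matches_direct_summation(self):
        assert sel.binomial_upper_tail(2, 500, 0.001) == pytest.approx(
            binom_tail_oracle(2, 500, 0.001), abs=1e-12)

    def test_bins_never_span_chromosomes(self):
        vt = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(25)],
            "chrom": ["1"] * 13 + ["2"] * 12,
            "pos_bp": list(range(1, 14)) + list(range(1, 13)),
        })
        high = np.zeros(25, dtype=bool)
        high[:5] = True
        bins = sel.bin_binomial_enrichment(vt, high, bin_size=10)
        assert len(bins) == 2               # 13//10 + 12//10
        assert bins.loc[0, "k_high"] == 5


class TestAncestralStates:
    @pytest.mark.parametrize("chimp,orang,macaque,expect", [
        ("A", "G", "G", "ref"),            # chimp has priority
        (".", "G", "A", "alt"),            # fall through to orang
        (".", ".", "A", "ref"),            # fall through to macaque, matches ref
    ])
    def test_priority_rules(self, chimp, orang, macaque, expect):
        vt = pd.DataFrame({"snp_id": ["s1"], "chrom": "1", "pos_bp": [100],
                           "ref": ["A"], "alt": ["G"]})
        og = pd.DataFrame({"snp_id": ["s1"], "chimp": [chimp],
                           "orang": [orang], "macaque": [macaque]})
        out = sel.assign_ancestral_states(vt, og)
        assert out.loc[0, "ancestral_state"] == expect

    def test_unmatched_outgroup_is_unknown(self):
        vt = pd.DataFrame({"snp_id": ["s1"], "chrom": "1", "pos_bp": [100],
                           "ref": ["A"], "alt": ["G"]})
        og = pd.DataFrame({"snp_id": ["s1"], "chimp": ["T"],
                           "orang": ["C"], "macaque": ["."]})
        out = sel.assign_ancestral_states(vt, og)
        assert out.loc[0, "ancestral_state"] == "unknown"


# ---------------------------------------------------------------------------
# EHH / iHS / XP-EHH
# ---------------------------------------------------------------------------

class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        haps = np.tile(np.array([1, 0, 1, 1, 0], dtype=np.int8), (6, 1))
        dist, ehh = sel.ehh_curve(haps, 2, 1, "right")
        assert np.allclose(ehh, 1.0)

    def test_all_distinct_drops_to_zero(self):
        haps = np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=np.int8)
        _, ehh = sel.ehh_curve(haps, 0, 1, "right")
        assert ehh[-1] == 0.0

    def test_six_haplotype_toy_matches_pair_counting(self):
        rng = np.random.default_rng(8)
        haps = rng.integers(0, 2, (6, 9)).astype(np.int8)
        haps[:, 4] = [1, 1, 1, 0, 1, 0]
        for direction, order in (("right", [5, 6, 7, 8]), ("left", [3, 2, 1, 0])):
            got = sel.ehh_curve(haps, 4, 1, direction)[1]
            expect = ehh_oracle(haps.tolist(), 4, 1, order)
            assert np.allclose(got[1:], expect, atol=1e-15)

    def test_fewer_than_two_carriers_undefined(self):
        haps = np.zeros((4, 3), dtype=np.int8)
        haps[0, 1] = 1
        assert sel.ehh_curve(haps, 1, 1, "right") is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st_.integers(0, 2**31 - 1))
    def test_curves_monotone_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, (12, 15)).astype(np.int8)
        core = 7
        for allele in (0, 1):
            if (haps[:, core] == allele).sum() < 2:
                continue
            for direction in ("left", "right"):
                _, ehh = sel.ehh_curve(haps, core, allele, direction)
                assert np.all(np.diff(ehh) <= 1e-12)


class TestIhs:
    def test_bin_standardization_moments(self, ihs_bantu):
        # within every derived-frequency standardization bin the scores
        # have ~zero mean and ~unit SD
        scan = ihs_bantu
        ok = scan["std"].notna()
        checked = 0
        for b, s in scan.loc[ok].groupby("std_bin")["std"]:
            assert abs(s.mean()) < 0.05
            assert abs(s.std(ddof=0) - 1) < 0.05
            checked += 1
        assert checked >= 5

    def test_symmetric_panel_gives_zero_score(self):
        rng = np.random.default_rng(4)
        h = rng.integers(0, 2, (10, 41)).astype(np.int8)
        haps = np.vstack([h, 1 - h])        # ancestral/derived mirror images
        vt = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(41)], "chrom": "1",
            "pos_bp": np.arange(41) * 10_000 + 1,
            "cM": np.arange(41) * 0.01, "ancestral_state": "ref",
        })
        scan = sel.ihs_scan(haps, vt, min_bin=1)
        core = 20
        if np.isfinite(scan.loc[core, "raw"]):
            assert scan.loc[core, "raw"] == pytest.approx(0.0, abs=1e-12)

    def test_null_tail_fraction_normal(self, ihs_bantu):
        s = ihs_bantu["std"].dropna()
        frac = (s.abs() > 2).mean()
        assert 0.04 <= frac <= 0.06


class TestXpehh:
    def test_identical_panels_give_zero(self, cohort):
        from conftest import pop_haplotypes
        haps = pop_haplotypes(cohort, "bantu")[:40, :600]
        vt = cohort["variants"].iloc[:600]
        scan = sel.xpehh_scan(haps, haps.copy(), vt)
        raw = scan["raw"].dropna()
        assert len(raw) > 0 and np.allclose(raw, 0.0, atol=1e-12)

    def test_genomewide_standardization_exact(self, xpehh_fixture):
        s = xpehh_fixture["std"].dropna()
        assert abs(s.mean()) < 1e-8
        assert abs(s.std(ddof=0) - 1) < 1e-8

    def test_sweep_in_panel_a_detected(self):
        # a partial sweep planted in one population reaches the extreme
        # tail of both haplotype scans (single replicate; the acceptance
        # suite repeats this over 20 seeds)
        cfg = sd.SimConfig(seed=301, n_snps=1500, chrom_length_bp=15_000_000,
                           n_admixed=0, n_bantu=40, n_pygmy_anc=40,
                           sweep_specs=[(7_500_000, "pygmy_anc", 0.8)])
        panel, vt, st, truth = sd.simulate_cohort(cfg)
        core_pos = truth.sweep_loci[0]
        hapsP = panel.haplotypes[panel.rows_for(
            st.loc[st.population == "pygmy_anc", "sample_id"])]
        hapsB = panel.haplotypes[panel.rows_for(
            st.loc[st.population == "bantu", "sample_id"])]
        near = lambda scan: np.abs(scan.pos_bp.to_numpy() - core_pos) <= 300_000
        ihs = sel.ihs_scan(hapsP, vt)
        assert ihs.high.to_numpy()[near(ihs)].any()
        xp = sel.xpehh_scan(hapsP, hapsB, vt)
        assert xp.high.to_numpy()[near(xp)].any()
        assert xp.loc[xp.pos_bp == core_pos, "std"].iloc[0] > 0


# ---------------------------------------------------------------------------
# sequence diversity
# ---------------------------------------------------------------------------

class TestSeqDiversity:
    def test_identical_sequences(self):
        d = sel.seq_diversity(["ACGTACGTAC"] * 4)
        assert d.pi_per_site == 0 and d.segregating_sites == 0
        assert not d.d_defined

    def test_two_sequences_direct_count(self):
        d = sel.seq_diversity(["A" * 100, "A" * 98 + "CC"])
        assert d.pi_per_site == pytest.approx(0.02)

    def test_toy_matches_constants_oracle(self):
        seqs = ["ACGTACGTAC", "ACGTACGTAA", "ACGAACGTAC", "ACGAACGCAC"]
        d = sel.seq_diversity(seqs)
        assert d.segregating_sites == 3
        pi_total = d.pi_per_site * d.n_sites
        assert d.tajimas_d == pytest.approx(tajima_oracle(4, 3, pi_total),
                                            abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sel.seq_diversity(["ACGT", "ACG"])


# ---------------------------------------------------------------------------
# haplotype template matching
# ---------------------------------------------------------------------------

def template_match_oracle(win, fpos):
    """Independent reimplementation of the outward matching procedure."""
    keys = ["".join(map(str, r)) for r in win]
    order, counts = {}, {}
    for i, k in enumerate(keys):
        counts[k] = counts.get(k, 0) + 1
        order.setdefault(k, i)
    ranked = sorted(counts, key=lambda k: (-counts[k], order[k]))[:10]
    templates = [list(map(int, k)) for k in ranked]
    out = []
    for h in win:
        live = [t for t in range(len(templates)) if templates[t][fpos] == h[fpos]]
        left = right = 0
        lopen = ropen = True
        li, ri = fpos - 1, fpos + 1
        while (lopen and li >= 0) or (ropen and ri < len(h)):
            if lopen and li >= 0:
                nxt = [t for t in live if templates[t][li] == h[li]]
                if nxt:
                    live, left, li = nxt, left + 1, li - 1
                else:
                    lopen = False
            if ropen and ri < len(h):
                nxt = [t for t in live if templates[t][ri] == h[ri]]
                if nxt:
                    live, right, ri = nxt, right + 1, ri + 1
                else:
                    ropen = False
        rank = live[0] + 1 if live else 0
        out.append((rank, left, right))
    return out


class TestTemplateMatch:
    def test_single_repeated_haplotype(self):
        haps = np.tile(np.array([1, 0, 1, 0, 1], dtype=np.int8), (8, 1))
        haps[:, 2] = [1, 1, 1, 1, 0, 0, 0, 0]      # keep focal polymorphic
        res = sel.haplotype_template_match(haps, 2, 2, maf_min=0.0)
        assert (res.template_rank > 0).all()
        assert ((res.left_extent == 2) & (res.right_extent == 2)).all()

    def test_exact_template_match_keeps_rank(self):
        rng = np.random.default_rng(9)
        haps = rng.integers(0, 2, (30, 11)).astype(np.int8)
        res = sel.haplotype_template_match(haps, 5, 5, maf_min=0.0)
        oracle = template_match_oracle(haps.tolist(), 5)
        got = list(zip(res.template_rank, res.left_extent, res.right_extent))
        assert got == oracle

    def test_eight_haplotype_toy_matches_oracle(self):
        rng = np.random.default_rng(10)
        haps = rng.integers(0, 2, (8, 7)).astype(np.int8)
        res = sel.haplotype_template_match(haps, 3, 3, maf_min=0.0)
        oracle = template_match_oracle(haps.tolist(), 3)
        got = list(zip(res.template_rank, res.left_extent, res.right_extent))
        assert got == oracle
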