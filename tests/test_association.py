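"""Mixed-model association: REML, GLS scans, admixture mapping, FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as ss

from admixscan import association as assoc, local_ancestry as la, \
    synthetic_data as sd


def _null_phenotype(sub, seed, beta_anc=-14.0, sigma=4.3):
    """Structured phenotype with no marker effect: ancestry plus noise."""
    rng = np.random.default_rng(seed)
    return beta_anc * sub.pygmy_fraction.to_numpy() + rng.normal(0, sigma, len(sub))


@pytest.fixture(scope="module")
def cohort_assoc(cohort, pygmy_bantu_geno, kinship):
    st = cohort["samples"]
    sub = st[st.population.isin(["pygmy", "bantu"])].reset_index(drop=True)
    K, ids = kinship
    X = (sub.sex == "M").to_numpy(float)[:, None]
    return {"sub": sub, "geno": pygmy_bantu_geno, "K": K, "ids": ids, "X": X}


class TestNullModel:
    def test_identity_kinship_reduces_to_ols(self, cohort_assoc):
        c = cohort_assoc
        y = _null_phenotype(c["sub"], 1)
        n = len(y)
        fit = assoc.fit_null_mixed_model(y, c["X"], np.eye(n))
        assert fit.sigma_g2 < 1e-6 * fit.sigma_e2
        G = np.where(c["geno"].matrix < 0, 0, c["geno"].matrix).astype(float)[:, :100]
        res = assoc.marker_scan(G, y, fit)
        Xf = np.column_stack([np.ones(n), c["X"]])
        for j in range(100):
            p_ols = sm.OLS(y, np.column_stack([Xf, G[:, j]])).fit().pvalues[-1]
            if np.isfinite(res.loc[j, "p"]):
                assert res.loc[j, "p"] == pytest.approx(p_ols, rel=1e-8)

    def test_reml_optimum_beats_fixed_delta(self, cohort_assoc):
        c = cohort_assoc
        y = _null_phenotype(c["sub"], 2)
        fit = assoc.fit_null_mixed_model(y, c["X"], c["K"])
        # re-evaluate the profile REML at delta = 1
        n = len(y)
        X = fit.X
        Q, _ = np.linalg.qr(X)
        S = np.eye(n) - Q @ Q.T
        Kc = assoc._center_kinship(c["K"])
        lam_s, U_s = np.linalg.eigh(S @ Kc @ S)
        q = n - X.shape[1]
        lam = np.maximum(lam_s[-q:], 0.0)
        eta2 = (U_s[:, -q:].T @ y) ** 2
        assert fit.reml_loglik >= assoc._reml_loglik(0.0, lam, eta2) - 1e-9

    def test_heritability_recovery(self):
        # y = u + e with sg2=2, se2=1 on a 200-sample admixed-cohort
        # kinship: the mean REML heritability over replicates is near 2/3
        from admixscan import io_qc
        cfg = sd.SimConfig(seed=19, n_snps=2000, chrom_length_bp=20_000_000,
                           n_admixed=100, n_bantu=100, n_pygmy_anc=0)
        panel, vt, st, _ = sd.simulate_cohort(cfg)
        gm = io_qc.GenotypeMatrix(sd.genotypes_from_panel(panel),
                                  list(st.sample_id), list(vt.snp_id))
        K, _ids = io_qc.ibs_kinship(gm)
        Kc = assoc._center_kinship(K)
        lam, U = np.linalg.eigh(Kc)
        lam = np.maximum(lam, 0)
        rng = np.random.default_rng(3)
        n = K.shape[0]
        h2 = []
        for _ in range(100):
            u = U @ (np.sqrt(2.0 * lam) * rng.normal(size=n))
            y = u + rng.normal(0, 1.0, n)
            fit = assoc.fit_null_mixed_model(y, None, K)
            h2.append(fit.sigma_g2 / (fit.sigma_g2 + fit.sigma_e2))
        assert np.mean(h2) == pytest.approx(2 / 3, abs=0.1)

    def test_asymmetric_kinship_rejected(self):
        K = np.eye(4)
        K[0, 1] = 0.5
        with pytest.raises(ValueError):
            assoc.fit_null_mixed_model(np.zeros(4), None, K)


class TestMarkerScan:
    def test_structured_null_calibrated_where_ols_inflates(self, cohort_assoc):
        c = cohort_assoc
        y = _null_phenotype(c["sub"], 11)
        fit = assoc.fit_null_mixed_model(y, c["X"], c["K"], sample_ids=c["ids"])
        res = assoc.marker_scan(c["geno"].matrix, y, fit)
        lam_mm = assoc.genomic_inflation(res.p.dropna())
        assert 0.9 <= lam_mm <= 1.1

        # naive OLS on the same structured data inflates badly
        G = c["geno"].matrix.astype(float)
        G = np.where(G < 0, np.nan, G)
        mu = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), mu, G)
        ok = G.std(axis=0) > 0
        Gc = G[:, ok] - G[:, ok].mean(0)
        yc = y - y.mean()
        r = (Gc.T @ yc) / (np.linalg.norm(Gc, axis=0) * np.linalg.norm(yc))
        n = len(y)
        t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-12))
        p_ols = 2 * ss.t.sf(np.abs(t), n - 2)
        assert assoc.genomic_inflation(p_ols) > 1.5

    def test_permuted_phenotype_gives_uniform_p(self, cohort_assoc):
        c = cohort_assoc
        rng = np.random.default_rng(21)
        y = rng.permutation(_null_phenotype(c["sub"], 13))
        fit = assoc.fit_null_mixed_model(y, c["X"], c["K"])
        res = assoc.marker_scan(c["geno"].matrix[:, ::4], y, fit)
        p = res.p.dropna()
        assert ss.kstest(p, "uniform").pvalue > 0.01

    def test_planted_snp_effect_found(self, cohort_assoc):
        # 0.5-SD marker effect: the top association is the causal marker
        # or an immediate neighbour in most replicates
        c = cohort_assoc
        G = c["geno"].matrix.astype(float)
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            j = int(rng.integers(200, 3800))
            g = G[:, j]
            if g.std() == 0:
                continue
            y = _null_phenotype(c["sub"], 600 + rep)
            y = y + 0.5 * y.std() * (g - g.mean()) / g.std()
            fit = assoc.fit_null_mixed_model(y, c["X"], c["K"])
            res = assoc.marker_scan(G, y, fit)
            top = int(res.p.idxmin())
            if abs(top - j) <= 1:
                hits += 1
        assert hits >= 0.8 * reps

    def test_constant_marker_skipped(self, cohort_assoc):
        c = cohort_assoc
        y = _null_phenotype(c["sub"], 31)
        fit = assoc.fit_null_mixed_model(y, c["X"], c["K"])
        M = np.column_stack([np.ones(len(y)), c["geno"].matrix[:, 0]])
        res = assoc.marker_scan(M, y, fit)
        assert bool(res.loc[0, "skipped"])


class TestAncestryScan:
    def _truth_matrix(self, truth, windows, sample_ids):
        tw = sd.true_window_ancestry(truth, windows, sample_ids)
        post = (tw == "P").astype(float)
        hap_ids = [f"{s}_h{i}" for s in sample_ids for i in range(2)]
        return la.AncestryMatrix(post, tw, np.ones_like(post, dtype=bool),
                                 windows, hap_ids, 0.9)

    def test_dosages_are_diploid_counts(self, cohort, la_run):
        st = cohort["samples"]
        adm = list(st.loc[st.population == "pygmy", "sample_id"])
        D = assoc.ancestry_dosage_matrix(la_run["am"], adm)
        vals = D[np.isfinite(D)]
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0}

    def test_unadmixed_cohort_all_windows_skipped(self, cohort):
        st = cohort["samples"]
        ids = list(st.loc[st.population == "bantu", "sample_id"])[:20]
        windows = la.window_partition(cohort["variants"]).iloc[:10].reset_index(drop=True)
        am = self._truth_matrix(cohort["truth"], windows, ids)
        y = np.random.default_rng(0).normal(size=len(ids))
        fit = assoc.fit_null_mixed_model(y, None, np.eye(len(ids)))
        res = assoc.ancestry_scan(am, ids, y, fit)
        assert res["skipped"].all()

    def test_planted_ancestry_qtl_maps_to_its_window(self):
        # admixture mapping on true local ancestry finds the planted QTL
        # window (or a neighbour) in most replicates
        hits = 0
        reps = 20
        for rep in range(reps):
            cfg = sd.SimConfig(seed=700 + rep, n_snps=1000,
                               chrom_length_bp=10_000_000, n_admixed=60,
                               n_bantu=5, n_pygmy_anc=5,
                               qtl_specs=[(5_000_000, -5.0)])
            panel, vt, st, truth = sd.simulate_cohort(cfg)
            adm = st[st.population == "pygmy"].reset_index(drop=True)
            windows = la.window_partition(vt)
            am = self._truth_matrix(truth, windows, list(adm.sample_id))
            from admixscan import io_qc
            gm = io_qc.GenotypeMatrix(
                sd.genotypes_from_panel(panel), list(st.sample_id),
                list(vt.snp_id)).subset_samples(list(adm.sample_id))
            K, _ = io_qc.ibs_kinship(gm)
            X = (adm.sex == "M").to_numpy(float)[:, None]
            fit = assoc.fit_null_mixed_model(adm.height_cm.to_numpy(), X, K)
            res = assoc.ancestry_scan(am, list(adm.sample_id),
                                      adm.height_cm.to_numpy(), fit)
            qtl_win = int(windows.index[
                (windows.start_bp <= 5_000_000) & (windows.end_bp >= 5_000_000)][0]) \
                if ((windows.start_bp <= 5_000_000) & (windows.end_bp >= 5_000_000)).any() \
                else int(np.argmin(np.abs(
                    (windows.start_bp + windows.end_bp) / 2 - 5_000_000)))
            top = int(res.p.idxmin())
            if abs(top - qtl_win) <= 1:
                hits += 1
        assert hits > reps / 2


class TestFdr:
    def test_hand_computed_bh(self):
        q = assoc.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_all_unit_pvalues(self):
        assert np.allclose(assoc.bh_fdr(np.ones(10)), 1.0)

    def test_null_uniform_rarely_discovers(self):
        # BH at q<0.05 on uniform p-values should almost never reject
        rng = np.random.default_rng(9)
        any_hit = sum((assoc.bh_fdr(rng.uniform(size=1000)) < 0.05).any()
                      for _ in range(20))
        assert any_hit <= 4

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            assoc.bh_fdr([0.0, 0.5])

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=500)
        q = assoc.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestTargetedSubset:
    @pytest.fixture()
    def scan_results(self, cohort_assoc):
        c = cohort_assoc
        y = _null_phenotype(c["sub"], 77)
        fit = assoc.fit_null_mixed_model(y, c["X"], c["K"])
        return assoc.marker_scan(c["geno"].matrix[:, :1000], y, fit,
                                 marker_ids=[f"m{j}" for j in range(1000)])

    def test_full_subset_identical(self, scan_results):
        sub = assoc.targeted_subset(scan_results, scan_results["id"])
        tested = scan_results["p"].notna()
        assert np.allclose(sub.loc[sub.p.notna(), "q"].to_numpy(),
                           scan_results.loc[tested, "q"].to_numpy())

    def test_singleton_q_equals_p(self, scan_results):
        tested = scan_results[scan_results.p.notna()]
        one = assoc.targeted_subset(scan_results, [tested.iloc[0]["id"]])
        assert one.loc[0, "q"] == pytest.approx(one.loc[0, "p"])

    def test_subset_reduces_minimum_q(self, scan_results):
        best = scan_results.nsmallest(100, "p")
        sub = assoc.targeted_subset(scan_results, best["id"])
        assert sub["q"].min() <= scan_results["q"].min() + 1e-12

    def test_empty_subset_raises(self, scan_results):
        with pytest.raises(ValueError):
            assoc.targeted_subset(scan_results, ["nonexistent"])
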