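"""Shared fixtures: one synthetic study cohort reused across the suite.

The session cohort reproduces the study conditions the package targets:
67 admixed Pygmy samples (individual Pygmy proportion ~ Beta with mean
0.65), 58 unadmixed Bantu samples, a 30-sample unadmixed Pygmy reference
panel and a 45-sample Maasai-like outgroup, 4,000 SNPs on a 40 Mb
chromosome at 1 cM/Mb, admixture age g = 50 generations.
"""

import numpy as np
import pytest

from admixscan import io_qc, local_ancestry, structure, synthetic_data as sd

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def cohort():
    cfg = sd.SimConfig(seed=FIXTURE_SEED, n_maasai=45)
    panel, vt, st, truth = sd.simulate_cohort(cfg)
    return {"config": cfg, "panel": panel, "variants": vt,
            "samples": st, "truth": truth}


@pytest.fixture(scope="session")
def geno(cohort):
    return io_qc.GenotypeMatrix(
        sd.genotypes_from_panel(cohort["panel"]),
        list(cohort["samples"]["sample_id"]),
        list(cohort["variants"]["snp_id"]),
    )


def pop_haplotypes(cohort, population):
    st = cohort["samples"]
    panel = cohort["panel"]
    return panel.haplotypes[panel.rows_for(st.loc[st.population == population,
                                                  "sample_id"])]


@pytest.fixture(scope="session")
def pygmy_bantu_geno(cohort, geno):
    st = cohort["samples"]
    ids = list(st.loc[st.population.isin(["pygmy", "bantu"]), "sample_id"])
    return geno.subset_samples(ids)


@pytest.fixture(scope="session")
def kinship(pygmy_bantu_geno):
    K, ids = io_qc.ibs_kinship(pygmy_bantu_geno)
    return K, ids


@pytest.fixture(scope="session")
def admixture_fit(cohort, geno):
    """K=2 admixture proportions on the Pygmy/Bantu cohort plus the
    unadmixed reference panel (outgroup excluded, as in a two-cluster
    analysis), on a thinned near-independent SNP set; column 0 is the
    Pygmy cluster."""
    st = cohort["samples"]
    sub = st[st.population.isin(["pygmy", "bantu", "pygmy_anc"])]
    thin = geno.subset_samples(list(sub.sample_id)) \
               .subset_snps(np.arange(0, geno.n_snps, 3))
    fit = structure.admixture_em(thin, K=2, n_restarts=2, max_iter=600, seed=11)
    return {"fit": fit.relabel(sub["population"], "pygmy_anc"),
            "samples": sub.reset_index(drop=True)}


@pytest.fixture(scope="session")
def la_run(cohort, admixture_fit):
    """Full local-ancestry inference on the fixture admixed samples, with
    the bisection target taken from the global admixture estimate."""
    st = cohort["samples"]
    sub = admixture_fit["samples"]
    adm = (sub.population == "pygmy").to_numpy()
    target = float(admixture_fit["fit"].Q[adm, 0].mean())
    scores, windows, info = local_ancestry.classify_windows(
        cohort["panel"], st, cohort["variants"], target_global_P=target, seed=0)
    am = local_ancestry.hmm_posteriors(
        scores, windows, switch_prob=0.1, stationary_p=target,
        estimate_switch=True, hap_ids=info["hap_ids"])
    return {"scores": scores, "windows": windows, "info": info, "am": am,
            "target": target}


@pytest.fixture(scope="session")
def ihs_bantu(cohort):
    """Null iHS scan (no sweep) in the Bantu samples."""
    from admixscan import selection
    return selection.ihs_scan(pop_haplotypes(cohort, "bantu"),
                              cohort["variants"])


@pytest.fixture(scope="session")
def xpehh_fixture(cohort):
    """XP-EHH scan, unadmixed Pygmy panel vs Bantu samples."""
    from admixscan import selection
    return selection.xpehh_scan(pop_haplotypes(cohort, "pygmy_anc"),
                                pop_haplotypes(cohort, "bantu"),
                                cohort["variants"])


@pytest.fixture(scope="session")
def bundle(cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    paths = sd.write_fixture_bundle(d, cohort["panel"], cohort["variants"],
                                    cohort["samples"], cohort["truth"])
    return paths
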