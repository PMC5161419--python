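import numpy as np
import pytest

import gremlkin as gk
from gremlkin import SimulationConfig, TraitConfig


def test_fixed_sibship_pair_counts():
    cfg = SimulationConfig(n_families=10, mean_sibs=2, sib_distribution="fixed",
                           parent_inclusion=1.0, n_snps_common=50,
                           n_snps_rare=0, seed=1)
    ped, sample_ids, units = gk.simulate.simulate_pedigree(cfg)
    S = set(sample_ids)
    assert sum(1 for p in ped.couples if p <= S) == 10
    assert sum(1 for p in ped.full_sibs if p <= S) == 10  # C(2,2) per family
    assert len(units["couple"]) == 10


def test_empty_and_deterministic_pedigree():
    cfg = SimulationConfig(n_families=0, seed=3)
    ped, ids, _ = gk.simulate.simulate_pedigree(cfg)
    assert ids == [] and ped.records == []
    a = gk.generate_cohort(SimulationConfig(n_families=12, n_snps_common=80,
                                            n_snps_rare=10, seed=9))
    b = gk.generate_cohort(SimulationConfig(n_families=12, n_snps_common=80,
                                            n_snps_rare=10, seed=9))
    assert a.sample_ids == b.sample_ids
    assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
    assert np.array_equal(a.phenotypes, b.phenotypes)
    c = gk.generate_cohort(SimulationConfig(n_families=12, n_snps_common=80,
                                            n_snps_rare=10, seed=10))
    assert not np.array_equal(a.phenotypes, c.phenotypes)


def test_mendelian_consistency(cohort):
    """Every offspring dosage is compatible with its parents' dosages."""
    ped = cohort.pedigree
    pos = {s: i for i, s in enumerate(cohort.sample_ids)}
    dos = cohort.genotypes.dosages
    checked = 0
    for iid, (fa, mo) in ped._parents.items():
        if iid not in pos or fa not in pos or mo not in pos:
            continue
        child, f, m = dos[pos[iid]], dos[pos[fa]], dos[pos[mo]]
        lo = (f > 1).astype(int) + (m > 1).astype(int)  # min transmissible
        hi = 2 - (f < 1).astype(int) - (m < 1).astype(int)
        assert ((child >= lo) & (child <= hi)).all()
        checked += 1
    assert checked > 10


def test_founder_allele_frequencies_match_config():
    cfg = SimulationConfig(n_families=150, mean_sibs=1, sib_distribution="fixed",
                           n_snps_common=400, n_snps_rare=0,
                           maf_range=(0.2, 0.2000001), seed=21,
                           traits=[TraitConfig(0.2, 0, 0, 0, 0, 0.13)])
    co = gk.generate_cohort(cfg)
    founders = [s for s in co.sample_ids if "_P" in s]
    idx = [co.sample_ids.index(s) for s in founders]
    freq = co.genotypes.dosages[idx].mean() / 2
    assert freq == pytest.approx(0.2, abs=0.01)


def test_variance_calibration_is_exact(cohort):
    fr = cohort.truth.traits[0].fractions()
    for lab in "GKC":
        realized = cohort.components[lab][:, 0].var()
        assert realized == pytest.approx(fr[lab], rel=1e-6)
    assert cohort.liabilities[:, 0].var() == pytest.approx(1.0, abs=0.05)


def test_null_simulation_prevalence():
    """Residual-only traits hit the configured prevalence threshold."""
    cfg = SimulationConfig(n_families=400, n_snps_common=60, n_snps_rare=0,
                           seed=17, traits=[TraitConfig(0, 0, 0, 0, 0, 0.13)])
    co = gk.generate_cohort(cfg)
    assert co.phenotypes[:, 0].mean() == pytest.approx(0.13, abs=0.02)


def test_couple_effect_raises_spouse_concordance():
    cfg = SimulationConfig(n_families=300, n_snps_common=60, n_snps_rare=0,
                           seed=23,
                           traits=[TraitConfig(0, 0, 0, 0, 0.3, 0.2)])
    co = gk.generate_cohort(cfg)
    pos = {s: i for i, s in enumerate(co.sample_ids)}
    y = co.phenotypes[:, 0]
    couple_corr = np.corrcoef(
        *zip(*[(y[pos[a]], y[pos[b]])
               for a, b in map(sorted, co.pedigree.couples)
               if a in pos and b in pos]))[0, 1]
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(y))
    random_corr = np.corrcoef(y, y[perm])[0, 1]
    assert couple_corr > random_corr + 0.05


def test_shared_snp_effects_give_identical_genetic_scores():
    cfg = SimulationConfig(n_families=40, n_snps_common=200, n_snps_rare=0,
                           seed=31, r_g=1.0,
                           traits=[TraitConfig(0.4, 0, 0, 0, 0, 0.13),
                                   TraitConfig(0.4, 0, 0, 0, 0, 0.09)])
    co = gk.generate_cohort(cfg)
    g1, g2 = co.components["G"].T
    assert np.corrcoef(g1, g2)[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_couple_component_requires_couples():
    cfg = SimulationConfig(n_families=0, seed=2,
                           traits=[TraitConfig(0, 0, 0, 0, 0.3, 0.13)])
    with pytest.raises(ValueError):
        gk.generate_cohort(cfg)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="seed"):
        SimulationConfig()
    with pytest.raises(ValueError, match="sum"):
        SimulationConfig(seed=1, traits=[TraitConfig(0.9, 0.9, 0, 0, 0)])
    with pytest.raises(ValueError, match="correlation"):
        SimulationConfig(seed=1, r_g=1.5)


def test_truth_record_round_trip(cohort):
    assert cohort.truth.traits[0].h_g2 == 0.2
    assert cohort.truth.seed == 11
    assert cohort.phenotypes.shape == (cohort.n, 1)
    # threshold definition: case iff liability exceeds the K-quantile
    t = gk.liability_factor  # noqa: F841  (import sanity)
    from scipy import stats
    thr = stats.norm.isf(0.13)
    assert np.array_equal(co_pheno := cohort.phenotypes[:, 0],
                          (cohort.liabilities[:, 0] > thr).astype(int))
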