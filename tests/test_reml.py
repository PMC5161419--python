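import numpy as np
import pytest
from scipy import optimize

import gremlkin as gk
from gremlkin import REMLError, VarianceComponentSpec
from gremlkin.reml import REMLFit


def _spec(matrices, code):
    return VarianceComponentSpec([(lab, matrices[lab]) for lab in code])


# ---------------------------------------------------------------------------
# log-likelihood surface


def test_loglik_closed_form_identity_V():
    """With V = I and an intercept-only design the REML log-likelihood has a
    closed Gaussian form: -0.5[(n-1) log s2 + log n + rss/s2]."""
    rng = np.random.default_rng(0)
    n = 25
    y = rng.normal(2.0, 1.3, n)
    ids = [f"i{k}" for k in range(n)]
    A = gk.RelationshipMatrix(ids, np.diag(np.r_[np.ones(n - 1), 2.0]))
    spec = VarianceComponentSpec([("A", A)])
    X = np.ones((n, 1))
    s2 = 1.7
    # sigma2_A = 0 so V = s2 * I; compare to the hand formula
    got = gk.reml_loglik(y, X, spec, [1e-12, s2], sample_ids=ids)
    rss = np.sum((y - y.mean()) ** 2)
    expected = -0.5 * (n * np.log(s2) + np.log(n / s2) + rss / s2)
    assert got == pytest.approx(expected, abs=1e-6)
    # rescaling y by c shifts logL by -(n-1) log c at sigma2 -> c^2 sigma2
    c = 3.0
    got_scaled = gk.reml_loglik(c * y, X, spec, [1e-12, c**2 * s2], sample_ids=ids)
    assert got_scaled == pytest.approx(got - (n - 1) * np.log(c), abs=1e-6)


def test_loglik_finite_at_floor_and_collinear_design_fails(matrices, cohort):
    spec = _spec(matrices, "GK")
    n = cohort.n
    y = cohort.phenotypes[:, 0].astype(float)
    val = gk.reml_loglik(y, np.ones((n, 1)), spec,
                         [1e-8, 1e-8, np.var(y)], sample_ids=cohort.sample_ids)
    assert np.isfinite(val)
    X_bad = np.column_stack([np.ones(n), np.ones(n)])
    with pytest.raises(REMLError, match="collinear"):
        gk.reml_loglik(y, X_bad, spec, [0.01, 0.01, np.var(y)],
                       sample_ids=cohort.sample_ids)


# ---------------------------------------------------------------------------
# fitting


def test_identity_component_flagged_non_identifiable(cohort):
    ids = cohort.sample_ids
    I_mat = gk.RelationshipMatrix(ids, np.eye(cohort.n))
    y = cohort.phenotypes[:, 0].astype(float)
    with pytest.raises(REMLError, match="identifiable"):
        gk.fit_reml(y, np.ones((cohort.n, 1)),
                    VarianceComponentSpec([("A", I_mat)]), sample_ids=ids)


def test_airelm_matches_derivative_free_optimum(matrices, cohort, design):
    """The AI-REML solution maximizes the same REML surface a simplex
    optimizer does, to 1e-3 in logL and 0.01 per proportion."""
    spec = _spec(matrices, "GKC")
    y = cohort.phenotypes[:, 0].astype(float)
    fit = gk.fit_reml(y, design, spec, sample_ids=cohort.sample_ids)
    assert fit.converged

    def negll(log_theta):
        try:
            return -gk.reml_loglik(y, design, spec, np.exp(log_theta),
                                   sample_ids=cohort.sample_ids)
        except REMLError:
            return 1e9

    res = optimize.minimize(
        negll, np.log(np.full(4, np.var(y) / 4)), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    assert -res.fun <= fit.loglik + 1e-3
    theta = np.exp(res.x)
    assert np.allclose(fit.proportions, theta / theta.sum(), atol=0.01)


def test_proportions_sum_to_one_and_location_scale_invariance(
        matrices, cohort, design):
    spec = _spec(matrices, "GK")
    y = cohort.phenotypes[:, 0].astype(float)
    fit = gk.fit_reml(y, design, spec, sample_ids=cohort.sample_ids)
    assert fit.proportions.sum() == pytest.approx(1.0, abs=1e-8)
    assert (fit.prop_se >= 0).all()
    shifted = gk.fit_reml(y + 7.0, design * np.r_[1.0, 2.0, 0.5, 10.0],
                          spec, sample_ids=cohort.sample_ids)
    assert np.allclose(shifted.proportions, fit.proportions, atol=1e-6)


def test_quantitative_trait_heritability_recovery():
    """Single-GRM fits on family cohorts recover a simulated h2 = 0.5
    within the three-sigma Monte-Carlo interval of the replicate mean."""
    ests = []
    for seed in range(20):
        co = gk.generate_cohort(gk.SimulationConfig(
            n_families=80, n_snps_common=800, n_snps_rare=0, seed=500 + seed,
            traits=[gk.TraitConfig(h_g2=0.5, h_p2=0.0, e_c2=0.0)]))
        G = gk.compute_grm(co.genotypes)
        fit = gk.fit_reml(co.liabilities[:, 0], np.ones((co.n, 1)),
                          VarianceComponentSpec([("G", G)]),
                          sample_ids=co.sample_ids)
        ests.append(fit.proportion("G")[0])
    ests = np.array(ests)
    mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
    assert abs(ests.mean() - 0.5) < 3 * mc_se


# ---------------------------------------------------------------------------
# tests of components


def _dummy_fit(labels, loglik, ids=None, props=None, ses=None):
    k = len(labels)
    return REMLFit(
        labels=list(labels), sigma2=np.ones(k + 1),
        proportions=np.array(props or [1 / (k + 1)] * (k + 1)),
        prop_se=np.array(ses or [0.1] * (k + 1)),
        ai_cov=np.eye(k + 1), fixed_effects=np.zeros(1), loglik=loglik,
        converged=True, n_iter=1, n_used=10, sample_ids=ids or list("abcdefghij"))


def test_boundary_lrt_mixture():
    full = _dummy_fit("GC", 100.0)
    reduced = _dummy_fit("G", 100.0)
    t = gk.lrt_component(full, reduced, "C")
    assert t.lrt_stat == 0.0 and t.lrt_p == 0.5
    reduced2 = _dummy_fit("G", 100.0 - 2.706 / 2)
    t2 = gk.lrt_component(full, reduced2, "C")
    assert t2.lrt_p == pytest.approx(0.05, abs=5e-4)
    with pytest.raises(ValueError, match="minus"):
        gk.lrt_component(reduced, full, "C")


@pytest.mark.parametrize("est,se,z,p", [
    (0.14, 0.07, 2.0, 0.0228),
    (0.0, 0.07, 0.0, 0.5),
])
def test_wald_component_one_sided(est, se, z, p):
    fit = _dummy_fit("G", 0.0, props=[est, 1 - est], ses=[se, se])
    t = gk.wald_component(fit, "G")
    assert t.wald_z == pytest.approx(z, abs=1e-9)
    assert t.wald_p == pytest.approx(p, abs=1e-3)


def test_wald_degenerate_zero_se_warns():
    fit = _dummy_fit("G", 0.0, props=[0.2, 0.8], ses=[0.0, 0.0])
    t = gk.wald_component(fit, "G")
    assert t.wald_p == 0.0


# ---------------------------------------------------------------------------
# liability transform


@pytest.mark.parametrize("prop,K,expected", [
    (1.0, 0.5, np.pi / 2),
    (0.10, 0.13, 0.2527),
    (0.0, 0.30, 0.0),
])
def test_observed_to_liability_values(prop, K, expected):
    assert gk.observed_to_liability(prop, K) == pytest.approx(expected, abs=2e-4)


def test_liability_transform_scales_se_and_validates():
    est, se = gk.observed_to_liability(0.10, 0.13, se_obs=0.05)
    assert se / est == pytest.approx(0.5)
    with pytest.raises(ValueError, match="prevalence"):
        gk.observed_to_liability(0.1, 0.0)
    # ascertainment correction reduces to the base factor at P = K
    assert gk.liability_factor(0.13, 0.13) == pytest.approx(
        gk.liability_factor(0.13) * 0.13 * 0.87 / (0.13 * 0.87))
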