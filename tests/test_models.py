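import numpy as np
import pytest

from caninegp import (BayesC, BayesCPriors, BreedSpec, ChainConfig, GBLUP,
                      KinshipMatrix, TraitSimSpec, VarianceComponents,
                      compute_grm, simulate_genotypes, simulate_phenotype)
from caninegp.models import (BayesCResults, DegeneratePhenotypeError,
                             MarkerAlignmentError)

from conftest import make_genotypes


@pytest.fixture(scope="module")
def one_breed_data():
    g = simulate_genotypes([BreedSpec("beagle", 100)], L=150, seed=11)
    y, truth = simulate_phenotype(g, TraitSimSpec(n_qtn=20, heritability=0.5, seed=12))
    return g, y, truth


# ---------------------------------------------------------------------------
# GBLUP closed form


def test_gblup_zero_genetic_variance_is_ols(one_breed_data):
    g, y, _ = one_breed_data
    K = compute_grm(g)
    res = GBLUP(y, K, breed=g.breed, sex=g.sex).fit(VarianceComponents(1e-12, 1.0))
    np.testing.assert_allclose(res.g_train, 0.0, atol=1e-8)
    X = np.hstack([np.ones((g.n_samples, 1)),
                   (g.sex == "M").astype(float).reshape(-1, 1)])
    ols = np.linalg.lstsq(X, y.values, rcond=None)[0]
    np.testing.assert_allclose(res.beta, ols, atol=1e-6)


def test_gblup_identity_kinship_shrinkage():
    rng = np.random.default_rng(5)
    y = rng.normal(size=40)
    K = KinshipMatrix(np.eye(40), sample_ids=np.arange(40))
    vc = VarianceComponents(2.0, 3.0)
    res = GBLUP(y, K).fit(vc)
    np.testing.assert_allclose(res.g_train, 0.4 * (y - y.mean()), atol=1e-10)
    assert res.mu == pytest.approx(y.mean())


def test_gblup_satisfies_normal_equations(one_breed_data):
    g, y, _ = one_breed_data
    K = compute_grm(g)
    for h2 in (0.2, 0.5, 0.8):
        res = GBLUP(y, K, breed=g.breed, sex=g.sex).fit(
            VarianceComponents(h2, 1.0 - h2))
        assert res.mme_residual() < 1e-8


def test_gblup_reml_then_linear_predictor(one_breed_data):
    g, y, _ = one_breed_data
    res = GBLUP(y, compute_grm(g), breed=g.breed, sex=g.sex).fit()
    assert 0.0 < res.vc.h2 < 1.0
    # eta = mu + X beta + g reproduces the fitted values exactly
    eta = res.model._Xt @ res.beta + res.g_train
    np.testing.assert_allclose(res.fitted_values(), eta, atol=1e-12)
    # and training-sample prediction recovers eta
    np.testing.assert_allclose(res.predict(res.model.train_idx), eta, atol=1e-10)


def test_gblup_duplicate_sample_same_prediction(one_breed_data):
    from caninegp import GenotypeMatrix

    g, y, _ = one_breed_data
    idx = np.r_[np.arange(g.n_samples), 0]  # append a clone of dog 0
    dup = GenotypeMatrix(
        dosages=g.dosages[idx], marker_ids=g.marker_ids, chrom=g.chrom,
        pos_bp=g.pos_bp, breed=g.breed[idx], sex=g.sex[idx],
        sample_ids=np.array([f"s{i}" for i in range(len(idx))], dtype=object))
    K = compute_grm(dup)
    yv = np.r_[y.values, np.nan]  # the duplicate dog is unphenotyped
    res = GBLUP(yv, K, breed=dup.breed, sex=dup.sex).fit(VarianceComponents(0.5, 0.5))
    preds = res.predict([0, g.n_samples])
    assert preds[1] == pytest.approx(preds[0], abs=1e-6)


def test_gblup_allele_flip_invariance(one_breed_data):
    g, y, _ = one_breed_data
    flipped = make_flip(g, np.arange(0, g.n_markers, 3))
    vc = VarianceComponents(0.6, 0.4)
    p1 = GBLUP(y, compute_grm(g), breed=g.breed, sex=g.sex).fit(vc).predict()
    p2 = GBLUP(y, compute_grm(flipped), breed=g.breed, sex=g.sex).fit(vc).predict()
    np.testing.assert_allclose(p1, p2, atol=1e-8)


def make_flip(g, idx):
    import dataclasses
    dos = g.dosages.copy()
    dos[:, idx] = 2 - dos[:, idx]
    return dataclasses.replace(g, dosages=dos)


def test_gblup_confounded_design_errors():
    g = simulate_genotypes([BreedSpec("a", 30)], L=50, seed=3)
    rng = np.random.default_rng(4)
    y = rng.normal(size=30)
    breed = np.where(np.arange(30) < 15, "x", "z")
    sex = np.where(np.arange(30) < 15, "M", "F")  # perfectly confounded with breed
    with pytest.raises(np.linalg.LinAlgError, match="breed"):
        GBLUP(y, compute_grm(g), breed=breed, sex=sex).fit(VarianceComponents(0.5, 0.5))


def test_gblup_constant_phenotype_errors():
    g = simulate_genotypes([BreedSpec("a", 20)], L=30, seed=6)
    with pytest.raises(DegeneratePhenotypeError):
        GBLUP(np.ones(20), compute_grm(g))


# ---------------------------------------------------------------------------
# GBLUP Gibbs


def test_gblup_gibbs_deterministic(one_breed_data):
    g, y, _ = one_breed_data
    K = compute_grm(g)
    chain = ChainConfig(n_iter=600, burn_in=100, thin=2)
    a = GBLUP(y, K, breed=g.breed, sex=g.sex).fit_gibbs(chain, seed=99)
    b = GBLUP(y, K, breed=g.breed, sex=g.sex).fit_gibbs(chain, seed=99)
    np.testing.assert_array_equal(a.g_train, b.g_train)
    assert a.vc == b.vc
    c = GBLUP(y, K, breed=g.breed, sex=g.sex).fit_gibbs(chain, seed=100)
    assert not np.array_equal(a.g_train, c.g_train)


def test_gblup_gibbs_matches_closed_form(one_breed_data):
    """Posterior-mean genetic values track the exact solve at the
    posterior-mean variance components."""
    g, y, _ = one_breed_data
    K = compute_grm(g)
    gibbs = GBLUP(y, K, breed=g.breed, sex=g.sex).fit_gibbs(
        ChainConfig(n_iter=6000, burn_in=1000, thin=2), seed=21)
    exact = GBLUP(y, K, breed=g.breed, sex=g.sex).fit(gibbs.vc)
    r = np.corrcoef(gibbs.g_train, exact.g_train)[0, 1]
    assert r > 0.98


# ---------------------------------------------------------------------------
# BayesC


def test_bayesc_ridge_limit():
    """With pi = 1 and fixed variances the model is ridge regression."""
    g = simulate_genotypes([BreedSpec("a", 80)], L=50, seed=31)
    y, _ = simulate_phenotype(g, TraitSimSpec(n_qtn=10, heritability=0.5, seed=32))
    sigma_a2, sigma_e2 = 0.4, 1.2
    priors = BayesCPriors(pi0=1.0, fix_pi=True,
                          fix_sigma_a2=sigma_a2, fix_sigma_e2=sigma_e2)
    res = BayesC(y, g, priors=priors).fit(ChainConfig(6000, 1000, 2), seed=33)

    M = g.dosages.astype(float)
    W = M - M.mean(axis=0)  # model's own centering, all columns
    X = np.ones((80, 1))
    lam = sigma_e2 / sigma_a2
    A = np.block([[X.T @ X, X.T @ W], [W.T @ X, W.T @ W + lam * np.eye(W.shape[1])]])
    b = np.concatenate([X.T @ y.values, W.T @ y.values])
    ref = np.linalg.solve(A, b)
    resid_sd = np.sqrt(sigma_e2)
    assert np.max(np.abs(res.alpha - ref[1:])) / resid_sd < 0.05
    assert res.mu == pytest.approx(ref[0], abs=0.05 * resid_sd)


def test_bayesc_recovers_single_large_qtn():
    g = simulate_genotypes([BreedSpec("a", 150)], L=201, seed=41)
    rng = np.random.default_rng(42)
    causal = 100
    yv = 3.0 * g.dosages[:, causal].astype(float) + rng.normal(0, 0.5, 150)
    res = BayesC(yv, g).fit(ChainConfig(3000, 500, 2), seed=43)
    assert int(np.argmax(res.inclusion_prob)) == causal
    assert res.inclusion_prob[causal] > 0.9


def test_bayesc_deterministic(one_breed_data):
    g, y, _ = one_breed_data
    chain = ChainConfig(400, 100, 2)
    a = BayesC(y, g, breed=g.breed, sex=g.sex).fit(chain, seed=7)
    b = BayesC(y, g, breed=g.breed, sex=g.sex).fit(chain, seed=7)
    np.testing.assert_array_equal(a.alpha, b.alpha)
    np.testing.assert_array_equal(a.inclusion_prob, b.inclusion_prob)
    assert a.pi == b.pi


def test_bayesc_null_effects_predict_fixed_part_only(one_breed_data):
    g, y, _ = one_breed_data
    model = BayesC(y, g, breed=g.breed, sex=g.sex)
    fit = model.fit(ChainConfig(200, 50, 1), seed=1)
    null = BayesCResults(model=model, beta=fit.beta,
                         alpha=np.zeros_like(fit.alpha),
                         inclusion_prob=np.zeros_like(fit.alpha),
                         pi=0.0, vc=fit.vc, posterior_h2=0.0,
                         chain=fit.chain, seed=fit.seed)
    X = np.hstack([np.ones((g.n_samples, 1)),
                   model.design.encode({"breed": g.breed, "sex": g.sex})])
    np.testing.assert_allclose(null.predict(), X @ fit.beta, atol=1e-12)


def test_bayesc_marker_mismatch_errors(one_breed_data):
    g, y, _ = one_breed_data
    fit = BayesC(y, g).fit(ChainConfig(200, 50, 1), seed=2)
    subset = g.take_markers(np.arange(10))
    with pytest.raises(MarkerAlignmentError, match="absent"):
        fit.predict(newg=subset)


def test_bayesc_flip_invariant_predictions():
    """Allele-coding flips change effect signs but not predictions."""
    g = simulate_genotypes([BreedSpec("a", 60)], L=40, seed=51)
    y, _ = simulate_phenotype(g, TraitSimSpec(n_qtn=10, heritability=0.6, seed=52))
    priors = BayesCPriors(pi0=1.0, fix_pi=True, fix_sigma_a2=0.3, fix_sigma_e2=1.0)
    chain = ChainConfig(8000, 2000, 2)
    p1 = BayesC(y, g, priors=priors).fit(chain, seed=53).predict()
    flipped = make_flip(g, np.arange(0, 40, 2))
    p2 = BayesC(y, flipped, priors=priors).fit(chain, seed=53).predict()
    sd = y.values.std()
    assert np.max(np.abs(p1 - p2)) / sd < 0.1  # Monte-Carlo tolerance


def test_chain_config_validation():
    with pytest.raises(ValueError):
        ChainConfig(n_iter=100, burn_in=100)
    with pytest.raises(ValueError):
        ChainConfig(n_iter=100, burn_in=10, thin=0)
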