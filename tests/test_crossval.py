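import numpy as np
import pytest

from caninegp import (BreedSpec, PhenotypeVector, TraitSimSpec, make_folds,
                      run_cv, simulate_genotypes, simulate_phenotype)
from caninegp.crossval import ALWAYS_REF, EXCLUDED


@pytest.fixture(scope="module")
def cv_data():
    g = simulate_genotypes(
        [BreedSpec("labrador", 80), BreedSpec("setter", 40), BreedSpec("gsd", 30)],
        L=300, seed=61)
    y, truth = simulate_phenotype(
        g, TraitSimSpec(n_qtn=20, heritability=0.5, seed=62))
    return g, y, truth


# ---------------------------------------------------------------------------
# fold construction


def test_random_folds_partition_evenly():
    breeds = np.array(["a"] * 10, dtype=object)
    plan = make_folds(breeds, "random", n_folds=5, n_rounds=3, seed=1)
    for r in range(3):
        a = plan.fold_assignment[r]
        assert sorted(np.bincount(a, minlength=5)) == [2, 2, 2, 2, 2]
        assert set(a) == {0, 1, 2, 3, 4}  # disjoint and exhaustive


def test_uneven_folds_differ_by_at_most_one():
    breeds = np.array(["a"] * 11, dtype=object)
    plan = make_folds(breeds, "random", n_folds=5, n_rounds=2, seed=2)
    sizes = np.bincount(plan.fold_assignment[0], minlength=5)
    assert sizes.max() - sizes.min() <= 1
    assert sizes.sum() == 11


def test_single_breed_strategies_flag_other_dogs():
    breeds = np.array(["lab"] * 12 + ["setter"] * 5, dtype=object)
    pure = make_folds(breeds, "single_breed", target_breed="lab",
                      n_folds=4, n_rounds=2, seed=3)
    aug = make_folds(breeds, "single_breed_augmented", target_breed="lab",
                     n_folds=4, n_rounds=2, seed=3)
    assert (pure.fold_assignment[:, 12:] == EXCLUDED).all()
    assert (aug.fold_assignment[:, 12:] == ALWAYS_REF).all()
    # identical validation sets for the same seed (only the reference differs)
    np.testing.assert_array_equal(pure.fold_assignment[:, :12],
                                  aug.fold_assignment[:, :12])
    # augmented reference contains every non-target dog
    ref = aug.reference_idx(0, 0)
    assert set(range(12, 17)) <= set(ref.tolist())
    valid = aug.validation_idx(0, 0)
    assert set(valid.tolist()) <= set(range(12))


def test_make_folds_validation_errors():
    breeds = np.array(["a"] * 6 + ["b"] * 2, dtype=object)
    with pytest.raises(ValueError, match="target breed"):
        make_folds(breeds, "single_breed", target_breed="zzz")
    with pytest.raises(ValueError, match="eligible"):
        make_folds(breeds, "single_breed", target_breed="b", n_folds=5)
    with pytest.raises(ValueError, match="strategy"):
        make_folds(breeds, "leave_one_out")


def test_folds_reproducible_by_seed():
    breeds = np.array(["a"] * 25, dtype=object)
    p1 = make_folds(breeds, "random", n_rounds=4, seed=9)
    p2 = make_folds(breeds, "random", n_rounds=4, seed=9)
    np.testing.assert_array_equal(p1.fold_assignment, p2.fold_assignment)
    p3 = make_folds(breeds, "random", n_rounds=4, seed=10)
    assert not np.array_equal(p1.fold_assignment, p3.fold_assignment)


# ---------------------------------------------------------------------------
# running CV


def test_run_cv_deterministic_and_counts(cv_data):
    g, y, _ = cv_data
    plan = make_folds(g.breed, "random", n_folds=5, n_rounds=2, seed=71)
    r1 = run_cv(plan, y, g, model="gblup")
    r2 = run_cv(plan, y, g, model="gblup")
    assert r1.mean_r == r2.mean_r
    assert len(r1.frame) == 10  # 2 rounds x 5 folds, none skipped
    assert r1.frame["n_valid"].sum() == 2 * g.n_samples
    assert (r1.frame["pearson_r"].abs() <= 1.0).all()


def test_run_cv_missing_phenotypes_never_train_or_validate(cv_data):
    g, y, _ = cv_data
    yv = y.values.copy()
    yv[:20] = np.nan
    ymiss = PhenotypeVector(yv, "continuous", "t")
    plan = make_folds(g.breed, "random", n_folds=5, n_rounds=1, seed=72)
    res = run_cv(plan, ymiss, g, model="gblup")
    assert res.frame["n_valid"].sum() == g.n_samples - 20
    assert (res.frame["n_train"] + res.frame["n_valid"] == g.n_samples - 20).all()


def test_run_cv_binary_trait_reports_auc(cv_data):
    g, _, _ = cv_data
    from caninegp import simulate_binary_trait

    yb, _ = simulate_binary_trait(
        g, TraitSimSpec(n_qtn=20, heritability=0.8, seed=63), prevalence=0.4)
    plan = make_folds(g.breed, "random", n_folds=5, n_rounds=2, seed=73)
    res = run_cv(plan, yb, g, model="gblup")
    assert np.isfinite(res.mean_auc)
    assert 0.0 <= res.mean_auc <= 1.0
    assert res.mean_auc > 0.5  # heritable trait must beat chance


def test_run_cv_negates_scores_for_low_value_cases(cv_data):
    """With case = low trait value, AUC must still land above 0.5."""
    g, y, _ = cv_data
    cutoff = np.quantile(y.values, 0.4)
    labels = PhenotypeVector((y.values < cutoff).astype(float), "binary", "b")
    plan = make_folds(g.breed, "random", n_folds=5, n_rounds=2, seed=74)
    res = run_cv(plan, y, g, model="gblup", binary_labels=labels)
    assert res.mean_auc > 0.5


def test_run_cv_bayesc_path(cv_data):
    g, y, _ = cv_data
    from caninegp import ChainConfig

    plan = make_folds(g.breed, "random", n_folds=5, n_rounds=1, seed=75)
    res = run_cv(plan, y, g, model="bayesc",
                 chain=ChainConfig(n_iter=400, burn_in=100, thin=2))
    assert len(res.frame) == 5
    assert np.isfinite(res.mean_r)


def test_run_cv_skips_tiny_validation_folds():
    g = simulate_genotypes([BreedSpec("a", 40)], L=100, seed=81)
    yv = np.full(40, np.nan)
    yv[:12] = np.random.default_rng(82).normal(size=12)
    y = PhenotypeVector(yv, "continuous", "t")
    plan = make_folds(g.breed, "random", n_folds=5, n_rounds=2, seed=83)
    res = run_cv(plan, y, g, model="gblup")
    # 12 phenotyped dogs over 5 folds of 8: some folds fall under 3 dogs
    assert res.n_skipped > 0
    assert (res.frame["n_valid"] >= 3).all()


def test_cv_result_tsv_layout(cv_data, tmp_path):
    import pandas as pd

    g, y, _ = cv_data
    plan = make_folds(g.breed, "random", n_folds=5, n_rounds=1, seed=76)
    res = run_cv(plan, y, g, model="gblup")
    out = tmp_path / "cv.tsv"
    res.to_tsv(out, model="gblup", trait="sim", strategy="random")
    df = pd.read_csv(out, sep="\t")
    assert len(df) == 6  # 5 fold rows + 1 aggregate
    assert df.iloc[-1]["round"] == "aggregate"
    assert df.iloc[-1]["pearson_r"] == pytest.approx(res.mean_r)
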