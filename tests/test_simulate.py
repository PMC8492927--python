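import json

import numpy as np
import pytest

from caninegp import (BreedSpec, TraitSimSpec, auc, pearson, read_genotypes,
                      simulate_binary_trait, simulate_genotypes,
                      simulate_phenotype)
from caninegp.io import read_phenotype_table
from caninegp.simulate import write_fixture_bundle


def test_genotypes_deterministic():
    breeds = [BreedSpec("a", 20), BreedSpec("b", 15)]
    g1 = simulate_genotypes(breeds, L=100, seed=5)
    g2 = simulate_genotypes(breeds, L=100, seed=5)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)
    assert (g1.sex == g2.sex).all()
    g3 = simulate_genotypes(breeds, L=100, seed=6)
    assert not np.array_equal(g1.dosages, g3.dosages)


def test_low_fst_means_no_breed_divergence():
    breeds = [BreedSpec("a", 1000, fst=0.001), BreedSpec("b", 1000, fst=0.001)]
    g = simulate_genotypes(breeds, L=5000, seed=7)
    fa = g.dosages[g.breed == "a"].mean(axis=0) / 2
    fb = g.dosages[g.breed == "b"].mean(axis=0) / 2
    assert np.mean(np.abs(fa - fb)) < 0.02


def test_breeds_separate_on_leading_pc():
    g = simulate_genotypes(
        [BreedSpec("a", 100, fst=0.2), BreedSpec("b", 100, fst=0.2)],
        L=5000, seed=8)
    M = g.dosages.astype(float)
    W = M - M.mean(axis=0)
    # leading right singular vector of the centered matrix
    u = np.linalg.svd(W, full_matrices=False)[0][:, 0]
    labels = (g.breed == "b").astype(int)
    side = (u > np.median(u)).astype(int)
    accuracy = max((side == labels).mean(), (side != labels).mean())
    assert accuracy > 0.99


def test_marker_map_valid():
    g = simulate_genotypes([BreedSpec("a", 10)], L=200, seed=9)
    for c in np.unique(g.chrom):
        pos = g.pos_bp[g.chrom == c]
        assert (np.diff(pos) > 0).all()


def test_phenotype_truth_record_and_qtns_shared():
    g = simulate_genotypes([BreedSpec("a", 50), BreedSpec("b", 50)], L=300, seed=10)
    y, truth = simulate_phenotype(g, TraitSimSpec(n_qtn=20, heritability="sample", seed=11))
    assert len(set(truth["qtn_marker_ids"])) == 20
    # one QTN set for the whole population: genetic values derive from the
    # same columns in every breed
    M = g.dosages.astype(float)[:, truth["qtn_indices"]]
    np.testing.assert_allclose(
        M @ np.array(truth["qtn_effects"]), truth["genetic_values"], atol=1e-9)
    for h2 in truth["h2_target"].values():
        assert 0.2 <= h2 <= 0.8


def test_perfect_heritability_phenotype_is_genetic_value():
    g = simulate_genotypes([BreedSpec("a", 60)], L=200, seed=12)
    y, truth = simulate_phenotype(g, TraitSimSpec(n_qtn=20, heritability=1.0, seed=13))
    assert pearson(y.values, np.array(truth["genetic_values"])) == pytest.approx(1.0)


def test_realized_heritability_close_at_large_n():
    g = simulate_genotypes([BreedSpec("a", 1000)], L=400, seed=14)
    y, truth = simulate_phenotype(g, TraitSimSpec(n_qtn=20, heritability=0.5, seed=15))
    gv = np.array(truth["genetic_values"])
    ratio = gv.var() / y.values.var()
    assert 0.45 <= ratio <= 0.55


def test_qtn_count_cannot_exceed_polymorphic_markers():
    g = simulate_genotypes([BreedSpec("a", 10)], L=30, seed=16)
    with pytest.raises(ValueError, match="polymorphic"):
        simulate_phenotype(g, TraitSimSpec(n_qtn=31, heritability=0.5, seed=17))


# ---------------------------------------------------------------------------
# binary traits


def test_binary_prevalence_half_splits_exactly():
    g = simulate_genotypes([BreedSpec("a", 200)], L=150, seed=18)
    y, _ = simulate_binary_trait(
        g, TraitSimSpec(n_qtn=20, heritability=0.5, seed=19), prevalence=0.5)
    assert int(y.values.sum()) == 100


def test_binary_prevalence_rccl_like_counts():
    g = simulate_genotypes([BreedSpec("a", 456)], L=150, seed=20)
    y, _ = simulate_binary_trait(
        g, TraitSimSpec(n_qtn=20, heritability=0.5, seed=21), prevalence=0.44)
    assert 199 <= int(y.values.sum()) <= 201


def test_null_binary_trait_gives_chance_auc():
    g = simulate_genotypes([BreedSpec("a", 400)], L=200, seed=22)
    y, truth = simulate_binary_trait(
        g, TraitSimSpec(n_qtn=20, heritability=0.0, seed=23), prevalence=0.5)
    # any genotype-derived score: use the true-QTN genetic value itself
    score = np.array(truth["genetic_values"])
    se = np.sqrt((len(score) / 2 + 1) / (12 * (len(score) / 2) ** 2))  # MW null SE approx
    assert abs(auc(score, y.values.astype(int)) - 0.5) < 2 * max(se, 0.05)


# ---------------------------------------------------------------------------
# fixture bundle


def test_fixture_bundle_round_trips(fixture_bundle):
    g = read_genotypes(fixture_bundle["bed"], format="plink-bed")
    assert g.n_samples == 300
    assert len(set(g.breed)) == 6
    tbl = read_phenotype_table(fixture_bundle["phenotypes"])
    assert len(tbl) == 300
    assert not g.missing_mask.any()


def test_fixture_gene_intervals_cover_qtns(fixture_bundle):
    import pandas as pd

    truth = json.loads(open(fixture_bundle["truth"]).read())
    genes = pd.read_csv(fixture_bundle["genes"], sep="\t", dtype={"chrom": str})
    g = read_genotypes(fixture_bundle["bed"], format="plink-bed")
    qtn_pos = {(g.chrom[j], int(g.pos_bp[j])) for j in truth["norberg"]["qtn_indices"]}
    covered = 0
    for _, row in genes.iterrows():
        if any(c == row["chrom"] and row["start"] <= p <= row["end"]
               for c, p in qtn_pos):
            covered += 1
    assert covered == len(genes)  # every interval covers a true QTN


def test_fixture_bundle_byte_identical_regeneration(tmp_path):
    d1 = write_fixture_bundle(tmp_path / "a", seed=3, n_markers=120)
    d2 = write_fixture_bundle(tmp_path / "b", seed=3, n_markers=120)
    for key in ("phenotypes", "genes"):
        assert open(d1[key], "rb").read() == open(d2[key], "rb").read()
    assert open(d1["bed"], "rb").read() == open(d2["bed"], "rb").read()
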