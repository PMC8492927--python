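import numpy as np
import pytest

from caninegp import BreedSpec, GenotypeMatrix, simulate_genotypes, write_fixture_bundle


def make_genotypes(dosages, breed=None, sex=None, chrom=None, pos=None):
    """Small hand-specified genotype object for unit tests."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=np.array([f"dog{i}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"m{j}" for j in range(L)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["1"] * L, dtype=object),
        pos_bp=np.array(pos if pos is not None else 1000 * (1 + np.arange(L))),
        breed=np.array(breed if breed is not None else ["beagle"] * n, dtype=object),
        sex=np.array(sex if sex is not None else ["F"] * n, dtype=object),
    )


@pytest.fixture(scope="session")
def two_breed_genotypes():
    return simulate_genotypes(
        [BreedSpec("labrador", 60, fst=0.15), BreedSpec("setter", 40, fst=0.15)],
        L=400, seed=101,
    )


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return write_fixture_bundle(outdir, seed=7, n_markers=400)
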