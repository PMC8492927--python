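"""Synthetic multi-breed genotypes and simulated quantitative traits.

The generator stands in for a real multi-breed SNP-array dataset. Breed
structure follows the Balding-Nichols model: each marker has an ancestral
allele frequency p ~ U(0.05, 0.95) and each breed draws its own frequency
from Beta(p(1-F)/F, (1-p)(1-F)/F) with that breed's divergence parameter F
(an FST). Dosages are binomial(2, p_breed), so markers are in linkage
equilibrium — the generator emulates breed-level allele-frequency
divergence, not within-chromosome LD or pedigree structure.

Traits are additive with a fixed number of causal markers (QTNs, default
20) shared across breeds; QTN effects are standard normal and each breed's
residual variance is scaled so that its realized heritability matches a
per-breed target, by default drawn uniformly from [0.2, 0.8].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import GenotypeMatrix, PhenotypeVector
from .io import write_genotypes

N_AUTOSOMES = 38  # dog karyotype

#: Study-census breed sizes (398/137/97/80/68/62) scaled by one half for
#: desk-speed defaults; FST values in the range reported between dog breeds.
DEFAULT_BREEDS = (
    ("labrador_retriever", 199),
    ("golden_retriever", 68),
    ("german_shepherd", 49),
    ("english_setter", 40),
    ("newfoundland", 34),
    ("rottweiler", 31),
)


@dataclass(frozen=True)
class BreedSpec:
    """One breed's size, divergence from the ancestral pool, and sex ratio."""

    name: str
    n_dogs: int
    fst: float = 0.15
    sex_ratio: float = 0.5  # proportion of females

    def __post_init__(self) -> None:
        if self.n_dogs < 1:
            raise ValueError("n_dogs must be >= 1")
        if not 0.0 < self.fst <= 0.5:
            raise ValueError("fst must lie in (0, 0.5]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")


def default_breeds(scale: float = 1.0) -> list[BreedSpec]:
    return [BreedSpec(name, max(2, round(n * scale))) for name, n in DEFAULT_BREEDS]


@dataclass(frozen=True)
class TraitSimSpec:
    """Additive-trait simulation settings.

    ``heritability`` may be a single value applied to every breed, a
    breed->value mapping, or the string ``"sample"`` to draw each breed's
    target uniformly from [0.2, 0.8].
    """

    n_qtn: int = 20
    heritability: float | dict | str = "sample"
    seed: int = 0
    sex_effect: float = 0.0
    breed_effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_qtn < 1:
            raise ValueError("n_qtn must be >= 1")
        if isinstance(self.heritability, (int, float)) and not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")


def simulate_genotypes(breeds: list[BreedSpec], L: int, seed: int = 0,
                       missing_rate: float = 0.0) -> GenotypeMatrix:
    """Balding-Nichols genotypes for a structured multi-breed population.

    Markers are spread over the 38 dog autosomes with strictly increasing
    positions within each chromosome. ``missing_rate`` masks calls at random
    (useful for exercising the completeness filter).
    """
    if L < 1:
        raise ValueError("need at least one marker")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=L)

    blocks, breed_labels, sex_labels, ids = [], [], [], []
    for spec in breeds:
        a = p_anc * (1.0 - spec.fst) / spec.fst
        b = (1.0 - p_anc) * (1.0 - spec.fst) / spec.fst
        p_breed = rng.beta(a, b)
        blocks.append(rng.binomial(2, p_breed, size=(spec.n_dogs, L)).astype(np.int8))
        breed_labels += [spec.name] * spec.n_dogs
        sexes = np.where(rng.random(spec.n_dogs) < spec.sex_ratio, "F", "M")
        sex_labels += sexes.tolist()
        ids += [f"{spec.name}_{i:04d}" for i in range(spec.n_dogs)]

    dosages = np.vstack(blocks)
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = -1

    n_chrom = min(N_AUTOSOMES, L)
    chrom = np.array([str(1 + j * n_chrom // L) for j in range(L)], dtype=object)
    pos = np.empty(L, dtype=np.int64)
    for c in np.unique(chrom):
        on = np.flatnonzero(chrom == c)
        pos[on] = 10_001 + 50_000 * np.arange(on.size)

    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=np.array(ids, dtype=object),
        marker_ids=np.array([f"snp{j:06d}" for j in range(L)], dtype=object),
        chrom=chrom,
        pos_bp=pos,
        breed=np.array(breed_labels, dtype=object),
        sex=np.array(sex_labels, dtype=object),
    )


def _breed_h2_targets(spec: TraitSimSpec, breed_names, rng) -> dict:
    if spec.heritability == "sample":
        return {b: float(rng.uniform(0.2, 0.8)) for b in breed_names}
    if isinstance(spec.heritability, dict):
        missing = set(breed_names) - set(spec.heritability)
        if missing:
            raise ValueError(f"heritability missing for breeds {sorted(missing)}")
        return {b: float(spec.heritability[b]) for b in breed_names}
    return {b: float(spec.heritability) for b in breed_names}


def simulate_phenotype(g: GenotypeMatrix, spec: TraitSimSpec) -> tuple[PhenotypeVector, dict]:
    """Additive 20-QTN-style trait with per-breed heritability targets.

    QTNs are drawn uniformly without replacement from the polymorphic
    markers and shared across breeds; effects are standard normal. Residuals
    are Gaussian with per-breed variance var_g,breed * (1 - h2) / h2 so that
    each breed's heritability matches its target in expectation. Returns the
    phenotype and a truth record (QTN ids/indices/effects, genetic values,
    per-breed target and realized h2, fixed effects).
    """
    if g.missing_mask.any():
        raise ValueError("simulate_phenotype requires complete genotypes")
    rng = np.random.default_rng(spec.seed)
    M = g.dosages.astype(np.float64)
    p = M.mean(axis=0) / 2.0
    poly = np.flatnonzero((p > 0) & (p < 1))
    if spec.n_qtn > poly.size:
        raise ValueError(
            f"n_qtn={spec.n_qtn} exceeds the {poly.size} polymorphic markers"
        )
    qtn_idx = np.sort(rng.choice(poly, size=spec.n_qtn, replace=False))
    effects = rng.standard_normal(spec.n_qtn)
    gvals = M[:, qtn_idx] @ effects

    breed_names = list(dict.fromkeys(g.breed.tolist()))
    h2_target = _breed_h2_targets(spec, breed_names, rng)
    var_g_all = float(np.var(gvals)) or 1.0

    y = np.empty(g.n_samples)
    realized = {}
    for b in breed_names:
        on = np.flatnonzero(g.breed == b)
        h2 = h2_target[b]
        var_g = float(np.var(gvals[on]))
        if var_g == 0.0:
            var_g = var_g_all
        if h2 >= 1.0:
            resid = np.zeros(on.size)
            y[on] = gvals[on]
        elif h2 <= 0.0:
            resid = rng.normal(0.0, np.sqrt(var_g_all), size=on.size)
            y[on] = resid  # no genetic signal at all
        else:
            resid = rng.normal(0.0, np.sqrt(var_g * (1.0 - h2) / h2), size=on.size)
            y[on] = gvals[on] + resid
        denom = float(np.var(y[on] if h2 <= 0 else gvals[on] + resid))
        realized[b] = float(np.var(gvals[on]) / denom) if h2 > 0 and denom > 0 else 0.0

    breed_shift = {b: (float(rng.normal(0.0, spec.breed_effect_sd))
                       if spec.breed_effect_sd > 0 else 0.0) for b in breed_names}
    for b, shift in breed_shift.items():
        y[g.breed == b] += shift
    if spec.sex_effect != 0.0:
        y[g.sex == "M"] += spec.sex_effect

    truth = {
        "qtn_indices": qtn_idx.tolist(),
        "qtn_marker_ids": g.marker_ids[qtn_idx].tolist(),
        "qtn_effects": effects.tolist(),
        "genetic_values": gvals.tolist(),
        "h2_target": h2_target,
        "h2_realized": realized,
        "breed_shift": breed_shift,
        "sex_effect": spec.sex_effect,
    }
    pheno = PhenotypeVector(values=y, trait_kind="continuous", trait_name="simulated")
    return pheno, truth


def simulate_binary_trait(g: GenotypeMatrix, spec: TraitSimSpec,
                          prevalence: float) -> tuple[PhenotypeVector, dict]:
    """0/1 trait from a liability threshold on the continuous simulation.

    The continuous liability is dichotomized at its empirical
    (1 - prevalence) quantile; dogs above the threshold are cases (1).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    liability, truth = simulate_phenotype(g, spec)
    thr = float(np.quantile(liability.values, 1.0 - prevalence))
    labels = (liability.values > thr).astype(np.float64)
    truth = dict(truth, liability=liability.values.tolist(), threshold=thr)
    return PhenotypeVector(values=labels, trait_kind="binary",
                           trait_name="simulated_binary"), truth


# ---------------------------------------------------------------------------
# Fixture bundle


#: 300 dogs split proportionally to the 398/137/97/80/68/62 study census.
_FIXTURE_BREED_SIZES = (142, 49, 35, 28, 24, 22)


def write_fixture_bundle(outdir, seed: int = 0, n_markers: int = 2_000) -> dict:
    """Write a complete miniature study to ``outdir`` (deterministic by seed).

    Six breeds (~300 dogs at the default scale), ``n_markers`` markers, a
    Norberg-angle-like continuous trait (left/right hip angles whose mean is
    the simulated value, on a 100 +/- 8 degree scale), an RCCL-like binary
    trait at 44% prevalence, a weight-like control trait, a gene-interval
    table whose intervals each cover one true QTN, and the truth record.
    Formats: PLINK bed/bim/fam, phenotype TSV, gene TSV, JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    breeds = [BreedSpec(name, n)
              for (name, _), n in zip(DEFAULT_BREEDS, _FIXTURE_BREED_SIZES)]
    g = simulate_genotypes(breeds, L=n_markers, seed=seed)

    na_spec = TraitSimSpec(n_qtn=20, heritability="sample", seed=seed + 1,
                           sex_effect=0.5, breed_effect_sd=0.5)
    na_z, na_truth = simulate_phenotype(g, na_spec)
    z = (na_z.values - na_z.values.mean()) / na_z.values.std()
    angle = 100.0 + 8.0 * z
    split = rng.normal(0.0, 1.0, size=g.n_samples)
    na_left, na_right = angle + split, angle - split

    rccl_spec = TraitSimSpec(n_qtn=20, heritability="sample", seed=seed + 2)
    rccl, rccl_truth = simulate_binary_trait(g, rccl_spec, prevalence=0.44)

    wt_spec = TraitSimSpec(n_qtn=20, heritability="sample", seed=seed + 3)
    wt_z, wt_truth = simulate_phenotype(g, wt_spec)
    zw = (wt_z.values - wt_z.values.mean()) / wt_z.values.std()
    weight = 30.0 + 7.0 * zw

    # sprinkle missing phenotypes, mimicking partially overlapping records
    miss_na = rng.random(g.n_samples) < 0.15
    miss_rccl = rng.random(g.n_samples) < 0.25
    miss_wt = rng.random(g.n_samples) < 0.40

    plink_prefix = outdir / "genotypes"
    write_genotypes(g, plink_prefix, format="plink-bed")

    def fmt(v, miss, nd=3):
        return "NA" if miss else f"{v:.{nd}f}"

    pheno_path = outdir / "phenotypes.tsv"
    with open(pheno_path, "w") as fh:
        fh.write("id\tbreed\tsex\tna_left\tna_right\trccl\tweight_kg\n")
        for i in range(g.n_samples):
            rc = "NA" if miss_rccl[i] else f"{int(rccl.values[i])}"
            fh.write(
                f"{g.sample_ids[i]}\t{g.breed[i]}\t{g.sex[i]}\t"
                f"{fmt(na_left[i], miss_na[i])}\t{fmt(na_right[i], miss_na[i])}\t"
                f"{rc}\t{fmt(weight[i], miss_wt[i], 1)}\n"
            )

    # gene intervals: one per of the first 10 NA-trait QTNs, +/- 5 kb
    genes_path = outdir / "genes.tsv"
    with open(genes_path, "w") as fh:
        fh.write("chrom\tstart\tend\tgene\n")
        for k, j in enumerate(na_truth["qtn_indices"][:10]):
            start = max(1, int(g.pos_bp[j]) - 5_000)
            end = int(g.pos_bp[j]) + 5_000
            fh.write(f"{g.chrom[j]}\t{start}\t{end}\tGENE{k:03d}\n")

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"norberg": na_truth, "rccl": rccl_truth, "weight": wt_truth,
                   "seed": seed}, fh, indent=1)

    return {
        "plink_prefix": str(plink_prefix),
        "bed": str(plink_prefix) + ".bed",
        "phenotypes": str(pheno_path),
        "genes": str(genes_path),
        "truth": str(truth_path),
    }
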