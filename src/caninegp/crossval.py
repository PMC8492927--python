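"""Repeated 5-fold cross-validation designs for genomic prediction.

Three sampling strategies:

* ``random`` — the whole multi-breed population is randomly partitioned into
  near-equal folds each round.
* ``single_breed`` — only dogs of one target breed are folded; all other
  dogs are excluded from the analysis entirely.
* ``single_breed_augmented`` — the target breed is folded exactly as in
  ``single_breed`` (identical validation sets for the same seed), but every
  non-target dog is kept permanently in the reference panel. The contrast
  between the two isolates whether out-of-breed reference dogs help.

Accuracy is the Pearson correlation between predictions and observed
phenotypes in the validation set, plus AUC for binary labels. Fold metrics
are averaged within a round first; the reported mean and SD are across
rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PhenotypeVector
from .kinship import KinshipMatrix, compute_grm
from .metrics import UndefinedMetricError, auc as _auc, pearson as _pearson
from .models import BayesC, BayesCPriors, ChainConfig, GBLUP, VarianceComponents

logger = logging.getLogger(__name__)

ALWAYS_REF = -1   # sample is in every round's reference panel
EXCLUDED = -2     # sample takes no part in this CV

STRATEGIES = ("random", "single_breed", "single_breed_augmented")


@dataclass
class CVPlan:
    """Fold assignments for ``n_rounds`` rounds of ``n_folds``-fold CV.

    ``fold_assignment[r, i]`` is the fold of sample i in round r, or one of
    the sentinels :data:`ALWAYS_REF` / :data:`EXCLUDED`.
    """

    strategy: str
    target_breed: str | None
    n_folds: int
    n_rounds: int
    fold_assignment: np.ndarray
    seed: int

    def validation_idx(self, rnd: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment[rnd] == fold)

    def reference_idx(self, rnd: int, fold: int) -> np.ndarray:
        a = self.fold_assignment[rnd]
        return np.flatnonzero((a == ALWAYS_REF) | ((a >= 0) & (a != fold)))


def make_folds(breeds, strategy: str, target_breed: str | None = None,
               n_folds: int = 5, n_rounds: int = 100, seed: int = 0) -> CVPlan:
    """Build fold assignments under one of the sampling strategies.

    Folds are made by shuffling the eligible samples and block-splitting;
    remainder dogs go one per fold, so fold sizes differ by at most one.
    ``single_breed`` and ``single_breed_augmented`` consume randomness
    identically, so the validation sets coincide for the same seed.
    """
    breeds = np.asarray(breeds, dtype=object)
    n = breeds.size
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if strategy == "random":
        eligible = np.arange(n)
        rest_code = EXCLUDED  # no rest exists
    else:
        if target_breed is None:
            raise ValueError("single-breed strategies need a target_breed")
        if target_breed not in set(breeds.tolist()):
            raise ValueError(f"target breed {target_breed!r} not present in data")
        eligible = np.flatnonzero(breeds == target_breed)
        rest_code = ALWAYS_REF if strategy == "single_breed_augmented" else EXCLUDED
    if eligible.size < n_folds:
        raise ValueError(
            f"only {eligible.size} eligible samples for {n_folds}-fold CV"
        )

    rng = np.random.default_rng(seed)
    assign = np.full((n_rounds, n), rest_code, dtype=np.int32)
    for r in range(n_rounds):
        perm = rng.permutation(eligible)
        for fold, chunk in enumerate(np.array_split(perm, n_folds)):
            assign[r, chunk] = fold
    return CVPlan(strategy=strategy, target_breed=target_breed, n_folds=n_folds,
                  n_rounds=n_rounds, fold_assignment=assign, seed=seed)


@dataclass
class CVResult:
    """Per-fold metrics plus across-round aggregates."""

    frame: pd.DataFrame           # round, fold, n_train, n_valid, pearson_r, auc
    mean_r: float
    sd_r: float
    mean_auc: float
    sd_auc: float
    n_skipped: int
    round_means: pd.DataFrame = field(repr=False, default=None)

    def to_tsv(self, path, model: str = "", trait: str = "", strategy: str = "") -> None:
        """Tidy per-fold TSV with one trailing aggregate row."""
        df = self.frame.copy()
        df.insert(2, "model", model)
        df.insert(3, "trait", trait)
        df.insert(4, "strategy", strategy)
        agg = pd.DataFrame([{
            "round": "aggregate", "fold": "", "model": model, "trait": trait,
            "strategy": strategy, "n_train": "", "n_valid": "",
            "pearson_r": self.mean_r, "auc": self.mean_auc,
        }])
        pd.concat([df, agg], ignore_index=True).to_csv(path, sep="\t", index=False)


def _model_seed(base: int, rnd: int, fold: int) -> int:
    return int(np.random.SeedSequence([base, rnd, fold]).generate_state(1)[0] % (2**31))


def run_cv(plan: CVPlan, y: PhenotypeVector, g: GenotypeMatrix,
           model: str = "gblup", *, method: str = "reml",
           chain: ChainConfig | None = None, priors: BayesCPriors | None = None,
           vc: VarianceComponents | None = None,
           binary_labels: PhenotypeVector | None = None,
           case_is_low: bool | None = None,
           use_fixed_effects: bool = True,
           kinship: KinshipMatrix | None = None) -> CVResult:
    """Run the cross-validation described by ``plan``.

    For each round x fold the model is fitted on the reference panel and the
    validation dogs are predicted. Samples with a missing phenotype never
    enter training or validation. AUC is computed against ``binary_labels``
    (or the trait itself if it is binary); when the case label corresponds to
    a *low* trait value (``case_is_low=True``, the Norberg-angle convention),
    predictions are negated before AUC so that higher score means more
    case-like. Folds whose validation set has fewer than 3 dogs, a single
    phenotype class, or a constant prediction are skipped with a warning.
    """
    if model not in ("gblup", "bayesc"):
        raise ValueError(f"unknown model {model!r}")
    chain = chain or ChainConfig()
    priors = priors or BayesCPriors()
    observed = ~y.missing

    labels = None
    if binary_labels is not None:
        labels = binary_labels.values
        if case_is_low is None:
            # Norberg-style: the case is defined by a low value of the
            # continuous trait the model predicts, so flip the score sign.
            case_is_low = y.trait_kind == "continuous"
    elif y.trait_kind == "binary":
        labels = y.values
        case_is_low = False
    if case_is_low:
        logger.info("AUC scores negated: case label corresponds to low trait values")

    breed = g.breed if use_fixed_effects else None
    sex = g.sex if use_fixed_effects else None
    if model == "gblup" and kinship is None:
        kinship = compute_grm(g)  # joint GRM over all samples, computed once

    rows, n_skipped = [], 0
    for rnd in range(plan.n_rounds):
        for fold in range(plan.n_folds):
            valid = plan.validation_idx(rnd, fold)
            train = plan.reference_idx(rnd, fold)
            valid = valid[observed[valid]]
            train = train[observed[train]]
            if valid.size < 3:
                logger.warning("round %d fold %d skipped: %d validation dogs",
                               rnd, fold, valid.size)
                n_skipped += 1
                continue
            if np.ptp(y.values[train]) == 0:
                logger.warning("round %d fold %d skipped: constant training trait",
                               rnd, fold)
                n_skipped += 1
                continue
            seed = _model_seed(plan.seed, rnd, fold)
            try:
                if model == "gblup":
                    mdl = GBLUP(y.values, kinship, breed=breed, sex=sex, train_idx=train)
                    fit = mdl.fit_gibbs(chain, seed) if method == "gibbs" else mdl.fit(vc)
                    pred = fit.predict(valid)
                else:
                    mdl = BayesC(y.values, g, breed=breed, sex=sex,
                                 priors=priors, train_idx=train)
                    fit = mdl.fit(chain, seed)
                    pred = fit.predict(idx=valid)
                r = _pearson(pred, y.values[valid])
            except UndefinedMetricError as exc:
                logger.warning("round %d fold %d skipped: %s", rnd, fold, exc)
                n_skipped += 1
                continue
            fold_auc = np.nan
            if labels is not None:
                lab = labels[valid]
                ok = ~np.isnan(lab)
                try:
                    score = -pred[ok] if case_is_low else pred[ok]
                    fold_auc = _auc(score, lab[ok])
                except UndefinedMetricError:
                    pass  # AUC undefined for this fold; Pearson row still counts
            rows.append({"round": rnd, "fold": fold, "n_train": train.size,
                         "n_valid": valid.size, "pearson_r": r, "auc": fold_auc})

    if not rows:
        raise RuntimeError("every fold was skipped; cannot aggregate")
    frame = pd.DataFrame(rows)
    per_round = frame.groupby("round")[["pearson_r", "auc"]].mean()
    mean_auc = float(per_round["auc"].mean()) if per_round["auc"].notna().any() else np.nan
    sd_auc = float(per_round["auc"].std(ddof=1)) if per_round["auc"].notna().sum() > 1 else np.nan
    return CVResult(
        frame=frame,
        mean_r=float(per_round["pearson_r"].mean()),
        sd_r=float(per_round["pearson_r"].std(ddof=1)) if len(per_round) > 1 else np.nan,
        mean_auc=mean_auc,
        sd_auc=sd_auc,
        n_skipped=n_skipped,
        round_means=per_round.reset_index(),
    )
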