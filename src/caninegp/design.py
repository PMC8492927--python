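"""Fixed-effects design matrices for sex and breed.

Treatment coding with the alphabetically first level of each factor as the
reference; a single-level factor contributes no column, so a single-breed,
single-sex population yields an intercept-only model. The intercept itself
is handled by the model classes, not stored here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UnseenLevelError(ValueError):
    """A factor level appears at prediction time that was absent in training."""


@dataclass
class FixedEffectsDesign:
    """Intercept-free dummy design for categorical covariates.

    ``levels`` maps each factor name to its sorted training levels (first
    level is the reference); ``matrix`` is the n x K treatment-coded design.
    """

    matrix: np.ndarray
    effect_names: list[str]
    levels: dict[str, list[str]]

    @property
    def n_effects(self) -> int:
        return self.matrix.shape[1]

    def encode(self, factors: dict[str, np.ndarray]) -> np.ndarray:
        """Encode new samples with the training levels; unseen levels error."""
        cols, n = [], None
        for name, train_levels in self.levels.items():
            vals = np.asarray(factors[name], dtype=object)
            n = len(vals) if n is None else n
            unseen = sorted(set(vals) - set(train_levels))
            if unseen:
                raise UnseenLevelError(
                    f"factor {name!r} has level(s) {unseen} not seen in training"
                )
            for lev in train_levels[1:]:
                cols.append((vals == lev).astype(np.float64))
        if not cols:
            m = n if n is not None else len(next(iter(factors.values())))
            return np.empty((m, 0))
        return np.column_stack(cols)


def build_design(breed: np.ndarray, sex: np.ndarray) -> FixedEffectsDesign:
    """Treatment-coded design for breed and sex.

    K = (n_breed_levels - 1) + (n_sex_levels - 1) columns; full column rank
    by construction when combined with an intercept.
    """
    breed = np.asarray(breed, dtype=object)
    sex = np.asarray(sex, dtype=object)
    if breed.shape != sex.shape or breed.size == 0:
        raise ValueError("breed and sex must be equal-length non-empty vectors")
    levels = {
        "breed": sorted(set(breed.tolist())),
        "sex": sorted(set(sex.tolist())),
    }
    names = [f"breed[{lev}]" for lev in levels["breed"][1:]]
    names += [f"sex[{lev}]" for lev in levels["sex"][1:]]
    design = FixedEffectsDesign(matrix=np.empty((breed.size, 0)),
                                effect_names=names, levels=levels)
    design.matrix = design.encode({"breed": breed, "sex": sex})
    return design
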