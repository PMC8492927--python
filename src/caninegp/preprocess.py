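"""Marker-panel filtering and trait coding.

Norberg-angle coding: the per-dog trait is the mean angle over both hips,
floored at 75 degrees (the low tail is truncated to approximate normality),
and optionally dichotomized at 105 degrees with angles *below* the cutoff
labelled 1 (dysplastic case — a lower angle means worse hip conformation)
and angles at or above it labelled 0.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .data import EmptyPanelError, GeneIntervalTable, GenotypeMatrix, PhenotypeVector

NORBERG_FLOOR = 75.0
NORBERG_CUTOFF = 105.0


def drop_incomplete_markers(g: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only markers with zero missing calls (column order preserved)."""
    keep = np.flatnonzero(~g.missing_mask.any(axis=0))
    if keep.size == 0:
        raise EmptyPanelError("every marker has at least one missing call")
    return g.take_markers(keep)


def select_associated_markers(g: GenotypeMatrix, genes: GeneIntervalTable) -> GenotypeMatrix:
    """Markers within any gene interval extended by ``genes.extension_bp``.

    Intervals are 1-based closed; a marker is retained if its position lies
    inside [start - ext, end + ext] (clamped at 1) of any gene on the same
    chromosome. The result is the union over genes, each marker once, in
    original order.
    """
    ext = genes.extended()
    keep = np.zeros(g.n_markers, dtype=bool)
    for chrom, grp in ext.groupby("chrom", sort=False):
        on_chrom = g.chrom == chrom
        if not on_chrom.any():
            continue
        pos = g.pos_bp
        hit = np.zeros(g.n_markers, dtype=bool)
        for s, e in zip(grp["start_bp"].to_numpy(), grp["end_bp"].to_numpy()):
            hit |= on_chrom & (pos >= s) & (pos <= e)
        keep |= hit
    if not keep.any():
        warnings.warn(
            "no marker overlaps any gene interval; check that chromosome "
            "naming matches between the genotype map and the gene table",
            stacklevel=2,
        )
        raise EmptyPanelError("associated-marker selection produced an empty panel")
    return g.take_markers(np.flatnonzero(keep))


def select_random_markers(g: GenotypeMatrix, k: int, seed: int) -> GenotypeMatrix:
    """Uniform sample of ``k`` markers without replacement, original order kept."""
    if k > g.n_markers:
        raise ValueError(f"requested {k} markers from a panel of {g.n_markers}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(g.n_markers, size=k, replace=False))
    return g.take_markers(idx)


# ---------------------------------------------------------------------------
# Norberg-angle coding


def average_norberg(left: np.ndarray, right: np.ndarray,
                    trait_name: str = "norberg_angle") -> PhenotypeVector:
    """Per-dog mean of left/right hip angles; missing if either side is missing."""
    left = np.asarray(left, dtype=np.float64)
    right = np.asarray(right, dtype=np.float64)
    if left.shape != right.shape:
        raise ValueError("left and right angle vectors differ in length")
    vals = (left + right) / 2.0  # NaN-propagating by design
    return PhenotypeVector(values=vals, trait_kind="continuous", trait_name=trait_name)


def truncate_norberg(y: PhenotypeVector, floor: float = NORBERG_FLOOR) -> PhenotypeVector:
    """Truncate angles below ``floor`` up to ``floor`` (low-tail winsorization)."""
    if y.trait_kind != "continuous":
        raise ValueError("truncation applies to the continuous angle trait")
    vals = y.values.copy()
    obs = ~y.missing
    vals[obs] = np.maximum(vals[obs], floor)
    return replace(y, values=vals)


def binarize_norberg(y: PhenotypeVector, cutoff: float = NORBERG_CUTOFF) -> PhenotypeVector:
    """Dichotomize the angle: values < cutoff -> 1 (case), >= cutoff -> 0."""
    if y.trait_kind != "continuous":
        raise ValueError("binarization applies to the continuous angle trait")
    vals = np.full_like(y.values, np.nan)
    obs = ~y.missing
    vals[obs] = (y.values[obs] < cutoff).astype(np.float64)
    return PhenotypeVector(
        values=vals,
        trait_kind="binary",
        trait_name=f"{y.trait_name}_lt{cutoff:g}",
        missing=y.missing.copy(),
    )
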