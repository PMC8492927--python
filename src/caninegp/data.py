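"""Core in-memory containers for genotype, phenotype, and gene-interval data.

The containers are thin, validated wrappers around numpy arrays and pandas
metadata. Dosages count copies of one designated allele per marker (A1 for
PLINK input, ALT for VCF input) and take values in {0, 1, 2}, with a
sentinel for missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the int8 dosage matrix.
MISSING = -1


class ConsistencyError(ValueError):
    """Raised when companion files or arrays disagree on samples/markers."""


class EmptyPanelError(ValueError):
    """Raised when a filtering step removes every marker."""


@dataclass
class GenotypeMatrix:
    """n x L allele-dosage matrix with marker map and sample metadata.

    Parameters
    ----------
    dosages : int8 array, shape (n, L)
        Allele counts in {0, 1, 2}; missing calls coded as :data:`MISSING`.
    sample_ids, marker_ids : unique string identifiers.
    chrom : chromosome label per marker.
    pos_bp : 1-based physical position per marker.
    breed, sex : categorical labels per sample.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    breed: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.breed = np.asarray(self.breed, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        n, L = self.dosages.shape
        if n < 2 or L < 1:
            raise ValueError(f"need n >= 2 samples and L >= 1 markers, got {n} x {L}")
        for name, arr, m in (
            ("sample_ids", self.sample_ids, n),
            ("breed", self.breed, n),
            ("sex", self.sex, n),
            ("marker_ids", self.marker_ids, L),
            ("chrom", self.chrom, L),
            ("pos_bp", self.pos_bp, L),
        ):
            if arr.shape[0] != m:
                raise ConsistencyError(f"{name} has length {arr.shape[0]}, expected {m}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.marker_ids)) != L:
            raise ValueError("marker_ids are not unique")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} dosage entries outside {{0,1,2,missing}}")
        if (self.pos_bp <= 0).any():
            raise ValueError("pos_bp must be positive (1-based)")

    # -- basic geometry -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def take_markers(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        """New matrix restricted to marker columns ``idx`` (order kept)."""
        idx = np.asarray(idx, dtype=np.intp)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            marker_ids=self.marker_ids[idx],
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
        )

    def take_samples(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        """New matrix restricted to sample rows ``idx`` (order kept)."""
        idx = np.asarray(idx, dtype=np.intp)
        return replace(
            self,
            dosages=self.dosages[idx, :],
            sample_ids=self.sample_ids[idx],
            breed=self.breed[idx],
            sex=self.sex[idx],
        )

    def dosage_float(self) -> np.ndarray:
        """Dosages as float64 with missing calls set to NaN."""
        out = self.dosages.astype(np.float64)
        out[self.dosages == MISSING] = np.nan
        return out

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "chrom": self.chrom, "pos_bp": self.pos_bp}
        )


@dataclass
class PhenotypeVector:
    """One trait's observed values aligned with a :class:`GenotypeMatrix`.

    Binary traits are coded 0/1; missing observations carry ``missing=True``
    and a NaN value.
    """

    values: np.ndarray
    trait_kind: str
    trait_name: str
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.missing is None:
            self.missing = np.isnan(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ConsistencyError("missing mask length does not match values")
        if self.trait_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        if self.trait_kind == "binary":
            obs = self.values[~self.missing]
            if not np.isin(obs, (0.0, 1.0)).all():
                raise ValueError("binary trait has non-0/1 observed values")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def observed_index(self) -> np.ndarray:
        return np.flatnonzero(~self.missing)

    def observed_values(self) -> np.ndarray:
        return self.values[~self.missing]


@dataclass
class GeneIntervalTable:
    """Gene intervals (1-based, closed) used to pick associated markers.

    ``extension_bp`` widens each interval symmetrically, clamped at
    position 1, before markers are intersected with it.
    """

    records: pd.DataFrame
    extension_bp: int = 10_000

    def __post_init__(self) -> None:
        required = {"chrom", "start_bp", "end_bp", "gene"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if self.extension_bp < 0:
            raise ValueError("extension_bp must be non-negative")
        bad = self.records["start_bp"] > self.records["end_bp"]
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} gene records have start_bp > end_bp"
            )

    def __len__(self) -> int:
        return len(self.records)

    def extended(self) -> pd.DataFrame:
        """Intervals widened by ``extension_bp`` on both sides, floor 1."""
        out = self.records.copy()
        out["start_bp"] = np.maximum(1, out["start_bp"] - self.extension_bp)
        out["end_bp"] = out["end_bp"] + self.extension_bp
        return out
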