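"""Reading and writing genotype and phenotype files.

Supported genotype formats are PLINK 1 binary triples (.bed/.bim/.fam,
SNP-major v1.00) and VCF 4.x with GT fields (read through cyvcf2).
Dosages count the A1 allele of the .bim file or the ALT allele of the VCF;
the two conventions differ only by per-marker sign flips of estimated
effects, which leave predictions unchanged, so no harmonization is done.

The phenotype table is a TSV with header
``id  breed  sex  na_left  na_right  rccl  weight_kg`` (NA for missing);
the gene-interval table is a TSV with header ``chrom  start  end  gene``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ConsistencyError, GeneIntervalTable, GenotypeMatrix, MISSING

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit PLINK codes -> A1 dosage: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}
_SEX_CODE = {"1": "M", "2": "F"}
_SEX_TO_CODE = {"M": "1", "F": "2"}


class FormatError(ValueError):
    """Malformed magic bytes, header, or record in a genotype file."""


def read_genotypes(path: str | os.PathLike, format: str = "plink-bed") -> GenotypeMatrix:
    """Read a genotype matrix from PLINK bed/bim/fam or VCF.

    ``path`` is the .bed path (or prefix) for PLINK, or the .vcf path.
    """
    if format == "plink-bed":
        return _read_plink(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str | os.PathLike, format: str = "plink-bed") -> None:
    """Write ``g`` as a PLINK bed/bim/fam triple or a text VCF."""
    if format == "plink-bed":
        _write_plink(g, path)
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# PLINK 1 binary


def _plink_prefix(path: str | os.PathLike) -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix == ".bed" else p


def _read_plink(path: str | os.PathLike) -> GenotypeMatrix:
    prefix = _plink_prefix(path)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)

    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "marker_id": str, "a1": str, "a2": str},
    )
    n, L = len(fam_df), len(bim_df)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{bed}: bad magic bytes (expected SNP-major v1.00)")
    bytes_per_marker = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_marker * L:
        raise ConsistencyError(
            f"{bed}: {body.size} data bytes inconsistent with "
            f"{n} samples x {L} markers from .fam/.bim"
        )
    blocks = body.reshape(L, bytes_per_marker)
    # unpack 2-bit fields, sample i lives in byte i//4 at bit offset 2*(i%4)
    shifts = (2 * (np.arange(n) % 4)).astype(np.uint8)
    codes = (blocks[:, np.arange(n) // 4] >> shifts) & 0b11
    dosages = _BED_CODE_TO_DOSAGE[codes].T  # (n, L)

    sex = np.array([_SEX_CODE.get(s, "U") for s in fam_df["sex"]], dtype=object)
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=fam_df["iid"].to_numpy(dtype=object),
        marker_ids=bim_df["marker_id"].to_numpy(dtype=object),
        chrom=bim_df["chrom"].to_numpy(dtype=object),
        pos_bp=bim_df["pos_bp"].to_numpy(dtype=np.int64),
        breed=fam_df["fid"].to_numpy(dtype=object),
        sex=sex,
    )


def _write_plink(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    prefix = _plink_prefix(path)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, L = g.dosages.shape

    lut = np.empty(256, dtype=np.uint8)  # int8 dosage (viewed as uint8) -> 2-bit code
    for dos, code in _DOSAGE_TO_BED_CODE.items():
        lut[dos % 256] = code
    codes = lut[g.dosages.T.astype(np.uint8)]  # (L, n)
    bytes_per_marker = (n + 3) // 4
    padded = np.zeros((L, bytes_per_marker * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = (2 * (np.arange(bytes_per_marker * 4) % 4)).astype(np.uint8)
    packed = (padded << shifts).reshape(L, bytes_per_marker, 4).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(L):
            fh.write(f"{g.chrom[j]}\t{g.marker_ids[j]}\t0\t{g.pos_bp[j]}\tA\tG\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(n):
            sex = _SEX_TO_CODE.get(g.sex[i], "0")
            fh.write(f"{g.breed[i]}\t{g.sample_ids[i]}\t0\t0\t{sex}\t-9\n")


# ---------------------------------------------------------------------------
# VCF


def _read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    cols, ids, chroms, pos = [], [], [], []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    gt_map = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"multiallelic record {rec.CHROM}:{rec.POS} ({rec.ID or '.'}) "
                "is not supported; split or filter first"
            )
        cols.append(gt_map[rec.gt_types])
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
    vcf.close()
    if not cols:
        raise FormatError(f"{path}: no variant records")
    dosages = np.stack(cols, axis=1)
    unknown = np.array(["unknown"] * len(samples), dtype=object)
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=samples,
        marker_ids=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        breed=unknown.copy(),
        sex=unknown.copy(),
    )


def _write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=caninegp\n")
        for c in dict.fromkeys(g.chrom):  # unique, order kept
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.sample_ids)) + "\n"
        )
        for j in range(g.n_markers):
            gts = "\t".join(gt_str[int(d)] for d in g.dosages[:, j])
            fh.write(
                f"{g.chrom[j]}\t{g.pos_bp[j]}\t{g.marker_ids[j]}\tG\tA\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Tabular inputs


def read_phenotype_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the phenotype/covariate TSV (id, breed, sex, na_left, na_right, rccl, weight_kg)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "breed": str, "sex": str})
    required = {"id", "breed", "sex", "na_left", "na_right", "rccl", "weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        raise ConsistencyError("phenotype table has duplicated ids")
    return df


def attach_metadata(g: GenotypeMatrix, pheno: pd.DataFrame) -> GenotypeMatrix:
    """Overwrite breed/sex metadata from a phenotype table joined on sample id."""
    tbl = pheno.set_index("id")
    missing = [s for s in g.sample_ids if s not in tbl.index]
    if missing:
        raise ConsistencyError(
            f"{len(missing)} genotyped samples absent from phenotype table, "
            f"e.g. {missing[:3]}"
        )
    sub = tbl.loc[list(g.sample_ids)]
    from dataclasses import replace

    return replace(
        g,
        breed=sub["breed"].to_numpy(dtype=object),
        sex=sub["sex"].to_numpy(dtype=object),
    )


def read_gene_intervals(
    path: str | os.PathLike,
    extension_bp: int = 10_000,
    coords: str = "1-based",
) -> GeneIntervalTable:
    """Read a gene-interval TSV (chrom, start, end, gene).

    ``coords='bed'`` treats start/end as 0-based half-open and converts to
    the package's 1-based closed convention on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    required = {"chrom", "start", "end", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gene-interval table missing columns: {sorted(missing)}")
    df = df.rename(columns={"start": "start_bp", "end": "end_bp"})
    if coords == "bed":
        df["start_bp"] = df["start_bp"] + 1
    elif coords != "1-based":
        raise ValueError(f"unknown coords convention {coords!r}")
    return GeneIntervalTable(records=df[["chrom", "start_bp", "end_bp", "gene"]],
                             extension_bp=extension_bp)
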