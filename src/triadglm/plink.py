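"""Minimal PLINK 1 bed/bim/fam reader and writer.

Only what the scan needs: SNP-major .bed decoding into allele-count
matrices, whitespace-delimited .fam/.bim parsing, and the reverse for
writing synthetic filesets.  Genotypes are returned as counts of the bim A1
allele, with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlinkParseError",
    "read_fam",
    "read_bim",
    "read_bed",
    "write_fam",
    "write_bim",
    "write_bed",
    "PedigreeIndex",
    "FamilyUnit",
    "build_pedigree_index",
]

_MAGIC = b"\x6c\x1b\x01"

# 2-bit genotype codes (per byte, little-endian bit pairs):
# 00 -> 2 copies of A1, 01 -> missing, 10 -> 1 copy, 11 -> 0 copies
_CODE_TO_DOSE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

_BYTE_LUT = np.zeros((256, 4), dtype=np.int8)
for _b in range(256):
    for _s in range(4):
        _BYTE_LUT[_b, _s] = _CODE_TO_DOSE[(_b >> (2 * _s)) & 0b11]

FAM_COLUMNS = ["fid", "iid", "pat", "mat", "sex", "pheno"]
BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]


class PlinkParseError(ValueError):
    """Malformed .bed/.bim/.fam content."""


def read_fam(path) -> pd.DataFrame:
    try:
        fam = pd.read_csv(path, sep=r"\s+", header=None, names=FAM_COLUMNS, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise PlinkParseError(f"cannot parse fam file {path}: {exc}") from exc
    if fam.isna().any().any():
        bad = int(fam.isna().any(axis=1).idxmax()) + 1
        raise PlinkParseError(f"{path}: malformed fam line {bad}")
    return fam


def read_bim(path) -> pd.DataFrame:
    try:
        bim = pd.read_csv(path, sep=r"\s+", header=None, names=BIM_COLUMNS, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise PlinkParseError(f"cannot parse bim file {path}: {exc}") from exc
    if bim.isna().any().any():
        bad = int(bim.isna().any(axis=1).idxmax()) + 1
        raise PlinkParseError(f"{path}: malformed bim line {bad}")
    bim["pos"] = bim["pos"].astype(int)
    return bim


def read_bed(path, n_individuals: int, n_snps: int) -> np.ndarray:
    """Decode a SNP-major .bed file into an (n_snps, n_individuals) int8 matrix.

    Entries are counts of the bim A1 allele; -1 marks missing genotypes.
    """
    raw = Path(path).read_bytes()
    if raw[:3] != _MAGIC:
        raise PlinkParseError(f"{path}: bad magic bytes (not SNP-major PLINK 1 bed)")
    bytes_per_snp = (n_individuals + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * n_snps:
        raise PlinkParseError(
            f"{path}: size mismatch (expected {bytes_per_snp * n_snps} genotype "
            f"bytes for {n_snps} SNPs x {n_individuals} individuals, got {body.size})"
        )
    decoded = _BYTE_LUT[body.reshape(n_snps, bytes_per_snp)]
    return decoded.reshape(n_snps, bytes_per_snp * 4)[:, :n_individuals]


def write_fam(path, fam: pd.DataFrame) -> None:
    fam.to_csv(path, sep="\t", header=False, index=False)


def write_bim(path, bim: pd.DataFrame) -> None:
    bim.to_csv(path, sep="\t", header=False, index=False)


def write_bed(path, doses: np.ndarray) -> None:
    """Encode an (n_snps, n_individuals) A1-count matrix as SNP-major .bed."""
    doses = np.asarray(doses)
    n_snps, n_ind = doses.shape
    bytes_per_snp = (n_ind + 3) // 4
    padded = np.full((n_snps, bytes_per_snp * 4), -1, dtype=np.int8)
    padded[:, :n_ind] = doses
    codes = np.zeros(padded.shape, dtype=np.uint8)
    for dose, code in _DOSE_TO_CODE.items():
        codes[padded == dose] = code
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


@dataclass(frozen=True)
class FamilyUnit:
    """One child with references (row indices) to its genotyped parents."""

    family_id: str
    child_row: int
    mother_row: Optional[int]
    father_row: Optional[int]

    @property
    def kind(self) -> str:
        if self.mother_row is not None and self.father_row is not None:
            return "triad"
        if self.mother_row is not None:
            return "md"
        return "fd"


@dataclass
class PedigreeIndex:
    """Family units resolved from a fam pedigree, plus drop diagnostics."""

    units: list[FamilyUnit]
    n_dropped: int  # children with neither parent genotyped

    def __len__(self) -> int:
        return len(self.units)


def build_pedigree_index(fam: pd.DataFrame) -> PedigreeIndex:
    """Resolve triads and dyads from the fam PAT/MAT columns.

    A row is a child when PAT or MAT is non-zero; parents are looked up by
    (FID, IID).  A parent absent from the fileset degrades the unit to a
    dyad; a child with neither parent available is dropped.  Parents may be
    shared by several children (siblings).
    """
    lookup = {
        (fid, iid): row
        for row, (fid, iid) in enumerate(zip(fam["fid"], fam["iid"]))
    }
    units: list[FamilyUnit] = []
    dropped = 0
    for row in range(len(fam)):
        fid = fam["fid"].iat[row]
        pat, mat = fam["pat"].iat[row], fam["mat"].iat[row]
        if pat == "0" and mat == "0":
            continue
        father = lookup.get((fid, pat)) if pat != "0" else None
        mother = lookup.get((fid, mat)) if mat != "0" else None
        if mother is None and father is None:
            dropped += 1
            continue
        units.append(
            FamilyUnit(
                family_id=fid, child_row=row, mother_row=mother, father_row=father
            )
        )
    return PedigreeIndex(units=units, n_dropped=dropped)
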