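"""Genotype state space for a diallelic locus in the case-parent triad design.

A family unit is summarised by effect-allele dosages ``(x_m, x_f, x_c)`` for
mother, father and child.  Of the 27 dosage combinations only 15 are
Mendelian-consistent; these form the cells of the triad likelihood.  Each
cell carries a *transmission multiplicity*: the number of ordered
parental-allele configurations (which allele each parent transmits) that
collapse onto the same unordered dosage triple.  Only the doubly
heterozygous cell ``(1, 1, 1)`` has two such configurations; the
multiplicity enters all likelihoods as a log-offset.

Families with one missing parent collapse onto 7 mother-child or 7
father-child dyad cells, each compatible with the triad cells that share
the observed dosages.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "AlleleCoding",
    "TriadCell",
    "DyadCell",
    "CountTable",
    "Classification",
    "InvalidGenotypeError",
    "TRIAD_CELLS",
    "MD_CELLS",
    "FD_CELLS",
    "MD_AGG",
    "FD_AGG",
    "enumerate_triad_cells",
    "child_doses",
    "classify_family",
    "null_cell_probability",
    "null_cell_probs",
    "tabulate",
    "tabulate_doses",
]

Dose = int
MaybeDose = Optional[Union[int, float]]


class InvalidGenotypeError(ValueError):
    """A dosage outside {0, 1, 2} was supplied."""


@dataclass(frozen=True)
class AlleleCoding:
    """Reference/effect allele labels and the effect-allele frequency.

    By convention the major allele is the reference and the minor allele is
    the effect allele, but any orientation is accepted.
    """

    ref_allele: str
    effect_allele: str
    effect_freq: float

    def __post_init__(self) -> None:
        if self.ref_allele == self.effect_allele:
            raise ValueError("ref_allele and effect_allele must differ")
        if not 0.0 <= self.effect_freq <= 1.0:
            raise ValueError("effect_freq must be in [0, 1]")


@dataclass(frozen=True)
class TriadCell:
    """One Mendelian-consistent (mother, father, child) dosage combination."""

    x_m: Dose
    x_f: Dose
    x_c: Dose
    multiplicity: int

    @property
    def key(self) -> tuple[Dose, Dose, Dose]:
        return (self.x_m, self.x_f, self.x_c)


@dataclass(frozen=True)
class DyadCell:
    """Observed (parent, child) dosage pair for a one-parent family unit."""

    role: str  # "md" (mother-child) or "fd" (father-child)
    x_p: Dose
    x_c: Dose
    compatible_cells: tuple[int, ...]  # indices into TRIAD_CELLS

    @property
    def key(self) -> tuple[Dose, Dose]:
        return (self.x_p, self.x_c)


def child_doses(x_m: Dose, x_f: Dose) -> tuple[Dose, ...]:
    """Child dosages reachable from parental dosages under Mendelian transmission."""
    tm = (0,) if x_m == 0 else (1,) if x_m == 2 else (0, 1)
    tf = (0,) if x_f == 0 else (1,) if x_f == 2 else (0, 1)
    return tuple(sorted({a + b for a in tm for b in tf}))


def _build_triad_cells() -> tuple[TriadCell, ...]:
    # Multiplicity by brute-force enumeration of the 16 ordered
    # parental-allele quadruples (i, j, k, l): parent genotypes (A_i, A_j)
    # and (A_k, A_l), second allele transmitted, child (A_j, A_l).
    mult: dict[tuple[int, int, int], int] = {}
    for i in (0, 1):
        for j in (0, 1):
            for k in (0, 1):
                for l in (0, 1):
                    key = (i + j, k + l, j + l)
                    mult[key] = mult.get(key, 0) + 1
    cells = []
    for x_m in (0, 1, 2):
        for x_f in (0, 1, 2):
            for x_c in child_doses(x_m, x_f):
                cells.append(TriadCell(x_m, x_f, x_c, mult[(x_m, x_f, x_c)]))
    return tuple(cells)


#: The 15 triad cells in lexicographic (x_m, x_f, x_c) order.
TRIAD_CELLS: tuple[TriadCell, ...] = _build_triad_cells()
_TRIAD_INDEX: dict[tuple[int, int, int], int] = {
    c.key: i for i, c in enumerate(TRIAD_CELLS)
}

N_CELLS = len(TRIAD_CELLS)


def _build_dyad_cells(role: str) -> tuple[DyadCell, ...]:
    pairs = sorted(
        {
            (c.x_m, c.x_c) if role == "md" else (c.x_f, c.x_c)
            for c in TRIAD_CELLS
        }
    )
    cells = []
    for x_p, x_c in pairs:
        if role == "md":
            compat = tuple(
                i for i, c in enumerate(TRIAD_CELLS) if c.x_m == x_p and c.x_c == x_c
            )
        else:
            compat = tuple(
                i for i, c in enumerate(TRIAD_CELLS) if c.x_f == x_p and c.x_c == x_c
            )
        cells.append(DyadCell(role, x_p, x_c, compat))
    return tuple(cells)


#: The 7 mother-child and 7 father-child dyad cells, lexicographic in (x_p, x_c).
MD_CELLS: tuple[DyadCell, ...] = _build_dyad_cells("md")
FD_CELLS: tuple[DyadCell, ...] = _build_dyad_cells("fd")
_MD_INDEX = {c.key: i for i, c in enumerate(MD_CELLS)}
_FD_INDEX = {c.key: i for i, c in enumerate(FD_CELLS)}


def _agg_matrix(dyads: Sequence[DyadCell]) -> np.ndarray:
    a = np.zeros((len(dyads), N_CELLS))
    for r, d in enumerate(dyads):
        a[r, list(d.compatible_cells)] = 1.0
    return a


#: 7x15 0/1 matrices mapping triad-cell probabilities onto dyad cells.
MD_AGG: np.ndarray = _agg_matrix(MD_CELLS)
FD_AGG: np.ndarray = _agg_matrix(FD_CELLS)


def enumerate_triad_cells() -> list[TriadCell]:
    """Return the 15 triad cells in fixed lexicographic (x_m, x_f, x_c) order."""
    return list(TRIAD_CELLS)


def null_cell_probability(cell: TriadCell, p2: float) -> float:
    """Probability of a triad cell under HWE, random mating and Mendelian transmission.

    Equals ``multiplicity * p1**(4 - n) * p2**n`` with ``n = x_m + x_f``; the
    15 cell probabilities sum to one for any allele frequency.
    """
    if not 0.0 <= p2 <= 1.0:
        raise ValueError("p2 must be in [0, 1]")
    n = cell.x_m + cell.x_f
    return cell.multiplicity * (1.0 - p2) ** (4 - n) * p2**n


def null_cell_probs(p2: float) -> np.ndarray:
    """Vector of null probabilities over the 15 cells (ordering of TRIAD_CELLS)."""
    return np.array([null_cell_probability(c, p2) for c in TRIAD_CELLS])


@dataclass(frozen=True)
class Classification:
    """Outcome of classifying one family: a cell reference or an exclusion flag."""

    kind: str  # "triad" | "md" | "fd" | "mendel_error" | "unusable"
    index: Optional[int] = None  # index into the corresponding cell list


def _as_dose(g: MaybeDose) -> Optional[int]:
    if g is None:
        return None
    if isinstance(g, float) and math.isnan(g):
        return None
    gi = int(g)
    if gi != g or gi not in (0, 1, 2):
        raise InvalidGenotypeError(f"dose must be 0, 1 or 2, got {g!r}")
    return gi


def classify_family(g_m: MaybeDose, g_f: MaybeDose, g_c: MaybeDose) -> Classification:
    """Map one family's dosages to a triad cell, dyad cell, or an exclusion flag.

    ``None``/NaN denote a missing genotype.  A missing child, or two missing
    parents, makes the family unusable; Mendelian-inconsistent combinations
    are flagged for exclusion.
    """
    m, f, c = _as_dose(g_m), _as_dose(g_f), _as_dose(g_c)
    if c is None or (m is None and f is None):
        return Classification("unusable")
    if m is not None and f is not None:
        idx = _TRIAD_INDEX.get((m, f, c))
        if idx is None:
            return Classification("mendel_error")
        return Classification("triad", idx)
    if f is None:
        idx = _MD_INDEX.get((m, c))
        return Classification("md", idx) if idx is not None else Classification("mendel_error")
    idx = _FD_INDEX.get((f, c))
    return Classification("fd", idx) if idx is not None else Classification("mendel_error")


@dataclass
class CountTable:
    """Observed family counts for one SNP over triad and dyad cells.

    Fractional counts are permitted (used by the EM expectation step); counts
    must be nonnegative.
    """

    triad: np.ndarray = field(default_factory=lambda: np.zeros(N_CELLS))
    md: np.ndarray = field(default_factory=lambda: np.zeros(len(MD_CELLS)))
    fd: np.ndarray = field(default_factory=lambda: np.zeros(len(FD_CELLS)))
    n_mendel_errors: int = 0
    n_unusable: int = 0

    def __post_init__(self) -> None:
        self.triad = np.asarray(self.triad, dtype=float)
        self.md = np.asarray(self.md, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.triad.shape != (N_CELLS,):
            raise ValueError(f"triad counts must have shape ({N_CELLS},)")
        if self.md.shape != (len(MD_CELLS),) or self.fd.shape != (len(FD_CELLS),):
            raise ValueError("dyad counts have wrong shape")
        if (self.triad < 0).any() or (self.md < 0).any() or (self.fd < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_triads(self) -> float:
        return float(self.triad.sum())

    @property
    def n_md(self) -> float:
        return float(self.md.sum())

    @property
    def n_fd(self) -> float:
        return float(self.fd.sum())

    @property
    def n_total(self) -> float:
        return self.n_triads + self.n_md + self.n_fd

    def to_tsv(self, path_or_buf) -> None:
        """Write the table in the plain-text exchange format.

        Columns: ``x_m  x_f  x_c  unit  count`` with the missing parent's
        column left empty for dyad rows.  The Mendelian-error count is kept
        in a ``#`` header line.
        """
        buf = io.StringIO()
        buf.write(f"# n_mendel_errors\t{self.n_mendel_errors}\n")
        buf.write("x_m\tx_f\tx_c\tunit\tcount\n")
        for c, y in zip(TRIAD_CELLS, self.triad):
            buf.write(f"{c.x_m}\t{c.x_f}\t{c.x_c}\ttriad\t{y:g}\n")
        for d, y in zip(MD_CELLS, self.md):
            buf.write(f"{d.x_p}\t\t{d.x_c}\tmd\t{y:g}\n")
        for d, y in zip(FD_CELLS, self.fd):
            buf.write(f"\t{d.x_p}\t{d.x_c}\tfd\t{y:g}\n")
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "CountTable":
        if hasattr(path_or_buf, "read"):
            lines = path_or_buf.read().splitlines()
        else:
            with open(path_or_buf) as fh:
                lines = fh.read().splitlines()
        table = cls()
        for line in lines:
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts[0].strip() == "n_mendel_errors":
                    table.n_mendel_errors = int(parts[1])
                continue
            fields = line.split("\t")
            if fields[3] == "unit":  # header
                continue
            x_m, x_f, x_c, unit, count = fields
            if unit == "triad":
                table.triad[_TRIAD_INDEX[(int(x_m), int(x_f), int(x_c))]] = float(count)
            elif unit == "md":
                table.md[_MD_INDEX[(int(x_m), int(x_c))]] = float(count)
            elif unit == "fd":
                table.fd[_FD_INDEX[(int(x_f), int(x_c))]] = float(count)
            else:
                raise ValueError(f"unknown unit {unit!r}")
        return table


def _build_lookup3() -> np.ndarray:
    lut = np.full((3, 3, 3), -1, dtype=np.int64)
    for key, i in _TRIAD_INDEX.items():
        lut[key] = i
    return lut


def _build_lookup2(index: dict[tuple[int, int], int]) -> np.ndarray:
    lut = np.full((3, 3), -1, dtype=np.int64)
    for key, i in index.items():
        lut[key] = i
    return lut


_TRIAD_LUT = _build_lookup3()
_MD_LUT = _build_lookup2(_MD_INDEX)
_FD_LUT = _build_lookup2(_FD_INDEX)


def tabulate_doses(
    g_m: np.ndarray, g_f: np.ndarray, g_c: np.ndarray
) -> CountTable:
    """Vectorized :func:`tabulate` over parallel dose arrays (NaN = missing)."""
    g_m = np.asarray(g_m, dtype=float)
    g_f = np.asarray(g_f, dtype=float)
    g_c = np.asarray(g_c, dtype=float)
    for arr in (g_m, g_f, g_c):
        vals = arr[~np.isnan(arr)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise InvalidGenotypeError("doses must be 0, 1, 2 or missing")

    miss_m, miss_f, miss_c = np.isnan(g_m), np.isnan(g_f), np.isnan(g_c)
    table = CountTable()
    unusable = miss_c | (miss_m & miss_f)
    table.n_unusable = int(unusable.sum())

    def _count(mask: np.ndarray, lut: np.ndarray, *doses: np.ndarray) -> np.ndarray:
        idx = lut[tuple(d[mask].astype(int) for d in doses)]
        mendel = int((idx < 0).sum())
        counts = np.bincount(idx[idx >= 0], minlength=lut.max() + 1).astype(float)
        return counts, mendel

    triad_mask = ~unusable & ~miss_m & ~miss_f
    counts, mendel = _count(triad_mask, _TRIAD_LUT, g_m, g_f, g_c)
    table.triad = counts
    table.n_mendel_errors += mendel

    md_mask = ~unusable & ~miss_m & miss_f
    counts, mendel = _count(md_mask, _MD_LUT, g_m, g_c)
    table.md = counts
    table.n_mendel_errors += mendel

    fd_mask = ~unusable & miss_m & ~miss_f
    counts, mendel = _count(fd_mask, _FD_LUT, g_f, g_c)
    table.fd = counts
    table.n_mendel_errors += mendel
    return table


def tabulate(families: Iterable[tuple[MaybeDose, MaybeDose, MaybeDose]]) -> CountTable:
    """Classify families and accumulate them into a :class:`CountTable`.

    Mendelian-inconsistent families are excluded from the cell counts and
    tallied separately; order of input families does not matter.
    """
    table = CountTable()
    for g_m, g_f, g_c in families:
        cl = classify_family(g_m, g_f, g_c)
        if cl.kind == "triad":
            table.triad[cl.index] += 1
        elif cl.kind == "md":
            table.md[cl.index] += 1
        elif cl.kind == "fd":
            table.fd[cl.index] += 1
        elif cl.kind == "mendel_error":
            table.n_mendel_errors += 1
        else:
            table.n_unusable += 1
    return table
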