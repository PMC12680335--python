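"""Model specifications and design matrices over the 15 triad cells.

The joint model is a log-linear model for the cell probabilities:

    log pi proportional to  offset + intercept + a_m*x_m + a_f*x_f
                            + fetal terms + parental-interaction term

where the offset is the log transmission multiplicity.  The parental main
coefficients ``a_m``/``a_f`` are composites of the background allele
frequency and the non-identifiable parental main effects; only their
difference is interpretable within a single study sample.  The fetal and
interaction coefficients are directly identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cells import TRIAD_CELLS, N_CELLS

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "InvalidSpecError",
    "FETAL_KINDS",
    "INTERACTION_KINDS",
    "parental_interaction_coding",
    "fetal_coding",
    "build_design",
    "cell_log_weights",
    "expected_probs",
]

FETAL_KINDS = ("none", "dose", "free")
INTERACTION_KINDS = ("none", "multiplicative", "dominant", "complementary", "threshold")


class InvalidSpecError(ValueError):
    """An unsupported or internally inconsistent model specification."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative choice of fetal parameterization and parental interaction.

    fetal:
        "none"  -- no child-genotype terms;
        "dose"  -- one column ``x_c`` (multiplicative dose-response);
        "free"  -- columns ``(x_c, 1{x_c=2})`` allowing distinct single- and
        double-dose relative risks.
    parental_interaction:
        one of "none", "multiplicative", "dominant", "complementary",
        "threshold"; ``threshold_k`` applies to the threshold coding only.
    """

    fetal: str = "dose"
    parental_interaction: str = "none"
    threshold_k: int = 2

    def __post_init__(self) -> None:
        if self.fetal not in FETAL_KINDS:
            raise InvalidSpecError(f"unknown fetal kind {self.fetal!r}")
        if self.parental_interaction not in INTERACTION_KINDS:
            raise InvalidSpecError(
                f"unknown parental interaction {self.parental_interaction!r}"
            )
        if self.threshold_k < 1:
            raise InvalidSpecError("threshold_k must be >= 1")

    def to_config(self) -> str:
        """Serialize as a plain-text key-value block."""
        return (
            f"fetal = {self.fetal}\n"
            f"parental_interaction = {self.parental_interaction}\n"
            f"threshold_k = {self.threshold_k}\n"
        )

    @classmethod
    def from_config(cls, text: str) -> "ModelSpec":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        return cls(
            fetal=kv.get("fetal", "dose"),
            parental_interaction=kv.get("parental_interaction", "none"),
            threshold_k=int(kv.get("threshold_k", 2)),
        )


def parental_interaction_coding(kind: str, x_m: int, x_f: int, k: int = 2) -> int:
    """Interaction term value for one pair of parental dosages.

    multiplicative -> x_m * x_f; dominant -> 1 iff both parents carry the
    effect allele; complementary -> 1 iff the parents are homozygous for
    opposite alleles; threshold -> 1 iff x_m + x_f >= k.
    """
    if x_m not in (0, 1, 2) or x_f not in (0, 1, 2):
        raise ValueError("parental doses must be in {0, 1, 2}")
    if kind == "multiplicative":
        return x_m * x_f
    if kind == "dominant":
        return int(x_m >= 1 and x_f >= 1)
    if kind == "complementary":
        return int({x_m, x_f} == {0, 2})
    if kind == "threshold":
        return int(x_m + x_f >= k)
    raise InvalidSpecError(f"unknown parental interaction {kind!r}")


def fetal_coding(kind: str, x_c: int) -> tuple[float, ...]:
    """Column values contributed by the child dosage.

    "dose" yields ``(x_c,)``; "free" yields ``(x_c, 1{x_c = 2})`` so the
    single-dose log-RR is the first coefficient and the double-dose log-RR
    is twice the first plus the second.
    """
    if x_c not in (0, 1, 2):
        raise ValueError("child dose must be in {0, 1, 2}")
    if kind == "none":
        return ()
    if kind == "dose":
        return (float(x_c),)
    if kind == "free":
        return (float(x_c), float(x_c == 2))
    raise InvalidSpecError(f"unknown fetal kind {kind!r}")


# Canonical coefficient names.
COL_INTERCEPT = "intercept"
COL_AM = "a_m"
COL_AF = "a_f"
COL_GC = "gamma_c"
COL_GC12 = "gamma_c12"
COL_BMF = "beta_mf"


@dataclass(frozen=True)
class DesignMatrix:
    """Design matrix, column names and log-multiplicity offset over the 15 cells."""

    X: np.ndarray
    columns: tuple[str, ...]
    offset: np.ndarray
    spec: ModelSpec

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise KeyError(f"model has no coefficient {name!r}") from None


def build_design(spec: ModelSpec) -> DesignMatrix:
    """Construct the design matrix for a :class:`ModelSpec`.

    Columns are ``[intercept, a_m (x_m), a_f (x_f)]`` followed by the fetal
    columns and the interaction column when requested; the offset row is the
    log transmission multiplicity.  Raises :class:`InvalidSpecError` on rank
    deficiency (cannot occur for the supported spec combinations).
    """
    cols: list[np.ndarray] = [np.ones(N_CELLS)]
    names: list[str] = [COL_INTERCEPT]
    x_m = np.array([c.x_m for c in TRIAD_CELLS], dtype=float)
    x_f = np.array([c.x_f for c in TRIAD_CELLS], dtype=float)
    cols += [x_m, x_f]
    names += [COL_AM, COL_AF]

    if spec.fetal != "none":
        fet = np.array([fetal_coding(spec.fetal, c.x_c) for c in TRIAD_CELLS])
        cols.append(fet[:, 0])
        names.append(COL_GC)
        if spec.fetal == "free":
            cols.append(fet[:, 1])
            names.append(COL_GC12)

    if spec.parental_interaction != "none":
        inter = np.array(
            [
                parental_interaction_coding(
                    spec.parental_interaction, c.x_m, c.x_f, spec.threshold_k
                )
                for c in TRIAD_CELLS
            ],
            dtype=float,
        )
        cols.append(inter)
        names.append(COL_BMF)

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidSpecError(f"rank-deficient design for spec {spec}")
    offset = np.log(np.array([c.multiplicity for c in TRIAD_CELLS], dtype=float))
    return DesignMatrix(X=X, columns=tuple(names), offset=offset, spec=spec)


def cell_log_weights(theta: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Linear predictor ``X @ theta`` over the 15 cells (offset excluded)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (design.n_params,):
        raise ValueError("parameter vector does not match design columns")
    return design.X @ theta


def expected_probs(theta: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Normalized cell probabilities ``softmax(X @ theta + offset)``."""
    eta = cell_log_weights(theta, design) + design.offset
    eta -= eta.max()
    w = np.exp(eta)
    return w / w.sum()


def theta_from_rrs(
    design: DesignMatrix, p2: float, rrs: Mapping[str, float] | None = None
) -> np.ndarray:
    """Parameter vector for a population with effect-allele frequency ``p2``
    and given relative risks keyed by coefficient name.

    Baseline (all RRs = 1) reproduces the null cell distribution; requires
    0 < p2 < 1 so that ``log(p2/p1)`` is finite.
    """
    if not 0.0 < p2 < 1.0:
        raise ValueError("p2 must be strictly inside (0, 1)")
    theta = np.zeros(design.n_params)
    alpha = np.log(p2 / (1.0 - p2))
    theta[design.column_index(COL_AM)] = alpha
    theta[design.column_index(COL_AF)] = alpha
    for name, rr in (rrs or {}).items():
        if rr <= 0:
            raise ValueError(f"relative risk for {name!r} must be > 0")
        theta[design.column_index(name)] += np.log(rr)
    return theta
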