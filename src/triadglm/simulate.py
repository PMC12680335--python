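"""Forward simulation of triad/dyad data and Monte-Carlo power estimation.

Families are drawn at the cell level: triad counts follow a multinomial over
the 15 cells, dyad units are drawn from the same distribution with the
designated parent then masked (equivalently, a multinomial over the 7 dyad
cells with the aggregated probabilities).  This is distributionally
identical to per-family gamete simulation and makes cost independent of
sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cells import FD_AGG, MD_AGG, CountTable, null_cell_probs
from .design import (
    COL_BMF,
    COL_GC,
    COL_GC12,
    DesignMatrix,
    ModelSpec,
    build_design,
)
from .fit import FitResult, fit_complete, fit_with_missing, wald_effects

__all__ = [
    "SimConfig",
    "PowerResult",
    "effect_log_rrs",
    "cell_distribution",
    "simulate_counts",
    "run_power",
]


@dataclass(frozen=True)
class SimConfig:
    """One simulation scenario.

    ``true_effects`` maps effect names to relative risks:
    ``fetal_single`` (per-dose RR, or single-dose RR under a free fetal
    model), ``fetal_double`` (double-dose RR, free model only) and
    ``interaction`` (parental interaction RR).  Omitted effects are null.
    """

    n_triads: int
    n_md: int = 0
    n_fd: int = 0
    p2: float = 0.5
    true_effects: Mapping[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.n_triads, self.n_md, self.n_fd) < 0:
            raise ValueError("family-unit counts must be nonnegative")
        if self.n_triads + self.n_md + self.n_fd <= 0:
            raise ValueError("at least one family unit is required")
        if not 0.0 < self.p2 < 1.0:
            raise ValueError("p2 must be strictly inside (0, 1)")
        for name, rr in self.true_effects.items():
            if rr <= 0:
                raise ValueError(f"relative risk for {name!r} must be > 0")


def effect_log_rrs(spec: ModelSpec, true_effects: Mapping[str, float]) -> dict[str, float]:
    """Translate named true RRs into log-RRs keyed by design-column name."""
    known = {"fetal_single", "fetal_double", "interaction"}
    unknown = set(true_effects) - known
    if unknown:
        raise ValueError(f"unknown effect names: {sorted(unknown)}")
    out: dict[str, float] = {}
    rr1 = float(true_effects.get("fetal_single", 1.0))
    rr2 = true_effects.get("fetal_double")
    if rr1 != 1.0 or rr2 is not None:
        if spec.fetal == "none":
            raise ValueError("fetal effect requested but spec has no fetal term")
        out[COL_GC] = np.log(rr1)
        if spec.fetal == "free":
            rr2 = rr1**2 if rr2 is None else float(rr2)
            out[COL_GC12] = np.log(rr2) - 2.0 * np.log(rr1)
        elif rr2 is not None and not np.isclose(rr2, rr1**2):
            raise ValueError("fetal_double requires fetal='free'")
    rr_int = float(true_effects.get("interaction", 1.0))
    if rr_int != 1.0:
        if spec.parental_interaction == "none":
            raise ValueError("interaction effect requested but spec has no interaction term")
        out[COL_BMF] = np.log(rr_int)
    return out


def cell_distribution(
    spec: ModelSpec,
    true_effects: Mapping[str, float],
    p2: float,
    design: Optional[DesignMatrix] = None,
) -> np.ndarray:
    """Cell probabilities: null distribution times the effect multipliers, renormalized.

    With all RRs equal to one this is exactly the null cell distribution.
    """
    design = design or build_design(spec)
    w = null_cell_probs(p2).copy()
    for name, log_rr in effect_log_rrs(spec, true_effects).items():
        w *= np.exp(design.X[:, design.column_index(name)] * log_rr)
    return w / w.sum()


def simulate_counts(
    config: SimConfig,
    spec: ModelSpec,
    rng: Optional[np.random.Generator] = None,
) -> CountTable:
    """Draw a :class:`CountTable` for one scenario (reproducible given seed)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pi = cell_distribution(spec, config.true_effects, config.p2)
    table = CountTable()
    if config.n_triads:
        table.triad = rng.multinomial(config.n_triads, pi).astype(float)
    if config.n_md:
        table.md = rng.multinomial(config.n_md, MD_AGG @ pi).astype(float)
    if config.n_fd:
        table.fd = rng.multinomial(config.n_fd, FD_AGG @ pi).astype(float)
    return table


@dataclass
class PowerResult:
    """Monte-Carlo rejection proportion for one scenario."""

    p2: float
    rr_int: float
    n_triads: int
    n_md: int
    n_fd: int
    reps: int
    rejections: int
    n_nonconverged: int
    alpha: float

    @property
    def power(self) -> float:
        return self.rejections / self.reps

    @property
    def mc_se(self) -> float:
        p = self.power
        return float(np.sqrt(p * (1.0 - p) / self.reps))


def _replicate_rng(seed: int, grid_index: int, rep: int) -> np.random.Generator:
    # independent, reproducible stream per (root seed, grid point, replicate)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(grid_index, rep))
    )


def run_power(
    spec: ModelSpec,
    grid: Sequence[tuple[float, float]],
    n_triads: int,
    n_md: int = 0,
    n_fd: int = 0,
    reps: int = 1500,
    alpha: float = 5e-8,
    seed: int = 0,
    effect: str = "interaction",
) -> list[PowerResult]:
    """Estimate rejection probability of the Wald test over a (p2, RR) grid.

    Each replicate simulates one dataset (fetal effect at the null unless the
    tested effect is fetal), fits the model (EM when dyads are present) and
    tests the requested effect at level ``alpha``.  Non-converged replicates
    count as non-rejections and are tallied separately.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    design = build_design(spec)
    results = []
    for g, (p2, rr) in enumerate(grid):
        effects = {} if rr == 1.0 else {effect: rr}
        config = SimConfig(
            n_triads=n_triads, n_md=n_md, n_fd=n_fd, p2=p2, true_effects=effects
        )
        rejections = 0
        nonconverged = 0
        for r in range(reps):
            rng = _replicate_rng(seed, g, r)
            table = simulate_counts(config, spec, rng=rng)
            fit = _fit_table(table, design)
            p = _effect_p(fit, effect)
            if p is None:
                nonconverged += 1
            elif p < alpha:
                rejections += 1
        results.append(
            PowerResult(
                p2=p2,
                rr_int=rr,
                n_triads=n_triads,
                n_md=n_md,
                n_fd=n_fd,
                reps=reps,
                rejections=rejections,
                n_nonconverged=nonconverged,
                alpha=alpha,
            )
        )
    return results


def _fit_table(table: CountTable, design: DesignMatrix) -> FitResult:
    if table.n_md or table.n_fd:
        return fit_with_missing(table, design)
    return fit_complete(table.triad, design)


def _effect_p(fit: FitResult, effect: str) -> Optional[float]:
    if not fit.converged or fit.covariance is None:
        return None
    eff = wald_effects(fit)
    est = {
        "interaction": eff.rr_interaction,
        "fetal_single": eff.rr_fetal_single,
        "fetal_double": eff.rr_fetal_double,
    }[effect]
    if est is None:
        raise ValueError(f"fitted model has no {effect!r} term")
    return est.p
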