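"""Maximum-likelihood estimation for triad/dyad count tables.

Complete triads are fitted by Newton-Raphson on the Poisson log-likelihood
with the log-multiplicity offset; with a free intercept this is equivalent
to the multinomial likelihood over the 15 cells, and the non-intercept
blocks of the two information matrices agree.  Families with one missing
parent enter through the marginal likelihood (cell probabilities summed
over the compatible triad cells) and are handled by EM: the E-step
allocates each dyad fractionally across its compatible cells, the M-step
refits the complete-data model on the fractional counts.

Standard errors under missingness come from the observed-data (marginal)
information, obtained by numerically differentiating the analytic score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .cells import MD_AGG, FD_AGG, CountTable
from .design import (
    COL_AF,
    COL_AM,
    COL_BMF,
    COL_GC,
    COL_GC12,
    DesignMatrix,
    expected_probs,
)

__all__ = [
    "FitResult",
    "EffectEstimate",
    "ReportedEffects",
    "HWEResult",
    "fit_complete",
    "marginal_loglik",
    "fit_with_missing",
    "wald_effects",
    "hwe_test",
    "lr_test",
]

Z975 = 1.959964
#: Coefficients larger than this in absolute value are treated as diverging
#: (separation / empty margin); no continuity correction is applied.
BOUNDARY_THETA = 15.0


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    theta: np.ndarray
    columns: tuple[str, ...]
    covariance: Optional[np.ndarray]
    loglik: float
    status: str  # converged | max-iter | rank-deficient | boundary
    n_iter: int
    n_triads: float = 0.0
    n_md: float = 0.0
    n_fd: float = 0.0
    boundary_coefficients: tuple[str, ...] = ()
    em_trajectory: tuple[float, ...] = ()  # marginal log-likelihood per EM iteration

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    def coef(self, name: str) -> float:
        return float(self.theta[self.columns.index(name)])

    def se(self, name: str) -> float:
        i = self.columns.index(name)
        return float(np.sqrt(self.covariance[i, i]))


def _multinomial_loglik(y: np.ndarray, pi: np.ndarray) -> float:
    mask = y > 0
    return float(y[mask] @ np.log(pi[mask]))


def fit_complete(
    triad_counts: np.ndarray,
    design: DesignMatrix,
    tol: float = 1e-8,
    max_iter: int = 100,
    theta0: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit the log-linear model to 15-cell triad counts (fractional allowed).

    Maximizes the Poisson log-likelihood ``sum(y*eta - exp(eta))`` with
    ``eta = offset + X theta`` by Newton-Raphson with step halving;
    covariance is the inverse observed information.  The reported ``loglik``
    is the equivalent multinomial log-likelihood, so it is directly
    comparable with :func:`marginal_loglik`.
    """
    y = np.asarray(triad_counts, dtype=float)
    if y.shape != (design.X.shape[0],):
        raise ValueError("counts not aligned to the 15 triad cells")
    if (y < 0).any():
        raise ValueError("counts must be nonnegative")
    total = y.sum()
    if total <= 0:
        raise ValueError("all-zero count table")

    X, off = design.X, design.offset
    p = design.n_params
    if theta0 is not None:
        theta = np.array(theta0, dtype=float)
    else:
        theta = np.zeros(p)
        theta[0] = math.log(total / np.exp(off).sum())

    def poisson_ll(th: np.ndarray) -> float:
        eta = off + X @ th
        return float(y @ eta - np.exp(eta).sum())

    ll = poisson_ll(theta)
    status = "max-iter"
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = np.exp(off + X @ theta)
        score = X.T @ (y - mu)
        info = X.T @ (mu[:, None] * X)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return FitResult(theta, design.columns, None, -np.inf, "rank-deficient", n_iter)
        # step halving keeps the update an ascent step
        new_ll = poisson_ll(theta + step)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step *= 0.5
            halvings += 1
            if halvings > 30:
                break
            new_ll = poisson_ll(theta + step)
        theta = theta + step
        if not np.isfinite(new_ll):
            break
        # small relative deviance change AND a small Newton step: quadratic
        # convergence then puts the remaining error far below the step size
        converged = (
            abs(new_ll - ll) < tol * (abs(ll) + 0.1)
            and np.max(np.abs(step)) < 1e-6
        )
        ll = new_ll
        if converged:
            status = "converged"
            break

    diverged = np.abs(theta[1:]) > BOUNDARY_THETA
    boundary = tuple(np.array(design.columns[1:])[diverged]) if diverged.any() else ()
    if boundary:
        status = "boundary"

    mu = np.exp(off + X @ theta)
    info = X.T @ (mu[:, None] * X)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = None
        if status == "converged":
            status = "rank-deficient"
    pi = expected_probs(theta, design)
    return FitResult(
        theta=theta,
        columns=design.columns,
        covariance=cov,
        loglik=_multinomial_loglik(y, pi),
        status=status,
        n_iter=n_iter,
        n_triads=float(total),
        boundary_coefficients=boundary,
    )


def marginal_loglik(
    theta: np.ndarray, table: CountTable, design: DesignMatrix
) -> float:
    """Observed-data log-likelihood of triads plus dyads.

    Each triad contributes ``log pi_cell``; each dyad contributes the log of
    the summed probability over its compatible triad cells.
    """
    pi = expected_probs(theta, design)
    ll = _multinomial_loglik(table.triad, pi)
    if table.md.any():
        ll += _multinomial_loglik(table.md, MD_AGG @ pi)
    if table.fd.any():
        ll += _multinomial_loglik(table.fd, FD_AGG @ pi)
    return ll


def _fractional_counts(theta: np.ndarray, table: CountTable, design: DesignMatrix) -> np.ndarray:
    """E-step: expected complete-data cell counts given current parameters."""
    pi = expected_probs(theta, design)
    y = table.triad.copy()
    for agg, counts in ((MD_AGG, table.md), (FD_AGG, table.fd)):
        if not counts.any():
            continue
        marg = agg @ pi
        for g in np.nonzero(counts)[0]:
            members = agg[g] > 0
            y[members] += counts[g] * pi[members] / marg[g]
    return y


def _marginal_score(theta: np.ndarray, table: CountTable, design: DesignMatrix) -> np.ndarray:
    """Analytic gradient of the marginal log-likelihood.

    Equals ``X' (yhat - N pi)`` where ``yhat`` are the E-step fractional
    counts — the EM fixed point is exactly a stationary point of the
    marginal likelihood.
    """
    pi = expected_probs(theta, design)
    yhat = _fractional_counts(theta, table, design)
    return design.X.T @ (yhat - table.n_total * pi)


def _marginal_information(
    theta: np.ndarray, table: CountTable, design: DesignMatrix
) -> np.ndarray:
    """Observed information of the non-intercept coefficients.

    The marginal likelihood is invariant to the intercept (it cancels in the
    softmax normalization), so the information is computed over theta[1:]
    via central differences of the analytic score.
    """
    p = design.n_params
    hess = np.zeros((p, p))
    for j in range(1, p):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        hess[:, j] = (
            _marginal_score(tp, table, design) - _marginal_score(tm, table, design)
        ) / (2 * h)
    sub = hess[1:, 1:]
    sub = 0.5 * (sub + sub.T)
    return -sub


def fit_with_missing(
    table: CountTable,
    design: DesignMatrix,
    tol: float = 1e-6,
    max_iter: int = 200,
    inner_tol: float = 1e-8,
) -> FitResult:
    """Fit by EM, marginalizing dyads over their compatible triad cells.

    With no dyads present this is exactly :func:`fit_complete`.  Standard
    errors come from the observed-data information (see module docstring);
    the intercept row of the covariance is taken from the final M-step since
    the intercept is a pure normalizer.
    """
    if table.n_total <= 0:
        raise ValueError("empty count table")
    if table.n_md == 0 and table.n_fd == 0:
        fit = fit_complete(table.triad, design, tol=inner_tol)
        fit.n_md = 0.0
        fit.n_fd = 0.0
        return fit

    # init: allocate dyads uniformly over compatible cells
    y0 = table.triad + MD_AGG.T @ (table.md / MD_AGG.sum(axis=1)) + FD_AGG.T @ (
        table.fd / FD_AGG.sum(axis=1)
    )
    mfit = fit_complete(y0, design, tol=inner_tol)
    theta = mfit.theta
    ll = marginal_loglik(theta, table, design)
    trajectory = [ll]

    status = "max-iter"
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        yhat = _fractional_counts(theta, table, design)
        mfit = fit_complete(yhat, design, tol=inner_tol, theta0=theta)
        theta = mfit.theta
        new_ll = marginal_loglik(theta, table, design)
        trajectory.append(new_ll)
        if mfit.status in ("boundary", "rank-deficient"):
            status = mfit.status
            ll = new_ll
            break
        if abs(new_ll - ll) < tol:
            status = "converged"
            ll = new_ll
            break
        ll = new_ll

    cov: Optional[np.ndarray] = None
    boundary = mfit.boundary_coefficients
    if status == "converged":
        info = _marginal_information(theta, table, design)
        try:
            cov_sub = np.linalg.inv(info)
            cov = np.zeros((design.n_params, design.n_params))
            cov[1:, 1:] = cov_sub
            if mfit.covariance is not None:
                cov[0, 0] = mfit.covariance[0, 0]
            if np.diag(cov_sub).min() < 0:
                status = "rank-deficient"
                cov = None
        except np.linalg.LinAlgError:
            status = "rank-deficient"

    return FitResult(
        theta=theta,
        columns=design.columns,
        covariance=cov,
        loglik=ll,
        status=status,
        n_iter=n_iter,
        n_triads=table.n_triads,
        n_md=table.n_md,
        n_fd=table.n_fd,
        boundary_coefficients=boundary,
        em_trajectory=tuple(trajectory),
    )


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimate with 95% CI and two-sided Wald p-value."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float
    se_log: float = float("nan")


@dataclass
class ReportedEffects:
    """Relative risks derived from a fit, on the scale reported in output tables."""

    rr_fetal_single: Optional[EffectEstimate] = None
    rr_fetal_double: Optional[EffectEstimate] = None
    rr_interaction: Optional[EffectEstimate] = None
    a_diff: Optional[EffectEstimate] = None  # log scale, maternal minus paternal


def _wald_rr(est: float, se: float) -> EffectEstimate:
    z = est / se if se > 0 else math.inf * np.sign(est) if est else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    return EffectEstimate(
        estimate=float(np.exp(est)),
        ci_low=float(np.exp(est - Z975 * se)),
        ci_high=float(np.exp(est + Z975 * se)),
        p=float(p),
        se_log=se,
    )


def wald_effects(fit: FitResult) -> ReportedEffects:
    """Relative risks, 95% CIs and p-values for the identifiable effects.

    rr_fetal_single = exp(gamma_c); rr_fetal_double = exp(2*gamma_c +
    gamma_c12) with a delta-method SE; rr_interaction = exp(beta_mf);
    a_diff is reported on the log scale (only the maternal-paternal
    difference is identifiable).
    """
    if fit.covariance is None:
        raise ValueError(f"no covariance available (status={fit.status})")
    cols = list(fit.columns)
    out = ReportedEffects()

    if COL_GC in cols:
        out.rr_fetal_single = _wald_rr(fit.coef(COL_GC), fit.se(COL_GC))
    if COL_GC12 in cols:
        i, j = cols.index(COL_GC), cols.index(COL_GC12)
        est = 2.0 * fit.theta[i] + fit.theta[j]
        var = (
            4.0 * fit.covariance[i, i]
            + fit.covariance[j, j]
            + 4.0 * fit.covariance[i, j]
        )
        out.rr_fetal_double = _wald_rr(float(est), float(np.sqrt(max(var, 0.0))))
    if COL_BMF in cols:
        out.rr_interaction = _wald_rr(fit.coef(COL_BMF), fit.se(COL_BMF))

    i, j = cols.index(COL_AM), cols.index(COL_AF)
    est = float(fit.theta[i] - fit.theta[j])
    var = float(
        fit.covariance[i, i] + fit.covariance[j, j] - 2.0 * fit.covariance[i, j]
    )
    se = math.sqrt(max(var, 0.0))
    z = est / se if se > 0 else 0.0
    out.a_diff = EffectEstimate(
        estimate=est,
        ci_low=est - Z975 * se,
        ci_high=est + Z975 * se,
        p=float(2.0 * stats.norm.sf(abs(z))),
        se_log=se,
    )
    return out


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    p: float
    degenerate: bool = False


def hwe_test(n_rr: float, n_ra: float, n_aa: float) -> HWEResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    Arguments are genotype counts (reference homozygote, heterozygote,
    effect homozygote).  Monomorphic input gives chi2 = 0, p = 1 with the
    degenerate flag set.
    """
    n = n_rr + n_ra + n_aa
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    q = (2.0 * n_aa + n_ra) / (2.0 * n)
    if q <= 0.0 or q >= 1.0:
        return HWEResult(chi2=0.0, df=1, p=1.0, degenerate=True)
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
    observed = np.array([n_rr, n_ra, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, df=1)))


def lr_test(fit_full: FitResult, fit_reduced: FitResult) -> float:
    """Likelihood-ratio p-value for nested fits on the same data."""
    if not set(fit_reduced.columns) <= set(fit_full.columns):
        raise ValueError("fits are not nested")
    df = len(fit_full.columns) - len(fit_reduced.columns)
    if df == 0:
        return 1.0
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    return float(stats.chi2.sf(stat, df=df))
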