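"""Estimation of the proportion of true null hypotheses (pi0) and q-values.

This is the statistical kernel of the package.  Every downstream module
(the conditional overlap test, the rank-threshold scans, the simulation
study) reduces its question to "what fraction of this p-value collection
is truly null?", answered here with Storey's estimator

    pi0_hat(lambda) = #{p_i > lambda} / (m * (1 - lambda)),

where ``lambda`` is a tuning cutoff above which p-values are assumed to
come from truly null features.  Three rules for choosing lambda are
offered: the bootstrap mean-squared-error rule, a smoothing-spline
extrapolation, and a user-fixed lambda (useful when the p-value histogram
has artefacts, e.g. a bump in the middle, that mislead the automatic
rules).  q-values follow Storey's min-over-tail construction; with
pi0 = 1 they coincide with Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "SMALL_SET_WARN_THRESHOLD",
    "Pi0Estimate",
    "QValueTable",
    "estimate_pi0",
    "compute_qvalues",
]

#: Conventional lambda grid 0.05, 0.10, ..., 0.95.
DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)

#: Below this many p-values, pi0 estimation is flagged as unreliable.
SMALL_SET_WARN_THRESHOLD = 200


@dataclass(frozen=True)
class Pi0Estimate:
    """A pi0 estimate with its lambda diagnostics.

    Attributes
    ----------
    pi0, pi1 :
        Estimated proportions of true nulls / true non-nulls; always
        clamped so ``pi0 + pi1 == 1`` with ``pi0 in [0, 1]``.
    method :
        One of ``"bootstrap"``, ``"smoother"``, ``"fixed"``.
    lambda_grid :
        The lambda values at which the raw estimator was evaluated.
    pi0_at_lambda :
        Raw (pre-clamp) ``pi0_hat(lambda)`` values, retained for
        diagnostics; entries may exceed 1.
    selected_lambda :
        The lambda the bootstrap rule selected, or the fixed lambda;
        ``None`` for the smoother (which extrapolates, not selects).
    """

    pi0: float
    pi1: float
    method: str
    lambda_grid: np.ndarray = field(repr=False)
    pi0_at_lambda: np.ndarray = field(repr=False)
    selected_lambda: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValidationError(f"pi0 must lie in [0, 1], got {self.pi0}")
        if abs(self.pi0 + self.pi1 - 1.0) > 1e-12:
            raise ValidationError("pi0 + pi1 must equal 1")


@dataclass(frozen=True)
class QValueTable:
    """Per-feature q-values with significance calls at a fixed FDR level."""

    feature_ids: np.ndarray
    qvalues: np.ndarray
    significant: np.ndarray
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"qvalue": self.qvalues, "significant": self.significant},
            index=pd.Index(self.feature_ids, name="feature_id"),
        )

    @property
    def significant_ids(self) -> np.ndarray:
        return self.feature_ids[self.significant]


def _as_pvalue_array(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        raise ValidationError("p-value vector is empty")
    if np.any(np.isnan(p)) or np.any((p < 0.0) | (p > 1.0)):
        bad = p[~((p >= 0.0) & (p <= 1.0))]
        raise ValidationError(
            f"p-values must lie in [0, 1]; offending values include {bad[:5]}"
        )
    return p


def _raw_pi0_curve(p: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda)) for each lambda.

    Strict inequality; p-values exactly 0 or 1 are legitimate inputs.
    """
    m = p.size
    exceed = np.array([(p > lam).sum() for lam in grid], dtype=float)
    return exceed / (m * (1.0 - grid))


def _bootstrap_lambda(
    p: np.ndarray, grid: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Select lambda minimising the bootstrap MSE around the minimum raw pi0.

    Resampling the p-values with replacement and counting exceedances of
    each lambda is distributionally identical to drawing multinomial bin
    counts over the partition the grid induces on [0, 1]; the latter is
    what we draw, which keeps the bootstrap O(n_boot * n_lambda).
    """
    m = p.size
    raw = _raw_pi0_curve(p, grid)
    pi0_min = raw.min()

    # bin masses of the partition (-inf, l1], (l1, l2], ..., (lK, +inf)
    edges_counts = np.array([(p <= lam).sum() for lam in grid], dtype=float)
    bin_counts = np.diff(np.concatenate(([0.0], edges_counts, [float(m)])))
    probs = bin_counts / m

    draws = rng.multinomial(m, probs, size=n_boot)  # (n_boot, K+1)
    # exceedances of lambda_j = m - cumulative count through bin j
    cum = np.cumsum(draws[:, :-1], axis=1)
    pi0_boot = (m - cum) / (m * (1.0 - grid))
    mse = np.mean((pi0_boot - pi0_min) ** 2, axis=0)
    best = int(np.argmin(mse))
    return float(grid[best]), raw


def _smoother_pi0(grid: np.ndarray, raw: np.ndarray, target_df: float = 3.0) -> float:
    """Penalized cubic B-spline fit to (lambda, pi0_hat(lambda)),
    with the roughness penalty tuned so the effective degrees of freedom
    (trace of the hat matrix) equal ``target_df``; returns the fitted
    value at the largest lambda."""
    from scipy.interpolate import BSpline

    x = np.asarray(grid, dtype=float)
    y = np.asarray(raw, dtype=float)
    k = 3
    n_basis = min(x.size, 10)
    inner = np.linspace(x[0], x[-1], n_basis - k + 1)
    t = np.concatenate(([x[0]] * k, inner, [x[-1]] * k))
    B = BSpline.design_matrix(x, t, k).toarray()
    nb = B.shape[1]
    D = np.diff(np.eye(nb), n=2, axis=0)
    BtB, DtD = B.T @ B, D.T @ D

    def edf(log_rho: float) -> float:
        H = B @ np.linalg.solve(BtB + np.exp(log_rho) * DtD, B.T)
        return float(np.trace(H))

    lo, hi = -20.0, 30.0
    if edf(lo) <= target_df:  # even unpenalized fit is at/below target
        rho = np.exp(lo)
    else:
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if edf(mid) > target_df:
                lo = mid
            else:
                hi = mid
        rho = np.exp(0.5 * (lo + hi))

    coef = np.linalg.solve(BtB + rho * DtD, B.T @ y)
    return float(BSpline(t, coef, k)(x[-1]))


def estimate_pi0(
    pvals,
    method: str = "bootstrap",
    lambda_grid: Optional[Sequence[float]] = None,
    fixed_lambda: Optional[float] = None,
    n_boot: int = 100,
    seed: Optional[int] = None,
) -> Pi0Estimate:
    """Estimate the proportion of true null hypotheses in a p-value set.

    Parameters
    ----------
    pvals :
        The p-values (array-like, values in [0, 1]).
    method :
        ``"bootstrap"`` (default; lambda chosen by the bootstrap MSE
        rule), ``"smoother"`` (spline extrapolation to the largest
        lambda), or ``"fixed"`` (evaluate at ``fixed_lambda``).
    lambda_grid :
        Strictly increasing lambdas in (0, 1); defaults to
        0.05, 0.10, ..., 0.95.
    fixed_lambda :
        Required for ``method="fixed"``; must lie in (0, 1).
    n_boot :
        Bootstrap resamples for the lambda-selection rule.
    seed :
        Seed for the bootstrap resampling; irrelevant for the other
        methods.

    Returns
    -------
    Pi0Estimate
        With ``pi0`` clamped to [0, 1] and the raw per-lambda curve
        retained in ``pi0_at_lambda``.
    """
    p = _as_pvalue_array(pvals)
    m = p.size
    if m < SMALL_SET_WARN_THRESHOLD:
        warnings.warn(
            f"pi0 estimated from only {m} p-values; estimates of the "
            "proportion of truly differential features can be unreliable "
            "for small sets — inspect the p-value histogram.",
            UserWarning,
            stacklevel=2,
        )

    if method == "fixed":
        if fixed_lambda is None or not (0.0 < fixed_lambda < 1.0):
            raise ValidationError(
                f"method='fixed' requires fixed_lambda in (0, 1), got {fixed_lambda}"
            )
        grid = np.array([fixed_lambda], dtype=float)
        raw = _raw_pi0_curve(p, grid)
        pi0 = float(np.clip(raw[0], 0.0, 1.0))
        return Pi0Estimate(pi0, 1.0 - pi0, "fixed", grid, raw, float(fixed_lambda))

    if method not in ("bootstrap", "smoother"):
        raise ValidationError(f"unknown pi0 method {method!r}")

    grid = (
        DEFAULT_LAMBDA_GRID.copy()
        if lambda_grid is None
        else np.asarray(lambda_grid, dtype=float)
    )
    if grid.size == 0:
        raise ValidationError("lambda_grid must be non-empty")
    if np.any((grid <= 0.0) | (grid >= 1.0)) or np.any(np.diff(grid) <= 0):
        raise ValidationError("lambda_grid must be strictly increasing within (0, 1)")
    if np.unique(p).size < 2:
        raise ValidationError(
            "fewer than 2 distinct p-values: the bootstrap/smoother lambda "
            "rules are undefined; use method='fixed' with an explicit lambda"
        )

    if method == "bootstrap":
        if n_boot < 1:
            raise ValidationError("n_boot must be a positive integer")
        rng = np.random.default_rng(seed)
        lam_star, raw = _bootstrap_lambda(p, grid, n_boot, rng)
        raw_at = raw[np.flatnonzero(grid == lam_star)[0]]
        pi0 = float(np.clip(raw_at, 0.0, 1.0))
        return Pi0Estimate(pi0, 1.0 - pi0, "bootstrap", grid, raw, lam_star)

    raw = _raw_pi0_curve(p, grid)
    pi0 = float(np.clip(_smoother_pi0(grid, raw), 0.0, 1.0))
    return Pi0Estimate(pi0, 1.0 - pi0, "smoother", grid, raw, None)


def compute_qvalues(
    pvals,
    pi0: float,
    alpha: float = 0.1,
    feature_ids: Optional[Sequence] = None,
) -> QValueTable:
    """Storey q-values: q(i) = min_{j >= i} pi0 * m * p(j) / j.

    ``pvals`` are sorted ascending (ties broken stably by feature id),
    the min-over-tail is taken, and results are mapped back to the input
    order.  ``significant`` flags mark q < ``alpha``.
    """
    p = _as_pvalue_array(pvals)
    m = p.size
    if not (0.0 <= pi0 <= 1.0):
        raise ValidationError(f"pi0 must lie in [0, 1], got {pi0}")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if feature_ids is None:
        ids = np.arange(m)
    else:
        ids = np.asarray(feature_ids)
        if ids.size != m:
            raise ValidationError("feature_ids and p-values must align 1:1")
        if pd.Index(ids).has_duplicates:
            raise ValidationError("feature_ids must be unique")

    order = np.lexsort((ids, p))  # ascending p, ties stably by id
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)

    q = np.empty(m)
    q[order] = q_sorted
    sig = q < alpha
    return QValueTable(ids, q, sig, alpha)
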