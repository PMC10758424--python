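"""Comparison methods: Granger causality and sparse partial correlation.

Granger causality (GC) fits an order-1 multivariate autoregressive (MVAR)
model and scores each ordered region pair ``i -> j`` by the log
likelihood-ratio ``ln(sigma^2_restricted / sigma^2_full)`` — how much the
residual variance of ``j``'s equation grows when ``i``'s lags are excluded.
Edges are the statistics above a percentile of the subject's own
off-diagonal statistic distribution (default: 95th).

Sparse partial correlation (SPC) is the undirected associative-connectivity
baseline: an L1-penalised (graphical-lasso) precision-matrix estimate with
the penalty chosen by k-fold cross-validated held-out Gaussian
log-likelihood, reported as partial correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .errors import CollinearityError, DegenerateDataError
from .graphs import RolledCFC
from .timeseries import ROITimeSeries

__all__ = [
    "MVARModel",
    "GCResult",
    "SPCResult",
    "fit_mvar",
    "gc_statistics",
    "threshold_gc",
    "graphical_lasso_fit",
    "cv_select_lambda",
]

#: Off-diagonal precision entries below this magnitude count as zero.
PRECISION_ZERO_TOL = 1e-8


@dataclass(frozen=True)
class MVARModel:
    """Least-squares multivariate autoregressive fit.

    ``coeff[k]`` is the region x region coefficient matrix at lag ``k+1``
    with entry ``(i, j)`` = effect of region ``i`` at lag ``k+1`` on region
    ``j`` now; ``intercept`` per equation; ``innovation_cov`` the residual
    covariance.
    """

    order: int
    coeff: np.ndarray  # (order, n, n)
    intercept: np.ndarray  # (n,)
    innovation_cov: np.ndarray  # (n, n)
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        cov = np.asarray(self.innovation_cov)
        if not np.allclose(cov, cov.T):
            raise ValueError("innovation_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("innovation_cov must be positive definite")


@dataclass(frozen=True)
class GCResult:
    """Granger likelihood-ratio statistics with a percentile threshold."""

    stat: np.ndarray  # (n, n), diagonal NaN
    threshold: float
    percentile: float
    region_labels: tuple[str, ...]

    @property
    def graph(self) -> RolledCFC:
        """Unweighted directed graph: edges where stat strictly exceeds
        the threshold (unit weights)."""
        labels = self.region_labels
        edges = {}
        n = len(labels)
        for i in range(n):
            for j in range(n):
                if i != j and self.stat[i, j] > self.threshold:
                    edges[(labels[i], labels[j])] = 1.0
        return RolledCFC(labels, edges)


@dataclass(frozen=True)
class SPCResult:
    """Graphical-lasso precision estimate as a partial-correlation network."""

    precision: np.ndarray
    partial_corr: np.ndarray
    lambda_selected: float
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.allclose(self.precision, self.precision.T, atol=1e-8):
            raise ValueError("precision must be symmetric")

    @property
    def graph(self) -> RolledCFC:
        """Symmetric weighted graph: both orientations of each pair with
        nonzero off-diagonal precision, weighted by partial correlation."""
        labels = self.region_labels
        n = len(labels)
        edges = {}
        for i in range(n):
            for j in range(i + 1, n):
                if abs(self.precision[i, j]) > PRECISION_ZERO_TOL:
                    w = float(self.partial_corr[i, j])
                    edges[(labels[i], labels[j])] = w
                    edges[(labels[j], labels[i])] = w
        return RolledCFC(labels, edges)


# ---------------------------------------------------------------------------
# Granger causality


def _lagged_design(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    T, n = x.shape
    y = x[order:]
    blocks = [np.ones((T - order, 1))]
    for k in range(1, order + 1):
        blocks.append(x[order - k : T - k])
    return np.hstack(blocks), y


def fit_mvar(ts: ROITimeSeries, order: int = 1) -> MVARModel:
    """Per-equation least-squares fit of an MVAR(order) model."""
    if order < 1:
        raise ValueError("order must be >= 1")
    T, n = ts.values.shape
    if T <= order * n + 10:
        raise ValueError(
            f"series length {T} too short for MVAR({order}) on {n} regions; "
            f"need > {order * n + 10}"
        )
    X, Y = _lagged_design(ts.values, order)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("rank-deficient MVAR regressor matrix")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    cov = resid.T @ resid / dof
    coeff = np.empty((order, n, n))
    for k in range(order):
        # rows of beta after the intercept: lag-(k+1) block, source-indexed
        coeff[k] = beta[1 + k * n : 1 + (k + 1) * n, :]
    return MVARModel(order, coeff, beta[0], cov, ts.region_labels)


def gc_statistics(ts: ROITimeSeries, order: int = 1) -> np.ndarray:
    """Granger log likelihood-ratio statistic for every ordered pair.

    ``stat[i, j] = ln(sigma^2_j(restricted: i's lags omitted) /
    sigma^2_j(full))``; nonnegative up to numerical noise, diagonal NaN.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    T, n = ts.values.shape
    if T <= order * n + 10:
        raise ValueError(f"series length {T} too short for GC at order {order}")
    X, Y = _lagged_design(ts.values, order)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("rank-deficient MVAR regressor matrix")
    nobs = X.shape[0]

    def rss_per_equation(design: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
        resid = Y - design @ beta
        return (resid**2).sum(axis=0)

    rss_full = rss_per_equation(X)
    stat = np.full((n, n), np.nan)
    for i in range(n):
        keep = [0] + [
            1 + k * n + s for k in range(order) for s in range(n) if s != i
        ]
        rss_restr = rss_per_equation(X[:, keep])
        for j in range(n):
            if j == i:
                continue
            if rss_full[j] <= 0:
                raise DegenerateDataError(
                    f"zero full-model residual variance for region "
                    f"{ts.region_labels[j]!r}"
                )
            stat[i, j] = max(0.0, math.log(rss_restr[j] / rss_full[j]))
    return stat


def threshold_gc(
    stat: np.ndarray,
    percentile: float = 95.0,
    region_labels: Sequence[str] | None = None,
) -> GCResult:
    """Threshold a GC statistic matrix at a percentile of its own
    off-diagonal distribution.

    Edges are the ordered pairs whose statistic *strictly* exceeds the
    empirical percentile, so with ``N`` regions and no ties exactly
    ``ceil((1 - p/100) * N * (N - 1))`` edges are retained; all-equal
    statistics yield an empty graph.
    """
    stat = np.asarray(stat, dtype=float)
    n = stat.shape[0]
    if stat.shape != (n, n):
        raise ValueError("stat must be square")
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    if region_labels is None:
        region_labels = tuple(f"R{i + 1:02d}" for i in range(n))
    off = stat[~np.eye(n, dtype=bool)]
    off = off[np.isfinite(off)]
    if off.size == 0:
        raise ValueError("no finite off-diagonal statistics")
    thr = float(np.percentile(off, percentile))
    return GCResult(stat, thr, percentile, tuple(region_labels))


# ---------------------------------------------------------------------------
# sparse partial correlation


def graphical_lasso_fit(
    sample_cov: np.ndarray, lam: float, max_iter: int = 500, tol: float = 1e-3
) -> np.ndarray:
    """L1-penalised precision estimate (off-diagonal penalty ``lam``).

    Maximises ``log det Theta - tr(S Theta) - lam * ||Theta||_1(offdiag)``.
    ``lam = 0`` returns the unpenalised MLE ``S^{-1}`` and requires a
    positive-definite ``S``.  ``tol`` is the duality-gap stopping tolerance
    of the coordinate-descent solver (1e-3 is ample for deciding edge
    support); exceeding ``max_iter`` without reaching it raises.
    """
    S = np.asarray(sample_cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("sample_cov must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("sample_cov must be symmetric")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        if np.any(np.linalg.eigvalsh(S) <= 0):
            raise DegenerateDataError(
                "singular sample covariance; lam = 0 needs positive-definite S"
            )
        theta = np.linalg.inv(S)
        return (theta + theta.T) / 2
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            _, theta = _sk_graphical_lasso(S, alpha=lam, max_iter=max_iter, tol=tol)
        except ConvergenceWarning as exc:
            raise DegenerateDataError(
                f"graphical lasso did not converge within {max_iter} "
                f"iterations at lam={lam}: {exc}"
            ) from None
    return (theta + theta.T) / 2


def _partial_corr_from_precision(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def _centered_cov(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    return xc.T @ xc / x.shape[0]


def cv_select_lambda(
    ts: ROITimeSeries,
    grid: Sequence[float],
    k_folds: int = 5,
) -> tuple[float, SPCResult]:
    """Choose the graphical-lasso penalty by k-fold cross-validation.

    Folds are contiguous time blocks (respecting serial dependence); the
    score is the held-out Gaussian log-likelihood ``log det Theta -
    tr(S_test Theta)`` under the training-fold precision, averaged over
    folds.  The selected penalty (ties favour the larger, sparser lam) is
    refit on all samples.
    """
    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    x = ts.values
    T, n = x.shape
    bounds = np.linspace(0, T, k_folds + 1).astype(int)
    if np.min(np.diff(bounds)) <= n:
        raise DegenerateDataError(
            f"fold of {np.min(np.diff(bounds))} samples too small to form a "
            f"covariance over {n} regions"
        )
    scores = np.zeros(len(grid))
    for f in range(k_folds):
        test = np.zeros(T, dtype=bool)
        test[bounds[f] : bounds[f + 1]] = True
        S_train = _centered_cov(x[~test])
        S_test = _centered_cov(x[test])
        for g, lam in enumerate(grid):
            theta = graphical_lasso_fit(S_train, lam)
            sign, logdet = np.linalg.slogdet(theta)
            if sign <= 0:
                scores[g] = -np.inf
                continue
            scores[g] += logdet - float(np.sum(S_test * theta))
    best = int(np.argmax(scores[::-1]))  # ties -> larger lam
    lam_star = grid[len(grid) - 1 - best]
    theta = graphical_lasso_fit(_centered_cov(x), lam_star)
    result = SPCResult(
        precision=theta,
        partial_corr=_partial_corr_from_precision(theta),
        lambda_selected=lam_star,
        region_labels=ts.region_labels,
    )
    return lam_star, result
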