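"""Constrained minimum-variance (kriging) prediction of log-rates.

The predictor at a target locality is a weighted average of the observed
area log-rates, theta_0 = sum_i w_i theta_i with sum_i w_i = 1, the weights
obtained from the bordered linear system

    [ A   1 ] [ w ]   [ c0 ]
    [ 1^T 0 ] [ l ] = [ 1  ]

where the off-diagonal entries of A are the covariances C(D_ij) between
areas, the right-hand side carries the covariances C(D_i0) to the target,
and l is the Lagrange multiplier enforcing the sum-to-one constraint.
The diagonal of A distinguishes three flavors:

* ``stabilized``      — tau^2 + v_i: each area's sampling variance enters,
  so unreliable (small-population) areas are down-weighted and a
  zero-case area (v = inf) drops out with weight exactly 0;
* ``traditional``     — tau^2: homoscedastic ordinary kriging, which
  interpolates the observed values exactly at the area centroids when the
  nugget is zero;
* ``nugget_adjusted`` — tau^2 + nugget: every area smoothed by the same
  amount regardless of population.

Areas with infinite variance are removed from the system outright — the
exact limit of v -> inf — rather than approximated by a large variance.
The bordered matrix is symmetric indefinite; it is factorized once (dense
LU with partial pivoting) and reused across all targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .geometry import Mesh, pairwise_distance
from .laa_data import LAATable
from .semivariogram import CovarianceModel

__all__ = ["KrigingWeights", "KrigingSolution", "solve_weights", "predict", "predict_grid"]

FLAVORS = ("stabilized", "traditional", "nugget_adjusted")


@dataclass
class KrigingWeights:
    weights: np.ndarray
    lambda_: float
    contributing_ids: list[str]


@dataclass
class KrigingSolution:
    point: tuple[float, float]
    weights: KrigingWeights
    log_rate: float

    @property
    def rate(self) -> float:
        return float(np.exp(self.log_rate))


class SingularSystemError(RuntimeError):
    pass


def _diagonal(flavor: str, tau2: float, v: np.ndarray, nugget: float) -> np.ndarray:
    if flavor == "stabilized":
        return tau2 + v
    if flavor == "traditional":
        return np.full_like(v, tau2)
    if flavor == "nugget_adjusted":
        return np.full_like(v, tau2 + nugget)
    raise ValueError(f"unknown flavor {flavor!r}; choose from {FLAVORS}")


def _build_system(
    table: LAATable,
    model: CovarianceModel,
    flavor: str,
    pairwise: np.ndarray | None,
    metric: str,
):
    """Bordered matrix over the finite-variance areas, LU-factorized."""
    mask = table.usable
    m = int(mask.sum())
    if m == 0:
        raise ValueError("no areas with defined log-rate and finite variance")
    idx = np.where(mask)[0]
    coords = table.coords[idx]
    theta = table.log_rates[idx]
    v = table.variances[idx]
    ids = [table.area_ids[i] for i in idx]

    if pairwise is None:
        D = pairwise_distance(coords, coords, metric=metric)
    else:
        D = np.asarray(pairwise, dtype=float)[np.ix_(idx, idx)]

    A = np.empty((m + 1, m + 1))
    A[:m, :m] = model(D)
    np.fill_diagonal(
        A[:m, :m], _diagonal(flavor, model.tau2, v, model.variogram.nugget)
    )
    A[m, :m] = 1.0
    A[:m, m] = 1.0
    A[m, m] = 0.0

    sill = model.variogram.sill
    factor = _factor_with_jitter(A, m, sill, ids)
    return factor, coords, theta, ids, idx


def _factor_with_jitter(A: np.ndarray, m: int, sill: float, ids: list[str]):
    cond = _condition(A)
    if cond < 1e12:
        return lu_factor(A)
    # A condition number near 1/eps means the system is singular in floating
    # point — typically duplicate representative points with equal diagonal
    # entries — and must surface rather than be papered over.
    if not np.isfinite(cond) or cond > 1e15:
        raise SingularSystemError(
            f"singular kriging system (duplicate points among areas {ids}?)"
        )
    jitter = 1e-10 * max(sill, 1.0)
    Aj = A.copy()
    Aj[np.arange(m), np.arange(m)] += jitter
    warnings.warn("near-singular kriging system; added diagonal jitter once")
    if _condition(Aj) > 1e12:
        raise SingularSystemError(
            f"kriging system still ill-conditioned after jitter (areas {ids})"
        )
    return lu_factor(Aj)


def _condition(A: np.ndarray) -> float:
    try:
        return float(np.linalg.cond(A))
    except np.linalg.LinAlgError:
        return np.inf


def solve_weights(
    table: LAATable,
    model: CovarianceModel,
    target,
    flavor: str = "stabilized",
    distances_to_target: np.ndarray | None = None,
    pairwise: np.ndarray | None = None,
    metric: str = "euclidean",
) -> KrigingWeights:
    """Kriging weights for one target point.

    ``distances_to_target`` (length = number of table rows) and ``pairwise``
    (full table-row matrix) may be precomputed; otherwise they are derived
    from coordinates with ``metric``.  Areas with infinite variance carry no
    weight entry (their weight is identically zero).
    """
    factor, coords, _, ids, idx = _build_system(table, model, flavor, pairwise, metric)
    if distances_to_target is not None:
        d0 = np.asarray(distances_to_target, dtype=float)[idx]
    else:
        tx, ty = (target.x, target.y) if hasattr(target, "x") else target
        d0 = pairwise_distance(coords, np.array([[tx, ty]]), metric=metric)[:, 0]
    m = len(ids)
    rhs = np.empty(m + 1)
    rhs[:m] = model(d0)
    rhs[m] = 1.0
    sol = lu_solve(factor, rhs)
    point = (target.x, target.y) if hasattr(target, "x") else tuple(target)
    return KrigingWeights(weights=sol[:m], lambda_=float(sol[m]), contributing_ids=ids)


def predict_grid(
    table: LAATable,
    model: CovarianceModel,
    target_points: np.ndarray,
    flavor: str = "stabilized",
    metric: str = "euclidean",
    pairwise: np.ndarray | None = None,
    distances_to_targets: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted log-rates at an ``(n, 2)`` array of targets (vectorized).

    The bordered system is factorized once; all right-hand sides are solved
    in a single call, so results are identical to per-target solves up to
    the solver's deterministic arithmetic.
    """
    factor, coords, theta, ids, idx = _build_system(table, model, flavor, pairwise, metric)
    target_points = np.asarray(target_points, dtype=float)
    if distances_to_targets is not None:
        D0 = np.asarray(distances_to_targets, dtype=float)[idx]
    else:
        D0 = pairwise_distance(coords, target_points, metric=metric)
    m = len(ids)
    RHS = np.empty((m + 1, target_points.shape[0]))
    RHS[:m] = model(D0)
    RHS[m] = 1.0
    W = lu_solve(factor, RHS)
    return theta @ W[:m]


def predict(
    table: LAATable,
    model: CovarianceModel,
    targets,
    flavor: str = "stabilized",
    metric: str = "euclidean",
    pairwise: np.ndarray | None = None,
) -> list[KrigingSolution]:
    """One :class:`KrigingSolution` per target point.

    ``targets`` is a :class:`Mesh` (all points, inside or not) or a sequence
    of points / ``(x, y)`` pairs.
    """
    if isinstance(targets, Mesh):
        pts = targets.points
    else:
        pts = np.array(
            [(p.x, p.y) if hasattr(p, "x") else tuple(p) for p in targets], dtype=float
        )
    factor, coords, theta, ids, idx = _build_system(table, model, flavor, pairwise, metric)
    D0 = pairwise_distance(coords, pts, metric=metric)
    m = len(ids)
    RHS = np.empty((m + 1, pts.shape[0]))
    RHS[:m] = model(D0)
    RHS[m] = 1.0
    W = lu_solve(factor, RHS)
    out = []
    for j in range(pts.shape[0]):
        kw = KrigingWeights(
            weights=W[:m, j], lambda_=float(W[m, j]), contributing_ids=ids
        )
        out.append(
            KrigingSolution(
                point=(float(pts[j, 0]), float(pts[j, 1])),
                weights=kw,
                log_rate=float(theta @ W[:m, j]),
            )
        )
    return out
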