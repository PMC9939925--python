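"""Semivariogram construction, spherical model fitting, covariance readout.

For m areas with defined log-rates there are m(m-1)/2 cloud points
(D_ij, (theta_i - theta_j)^2 / 2).  A spherical model

    gamma(h) = c0 + c * (1.5 h/a - 0.5 (h/a)^3)   for 0 < h <= a
    gamma(h) = c0 + c                              for h > a
    gamma(0) = 0

is fitted by constrained least squares (nugget c0 >= 0, partial sill c >= 0,
range a > 0).  The covariance function is the sill minus the semivariance,
and its value at distance zero is the random-effects variance tau^2.

Because the fitted model is discontinuous at the origin when c0 > 0, tau^2
is read off as sill - gamma(0) = c0 + c, i.e. the nugget contributes to the
between-area variance.  The alternative convention tau^2 = c (partial sill
only) is available via ``tau2="partial_sill"`` for sensitivity analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .laa_data import LAATable

__all__ = [
    "SemivarianceCloud",
    "SphericalVariogram",
    "CovarianceModel",
    "build_cloud",
    "fit_spherical",
    "covariance_at",
    "VariogramFitError",
]


class VariogramFitError(RuntimeError):
    """Raised when the spherical fit is impossible or fails to converge."""


@dataclass
class SemivarianceCloud:
    distances: np.ndarray
    semivariances: np.ndarray
    n_areas: int

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.semivariances = np.asarray(self.semivariances, dtype=float)
        if self.distances.shape != self.semivariances.shape:
            raise ValueError("distances and semivariances must align")

    def __len__(self) -> int:
        return self.distances.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"distance": self.distances, "semivariance": self.semivariances}
        )


@dataclass(frozen=True)
class SphericalVariogram:
    """Fitted spherical semivariance model."""

    nugget: float
    partial_sill: float
    range_: float
    fit_mode: str = "cloud"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError(
                "require nugget >= 0, partial_sill >= 0, range > 0; got "
                f"({self.nugget}, {self.partial_sill}, {self.range_})"
            )

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h) -> np.ndarray | float:
        """Semivariance gamma(h); gamma(0) = 0 exactly."""
        h = np.asarray(h, dtype=float)
        if np.any(h < 0):
            raise ValueError("distance must be non-negative")
        u = np.minimum(h / self.range_, 1.0)
        g = self.nugget + self.partial_sill * (1.5 * u - 0.5 * u**3)
        g = np.where(h == 0.0, 0.0, g)
        return g if g.ndim else float(g)


@dataclass(frozen=True)
class CovarianceModel:
    """Covariance induced by a variogram: C(h) = sill - gamma(h).

    ``tau2_mode`` controls the distance-zero readout: ``"sill"`` gives
    tau^2 = nugget + partial sill (the default), ``"partial_sill"`` gives
    tau^2 = partial sill.
    """

    variogram: SphericalVariogram
    tau2_mode: str = "sill"

    def __post_init__(self) -> None:
        if self.tau2_mode not in ("sill", "partial_sill"):
            raise ValueError(f"unknown tau2_mode {self.tau2_mode!r}")

    @property
    def tau2(self) -> float:
        if self.tau2_mode == "sill":
            return self.variogram.sill
        return self.variogram.partial_sill

    def __call__(self, h) -> np.ndarray | float:
        h = np.asarray(h, dtype=float)
        if np.any(h < 0):
            raise ValueError("distance must be non-negative")
        c = self.variogram.sill - self.variogram(h)
        c = np.where(h == 0.0, self.tau2, c)
        return c if c.ndim else float(c)

    def to_json(self) -> str:
        v = self.variogram
        return json.dumps(
            {
                "nugget": v.nugget,
                "partial_sill": v.partial_sill,
                "range": v.range_,
                "sill": v.sill,
                "tau2": self.tau2,
                "tau2_mode": self.tau2_mode,
                "fit_mode": v.fit_mode,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CovarianceModel":
        d = json.loads(text)
        v = SphericalVariogram(
            nugget=d["nugget"],
            partial_sill=d["partial_sill"],
            range_=d["range"],
            fit_mode=d.get("fit_mode", "cloud"),
        )
        return cls(variogram=v, tau2_mode=d.get("tau2_mode", "sill"))


def covariance_at(model: CovarianceModel, h) -> np.ndarray | float:
    """Covariance at distance ``h`` (functional form of ``model(h)``)."""
    return model(h)


def build_cloud(table: LAATable, distances: np.ndarray) -> SemivarianceCloud:
    """Semivariance cloud over all pairs of areas with defined log-rates.

    ``distances`` is the full pairwise matrix over the table's rows; rows
    with undefined log-rate (zero cases) are dropped before pairing.
    """
    mask = table.usable
    m = int(mask.sum())
    if m < 2:
        raise ValueError(f"need at least 2 areas with defined log-rates, got {m}")
    theta = table.log_rates[mask]
    D = np.asarray(distances, dtype=float)[np.ix_(mask, mask)]
    iu = np.triu_indices(m, k=1)
    return SemivarianceCloud(
        distances=D[iu],
        semivariances=0.5 * (theta[iu[0]] - theta[iu[1]]) ** 2,
        n_areas=m,
    )


def _bin_cloud(
    cloud: SemivarianceCloud, n_bins: int, max_dist_fraction: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equal-width bin means up to a fraction of the max pairwise distance."""
    dmax = cloud.distances.max() * max_dist_fraction
    edges = np.linspace(0.0, dmax, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, cloud.distances, side="right") - 1, 0, n_bins - 1)
    keep = cloud.distances <= dmax
    d, g, w = [], [], []
    for b in range(n_bins):
        sel = keep & (idx == b)
        if sel.any():
            d.append(cloud.distances[sel].mean())
            g.append(cloud.semivariances[sel].mean())
            w.append(sel.sum())
    return np.array(d), np.array(g), np.array(w, dtype=float)


def _spherical_basis(h: np.ndarray, a: float) -> np.ndarray:
    u = np.minimum(h / a, 1.0)
    return 1.5 * u - 0.5 * u**3


def fit_spherical(
    cloud: SemivarianceCloud,
    binning: str = "binned",
    n_bins: int = 15,
    max_dist_fraction: float = 0.5,
    n_starts: int = 24,
) -> SphericalVariogram:
    """Fit a spherical model to a semivariance cloud.

    ``binning="cloud"`` does unweighted least squares on every pair;
    ``"binned"`` (the robust default for real data) uses equal-width bin
    means up to ``max_dist_fraction`` of the maximum distance, weighted by
    bin pair counts.

    The range parameter creates local minima, so the fit profiles it: for
    each of ``n_starts`` candidate ranges (log-spaced between the smallest
    and largest nonzero distance) the nugget and partial sill are the exact
    solution of a 2-parameter non-negative linear least-squares problem;
    the best profile point then seeds one bounded trust-region polish over
    all three parameters.  Ties are broken by residual sum of squares, then
    by the smaller range.  Deterministic for given inputs (and invariant to
    pair order, since only sums over pairs enter).
    """
    if len(cloud) == 0:
        raise VariogramFitError("empty semivariance cloud")
    if binning == "cloud":
        h, g, w = cloud.distances, cloud.semivariances, np.ones(len(cloud))
    elif binning == "binned":
        if n_bins < 3:
            raise ValueError("n_bins must be >= 3")
        h, g, w = _bin_cloud(cloud, n_bins, max_dist_fraction)
    else:
        raise ValueError(f"unknown binning {binning!r}")

    if np.allclose(g, 0.0):
        # All usable log-rates identical: flat cloud at zero.
        warnings.warn("all semivariances are zero; returning a degenerate flat model")
        return SphericalVariogram(
            nugget=0.0,
            partial_sill=0.0,
            range_=float(cloud.distances.max()),
            fit_mode=binning,
            degenerate=True,
        )

    hpos = h[h > 0]
    if hpos.size == 0 or np.ptp(h) == 0.0:
        raise VariogramFitError("all pairwise distances identical; range unidentifiable")

    sw = np.sqrt(w)

    def profile(a: float) -> tuple[float, float, float]:
        """Best (c0, c) >= 0 for fixed range, and the weighted RSS."""
        f = _spherical_basis(h, a)
        X = np.column_stack([np.ones_like(h), f]) * sw[:, None]
        y = g * sw
        # 2-var NNLS by case analysis of the unconstrained solution
        sol, *_ = np.linalg.lstsq(X, y, rcond=None)
        c0, c = sol
        if c0 < 0 or c < 0:
            cands = []
            fc = float(f @ (w * g)) / max(float(f @ (w * f)), 1e-300)
            cands.append((0.0, max(fc, 0.0)))
            cands.append((max(float(np.average(g, weights=w)), 0.0), 0.0))
            best = min(
                cands, key=lambda p: float(w @ (g - p[0] - p[1] * f) ** 2)
            )
            c0, c = best
        rss = float(w @ (g - c0 - c * f) ** 2)
        return c0, c, rss

    a_grid = np.geomspace(hpos.min(), h.max(), n_starts)
    prof = [(a, *profile(a)) for a in a_grid]
    a0, c00, c_0, rss0 = min(prof, key=lambda t: (t[3], t[0]))

    def resid(p: np.ndarray) -> np.ndarray:
        c0p, cp, ap = p
        return sw * (c0p + cp * _spherical_basis(h, ap) - g)

    tiny = 1e-12
    res = least_squares(
        resid,
        x0=[max(c00, 0.0), max(c_0, tiny), max(a0, tiny)],
        bounds=([0.0, 0.0, hpos.min() * 1e-3], [np.inf, np.inf, h.max() * 1e3]),
        method="trf",
    )
    if not res.success:
        raise VariogramFitError(f"spherical fit did not converge: {res.message}")
    c0f, cf, af = res.x
    rss_f = float(res.cost * 2)
    if rss_f > rss0 + 1e-12:  # polish should never be worse than its seed
        c0f, cf, af = max(c00, 0.0), max(c_0, 0.0), a0
    return SphericalVariogram(
        nugget=float(c0f),
        partial_sill=float(cf),
        range_=float(af),
        fit_mode=binning,
    )
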