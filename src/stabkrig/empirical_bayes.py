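"""Empirical-Bayes comparators: DerSimonian-Laird and Poisson-gamma shrinkage.

Two families, each usable globally or locally:

* Distribution-free (DerSimonian-Laird): the area log-rates theta_i are
  treated as draws from a prior with mean mu and variance tau^2, estimated
  by the DL moment method from the (theta_i, v_i) pairs; the posterior
  log-rate is the precision-weighted average of theta_i and mu.
* Poisson-gamma: true rates r_i ~ Gamma(shape alpha, rate nu), counts
  d_i ~ Poisson(p_i r_i); marginally d_i is negative binomial, (alpha, nu)
  are fitted by maximum likelihood, and the conjugate posterior mean rate
  is (d_i + alpha) / (p_i + nu).

"Local" variants re-estimate the hyperparameters for each area from that
area plus its k nearest neighbours (centroid distance; default k = 15) and
keep only the centre area's stabilized value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .geometry import pairwise_distance
from .laa_data import LAATable

__all__ = [
    "RandomEffectsEstimate",
    "PoissonGammaEstimate",
    "dl_estimate",
    "pg_estimate",
    "local_estimate",
    "EBFitError",
]


class EBFitError(RuntimeError):
    pass


@dataclass
class RandomEffectsEstimate:
    """DL fit: prior (mu, tau^2) plus per-area posterior log-rates.

    ``posterior_log_rates`` aligns with the full table (zero-case areas get
    the fully shrunk value mu); ``shrinkage`` is B_i = v_i / (v_i + tau^2),
    equal to 1 for infinite-variance areas.
    """

    mu: float
    tau2: float
    posterior_log_rates: np.ndarray
    shrinkage: np.ndarray

    @property
    def posterior_rates(self) -> np.ndarray:
        return np.exp(self.posterior_log_rates)


@dataclass
class PoissonGammaEstimate:
    """Gamma(shape alpha, rate nu) prior fitted by marginal ML."""

    alpha: float
    nu: float
    posterior_rates: np.ndarray

    @property
    def prior_mean(self) -> float:
        return self.alpha / self.nu


def _dl_fit(theta: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """DL moment estimate (mu, tau2) from defined log-rates with finite v."""
    m = theta.size
    wi = 1.0 / v
    s1 = wi.sum()
    mu_fe = float((wi * theta).sum() / s1)
    q = float((wi * (theta - mu_fe) ** 2).sum())
    s2 = (wi**2).sum()
    denom = s1 - s2 / s1
    tau2 = max(0.0, (q - (m - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (v + tau2)
    mu = float((w_re * theta).sum() / w_re.sum())
    return mu, tau2


def dl_estimate(table: LAATable) -> RandomEffectsEstimate:
    """DerSimonian-Laird moment estimate and posterior log-rates.

    mu_FE = sum(theta/v) / sum(1/v);  Q = sum((theta - mu_FE)^2 / v);
    tau2 = max(0, (Q - (m-1)) / (S1 - S2/S1)) with S1 = sum(1/v),
    S2 = sum(1/v^2); mu is then re-estimated with weights 1/(v + tau2).
    Posterior: theta_i weighted with mu by precisions 1/v_i and 1/tau2;
    when tau2 = 0 every area is fully shrunk to mu.
    """
    mask = table.usable
    m = int(mask.sum())
    if m < 2:
        raise EBFitError(f"DerSimonian-Laird needs >= 2 usable areas, got {m}")
    theta = table.log_rates[mask]
    v = table.variances[mask]
    mu, tau2 = _dl_fit(theta, v)

    n = len(table)
    post = np.full(n, mu)
    shrink = np.ones(n)
    if tau2 > 0:
        prec_data = 1.0 / v
        prec_prior = 1.0 / tau2
        post_usable = (theta * prec_data + mu * prec_prior) / (prec_data + prec_prior)
        post[mask] = post_usable
        shrink[mask] = v / (v + tau2)
    return RandomEffectsEstimate(
        mu=mu, tau2=tau2, posterior_log_rates=post, shrinkage=shrink
    )


def _nb_negloglik_grad(logab: np.ndarray, d: np.ndarray, p: np.ndarray):
    """Negative log-likelihood of the gamma-Poisson marginal and its gradient.

    Marginally d_i ~ NegBin: log L_i = ln G(d+a) - ln G(a) + a ln nu
    - (d+a) ln(nu+p) + d ln p (+ const); gradient in (ln a, ln nu) by the
    chain rule.
    """
    alpha, nu = np.exp(logab)
    lognup = np.log(nu + p)
    ll = gammaln(d + alpha) - gammaln(alpha) + alpha * np.log(nu) - (d + alpha) * lognup
    dll_da = float((digamma(d + alpha) - digamma(alpha) + np.log(nu) - lognup).sum())
    dll_dnu = float((alpha / nu - (d + alpha) / (nu + p)).sum())
    return -float(ll.sum()), -np.array([dll_da * alpha, dll_dnu * nu])


def _pg_fit(d: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Marginal-ML gamma prior (shape alpha, rate nu) for Poisson counts."""
    if d.size < 2:
        raise EBFitError("Poisson-gamma needs >= 2 areas")
    if d.sum() <= 0:
        raise EBFitError("Poisson-gamma needs at least one case in total")
    # Moment starting values: prior mean from the pooled rate, prior variance
    # from the between-area excess over Poisson noise.
    rates = d / p
    mbar = float(d.sum() / p.sum())
    var_between = float(np.var(rates, ddof=1) - np.mean(d / p**2))
    underdispersed = var_between <= 0
    if underdispersed:
        var_between = (mbar**2) * 1e-4  # tiny prior variance -> heavy shrinkage
    alpha0 = min(max(mbar**2 / var_between, 1e-12), 1e12)
    nu0 = min(max(mbar / var_between, 1e-12), 1e20)

    res = minimize(
        _nb_negloglik_grad,
        x0=np.log([alpha0, nu0]),
        args=(d, p),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-40.0, 40.0), (-40.0, 60.0)],
    )
    if not res.success and not underdispersed:
        raise EBFitError(f"Poisson-gamma ML did not converge: {res.message}")
    if underdispersed:
        warnings.warn(
            "between-area variance below Poisson noise; gamma prior nearly "
            "degenerate, rates shrunk almost fully to the pooled mean"
        )
    alpha, nu = np.exp(res.x)
    return float(alpha), float(nu)


def pg_estimate(table: LAATable) -> PoissonGammaEstimate:
    """Maximum-likelihood Poisson-gamma fit and conjugate posterior rates.

    Requires count-provenance data (the marginal likelihood is over case
    counts).  Underdispersed data push the prior variance to zero; the fit
    then returns a near-degenerate prior (heavy shrinkage) with a warning.
    """
    if table.provenance != "counts":
        raise EBFitError("Poisson-gamma requires count data (Poisson sampling model)")
    d = table.df["cases"].to_numpy(dtype=float)
    p = table.df["population"].to_numpy(dtype=float)
    alpha, nu = _pg_fit(d, p)
    return PoissonGammaEstimate(
        alpha=alpha, nu=nu, posterior_rates=(d + alpha) / (p + nu)
    )


def _stabilized_rates(table: LAATable, method: str) -> np.ndarray:
    if method == "dl":
        return dl_estimate(table).posterior_rates
    if method == "pg":
        return pg_estimate(table).posterior_rates
    raise ValueError(f"unknown method {method!r}; use 'dl' or 'pg'")


def local_estimate(
    table: LAATable,
    method: str = "dl",
    k_neighbors: int = 15,
    metric: str = "euclidean",
    neighbor_index: np.ndarray | None = None,
) -> np.ndarray:
    """Per-area stabilized rates with locally estimated hyperparameters.

    For each area the global estimator runs on the sub-table of the area
    plus its ``k_neighbors`` nearest areas (ties broken by table order) and
    only the centre area's value is kept.  A failed local fit falls back to
    the global fit for that area, with a warning.

    ``neighbor_index`` may supply precomputed neighbourhoods as an
    ``(n, k_neighbors + 1)`` index array whose first column is each area
    itself (useful when the geometry is fixed across many replicates).
    """
    n = len(table)
    if k_neighbors + 1 > n:
        raise ValueError(f"k_neighbors + 1 = {k_neighbors + 1} exceeds {n} areas")
    if neighbor_index is None:
        neighbor_index = neighborhoods(table.coords, k_neighbors, metric=metric)
    global_rates: np.ndarray | None = None
    out = np.empty(n)

    if method == "pg":
        if table.provenance != "counts":
            raise EBFitError("Poisson-gamma requires count data")
        d = table.df["cases"].to_numpy(dtype=float)
        p = table.df["population"].to_numpy(dtype=float)
    elif method == "dl":
        theta_all = table.log_rates
        v_all = table.variances
        usable = table.usable
    else:
        raise ValueError(f"unknown method {method!r}; use 'dl' or 'pg'")

    for i in range(n):
        nb = neighbor_index[i]
        try:
            if method == "pg":
                alpha, nu = _pg_fit(d[nb], p[nb])
                out[i] = (d[i] + alpha) / (p[i] + nu)
            else:
                sel = nb[usable[nb]]
                if sel.size < 2:
                    raise EBFitError("fewer than 2 usable areas in neighbourhood")
                mu, tau2 = _dl_fit(theta_all[sel], v_all[sel])
                if usable[i] and tau2 > 0:
                    w_d, w_p = 1.0 / v_all[i], 1.0 / tau2
                    out[i] = np.exp((theta_all[i] * w_d + mu * w_p) / (w_d + w_p))
                else:
                    out[i] = np.exp(mu)
        except EBFitError as exc:
            if global_rates is None:
                global_rates = _stabilized_rates(table, method)
            warnings.warn(
                f"local {method} fit failed for area {table.area_ids[i]!r} "
                f"({exc}); using the global fit"
            )
            out[i] = global_rates[i]
    return out


def neighborhoods(
    coords: np.ndarray, k_neighbors: int, metric: str = "euclidean"
) -> np.ndarray:
    """Index array (n, k+1): each row is an area followed by its k nearest.

    Distance ties are broken by area order (stable mergesort), so the result
    is deterministic.
    """
    D = pairwise_distance(coords, coords, metric=metric)
    n = coords.shape[0]
    order = np.argsort(D, axis=1, kind="stable")
    idx = np.empty((n, k_neighbors + 1), dtype=np.int64)
    for i in range(n):
        row = order[i][order[i] != i][:k_neighbors]
        idx[i, 0] = i
        idx[i, 1:] = row
    return idx
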