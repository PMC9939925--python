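"""Monte Carlo evaluation of the eight mapping methods on hotspot surfaces.

Each replicate of a scenario:

1. places one (or two) hotspot centres uniformly at random among the mesh
   points and builds the true log-rate surface — a two-dimensional Gaussian
   decaying from a peak log-rate of -6.725 (rate 120e-5) down to a floor of
   -7.725 (rate 44.16e-5); for double hotspots, the surface is the average
   of two rapidly decaying single-centre surfaces;
2. draws each LAA's population from a log-normal distribution
   moment-matched to the scenario's mean and coefficient of variation;
3. draws each LAA's case count as Poisson(population x rate at centroid);
4. fits a spherical variogram to that replicate's semivariance cloud and
   runs all eight estimators on the same data (paired comparison);
5. scores each method's in-boundary mesh-point rates against the truth
   with SMAPE = 100 * mean |est - true| / (est + true).

Methods: the raw LAA rate painted across the LAA ("original"), four
empirical-Bayes variants (global/local DerSimonian-Laird and
Poisson-gamma, painted likewise), and the three kriging flavors
(traditional, nugget-adjusted, stabilized) evaluated pointwise.

The 3 x 3 population grid follows means {100000, 50000, 25000} crossed
with coefficients of variation {0.1, 0.5, 1.0}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .empirical_bayes import EBFitError, local_estimate, neighborhoods, _stabilized_rates
from .geometry import SyntheticRegion, pairwise_distance, voronoi_region
from .kriging import predict_grid
from .laa_data import LAATable, from_counts
from .semivariogram import VariogramFitError, build_cloud, CovarianceModel, fit_spherical

__all__ = [
    "HotspotSurface",
    "ScenarioConfig",
    "ScenarioResult",
    "METHODS",
    "surface_value",
    "sample_populations",
    "sample_counts",
    "smape",
    "run_scenario",
    "default_region",
]

METHODS = (
    "original",
    "eb_dl",
    "eb_pg",
    "eb_dl_local",
    "eb_pg_local",
    "kriging_traditional",
    "kriging_nugget",
    "kriging_stabilized",
)

THETA_MAX = -6.725  # peak log-rate (rate 120e-5)
THETA_MIN = -7.725  # floor log-rate (rate 44.16e-5)

POPULATION_MEANS = (100_000, 50_000, 25_000)
POPULATION_CVS = (0.1, 0.5, 1.0)

# Gaussian bandwidths as fractions of the region's bounding-box diagonal:
# the slow surface spans most of the region, the rapid one is clearly
# sub-regional.
SIGMA_SLOW_FRACTION = 0.25
SIGMA_RAPID_FRACTION = 0.10


@dataclass(frozen=True)
class HotspotSurface:
    """True log-rate surface: Gaussian decay from hotspot centre(s).

    Single modes: theta(x) = theta_min + (theta_max - theta_min) *
    exp(-dist(x, centre)^2 / (2 sigma^2)).  Double mode: the average of two
    single-centre rapid surfaces, so the realized peak can fall below
    theta_max unless the centres coincide.
    """

    centers: np.ndarray  # (k, 2)
    bandwidths: np.ndarray  # (k,)
    mode: str
    theta_max: float = THETA_MAX
    theta_min: float = THETA_MIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.atleast_2d(np.asarray(self.centers, float)))
        bw = np.atleast_1d(np.asarray(self.bandwidths, float))
        object.__setattr__(self, "bandwidths", bw)
        if np.any(bw <= 0):
            raise ValueError("bandwidths must be positive")
        if self.theta_max <= self.theta_min:
            raise ValueError("theta_max must exceed theta_min")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        span = self.theta_max - self.theta_min
        vals = np.empty((self.centers.shape[0], pts.shape[0]))
        for k, (ctr, sig) in enumerate(zip(self.centers, self.bandwidths)):
            d2 = ((pts - ctr) ** 2).sum(axis=1)
            vals[k] = self.theta_min + span * np.exp(-d2 / (2 * sig**2))
        return vals.mean(axis=0)


def surface_value(surface: HotspotSurface, point) -> float:
    """True log-rate at one location."""
    return float(surface(np.asarray(point, dtype=float).reshape(1, 2))[0])


def make_surface(
    mode: str,
    centers: np.ndarray,
    bbox_diagonal: float,
    sigma_slow_fraction: float = SIGMA_SLOW_FRACTION,
    sigma_rapid_fraction: float = SIGMA_RAPID_FRACTION,
) -> HotspotSurface:
    if mode == "single_slow":
        bw = [sigma_slow_fraction * bbox_diagonal]
    elif mode == "single_rapid":
        bw = [sigma_rapid_fraction * bbox_diagonal]
    elif mode == "double":
        bw = [sigma_rapid_fraction * bbox_diagonal] * 2
    else:
        raise ValueError(f"unknown surface mode {mode!r}")
    centers = np.atleast_2d(centers)
    if centers.shape[0] != len(bw):
        raise ValueError(f"mode {mode!r} needs {len(bw)} centre(s)")
    return HotspotSurface(centers=centers, bandwidths=np.array(bw), mode=mode)


def sample_populations(mean: float, cv: float, n: int, rng) -> np.ndarray:
    """Log-normal populations with the stated mean and coefficient of variation.

    Moment matching: sigma_L^2 = ln(1 + cv^2), mu_L = ln(mean) - sigma_L^2/2.
    ``cv = 0`` returns the constant mean.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(rng)
    if cv == 0:
        return np.full(n, float(mean))
    s2 = np.log1p(cv**2)
    mu_l = np.log(mean) - s2 / 2
    return rng.lognormal(mean=mu_l, sigma=np.sqrt(s2), size=n)


def sample_counts(
    surface: HotspotSurface,
    region: SyntheticRegion,
    populations: np.ndarray,
    rng,
) -> LAATable:
    """Poisson counts at the LAA centroids -> count-provenance table."""
    rng = np.random.default_rng(rng)
    centroids = region.centroid_array()
    populations = np.asarray(populations, dtype=float)
    if populations.shape[0] != centroids.shape[0]:
        raise ValueError("need one population per LAA")
    expected = populations * np.exp(surface(centroids))
    cases = rng.poisson(expected)
    return from_counts(
        (pt.area_id, pt, int(d), p)
        for pt, d, p in zip(region.points, cases, populations)
    )


def smape(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Symmetric mean absolute percentage error, in percent (0..100).

    Per-point term |est - true| / (est + true); a zero estimate against a
    positive truth contributes the maximal term 1.
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimated and truth must have the same length")
    if np.any(est < 0) or np.any(tru <= 0):
        raise ValueError("rates must be non-negative (truth strictly positive)")
    return float(100.0 * np.mean(np.abs(est - tru) / (est + tru)))


@dataclass(frozen=True)
class ScenarioConfig:
    surface_mode: str = "single_slow"
    population_mean: float = 100_000
    population_cv: float = 0.1
    n_replicates: int = 1000
    seed: int = 0
    k_neighbors: int = 15
    restrict_hotspots_to_boundary: bool = False
    sigma_slow_fraction: float = SIGMA_SLOW_FRACTION
    sigma_rapid_fraction: float = SIGMA_RAPID_FRACTION

    def __post_init__(self) -> None:
        if self.population_mean <= 0:
            raise ValueError("population_mean must be positive")
        if self.population_cv < 0:
            raise ValueError("population_cv must be non-negative")


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    smape: pd.DataFrame  # replicate x method
    n_failures: dict = field(default_factory=dict)

    def means(self) -> pd.Series:
        return self.smape.mean(axis=0)


def default_region(seed: int = 2023, n_laas: int = 26, mesh_nx: int = 40, mesh_ny: int = 34) -> SyntheticRegion:
    """A 26-LAA Voronoi county on a rectangle with a Changhua-like aspect ratio."""
    return voronoi_region(seed=seed, n_laas=n_laas, bounds=(0.0, 0.5, 0.0, 0.42),
                          mesh_nx=mesh_nx, mesh_ny=mesh_ny)


def _replicate(
    config: ScenarioConfig,
    region: SyntheticRegion,
    rng: np.random.Generator,
    cache: dict,
) -> dict[str, float]:
    mesh = region.mesh
    candidates = mesh.points if not config.restrict_hotspots_to_boundary else mesh.inside_points
    n_centers = 2 if config.surface_mode == "double" else 1
    centers = candidates[rng.integers(0, candidates.shape[0], size=n_centers)]
    surface = make_surface(
        config.surface_mode,
        centers,
        cache["bbox_diagonal"],
        config.sigma_slow_fraction,
        config.sigma_rapid_fraction,
    )

    populations = sample_populations(
        config.population_mean, config.population_cv, region.n_laas, rng
    )
    table = sample_counts(surface, region, populations, rng)

    inside = mesh.inside_mask
    truth = np.exp(surface(mesh.points[inside]))
    assign = cache["assignment"][inside]

    out: dict[str, float] = {}

    # LAA-painted methods: each mesh point takes its area's rate
    crude = table.df["rate"].to_numpy(dtype=float)
    out["original"] = smape(crude[assign], truth)
    for name, method, local in (
        ("eb_dl", "dl", False),
        ("eb_pg", "pg", False),
        ("eb_dl_local", "dl", True),
        ("eb_pg_local", "pg", True),
    ):
        try:
            if local:
                r = local_estimate(
                    table, method=method,
                    k_neighbors=cache["neighbor_index"].shape[1] - 1,
                    neighbor_index=cache["neighbor_index"],
                )
            else:
                r = _stabilized_rates(table, method)
            out[name] = smape(r[assign], truth)
        except EBFitError:
            out[name] = np.nan

    # kriging methods share one fitted variogram
    try:
        cloud = build_cloud(table, cache["pairwise"])
        try:
            vgm = fit_spherical(cloud, binning="cloud")
        except VariogramFitError:
            vgm = fit_spherical(cloud, binning="binned")
        model = CovarianceModel(vgm)
        for name, flavor in (
            ("kriging_traditional", "traditional"),
            ("kriging_nugget", "nugget_adjusted"),
            ("kriging_stabilized", "stabilized"),
        ):
            theta0 = predict_grid(
                table, model, mesh.points[inside], flavor=flavor,
                pairwise=cache["pairwise"],
                distances_to_targets=cache["dist_to_mesh"][:, inside],
            )
            out[name] = smape(np.exp(theta0), truth)
    except (ValueError, VariogramFitError):
        for name in ("kriging_traditional", "kriging_nugget", "kriging_stabilized"):
            out[name] = np.nan
    return out


def run_scenario(config: ScenarioConfig, region: SyntheticRegion | None = None) -> ScenarioResult:
    """Run one (surface, population mean, cv) scenario end to end.

    A pure function of ``(config.seed, region)``: one master seed spawns an
    independent stream per replicate, and all eight methods see identical
    data within a replicate.  Per-replicate method failures are recorded
    (NaN) and excluded from that method's mean, not fatal.
    """
    if region is None:
        region = default_region()
    if region.n_laas < 4:
        raise ValueError("region must have at least 4 LAAs")
    centroids = region.centroid_array()
    bounds = region.boundary.bounds  # (xmin, ymin, xmax, ymax)
    cache = {
        "assignment": region.assign_mesh_points(),
        "pairwise": pairwise_distance(centroids, centroids),
        "dist_to_mesh": pairwise_distance(centroids, region.mesh.points),
        "neighbor_index": neighborhoods(
            centroids, min(config.k_neighbors, region.n_laas - 1)
        ),
        "bbox_diagonal": float(np.hypot(bounds[2] - bounds[0], bounds[3] - bounds[1])),
    }
    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-replicate degenerate-fit warnings
        for ss in streams:
            rows.append(_replicate(config, region, np.random.default_rng(ss), cache))
    df = pd.DataFrame(rows, columns=list(METHODS))
    failures = {m: int(df[m].isna().sum()) for m in METHODS if df[m].isna().any()}
    return ScenarioResult(config=config, smape=df, n_failures=failures)
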