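"""Study-region geometry: representative points, evaluation meshes, synthetic regions.

A disease map is built from local administrative areas (LAAs), each reduced
to a single representative point (by default its polygon's geometric
centroid).  Kriging predictions are evaluated on a rectangular lattice of
target points ("mesh") clipped to the region boundary.  For simulation work
a synthetic county is generated as a Voronoi tessellation of a rectangle.

Distances are never auto-detected: the caller states ``euclidean`` (planar
units) or ``haversine`` (coordinates are lon/lat degrees, distances in km).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon, box, shape
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "RepresentativePoint",
    "Mesh",
    "SyntheticRegion",
    "pairwise_distance",
    "make_mesh",
    "voronoi_region",
    "read_geojson_polygons",
    "read_points_csv",
]


@dataclass(frozen=True)
class RepresentativePoint:
    """A single point standing in for an areal unit.

    ``x``/``y`` are either projected planar coordinates or longitude/latitude
    in degrees; the distance metric chosen downstream fixes the
    interpretation.
    """

    area_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(
                f"non-finite coordinate for area {self.area_id!r}: ({self.x}, {self.y})"
            )


@dataclass
class Mesh:
    """Rectangular lattice of prediction targets with an in-region mask."""

    points: np.ndarray  # (n, 2) array of (x, y)
    inside_mask: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.inside_mask = np.asarray(self.inside_mask, dtype=bool)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("mesh points must be an (n, 2) array")
        if self.inside_mask.shape != (self.points.shape[0],):
            raise ValueError("inside_mask length must match number of points")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_inside(self) -> int:
        return int(self.inside_mask.sum())

    @property
    def inside_points(self) -> np.ndarray:
        return self.points[self.inside_mask]


@dataclass
class SyntheticRegion:
    """A synthetic county: boundary polygon tiled by LAA polygons.

    ``sites`` keeps the Voronoi generator points (one per LAA); they are
    retained because mesh-point-to-LAA assignment for a Voronoi tessellation
    is a nearest-site lookup.
    """

    boundary: Polygon
    laa_polygons: list[Polygon]
    points: list[RepresentativePoint]
    mesh: Mesh
    sites: np.ndarray | None = None
    _mesh_assignment: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_laas(self) -> int:
        return len(self.laa_polygons)

    def centroid_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points])

    def assign_mesh_points(self) -> np.ndarray:
        """Index of the LAA containing each mesh point (-1 if none).

        Cached: the assignment is a pure function of the fixed geometry and
        is reused across simulation replicates.
        """
        if self._mesh_assignment is not None:
            return self._mesh_assignment
        if self.sites is not None:
            # Voronoi cells: membership == nearest generator site.
            d2 = (
                (self.mesh.points[:, None, :] - self.sites[None, :, :]) ** 2
            ).sum(axis=2)
            idx = np.argmin(d2, axis=1).astype(np.int64)
            idx[~self.mesh.inside_mask] = -1
        else:
            tree = STRtree(self.laa_polygons)
            idx = np.full(self.mesh.n_points, -1, dtype=np.int64)
            for j, (x, y) in enumerate(self.mesh.points):
                if not self.mesh.inside_mask[j]:
                    continue
                pt = Point(x, y)
                cands = tree.query(pt, predicate="intersects")
                if len(cands):
                    idx[j] = int(cands[0])
        self._mesh_assignment = idx
        return idx


def _as_coord_array(points) -> tuple[np.ndarray, list[str]]:
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float)
        ids = [str(i) for i in range(arr.shape[0])]
    else:
        arr = np.array([[p.x, p.y] for p in points], dtype=float)
        ids = [p.area_id for p in points]
    if not np.all(np.isfinite(arr)):
        bad = [ids[i] for i in np.where(~np.isfinite(arr).all(axis=1))[0]]
        raise ValueError(f"non-finite coordinates for areas: {bad}")
    return arr, ids


def pairwise_distance(points_a, points_b, metric: str = "euclidean") -> np.ndarray:
    """Distance matrix between two point sets.

    Parameters
    ----------
    points_a, points_b
        Sequences of :class:`RepresentativePoint` or ``(n, 2)`` arrays.
    metric
        ``"euclidean"`` treats coordinates as planar; ``"haversine"``
        treats them as (longitude, latitude) degrees and returns
        great-circle distances in kilometres (Earth radius 6371 km).
    """
    a, _ = _as_coord_array(points_a)
    b, _ = _as_coord_array(points_b)
    if metric == "euclidean":
        diff = a[:, None, :] - b[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "haversine":
        lon1, lat1 = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
        lon2, lat2 = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
        dlat = lat2 - lat1
        dlon = lon2 - lon1
        h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
        return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    raise ValueError(f"unknown metric {metric!r}; use 'euclidean' or 'haversine'")


def make_mesh(
    bounds: tuple[float, float, float, float],
    n_x: int,
    n_y: int,
    boundary: Polygon | None = None,
) -> Mesh:
    """Regular ``n_x``-by-``n_y`` lattice over ``(xmin, xmax, ymin, ymax)``.

    Points exactly on the boundary count as inside (mesh points on a county
    border are mapped).
    """
    xmin, xmax, ymin, ymax = bounds
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bounds {bounds}")
    if n_x < 2 or n_y < 2:
        raise ValueError("n_x and n_y must be at least 2")
    xs = np.linspace(xmin, xmax, n_x)
    ys = np.linspace(ymin, ymax, n_y)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if boundary is None:
        mask = np.ones(pts.shape[0], dtype=bool)
    else:
        # intersects = boundary-inclusive containment
        mask = np.array(
            [boundary.intersects(Point(x, y)) for x, y in pts], dtype=bool
        )
    return Mesh(points=pts, inside_mask=mask)


def voronoi_region(
    seed: int,
    n_laas: int,
    bounds: tuple[float, float, float, float],
    mesh_nx: int = 40,
    mesh_ny: int = 34,
) -> SyntheticRegion:
    """Synthetic county: Voronoi cells of uniform random sites in a rectangle.

    The cells tile the rectangle exactly (clipped Voronoi diagram), each LAA's
    representative point is its cell's geometric centroid, and a rectangular
    evaluation mesh covers the bounds.  Deterministic for a given seed.
    """
    if n_laas < 3:
        raise ValueError("need at least 3 LAAs")
    xmin, xmax, ymin, ymax = bounds
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bounds {bounds}")
    rng = np.random.default_rng(seed)
    sites = np.column_stack(
        [rng.uniform(xmin, xmax, n_laas), rng.uniform(ymin, ymax, n_laas)]
    )
    return region_from_sites(sites, bounds, mesh_nx=mesh_nx, mesh_ny=mesh_ny)


def region_from_sites(
    sites: np.ndarray,
    bounds: tuple[float, float, float, float],
    mesh_nx: int = 40,
    mesh_ny: int = 34,
) -> SyntheticRegion:
    """Build a :class:`SyntheticRegion` from explicit Voronoi sites."""
    sites = np.asarray(sites, dtype=float)
    boundary = box(*_shapely_bounds(bounds))
    cells_raw = voronoi_diagram(MultiPoint([tuple(s) for s in sites]), envelope=boundary)
    # voronoi_diagram does not preserve input order; match cells to sites.
    polys: list[Polygon | None] = [None] * len(sites)
    for geom in cells_raw.geoms:
        clipped = geom.intersection(boundary)
        for i, s in enumerate(sites):
            if polys[i] is None and geom.intersects(Point(*s)):
                polys[i] = clipped
                break
    if any(p is None or p.is_empty for p in polys):
        raise RuntimeError("Voronoi cell matching failed (coincident sites?)")
    points = [
        RepresentativePoint(area_id=f"A{i:02d}", x=p.centroid.x, y=p.centroid.y)
        for i, p in enumerate(polys)
    ]
    mesh = make_mesh(bounds, mesh_nx, mesh_ny, boundary=None)
    return SyntheticRegion(
        boundary=boundary,
        laa_polygons=polys,
        points=points,
        mesh=mesh,
        sites=sites,
    )


def _shapely_bounds(b: tuple[float, float, float, float]):
    xmin, xmax, ymin, ymax = b
    return (xmin, ymin, xmax, ymax)


def read_geojson_polygons(path) -> tuple[list[Polygon], list[str]]:
    """Read region/LAA polygons from a GeoJSON FeatureCollection.

    Coordinates are taken as-is in the file's native CRS; no reprojection.
    Returns (polygons, feature ids).  The id is taken from the feature's
    ``id`` member or an ``area_id``/``id``/``name`` property, falling back to
    the feature index.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polys, ids = [], []
    for k, feat in enumerate(feats):
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        fid = feat.get("id", props.get("area_id", props.get("id", props.get("name", k))))
        polys.append(geom)
        ids.append(str(fid))
    return polys, ids


def read_points_csv(path) -> list[RepresentativePoint]:
    """Representative points from a CSV with header ``area_id,x,y``."""
    df = pd.read_csv(path)
    required = {"area_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"points CSV must have columns {sorted(required)}")
    return [
        RepresentativePoint(area_id=str(r.area_id), x=float(r.x), y=float(r.y))
        for r in df.itertuples()
    ]
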