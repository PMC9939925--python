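"""Per-area observations: counts, populations, log-rates and their variances.

Under a Poisson model for the case count ``d`` of an area with error-free
population ``p``, the crude rate is ``r = d/p``, the log-rate is
``theta = log r`` and, by the delta method, ``Var(theta) ≈ 1/d``.  An area
with zero cases has an undefined log-rate and infinite variance; such areas
are retained in the table with explicit markers (the stabilized kriging
solver then gives them weight exactly zero).

Tables may instead carry externally supplied (log-rate, variance) pairs —
for example directly age-standardized rates — in which case the downstream
methods use them verbatim.  The two provenances are never mixed in one table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import RepresentativePoint

__all__ = ["LAATable", "from_counts", "with_external_variance", "read_csv"]


@dataclass
class LAATable:
    """Per-LAA data frame plus provenance flag.

    Columns: ``area_id, x, y, cases, population, rate, log_rate, variance``.
    ``cases``/``population``/``rate`` are NaN for external-variance tables.
    Undefined log-rates (zero cases) are NaN with ``variance = inf``.
    """

    df: pd.DataFrame
    provenance: str  # "counts" or "external"

    def __post_init__(self) -> None:
        if self.provenance not in ("counts", "external"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def area_ids(self) -> list[str]:
        return self.df["area_id"].tolist()

    @property
    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def log_rates(self) -> np.ndarray:
        return self.df["log_rate"].to_numpy(dtype=float)

    @property
    def variances(self) -> np.ndarray:
        return self.df["variance"].to_numpy(dtype=float)

    @property
    def usable(self) -> np.ndarray:
        """Mask of areas with a defined log-rate and finite variance."""
        lr = self.log_rates
        v = self.variances
        return np.isfinite(lr) & np.isfinite(v)

    def points(self) -> list[RepresentativePoint]:
        return [
            RepresentativePoint(area_id=str(r.area_id), x=float(r.x), y=float(r.y))
            for r in self.df.itertuples()
        ]

    def subset(self, index: np.ndarray) -> "LAATable":
        """Row subset (positional), preserving provenance."""
        return LAATable(self.df.iloc[index].reset_index(drop=True), self.provenance)


def from_counts(records) -> LAATable:
    """Build a table from ``(area_id, point, cases, population)`` records.

    ``point`` may be a :class:`RepresentativePoint` or an ``(x, y)`` pair.
    """
    rows = []
    for area_id, point, cases, population in records:
        x, y = (point.x, point.y) if isinstance(point, RepresentativePoint) else point
        population = float(population)
        if not population > 0:
            raise ValueError(f"non-positive population for area {area_id!r}")
        if cases < 0 or int(cases) != cases:
            raise ValueError(f"cases must be a non-negative integer for area {area_id!r}")
        cases = int(cases)
        rate = cases / population
        if cases > 0:
            log_rate = np.log(cases) - np.log(population)
            variance = 1.0 / cases
        else:
            log_rate = np.nan  # log(0/p) -> -inf; flagged undefined
            variance = np.inf
        rows.append((str(area_id), x, y, cases, population, rate, log_rate, variance))
    df = pd.DataFrame(
        rows,
        columns=["area_id", "x", "y", "cases", "population", "rate", "log_rate", "variance"],
    )
    _check_unique_ids(df)
    return LAATable(df, "counts")


def with_external_variance(records) -> LAATable:
    """Build a table from ``(area_id, point, log_rate, variance)`` records.

    ``variance`` must be positive; ``inf`` marks an area whose estimate is
    unusable (for instance zero observed cases after standardization).
    """
    rows = []
    for area_id, point, log_rate, variance in records:
        x, y = (point.x, point.y) if isinstance(point, RepresentativePoint) else point
        variance = float(variance)
        if not (variance > 0):  # rejects 0, negatives and NaN; inf allowed
            raise ValueError(
                f"variance must be positive or infinite for area {area_id!r}"
            )
        lr = float(log_rate) if np.isfinite(variance) else np.nan
        rows.append(
            (str(area_id), x, y, np.nan, np.nan, np.nan, lr, variance)
        )
    df = pd.DataFrame(
        rows,
        columns=["area_id", "x", "y", "cases", "population", "rate", "log_rate", "variance"],
    )
    _check_unique_ids(df)
    return LAATable(df, "external")


def _check_unique_ids(df: pd.DataFrame) -> None:
    dup = df["area_id"][df["area_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate area_id values: {sorted(set(dup))}")


def read_csv(path) -> LAATable:
    """Read an LAA table from CSV, auto-detecting the schema by header.

    ``area_id,x,y,cases,population`` yields a count-derived table;
    ``area_id,x,y,log_rate,variance`` an external-variance table.  In the
    latter, the variance column accepts ``inf`` as the infinite marker.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"area_id", "x", "y", "cases", "population"}.issubset(cols):
        return from_counts(
            (r.area_id, (float(r.x), float(r.y)), int(r.cases), float(r.population))
            for r in df.itertuples()
        )
    if {"area_id", "x", "y", "log_rate", "variance"}.issubset(cols):
        return with_external_variance(
            (r.area_id, (float(r.x), float(r.y)), float(r.log_rate), float(r.variance))
            for r in df.itertuples()
        )
    raise ValueError(
        "CSV must have columns area_id,x,y plus either cases,population "
        "or log_rate,variance"
    )


def write_csv(table: LAATable, path) -> None:
    if table.provenance == "counts":
        cols = ["area_id", "x", "y", "cases", "population"]
    else:
        cols = ["area_id", "x", "y", "log_rate", "variance"]
    table.df[cols].to_csv(path, index=False, float_format="%.17g")
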