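"""Direct age standardization: DASIR and the variance of its logarithm.

The directly age-standardized incidence rate of an area is the
standard-population-weighted average of its age-specific rates,

    DASIR = sum_a w_a * d_a / p_a,        sum_a w_a = 1.

With Poisson stratum counts, Var(DASIR) = sum_a w_a^2 * d_a / p_a^2
(observed counts plugged in for their expectations), and by the delta
method Var(log DASIR) = Var(DASIR) / DASIR^2.  An area with zero total
cases gets the infinite-variance marker, exactly like a zero-case crude
rate, and is then down-weighted to zero by stabilized kriging.

The WHO 2000 World Standard Population ships in 5-year bands (0-4 ... 85+);
its published percentages sum to 100.03 and are renormalized to exactly 1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import RepresentativePoint
from .laa_data import LAATable, with_external_variance

__all__ = [
    "AgeStratifiedCounts",
    "StandardPopulation",
    "who2000_standard",
    "dasir",
    "dasir_table",
]


@dataclass(frozen=True)
class StandardPopulation:
    """Ordered age bands with proportions summing to one."""

    strata: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if len(self.strata) != w.size:
            raise ValueError("strata and weights must align")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    def aggregate(self, groups: list[list[str]]) -> "StandardPopulation":
        """Merge bands (weights re-summed), e.g. 5-year into 10-year bands.

        ``groups`` must partition the current strata so the aggregated
        weights still sum to one.
        """
        pos = {s: i for i, s in enumerate(self.strata)}
        flat = [s for g in groups for s in g]
        if sorted(flat) != sorted(self.strata):
            raise ValueError("groups must partition the existing age bands")
        new_strata, new_w = [], []
        for g in groups:
            new_strata.append("+".join(g))
            new_w.append(sum(self.weights[pos[s]] for s in g))
        return StandardPopulation(tuple(new_strata), np.array(new_w))

    @classmethod
    def from_csv(cls, path) -> "StandardPopulation":
        df = pd.read_csv(path)
        w = df["weight"].to_numpy(dtype=float)
        return cls(tuple(df["age_band"].astype(str)), w / w.sum())


@dataclass(frozen=True)
class AgeStratifiedCounts:
    """One area's cases and person-years per age band."""

    area_id: str
    strata: tuple[str, ...]
    cases: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.cases, dtype=float)
        p = np.asarray(self.populations, dtype=float)
        object.__setattr__(self, "cases", d)
        object.__setattr__(self, "populations", p)
        if not (len(self.strata) == d.size == p.size):
            raise ValueError(f"misaligned strata for area {self.area_id!r}")
        if np.any(d < 0):
            raise ValueError(f"negative cases for area {self.area_id!r}")


def who2000_standard() -> StandardPopulation:
    """WHO 2000 World Standard Population, 5-year bands, renormalized."""
    ref = importlib.resources.files("stabkrig.data").joinpath("who2000.csv")
    with importlib.resources.as_file(ref) as path:
        return StandardPopulation.from_csv(path)


def dasir(counts: AgeStratifiedCounts, std: StandardPopulation) -> tuple[float, float]:
    """Directly age-standardized rate and the variance of its log.

    Returns ``(rate, var_log)``; ``var_log`` is ``inf`` when the area has
    zero cases in every stratum.
    """
    if counts.strata != std.strata:
        raise ValueError(
            f"strata of area {counts.area_id!r} do not match the standard "
            f"population ({counts.strata} vs {std.strata})"
        )
    w = std.weights
    d, p = counts.cases, counts.populations
    bad = (w > 0) & (p <= 0)
    if np.any(bad):
        names = [counts.strata[i] for i in np.where(bad)[0]]
        raise ValueError(
            f"zero population in positively weighted strata {names} "
            f"of area {counts.area_id!r}"
        )
    safe_p = np.where(p > 0, p, 1.0)  # zero-weight strata may have p = 0
    rate = float((w * d / safe_p).sum())
    if d[w > 0].sum() <= 0:
        return rate, np.inf
    var_rate = float((w**2 * d / safe_p**2).sum())
    return rate, var_rate / rate**2


def dasir_table(
    per_area_counts: list[AgeStratifiedCounts],
    std: StandardPopulation,
    points: list[RepresentativePoint],
) -> LAATable:
    """External-variance LAA table of log-DASIRs, one row per area.

    A failing area (for example, misaligned strata) is flagged with infinite
    variance rather than aborting the table, unless every area fails.
    """
    if len(per_area_counts) != len(points):
        raise ValueError("need one representative point per area")
    records = []
    n_failed = 0
    for counts, pt in zip(per_area_counts, points):
        try:
            rate, var_log = dasir(counts, std)
        except ValueError:
            n_failed += 1
            records.append((counts.area_id, pt, np.nan, np.inf))
            continue
        if np.isfinite(var_log):
            records.append((counts.area_id, pt, float(np.log(rate)), var_log))
        else:
            records.append((counts.area_id, pt, np.nan, np.inf))
    if n_failed == len(per_area_counts):
        raise ValueError("direct standardization failed for every area")
    return with_external_variance(records)


def read_age_stratified_csv(path, std: StandardPopulation) -> list[AgeStratifiedCounts]:
    """Long-format CSV ``area_id,age_band,cases,population`` -> per-area counts.

    Bands are aligned to the standard population's order; missing bands are
    an error (a band with no population must still be listed with its
    person-years, or the standard must be aggregated first).
    """
    df = pd.read_csv(path)
    out = []
    for area_id, grp in df.groupby("area_id", sort=True):
        grp = grp.set_index("age_band")
        try:
            grp = grp.loc[list(std.strata)]
        except KeyError as exc:
            raise ValueError(f"area {area_id!r} missing age bands: {exc}") from exc
        out.append(
            AgeStratifiedCounts(
                area_id=str(area_id),
                strata=std.strata,
                cases=grp["cases"].to_numpy(dtype=float),
                populations=grp["population"].to_numpy(dtype=float),
            )
        )
    return out
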