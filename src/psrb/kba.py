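"""Response indicator: protected-area coverage of key biodiversity areas.

Coverage is the percent of each site's area overlapped by the union of
protected areas established by a given year.  Missing establishment
dates are imputed by resampling known same-country dates; uncertainty
from that imputation is propagated by bootstrapping the 1950-2010 mean
coverage series and reporting percentile confidence bands.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import DataIntegrityError, UndefinedScoreError

__all__ = [
    "KBASite",
    "ProtectedArea",
    "ProtectionSeries",
    "SERIES_YEARS",
    "kba_protection_percent",
    "mean_protection",
    "impute_establishment_dates",
    "bootstrap_protection_series",
    "protection_annual_rate",
]

log = logging.getLogger(__name__)

SERIES_START, SERIES_END = 1950, 2010
SERIES_YEARS = np.arange(SERIES_START, SERIES_END + 1)
RATE_WINDOW = (1980, 2010)


@dataclass(frozen=True)
class KBASite:
    site_id: str
    kind: str  # "IBA" or "AZE"
    country_id: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.geometry.area <= 0:
            raise DataIntegrityError(f"KBA site {self.site_id!r} has zero area")


@dataclass(frozen=True)
class ProtectedArea:
    pa_id: str
    country_id: str
    geometry: BaseGeometry
    establishment_year: int | None = None

    def __post_init__(self) -> None:
        year = self.establishment_year
        if year is not None and not (SERIES_START <= year <= SERIES_END):
            raise DataIntegrityError(
                f"protected area {self.pa_id!r}: establishment year {year} outside "
                f"{SERIES_START}-{SERIES_END}"
            )


@dataclass
class ProtectionSeries:
    unit_id: str
    years: np.ndarray
    mean_pct: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int


def kba_protection_percent(
    site: KBASite, pas: Sequence[ProtectedArea], year: int = SERIES_END
) -> float:
    """Percent of the site overlapped by PAs established by ``year``.

    Overlapping PAs are unioned first, so doubly-protected ground is not
    double counted.  Undated PAs are ignored (impute first).
    """
    established = [
        pa.geometry
        for pa in pas
        if pa.establishment_year is not None and pa.establishment_year <= year
    ]
    if not established:
        return 0.0
    covered = site.geometry.intersection(unary_union(established)).area
    return 100.0 * covered / site.geometry.area


def mean_protection(
    sites: Sequence[KBASite], pas: Sequence[ProtectedArea], year: int = SERIES_END
) -> float:
    """Unweighted mean coverage percent over a unit's sites."""
    if not sites:
        raise UndefinedScoreError("mean protection undefined for a unit with no KBA sites")
    return float(np.mean([kba_protection_percent(s, pas, year) for s in sites]))


def impute_establishment_dates(
    pas: Sequence[ProtectedArea], rng: np.random.Generator
) -> list[ProtectedArea]:
    """Fill missing establishment years by resampling known dates.

    Each undated PA draws (with replacement) from the known years of PAs
    in the same country; countries with no dated PA fall back to the
    pooled known-date set across all countries.
    """
    by_country: dict[str, list[int]] = {}
    global_pool: list[int] = []
    for pa in pas:
        if pa.establishment_year is not None:
            by_country.setdefault(pa.country_id, []).append(pa.establishment_year)
            global_pool.append(pa.establishment_year)
    out = []
    for pa in pas:
        if pa.establishment_year is not None:
            out.append(pa)
            continue
        pool = by_country.get(pa.country_id)
        if not pool:
            if not global_pool:
                raise DataIntegrityError("no known establishment dates anywhere to impute from")
            log.warning(
                "country %s has no dated protected areas; imputing %s from the global pool",
                pa.country_id,
                pa.pa_id,
            )
            pool = global_pool
        year = int(pool[rng.integers(len(pool))])
        out.append(replace(pa, establishment_year=year))
    return out


def _site_series(
    site: KBASite,
    dated_pas: Sequence[ProtectedArea],
    union_cache: dict[tuple[str, frozenset], float],
) -> np.ndarray:
    """Coverage percent of one site for every year in SERIES_YEARS.

    Coverage only steps up at PA establishment years; prefix-union areas
    are memoized on the (site, PA-id-set) key since geometries never
    change between bootstrap replicates.
    """
    relevant = sorted(
        (pa for pa in dated_pas if pa.geometry.intersects(site.geometry)),
        key=lambda pa: (pa.establishment_year, pa.pa_id),
    )
    series = np.zeros(len(SERIES_YEARS))
    if not relevant:
        return series
    prefix_ids: set[str] = set()
    geoms: list[BaseGeometry] = []
    area = site.geometry.area
    for pa in relevant:
        prefix_ids.add(pa.pa_id)
        geoms.append(pa.geometry)
        key = (site.site_id, frozenset(prefix_ids))
        if key not in union_cache:
            union_cache[key] = site.geometry.intersection(unary_union(geoms)).area
        pct = 100.0 * union_cache[key] / area
        series[SERIES_YEARS >= pa.establishment_year] = pct
    return series


def bootstrap_protection_series(
    unit_id: str,
    sites: Sequence[KBASite],
    pas: Sequence[ProtectedArea],
    n_boot: int = 1000,
    seed: int = 0,
) -> ProtectionSeries:
    """Mean coverage series 1950-2010 with 95% percentile bounds.

    Each replicate re-imputes missing establishment dates with a fresh
    sub-seed, recomputes the unit-mean coverage for every year, and the
    per-year mean and 2.5/97.5 percentiles are taken across replicates.
    PA input order does not affect the result.
    """
    if n_boot < 1:
        raise DataIntegrityError("n_boot must be >= 1")
    if not sites:
        raise UndefinedScoreError(f"unit {unit_id!r} has no KBA sites")
    pas = sorted(pas, key=lambda pa: pa.pa_id)  # order-invariance
    union_cache: dict[tuple[str, frozenset], float] = {}
    seeds = np.random.SeedSequence(seed).spawn(n_boot)
    replicates = np.empty((n_boot, len(SERIES_YEARS)))
    for b in range(n_boot):
        rng = np.random.default_rng(seeds[b])
        dated = impute_establishment_dates(pas, rng)
        site_stack = [_site_series(s, dated, union_cache) for s in sites]
        replicates[b] = np.mean(site_stack, axis=0)
    return ProtectionSeries(
        unit_id=unit_id,
        years=SERIES_YEARS.copy(),
        mean_pct=replicates.mean(axis=0),
        ci_low=np.percentile(replicates, 2.5, axis=0),
        ci_high=np.percentile(replicates, 97.5, axis=0),
        n_boot=n_boot,
    )


def protection_annual_rate(series: ProtectionSeries) -> float:
    """Annual rate of change in mean coverage between 1980 and 2010 (%/yr)."""
    start, end = RATE_WINDOW
    years = series.years
    if start not in years or end not in years:
        raise DataIntegrityError(f"series must cover {start} and {end}")
    v0 = series.mean_pct[years == start][0]
    v1 = series.mean_pct[years == end][0]
    return float((v1 - v0) / (end - start))


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def write_sites(sites: Iterable[KBASite], path: str) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"site_id": s.site_id, "kind": s.kind, "country_id": s.country_id},
            "geometry": mapping(s.geometry),
        }
        for s in sites
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_sites(path: str) -> list[KBASite]:
    with open(path) as fh:
        fc = json.load(fh)
    return [
        KBASite(
            site_id=f["properties"]["site_id"],
            kind=f["properties"]["kind"],
            country_id=f["properties"]["country_id"],
            geometry=shape(f["geometry"]),
        )
        for f in fc["features"]
    ]


def write_protected_areas(pas: Iterable[ProtectedArea], path: str) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "pa_id": p.pa_id,
                "country_id": p.country_id,
                "establishment_year": p.establishment_year,
            },
            "geometry": mapping(p.geometry),
        }
        for p in pas
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_protected_areas(path: str) -> list[ProtectedArea]:
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for f in fc["features"]:
        year = f["properties"].get("establishment_year")
        out.append(
            ProtectedArea(
                pa_id=f["properties"]["pa_id"],
                country_id=f["properties"]["country_id"],
                geometry=shape(f["geometry"]),
                establishment_year=None if year is None else int(year),
            )
        )
    return out
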