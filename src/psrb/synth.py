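"""Synthetic scenario generation with known ground truth.

Every pipeline input — rasters, analysis units, species tables, KBA/PA
geometries, survey responses — can be generated from a seeded
:class:`ScenarioConfig`, together with a ground-truth sidecar holding
the quantities each indicator should recover.  All generators are pure
functions of (seed, config); each artifact draws from its own named
sub-stream so adding a generator never shifts the others.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely

from .errors import ConfigurationError
from .kba import (
    KBASite,
    ProtectedArea,
    write_protected_areas,
    write_sites,
)
from .rli import (
    ASSESSMENT_YEARS,
    CATEGORY_WEIGHTS,
    TAXA,
    GenuineChange,
    SpeciesAssessment,
    write_species_csv,
)
from .spatial import RasterGrid, SpatialUnit, write_ascii_grid, write_units
from .survey import INDICATORS, SCALES, SECTORS, STATUSES, SurveyResponse, write_survey_csv
from .freshwater import DEFAULT_QUALITY, write_quality_table

__all__ = [
    "ScenarioConfig",
    "Landscape",
    "Scenario",
    "gen_landscape",
    "gen_species_table",
    "gen_sites",
    "gen_survey",
    "generate_scenario",
    "write_scenario",
]

# Fixed sub-stream tags: default_rng([tag, seed]) gives each artifact an
# independent, stable stream.
_STREAM_LANDSCAPE = 101
_STREAM_SPECIES = 202
_STREAM_SITES = 303
_STREAM_SURVEY = 404

REGION_ID = "R0"

# Weighted category pool for last-assessment draws (mostly LC, a tail of
# threatened classes) plus a small Data Deficient share.
_CATEGORY_POOL = ("LC", "NT", "VU", "EN", "CR", "DD")
_CATEGORY_PROBS = (0.50, 0.18, 0.13, 0.09, 0.05, 0.05)
_ORDERED_WEIGHTED = ("LC", "NT", "VU", "EN", "CR")  # one-step neighbors live here

_SCALE_PROBS = {"site": 0.82, "national": 0.76, "watershed": 0.71, "sub-national": 0.68, "regional": 0.65}


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int = 0
    n_units: int = 3
    grid_shape: tuple[int, int] = (20, 20)
    forest_cover_mean: float = 50.0
    true_annual_loss_rate: float = 0.5  # percent of baseline per year
    n_species_per_taxon: tuple[int, int, int] = (12, 15, 10)  # mammal, bird, amphibian
    category_change_prob: float = 0.2
    n_kba: int = 6
    n_pa: int = 8
    missing_date_fraction: float = 0.2
    survey_n: int = 30
    survey_probs: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_kba < 1 or self.n_pa < 1 or self.survey_n < 1:
            raise ConfigurationError("counts must be positive")
        if any(n < 1 for n in self.n_species_per_taxon):
            raise ConfigurationError("species counts must be positive")
        if not (0.0 <= self.category_change_prob <= 1.0):
            raise ConfigurationError("category_change_prob must lie in [0, 1]")
        if not (0.0 <= self.missing_date_fraction <= 1.0):
            raise ConfigurationError("missing_date_fraction must lie in [0, 1]")
        if self.true_annual_loss_rate < 0:
            raise ConfigurationError("loss rate must be non-negative")
        if not (0.0 <= self.forest_cover_mean <= 100.0):
            raise ConfigurationError("forest_cover_mean must lie in [0, 100]")
        if any(p < 0 for p in self.survey_probs) or abs(sum(self.survey_probs) - 1.0) > 1e-9:
            raise ConfigurationError("survey_probs must be non-negative and sum to 1")

    @property
    def country_ids(self) -> tuple[str, ...]:
        return tuple(f"C{i + 1}" for i in range(self.n_units))


def _rng(cfg: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, cfg.seed])


@dataclass
class Landscape:
    cover2000: RasterGrid
    loss: RasterGrid
    landcover: RasterGrid
    runoff: RasterGrid
    ddir: RasterGrid
    population: RasterGrid
    units: list[SpatialUnit]


def _make_units(cfg: ScenarioConfig, rows: int, cols: int) -> list[SpatialUnit]:
    """One region covering the grid plus n_units country strips (columns)."""
    if cols < cfg.n_units:
        raise ConfigurationError(
            f"grid with {cols} columns too small to host {cfg.n_units} country strips"
        )
    units = [
        SpatialUnit(
            id=REGION_ID,
            name="Synthetic Region",
            level="region",
            geometry=shapely.box(0.0, 0.0, float(cols), float(rows)),
        )
    ]
    edges = np.linspace(0, cols, cfg.n_units + 1)
    for i, cid in enumerate(cfg.country_ids):
        units.append(
            SpatialUnit(
                id=cid,
                name=f"Country {i + 1}",
                level="country",
                geometry=shapely.box(float(edges[i]), 0.0, float(edges[i + 1]), float(rows)),
                parent_region=REGION_ID,
            )
        )
    return units


def gen_landscape(cfg: ScenarioConfig) -> Landscape:
    """Aligned raster stack plus analysis units.

    The loss grid is constructed cell-by-cell as
    ``rate * 5 * cover / 100`` so the per-unit annual loss rate is
    recoverable exactly.  The D8 grid routes every cell east or south
    toward a single sink at the bottom-right corner, which makes it
    acyclic by construction.
    """
    rng = _rng(cfg, _STREAM_LANDSCAPE)
    rows, cols = cfg.grid_shape
    units = _make_units(cfg, rows, cols)
    origin = (0.0, float(rows))

    lo = max(0.0, cfg.forest_cover_mean - 20.0)
    hi = min(100.0, cfg.forest_cover_mean + 20.0)
    cover = rng.uniform(lo, hi, size=(rows, cols))
    loss = cfg.true_annual_loss_rate * 5.0 * cover / 100.0

    landcover = rng.integers(0, 4, size=(rows, cols)).astype(float)
    runoff = rng.uniform(0.5, 10.0, size=(rows, cols))
    population = rng.integers(0, 100, size=(rows, cols)).astype(float)

    ddir = np.zeros((rows, cols))
    go_east = rng.random(size=(rows, cols)) < 0.5
    for r in range(rows):
        for c in range(cols):
            if r == rows - 1 and c == cols - 1:
                ddir[r, c] = 0  # sink at the edge, guarantees acyclicity
            elif c == cols - 1:
                ddir[r, c] = 4  # S
            elif r == rows - 1:
                ddir[r, c] = 1  # E
            else:
                ddir[r, c] = 1 if go_east[r, c] else 4

    def grid(vals: np.ndarray, sem: str) -> RasterGrid:
        return RasterGrid(vals, cell_size=1.0, origin=origin, semantics=sem)

    return Landscape(
        cover2000=grid(cover, "percent forest cover 2000"),
        loss=grid(loss, "percent of cell area lost 2000-2005"),
        landcover=grid(landcover, "land cover class"),
        runoff=grid(runoff, "runoff"),
        ddir=grid(ddir, "D8 code"),
        population=grid(population, "persons per cell"),
        units=units,
    )


def _rli_of(cats: Sequence[str]) -> float:
    return 1.0 - sum(CATEGORY_WEIGHTS[c] for c in cats) / (5 * len(cats))


def gen_species_table(
    cfg: ScenarioConfig,
) -> tuple[list[SpeciesAssessment], dict]:
    """Species table with planted one-step genuine changes, plus ground truth.

    The sidecar records the exact RLI at the first and last assessment
    date for every unit x taxon combination (and the pooled 'all' set).
    """
    rng = _rng(cfg, _STREAM_SPECIES)
    countries = cfg.country_ids
    species: list[SpeciesAssessment] = []
    counter = 0
    for taxon, n in zip(TAXA, cfg.n_species_per_taxon):
        for _ in range(n):
            counter += 1
            last = str(rng.choice(_CATEGORY_POOL, p=_CATEGORY_PROBS))
            member = [c for c in countries if rng.random() < 0.5]
            if not member:
                member = [countries[rng.integers(len(countries))]]
            changes: tuple[GenuineChange, ...] = ()
            if last in _ORDERED_WEIGHTED and rng.random() < cfg.category_change_prob:
                idx = _ORDERED_WEIGHTED.index(last)
                neighbors = [i for i in (idx - 1, idx + 1) if 0 <= i < len(_ORDERED_WEIGHTED)]
                frm = _ORDERED_WEIGHTED[neighbors[rng.integers(len(neighbors))]]
                n_drivers = int(rng.integers(1, len(member) + 1))
                driver_countries = sorted(
                    rng.choice(member, size=n_drivers, replace=False).tolist()
                )
                changes = (
                    GenuineChange(
                        from_category=frm,
                        to_category=last,
                        driver_units=frozenset(driver_countries) | {REGION_ID},
                    ),
                )
            species.append(
                SpeciesAssessment(
                    species_id=f"sp{counter:04d}",
                    taxon=taxon,
                    last_category=last,
                    units=frozenset(member) | {REGION_ID},
                    genuine_changes=changes,
                )
            )

    truth: dict[str, dict] = {}
    for unit in (REGION_ID,) + countries:
        members = [sp for sp in species if unit in sp.units and sp.last_category != "DD"]
        for taxon in ("all",) + TAXA:
            subset = members if taxon == "all" else [sp for sp in members if sp.taxon == taxon]
            if not subset:
                continue
            last_cats = [sp.last_category for sp in subset]
            first_cats = []
            for sp in subset:
                cat = sp.last_category
                if sp.genuine_changes and unit in sp.genuine_changes[0].driver_units:
                    cat = sp.genuine_changes[0].from_category
                first_cats.append(cat)
            truth[f"{unit}/{taxon}"] = {
                "rli_first": _rli_of(first_cats),
                "rli_last": _rli_of(last_cats),
                "n_species": len(subset),
            }
    return species, truth


def gen_sites(cfg: ScenarioConfig) -> tuple[list[KBASite], list[ProtectedArea], dict]:
    """KBA and PA rectangles with constructed overlap fractions.

    PAs are vertical slabs of their host KBA, so the true 2010 coverage
    of a site is the length of the union of 1-D intervals.  A
    ``missing_date_fraction`` share of PAs has its establishment year
    withheld; the true year is stored in the sidecar.
    """
    rng = _rng(cfg, _STREAM_SITES)
    rows, cols = cfg.grid_shape
    edges = np.linspace(0, cols, cfg.n_units + 1)
    countries = cfg.country_ids

    # Sites are kept pairwise disjoint by giving each one its own horizontal
    # band inside its country strip, so a PA built for one site can never
    # touch another and the stored overlap fractions stay exact.
    n_in_country = [len(range(ci, cfg.n_kba, cfg.n_units)) for ci in range(cfg.n_units)]
    sites: list[KBASite] = []
    for i in range(cfg.n_kba):
        ci = i % cfg.n_units
        slot = i // cfg.n_units
        x0, x1 = edges[ci], edges[ci + 1]
        band_h = rows / max(n_in_country[ci], 1)
        y0 = slot * band_h
        width = (x1 - x0) * rng.uniform(0.3, 0.8)
        height = band_h * rng.uniform(0.3, 0.8)
        sx = rng.uniform(x0, x1 - width)
        sy = y0 + rng.uniform(0, band_h - height)
        sites.append(
            KBASite(
                site_id=f"kba{i + 1:03d}",
                kind="IBA" if rng.random() < 0.8 else "AZE",
                country_id=countries[ci],
                geometry=shapely.box(sx, sy, sx + width, sy + height),
            )
        )

    pas: list[ProtectedArea] = []
    intervals: dict[str, list[tuple[float, float]]] = {s.site_id: [] for s in sites}
    for j in range(cfg.n_pa):
        site = sites[j % len(sites)]
        minx, miny, maxx, maxy = site.geometry.bounds
        a, b = np.sort(rng.uniform(0.0, 1.0, size=2))
        if b - a < 0.05:
            b = min(1.0, a + 0.05)
        px0 = minx + a * (maxx - minx)
        px1 = minx + b * (maxx - minx)
        intervals[site.site_id].append((a, b))
        pas.append(
            ProtectedArea(
                pa_id=f"pa{j + 1:03d}",
                country_id=site.country_id,
                geometry=shapely.box(px0, miny, px1, maxy),
                establishment_year=int(rng.integers(1950, 2011)),
            )
        )

    def union_length(spans: list[tuple[float, float]]) -> float:
        total, end = 0.0, -1.0
        for a, b in sorted(spans):
            if a > end:
                total += b - a
                end = b
            elif b > end:
                total += b - end
                end = b
        return total

    true_years = {pa.pa_id: pa.establishment_year for pa in pas}
    n_missing = int(round(cfg.missing_date_fraction * cfg.n_pa))
    undated_ids = sorted(
        rng.choice([pa.pa_id for pa in pas], size=n_missing, replace=False).tolist()
    )
    pas = [
        dataclasses.replace(pa, establishment_year=None) if pa.pa_id in undated_ids else pa
        for pa in pas
    ]

    truth = {
        "site_coverage_pct_2010": {
            s.site_id: 100.0 * union_length(intervals[s.site_id]) for s in sites
        },
        "pa_true_years": true_years,
        "undated_pa_ids": undated_ids,
    }
    return sites, pas, truth


def gen_survey(cfg: ScenarioConfig) -> tuple[list[SurveyResponse], dict]:
    """Per-country, per-indicator responses drawn from the status probabilities."""
    rng = _rng(cfg, _STREAM_SURVEY)
    probs = np.asarray(cfg.survey_probs)
    responses: list[SurveyResponse] = []
    for ci, country in enumerate(cfg.country_ids):
        for r in range(cfg.survey_n):
            rid = f"{country}-resp{r + 1:04d}"
            sector = str(rng.choice(SECTORS))
            scales = frozenset(s for s in SCALES if rng.random() < _SCALE_PROBS[s])
            for indicator in INDICATORS:
                responses.append(
                    SurveyResponse(
                        respondent_id=rid,
                        country_id=country,
                        sector=sector,
                        indicator=indicator,
                        status=str(rng.choice(STATUSES, p=probs)),
                        scales_wanted=scales,
                    )
                )
    p1, p2 = cfg.survey_probs[0], cfg.survey_probs[1]
    truth = {"expected_score": p1 + 0.5 * p2, "survey_probs": list(cfg.survey_probs)}
    return responses, truth


@dataclass
class Scenario:
    config: ScenarioConfig
    landscape: Landscape
    species: list[SpeciesAssessment]
    sites: list[KBASite]
    pas: list[ProtectedArea]
    survey: list[SurveyResponse]
    ground_truth: dict = field(default_factory=dict)


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    landscape = gen_landscape(cfg)
    species, rli_truth = gen_species_table(cfg)
    sites, pas, site_truth = gen_sites(cfg)
    survey, survey_truth = gen_survey(cfg)
    truth = {
        "true_annual_loss_rate": cfg.true_annual_loss_rate,
        "rli": rli_truth,
        "kba": site_truth,
        "survey": survey_truth,
    }
    return Scenario(cfg, landscape, species, sites, pas, survey, truth)


def write_scenario(scenario: Scenario, outdir: str) -> None:
    """Write every artifact in the open formats the pipeline reads."""
    os.makedirs(outdir, exist_ok=True)
    ls = scenario.landscape
    write_units(ls.units, os.path.join(outdir, "units.geojson"))
    for name, grid in (
        ("cover2000", ls.cover2000),
        ("loss", ls.loss),
        ("landcover", ls.landcover),
        ("runoff", ls.runoff),
        ("ddir", ls.ddir),
        ("population", ls.population),
    ):
        write_ascii_grid(grid, os.path.join(outdir, f"{name}.asc"))
    write_quality_table(DEFAULT_QUALITY, os.path.join(outdir, "quality.csv"))
    write_species_csv(scenario.species, os.path.join(outdir, "species.csv"))
    write_sites(scenario.sites, os.path.join(outdir, "kba.geojson"))
    write_protected_areas(scenario.pas, os.path.join(outdir, "pa.geojson"))
    write_survey_csv(scenario.survey, os.path.join(outdir, "survey.csv"))
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(scenario.ground_truth, fh, indent=1)
    with open(os.path.join(outdir, "scenario.json"), "w") as fh:
        json.dump(dataclasses.asdict(scenario.config), fh, indent=1)
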