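"""Red List Index per analysis unit and taxon.

The index aggregates extinction-risk categories for a species set:
1 when every species is Least Concern, 0 when every species is Extinct
or Extinct in the Wild.  Trends come from back-casting last-assessment
categories through genuine category changes, counted only when the
driving process operated inside the unit of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataIntegrityError, UndefinedScoreError

__all__ = [
    "CATEGORY_WEIGHTS",
    "UNWEIGHTED_CATEGORIES",
    "ASSESSMENT_YEARS",
    "GenuineChange",
    "SpeciesAssessment",
    "rli",
    "filter_species",
    "backcast_first_categories",
    "annual_rli_change",
    "compute_rli_table",
    "read_species_csv",
    "write_species_csv",
]

# LC=0 ... CR=4, EW and EX share the maximum weight 5.
CATEGORY_WEIGHTS: dict[str, int] = {
    "LC": 0,
    "NT": 1,
    "VU": 2,
    "EN": 3,
    "CR": 4,
    "EW": 5,
    "EX": 5,
}
MAX_WEIGHT = 5
UNWEIGHTED_CATEGORIES = frozenset({"DD", "NE"})

TAXA = ("mammal", "bird", "amphibian")
# (first, last) comprehensive assessment years per taxon group.
ASSESSMENT_YEARS: dict[str, tuple[int, int]] = {
    "mammal": (1996, 2008),
    "bird": (1988, 2008),
    "amphibian": (1980, 2004),
}


def _delta_years(taxon: str) -> float:
    if taxon == "all":
        spans = [last - first for first, last in ASSESSMENT_YEARS.values()]
        return sum(spans) / len(spans)  # mean span across the three groups
    first, last = ASSESSMENT_YEARS[taxon]
    return float(last - first)


@dataclass(frozen=True)
class GenuineChange:
    """A real status change (threat- or action-driven), one category step."""

    from_category: str
    to_category: str
    driver_units: frozenset[str]

    def __post_init__(self) -> None:
        if self.from_category == self.to_category:
            raise DataIntegrityError("genuine change must alter the category")
        for cat in (self.from_category, self.to_category):
            if cat not in CATEGORY_WEIGHTS:
                raise DataIntegrityError(f"genuine change involves unweighted category {cat!r}")


@dataclass
class SpeciesAssessment:
    species_id: str
    taxon: str
    last_category: str
    units: frozenset[str]
    genuine_changes: tuple[GenuineChange, ...] = ()

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise DataIntegrityError(f"unknown taxon {self.taxon!r}")
        if self.last_category not in CATEGORY_WEIGHTS and self.last_category not in UNWEIGHTED_CATEGORIES:
            raise DataIntegrityError(f"unknown category {self.last_category!r}")
        if not self.units:
            raise DataIntegrityError(f"species {self.species_id!r} belongs to no unit")


def rli(categories: Sequence[str]) -> float:
    """Standardized Red List Index: ``1 - sum(weights) / (5 * N)``.

    Data Deficient / Not Evaluated must be filtered out beforehand.
    """
    if len(categories) == 0:
        raise UndefinedScoreError("RLI undefined for an empty species set")
    total = 0
    for cat in categories:
        if cat in UNWEIGHTED_CATEGORIES:
            raise DataIntegrityError(f"unweighted category {cat!r} passed to rli()")
        total += CATEGORY_WEIGHTS[cat]
    return 1.0 - total / (MAX_WEIGHT * len(categories))


def filter_species(
    assessments: Iterable[SpeciesAssessment], unit_id: str
) -> list[SpeciesAssessment]:
    """Species whose range touches the unit, with DD/NE dropped.

    Membership is binary: a species in several units counts fully in each
    (no range-fraction weighting).
    """
    return [
        sp
        for sp in assessments
        if unit_id in sp.units and sp.last_category not in UNWEIGHTED_CATEGORIES
    ]


def backcast_first_categories(
    assessments: Sequence[SpeciesAssessment], unit_id: str
) -> list[str]:
    """Category of each species at the first assessment, for one unit.

    A genuine change is reversed only when its driving process operated
    within the unit; changes driven elsewhere leave the last category in
    place at the first date.
    """
    first = []
    for sp in assessments:
        cat = sp.last_category
        for change in reversed(sp.genuine_changes):
            if change.driver_units & {unit_id}:
                if cat != change.to_category:
                    raise DataIntegrityError(
                        f"species {sp.species_id!r}: cannot reverse change "
                        f"{change.from_category}->{change.to_category} from state {cat}"
                    )
                cat = change.from_category
        if cat in UNWEIGHTED_CATEGORIES:
            raise DataIntegrityError(
                f"species {sp.species_id!r}: back-cast produced unweighted category {cat!r}"
            )
        first.append(cat)
    return first


def annual_rli_change(rli_first: float, rli_last: float, taxon: str) -> float:
    """Per-year RLI change over the taxon's assessment span.

    ``taxon='all'`` divides by the mean span of the three groups.
    Negative values mean deterioration.
    """
    return (rli_last - rli_first) / _delta_years(taxon)


def compute_rli_table(
    assessments: Sequence[SpeciesAssessment], unit_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-unit, per-taxon (and pooled 'all') RLI values and annual change.

    Units or taxa with no weighted species are reported with NaN values
    rather than dropped, so missingness stays explicit.
    """
    rows = []
    for unit_id in unit_ids:
        in_unit = filter_species(assessments, unit_id)
        for taxon in ("all",) + TAXA:
            subset = in_unit if taxon == "all" else [sp for sp in in_unit if sp.taxon == taxon]
            if subset:
                last_cats = [sp.last_category for sp in subset]
                first_cats = backcast_first_categories(subset, unit_id)
                rli_last = rli(last_cats)
                rli_first = rli(first_cats)
                change = annual_rli_change(rli_first, rli_last, taxon)
            else:
                rli_first = rli_last = change = float("nan")
            rows.append(
                {
                    "unit_id": unit_id,
                    "taxon": taxon,
                    "rli_first": rli_first,
                    "rli_last": rli_last,
                    "annual_change": change,
                    "n_species": len(subset),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_species_csv(assessments: Iterable[SpeciesAssessment], path: str) -> None:
    rows = []
    for sp in assessments:
        change = sp.genuine_changes[0] if sp.genuine_changes else None
        rows.append(
            {
                "species_id": sp.species_id,
                "taxon": sp.taxon,
                "last_category": sp.last_category,
                "units": ";".join(sorted(sp.units)),
                "change_from": change.from_category if change else "",
                "change_to": change.to_category if change else "",
                "driver_units": ";".join(sorted(change.driver_units)) if change else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_species_csv(path: str) -> list[SpeciesAssessment]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        changes: tuple[GenuineChange, ...] = ()
        if row["change_from"]:
            changes = (
                GenuineChange(
                    from_category=row["change_from"],
                    to_category=row["change_to"],
                    driver_units=frozenset(row["driver_units"].split(";")) if row["driver_units"] else frozenset(),
                ),
            )
        out.append(
            SpeciesAssessment(
                species_id=row["species_id"],
                taxon=row["taxon"],
                last_category=row["last_category"],
                units=frozenset(row["units"].split(";")),
                genuine_changes=changes,
            )
        )
    return out
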