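"""Pressure indicator: mean forest cover (2000) and annual gross-loss rate.

Loss grids store percent of *cell area* deforested over 2000-2005; the
annual rate converts to percent of the 2000 forest baseline per year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, EmptyMaskError, UndefinedMeanError, UndefinedRateError
from .spatial import RasterGrid, SpatialUnit, rasterize_unit, zonal_mean

__all__ = [
    "ForestResult",
    "mean_forest_cover",
    "mean_gfcl",
    "annual_loss_rate",
    "compute_forest_table",
]

LOSS_PERIOD_YEARS = 5  # 2000-2005


@dataclass(frozen=True)
class ForestResult:
    unit_id: str
    mean_cover_2000: float  # percent of land area
    mean_gfcl: float  # percent of cell area lost 2000-2005
    annual_rate: float | None  # percent of 2000 baseline per year; None if undefined


def mean_forest_cover(cover2000: RasterGrid, mask: np.ndarray) -> float:
    """Zonal mean percent forest cover in 2000."""
    return zonal_mean(cover2000, mask)


def mean_gfcl(loss: RasterGrid, mask: np.ndarray) -> float:
    """Zonal mean gross forest cover loss (percent of cell area, 2000-2005).

    Loss is unidirectional: any negative cell is an input error.
    """
    valid = ~loss.nodata_mask()
    if np.any(loss.values[valid] < 0):
        raise DataIntegrityError("gross forest cover loss must be non-negative (unidirectional)")
    return zonal_mean(loss, mask)


def annual_loss_rate(mean_gfcl_area: float, mean_cover_2000: float) -> float:
    """Annual percent forest loss from the 2000 baseline.

    ``100 * (mean_gfcl_area / mean_cover_2000) / 5``; undefined when the
    unit had no forest in 2000.
    """
    if mean_cover_2000 <= 0:
        raise UndefinedRateError("annual loss rate undefined for zero 2000 forest baseline")
    return 100.0 * (mean_gfcl_area / mean_cover_2000) / LOSS_PERIOD_YEARS


def compute_forest_table(
    units: Sequence[SpatialUnit], cover2000: RasterGrid, loss: RasterGrid
) -> pd.DataFrame:
    """Per-unit forest cover, mean loss, and annual rate (NaN when undefined)."""
    rows = []
    for unit in units:
        try:
            mask = rasterize_unit(unit, cover2000)
            cover = mean_forest_cover(cover2000, mask)
            gfcl = mean_gfcl(loss, mask)
        except (EmptyMaskError, UndefinedMeanError):
            rows.append(
                {"unit_id": unit.id, "mean_cover_2000": np.nan, "mean_gfcl": np.nan, "annual_rate": np.nan}
            )
            continue
        try:
            rate = annual_loss_rate(gfcl, cover)
        except UndefinedRateError:
            rate = np.nan
        rows.append(
            {"unit_id": unit.id, "mean_cover_2000": cover, "mean_gfcl": gfcl, "annual_rate": rate}
        )
    return pd.DataFrame(rows)
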