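"""Benefit indicator: quality-weighted freshwater provision.

A cell's index is its land-cover-quality-weighted runoff times the
population living strictly downstream of it along the D8 drainage
network, normalized by the run-wide maximum.  The result is relative:
values are comparable only within one run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError
from .spatial import RasterGrid

__all__ = [
    "D8_OFFSETS",
    "D8_SINK",
    "FlowGrid",
    "DEFAULT_QUALITY",
    "validate_ddir",
    "quality_weighted_runoff",
    "downstream_population",
    "accumulate",
    "provision_index",
    "unit_mean_provision",
    "read_quality_table",
    "write_quality_table",
]

# ESRI D8 direction codes -> (row, col) offset; 0 marks a terminal sink.
D8_SINK = 0
D8_OFFSETS: dict[int, tuple[int, int]] = {
    1: (0, 1),     # E
    2: (1, 1),     # SE
    4: (1, 0),     # S
    8: (1, -1),    # SW
    16: (0, -1),   # W
    32: (-1, -1),  # NW
    64: (-1, 0),   # N
    128: (-1, 1),  # NE
}

# Stand-in quality coefficients per land-cover class, user-overridable.
DEFAULT_QUALITY: dict[int, float] = {0: 1.0, 1: 0.7, 2: 0.4, 3: 0.1}
QUALITY_CLASS_NAMES = {0: "forest", 1: "shrub", 2: "crop", 3: "urban"}


@dataclass
class FlowGrid:
    """Aligned drainage-direction, runoff, land-cover and population grids."""

    ddir: RasterGrid
    runoff: RasterGrid
    landcover: RasterGrid
    population: RasterGrid
    quality: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_QUALITY))

    def __post_init__(self) -> None:
        shapes = {g.shape for g in (self.ddir, self.runoff, self.landcover, self.population)}
        if len(shapes) != 1:
            raise DataIntegrityError(f"flow grids are not aligned: shapes {shapes}")
        if np.any(self.runoff.values[~self.runoff.nodata_mask()] < 0):
            raise DataIntegrityError("runoff must be non-negative")
        if np.any(self.population.values[~self.population.nodata_mask()] < 0):
            raise DataIntegrityError("population must be non-negative")
        for cls, coef in self.quality.items():
            if not 0.0 <= coef <= 1.0:
                raise ConfigurationError(f"quality coefficient for class {cls} outside [0, 1]: {coef}")


def _downstream_indices(ddir: RasterGrid) -> np.ndarray:
    """Flat index of each cell's receiving neighbor; -1 for sinks.

    Raises on unknown codes and on pointers leaving the grid.
    """
    rows, cols = ddir.shape
    codes = ddir.values.astype(int)
    down = np.full(rows * cols, -1, dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            code = codes[r, c]
            if code == D8_SINK:
                continue
            if code not in D8_OFFSETS:
                raise DataIntegrityError(f"invalid D8 code {code} at cell ({r}, {c})")
            dr, dc = D8_OFFSETS[code]
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols):
                raise DataIntegrityError(f"D8 pointer at ({r}, {c}) leaves the grid")
            down[r * cols + c] = nr * cols + nc
    return down


def validate_ddir(ddir: RasterGrid) -> None:
    """Every flow path must reach a sink within rows*cols steps (no cycles)."""
    down = _downstream_indices(ddir)
    n = down.size
    for start in range(n):
        cur, steps = start, 0
        while down[cur] != -1:
            cur = down[cur]
            steps += 1
            if steps > n:
                raise DataIntegrityError(f"cycle detected in D8 grid from cell {start}")


def quality_weighted_runoff(grid: FlowGrid) -> np.ndarray:
    """Per-cell runoff times the quality coefficient of its land-cover class."""
    classes = grid.landcover.values.astype(int)
    present = set(np.unique(classes).tolist())
    missing = sorted(present - set(grid.quality))
    if missing:
        raise ConfigurationError(f"no quality coefficient for land-cover class(es): {missing}")
    coef = np.vectorize(grid.quality.__getitem__, otypes=[float])(classes)
    return coef * grid.runoff.values


def downstream_population(grid: FlowGrid, inclusive: bool = False) -> np.ndarray:
    """Population summed along each cell's flow path to the sink.

    Strictly downstream by default (the cell's own population excluded);
    ``inclusive=True`` adds it back.
    """
    down = _downstream_indices(grid.ddir)
    pop = grid.population.values.ravel()
    n = down.size
    memo = np.full(n, np.nan)
    for start in range(n):
        if not np.isnan(memo[start]):
            continue
        path = []
        cur = start
        while np.isnan(memo[cur]):
            path.append(cur)
            if down[cur] == -1:
                memo[cur] = 0.0
                path.pop()
                break
            cur = down[cur]
            if len(path) > n:
                raise DataIntegrityError("cycle detected in D8 grid")
        for cell in reversed(path):
            nxt = down[cell]
            memo[cell] = pop[nxt] + memo[nxt]
    result = memo.reshape(grid.ddir.shape)
    if inclusive:
        result = result + grid.population.values
    return result


def accumulate(ddir: RasterGrid, values: np.ndarray) -> np.ndarray:
    """Flow accumulation: each cell's value plus everything draining into it.

    Used for the mass-conservation check: summed over sinks, the
    accumulation equals the grid-wide total input.
    """
    down = _downstream_indices(ddir)
    vals = np.asarray(values, dtype=float).ravel().copy()
    n = down.size
    indeg = np.zeros(n, dtype=int)
    for d in down:
        if d != -1:
            indeg[d] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    acc = vals.copy()
    processed = 0
    while queue:
        cell = queue.pop()
        processed += 1
        d = down[cell]
        if d != -1:
            acc[d] += acc[cell]
            indeg[d] -= 1
            if indeg[d] == 0:
                queue.append(d)
    if processed != n:
        raise DataIntegrityError("cycle detected in D8 grid during accumulation")
    return acc.reshape(ddir.shape)


def provision_index(grid: FlowGrid, inclusive: bool = False) -> RasterGrid:
    """Relative per-cell freshwater provision index on [0, 1].

    quality-weighted runoff x downstream population, divided by the
    run-wide maximum.  An all-zero field is returned unnormalized.
    """
    raw = quality_weighted_runoff(grid) * downstream_population(grid, inclusive=inclusive)
    peak = raw.max()
    if peak > 0:
        raw = raw / peak
    else:
        import logging

        logging.getLogger(__name__).info("provision index is identically zero; skipping normalization")
    return grid.runoff.copy_with(raw, semantics="freshwater provision index (relative)")


def unit_mean_provision(index: RasterGrid, mask: np.ndarray) -> float:
    """Mean provision index over a unit mask (zonal mean semantics)."""
    from .spatial import zonal_mean

    return zonal_mean(index, mask)


def read_quality_table(path: str) -> dict[int, float]:
    df = pd.read_csv(path)
    return {int(r["class"]): float(r["coefficient"]) for _, r in df.iterrows()}


def write_quality_table(quality: Mapping[int, float], path: str) -> None:
    pd.DataFrame(
        {"class": list(quality), "coefficient": [quality[c] for c in quality]}
    ).to_csv(path, index=False)
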