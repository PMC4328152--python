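"""Area-of-occupancy scoring on a fixed geographic grid.

The area of occupancy of a species is the number of fixed-size grid cells
(default 0.5 degree) that contain at least one occurrence record.  Cells are
half-open intervals ``[k*cell, (k+1)*cell)`` anchored at (0, 0), with floor
semantics for negative coordinates, so every coordinate belongs to exactly
one cell.  The score is a cell count (not an area): any constant multiple is
irrelevant to the downstream log-scale regression, where species occupying a
single cell contribute ``log(1) = 0``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = ["OccupancyScore", "cell_index", "occupancy", "occupancy_table"]

DEFAULT_CELL_SIZE = 0.5  # degrees


@dataclass(frozen=True)
class OccupancyScore:
    species: str
    n_cells: int
    cell_size: float


def cell_index(lat: float, lon: float,
               cell_size: float = DEFAULT_CELL_SIZE) -> tuple[int, int]:
    """Grid cell of a coordinate: ``(floor(lat/cell), floor(lon/cell))``."""
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not (-180.0 <= lon < 180.0):
        raise ValueError(f"longitude {lon} outside [-180, 180)")
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    return math.floor(lat / cell_size), math.floor(lon / cell_size)


def occupancy(species: str, coords: Iterable[tuple[float, float]],
              cell_size: float = DEFAULT_CELL_SIZE) -> OccupancyScore | None:
    """Count distinct occupied cells; invalid records are skipped with a
    warning, and a species with no valid record gets a missing score."""
    cells = set()
    bad = 0
    for lat, lon in coords:
        try:
            cells.add(cell_index(float(lat), float(lon), cell_size))
        except (ValueError, TypeError):
            bad += 1
    if bad:
        warnings.warn(f"{species}: skipped {bad} invalid occurrence records",
                      stacklevel=2)
    if not cells:
        return None
    return OccupancyScore(species=species, n_cells=len(cells),
                          cell_size=cell_size)


def occupancy_table(occurrences: pd.DataFrame,
                    cell_size: float = DEFAULT_CELL_SIZE) -> pd.DataFrame:
    """Per-species occupancy scores from an occurrence frame with columns
    ``species``, ``latitude``, ``longitude``."""
    rows = []
    for sp, grp in occurrences.groupby("species", sort=True):
        score = occupancy(sp, zip(grp["latitude"], grp["longitude"]), cell_size)
        if score is not None:
            rows.append({"species": sp, "occupancy": score.n_cells,
                         "cell_size": cell_size})
    return pd.DataFrame(rows, columns=["species", "occupancy", "cell_size"])
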