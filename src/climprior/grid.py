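"""Grid domain, climate layers, species records and occupancy matrices.

The study region is a regular latitude-longitude grid. Cells are indexed
(row, col) from the lower-left corner, 0-based, with row 0 the southernmost
row. In-mask cells receive contiguous integer ids 0..N-1 in row-major order
(row 0 first, then row 1, ...). All distances downstream use cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Bioclimatic variables carried by every climate layer set, in order:
#: annual mean temperature (degC), temperature seasonality (SD x 100),
#: annual precipitation (mm), precipitation seasonality (CV).
CLIMATE_VARS = (
    "annual_mean_temp",
    "temp_seasonality",
    "annual_precip",
    "precip_seasonality",
)

#: Feature weights by IUCN Red List category: non-threatened 1, vulnerable
#: and data-deficient 2, endangered 3, critically endangered 4.
IUCN_WEIGHTS = {"LC": 1.0, "NT": 1.0, "VU": 2.0, "DD": 2.0, "EN": 3.0, "CR": 4.0}

#: km per degree used to scale grid distances; the grid is treated as
#: equal-area with a single isotropic factor (no latitude correction).
KM_PER_DEGREE = 111.32


class DomainError(ValueError):
    """Raised for invalid grid-domain construction or mismatched layers."""


@dataclass(frozen=True)
class GridDomain:
    """Regular grid with a study mask and stable in-mask cell ids."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float]  # (lon, lat) of lower-left corner of cell (0, 0)
    study_mask: np.ndarray  # bool, shape (n_rows, n_cols)
    # derived, filled in __post_init__
    cell_id_grid: np.ndarray = field(init=False, repr=False, compare=False)
    cell_rows: np.ndarray = field(init=False, repr=False, compare=False)
    cell_cols: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.study_mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise DomainError(
                f"study_mask shape {mask.shape} != ({self.n_rows}, {self.n_cols})"
            )
        if not mask.any():
            raise DomainError("empty domain: study_mask selects no cells")
        object.__setattr__(self, "study_mask", mask)
        ids = np.full(mask.shape, -1, dtype=np.int64)
        rows, cols = np.nonzero(mask)  # row-major order
        ids[rows, cols] = np.arange(rows.size)
        object.__setattr__(self, "cell_id_grid", ids)
        object.__setattr__(self, "cell_rows", rows)
        object.__setattr__(self, "cell_cols", cols)

    @property
    def n_cells(self) -> int:
        """Number of in-mask cells N."""
        return int(self.cell_rows.size)

    def cell_id(self, row: int, col: int) -> int:
        cid = int(self.cell_id_grid[row, col])
        if cid < 0:
            raise DomainError(f"cell ({row}, {col}) is outside the study mask")
        return cid

    def row_col(self, cell_id: int) -> tuple[int, int]:
        return int(self.cell_rows[cell_id]), int(self.cell_cols[cell_id])

    def cell_centers_lonlat(self) -> np.ndarray:
        """(N, 2) array of cell-center (lon, lat) coordinates."""
        lon = self.origin[0] + (self.cell_cols + 0.5) * self.cell_size
        lat = self.origin[1] + (self.cell_rows + 0.5) * self.cell_size
        return np.column_stack([lon, lat])

    def cell_centers_units(self) -> np.ndarray:
        """(N, 2) array of cell-center (x, y) in cell units from the origin."""
        return np.column_stack([self.cell_cols + 0.5, self.cell_rows + 0.5])

    @property
    def km_per_cell(self) -> float:
        return self.cell_size * KM_PER_DEGREE

    def to_grid(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a length-N vector onto the full (n_rows, n_cols) grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_cells:
            raise DomainError(
                f"layer length {values.shape[-1]} != n_cells {self.n_cells}"
            )
        out = np.full(self.study_mask.shape, fill, dtype=float)
        out[self.cell_rows, self.cell_cols] = values
        return out

    def from_grid(self, grid: np.ndarray) -> np.ndarray:
        """Gather a full grid into the length-N in-mask vector."""
        grid = np.asarray(grid)
        if grid.shape != self.study_mask.shape:
            raise DomainError(f"grid shape {grid.shape} != domain shape")
        return grid[self.cell_rows, self.cell_cols]


def rasterize_domain(
    n_rows: int,
    n_cols: int,
    cell_size: float,
    origin: tuple[float, float],
    study_mask: np.ndarray | None = None,
) -> GridDomain:
    """Build a :class:`GridDomain`; a missing mask means all cells in-study."""
    if n_rows < 1 or n_cols < 1:
        raise DomainError("n_rows and n_cols must be >= 1")
    if study_mask is None:
        study_mask = np.ones((n_rows, n_cols), dtype=bool)
    return GridDomain(n_rows, n_cols, float(cell_size), tuple(origin), study_mask)


@dataclass(frozen=True)
class ClimateLayerSet:
    """Four bioclimatic layers over one domain for one scenario.

    ``values`` has shape (N, 4) over in-mask cells, columns in
    :data:`CLIMATE_VARS` order.
    """

    scenario_id: str
    domain: GridDomain
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.domain.n_cells, len(CLIMATE_VARS)):
            raise DomainError(
                f"climate values shape {values.shape} != "
                f"({self.domain.n_cells}, {len(CLIMATE_VARS)})"
            )
        if not np.isfinite(values).all():
            raise DomainError("climate layers contain non-finite values in-mask")
        object.__setattr__(self, "values", values)

    def layer(self, var: str) -> np.ndarray:
        return self.values[:, CLIMATE_VARS.index(var)]


@dataclass(frozen=True)
class SpeciesRecord:
    """A species with its IUCN Red List category and derived feature weight."""

    species_id: str
    iucn_category: str

    def __post_init__(self) -> None:
        if self.iucn_category not in IUCN_WEIGHTS:
            raise ValueError(
                f"unknown IUCN category {self.iucn_category!r}; "
                f"expected one of {sorted(IUCN_WEIGHTS)}"
            )

    @property
    def weight(self) -> float:
        return IUCN_WEIGHTS[self.iucn_category]


@dataclass
class OccupancyMatrix:
    """Binary species x cell presence matrix for one scenario."""

    scenario_id: str
    species_ids: list[str]
    matrix: np.ndarray  # shape (S, N), values in {0, 1}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("occupancy matrix entries must be 0 or 1")
        if m.shape[0] != len(self.species_ids):
            raise ValueError("species_ids length != matrix rows")
        self.matrix = m.astype(np.uint8)

    def row(self, species_id: str) -> np.ndarray:
        try:
            idx = self.species_ids.index(species_id)
        except ValueError:
            raise KeyError(f"unknown species id {species_id!r}") from None
        return self.matrix[idx]


def range_size(occupancy: OccupancyMatrix, species_id: str) -> int:
    """Number of occupied cells for one species (its range size in cells)."""
    return int(occupancy.row(species_id).sum())
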