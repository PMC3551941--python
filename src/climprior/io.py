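"""Readers and writers for the package's plain-text formats.

Grid layers travel as ESRI ASCII grids (.asc) with NODATA marking cells
outside the study mask; occupancy matrices as (species_id, cell_id, value)
CSV triplets; species attributes as a two-column CSV. Write-then-read
round-trips are exact to the printed precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grid import DomainError, GridDomain, OccupancyMatrix, SpeciesRecord

NODATA_DEFAULT = -9999.0
#: float format used for every CSV / .asc value (byte-reproducible runs)
FLOAT_FORMAT = "%.9g"


def write_asc(
    path: str | Path,
    values: np.ndarray,
    domain: GridDomain,
    nodata: float = NODATA_DEFAULT,
) -> Path:
    """Write a length-N in-mask layer as an ESRI ASCII grid.

    Rows are written north to south (ESRI convention) while the domain
    indexes rows from the south, so the grid is flipped on output.
    """
    path = Path(path)
    grid = domain.to_grid(np.asarray(values, dtype=float), fill=np.nan)
    grid = np.where(np.isnan(grid), nodata, grid)
    header = (
        f"ncols {domain.n_cols}\n"
        f"nrows {domain.n_rows}\n"
        f"xllcorner {FLOAT_FORMAT % domain.origin[0]}\n"
        f"yllcorner {FLOAT_FORMAT % domain.origin[1]}\n"
        f"cellsize {FLOAT_FORMAT % domain.cell_size}\n"
        f"NODATA_value {FLOAT_FORMAT % nodata}\n"
    )
    body = "\n".join(
        " ".join(FLOAT_FORMAT % v for v in row) for row in grid[::-1]
    )
    path.write_text(header + body + "\n")
    return path


def read_asc(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid.

    Returns the full (n_rows, n_cols) array with rows indexed from the south
    and NODATA replaced by NaN, plus the parsed header dict.
    """
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    }:
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = np.loadtxt(lines[i:], dtype=float).reshape(n_rows, n_cols)
    data = data[::-1]  # back to south-first row order
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, header


def read_layer(path: str | Path, domain: GridDomain) -> np.ndarray:
    """Read an .asc layer and return the in-mask length-N vector."""
    grid, header = read_asc(path)
    if grid.shape != (domain.n_rows, domain.n_cols):
        raise DomainError(
            f"{path}: grid shape {grid.shape} does not match domain "
            f"({domain.n_rows}, {domain.n_cols})"
        )
    return domain.from_grid(grid)


def domain_from_asc(path: str | Path) -> GridDomain:
    """Build a domain from an .asc file; NODATA cells fall outside the mask."""
    grid, header = read_asc(path)
    return GridDomain(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=float(header["cellsize"]),
        origin=(float(header["xllcorner"]), float(header["yllcorner"])),
        study_mask=~np.isnan(grid),
    )


def write_occupancy_csv(
    path: str | Path, occupancy: OccupancyMatrix
) -> Path:
    """Write an occupancy matrix as sparse (species_id, cell_id, value) triplets."""
    path = Path(path)
    rows, cols = np.nonzero(occupancy.matrix)
    df = pd.DataFrame(
        {
            "species_id": [occupancy.species_ids[r] for r in rows],
            "cell_id": cols,
            "value": np.ones(cols.size, dtype=int),
        }
    )
    df.to_csv(path, index=False)
    return path


def read_occupancy_csv(
    path: str | Path,
    scenario_id: str,
    n_cells: int,
    species_ids: list[str] | None = None,
) -> OccupancyMatrix:
    """Read triplet CSV into an :class:`OccupancyMatrix`.

    ``species_ids`` fixes row order (and keeps empty-range species); if
    omitted, species appear in first-seen order.
    """
    df = pd.read_csv(path)
    if species_ids is None:
        species_ids = list(dict.fromkeys(df["species_id"].astype(str)))
    index = {s: i for i, s in enumerate(species_ids)}
    matrix = np.zeros((len(species_ids), n_cells), dtype=np.uint8)
    for sid, cid, val in zip(df["species_id"].astype(str), df["cell_id"], df["value"]):
        if int(val):
            matrix[index[sid], int(cid)] = 1
    return OccupancyMatrix(scenario_id, list(species_ids), matrix)


def write_species_csv(path: str | Path, species: list[SpeciesRecord]) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "species_id": [s.species_id for s in species],
            "iucn_category": [s.iucn_category for s in species],
        }
    ).to_csv(path, index=False)
    return path


def read_species_csv(path: str | Path) -> list[SpeciesRecord]:
    df = pd.read_csv(path)
    return [
        SpeciesRecord(str(r.species_id), str(r.iucn_category))
        for r in df.itertuples()
    ]


def write_table(path: str | Path, df: pd.DataFrame) -> Path:
    """CSV writer with the package-wide fixed float format."""
    path = Path(path)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path
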