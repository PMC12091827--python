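"""Geographic projection of niches and niche changes.

For one species, one variable, and the branch leading to it, every cell of
the accessible area is categorized by binning its environmental value and
comparing the ancestor's (A) and descendant's (D) states at that bin:
both (1/1), ancestral_only (1/0: the retraction zone), current_only (0/1:
the expansion zone), neither (0/0), indeterminate (any '?'), with cells
outside M marked outside_M.  Categories are exported as integer-coded
ASCII grids with a JSON legend sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bar_coding import ABSENT, PRESENT, BinScheme
from .errors import MismatchError
from .geo_io import EnvGrid, read_env_grid, write_env_grid
from .m_simulation import AccessibleArea

CATEGORY_CODES = {
    "outside_M": 0,
    "both": 1,
    "ancestral_only": 2,
    "current_only": 3,
    "neither": 4,
    "indeterminate": 5,
}
CODE_NAMES = {v: k for k, v in CATEGORY_CODES.items()}


@dataclass
class ProjectionGrid:
    species: str
    variable: str
    categories: np.ndarray  # int lattice over CATEGORY_CODES values
    frame: EnvGrid
    n_out_of_scheme: int = 0

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.categories == code))
            for name, code in CATEGORY_CODES.items()
        }


def project_change(
    species: str,
    area: AccessibleArea,
    grid: EnvGrid,
    scheme: BinScheme,
    A,
    D,
) -> ProjectionGrid:
    """Paint ancestor/descendant niche agreement onto the accessible area."""
    A = np.asarray(A, dtype="<U1")
    D = np.asarray(D, dtype="<U1")
    if len(A) != scheme.n_bins or len(D) != scheme.n_bins:
        raise MismatchError("state vectors not aligned to the bin scheme")
    if area.mask.shape != grid.values.shape:
        raise MismatchError("accessible area and grid are not on the same frame")

    cats = np.full(grid.values.shape, CATEGORY_CODES["outside_M"], dtype=int)
    m = area.mask & grid.data_mask
    vals = grid.values[m]
    with np.errstate(invalid="ignore"):
        in_range = (vals >= scheme.global_min) & (vals <= scheme.global_max)
    idx = np.clip(
        ((vals - scheme.global_min) / scheme.width).astype(int), 0, scheme.n_bins - 1
    )
    a = A[idx]
    d = D[idx]
    cell_cat = np.full(vals.shape, CATEGORY_CODES["indeterminate"], dtype=int)
    certain = (a != "?") & (d != "?") & in_range
    cell_cat[certain & (a == PRESENT) & (d == PRESENT)] = CATEGORY_CODES["both"]
    cell_cat[certain & (a == PRESENT) & (d == ABSENT)] = CATEGORY_CODES["ancestral_only"]
    cell_cat[certain & (a == ABSENT) & (d == PRESENT)] = CATEGORY_CODES["current_only"]
    cell_cat[certain & (a == ABSENT) & (d == ABSENT)] = CATEGORY_CODES["neither"]
    cats[m] = cell_cat
    return ProjectionGrid(
        species=species,
        variable=scheme.variable,
        categories=cats,
        frame=grid,
        n_out_of_scheme=int(np.sum(~in_range)),
    )


def category_centroid(pg: ProjectionGrid, category: str) -> tuple[float, float] | None:
    """Mean (lon, lat) of the cells in one category, or None if empty."""
    code = CATEGORY_CODES[category]
    cells = np.argwhere(pg.categories == code)
    if cells.size == 0:
        return None
    centers = np.array([pg.frame.cell_center(int(r), int(c)) for r, c in cells])
    return float(centers[:, 0].mean()), float(centers[:, 1].mean())


def export_category_grid(pg: ProjectionGrid, path) -> None:
    """Integer-coded ASCII grid plus ``<path>.legend.json`` sidecar."""
    grid = EnvGrid(
        variable=f"{pg.species}:{pg.variable}:categories",
        values=pg.categories.astype(float),
        nodata_mask=np.zeros_like(pg.categories, dtype=bool),
        xllcorner=pg.frame.xllcorner,
        yllcorner=pg.frame.yllcorner,
        cell_size=pg.frame.cell_size,
    )
    write_env_grid(grid, path)
    with open(f"{path}.legend.json", "w") as fh:
        json.dump(
            {
                "species": pg.species,
                "variable": pg.variable,
                "codes": CATEGORY_CODES,
            },
            fh,
            indent=1,
        )


def read_category_grid(path) -> np.ndarray:
    grid = read_env_grid(path)
    return grid.values.astype(int)
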