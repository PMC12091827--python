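"""Spatial I/O and occurrence hygiene.

Environmental layers live on a single shared lat/lon frame (WGS84,
lower-left-corner registered, equal x/y cell size) read and written in the
ESRI ASCII grid dialect.  Occurrence tables are plain CSV
(``species,longitude,latitude[,source]``).  Spatial thinning enforces a
minimum pairwise great-circle distance (default 5.2 km) while keeping as
many points as possible; the four "interactive" bioclim variables that mix
temperature and precipitation signals (bio8, bio9, bio18, bio19) can be
filtered out of a variable set.

Grid convention: ``values[0, 0]`` is the north-west (top-left) cell, rows
run north to south, exactly as serialized in the ASCII dialect.  Cells are
half-open ``[x, x + cellsize) x [y, y + cellsize)``; a point on the extreme
top/right boundary of the extent maps to the last cell.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptySpeciesError,
    FormatError,
    InvalidInputError,
    MismatchError,
)
from .trees import DatedTree

EARTH_RADIUS_KM = 6371.0088
INTERACTIVE_VARIABLES = ("bio8", "bio9", "bio18", "bio19")

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class EnvGrid:
    """One climatic variable on the shared georeferenced lattice.

    ``values`` holds NaN on nodata cells; ``nodata_mask`` is True there.
    """

    variable: str
    values: np.ndarray  # (n_rows, n_cols) float, NaN at nodata
    nodata_mask: np.ndarray  # (n_rows, n_cols) bool
    xllcorner: float
    yllcorner: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.nodata_mask.shape:
            raise InvalidInputError("values and nodata_mask shapes differ")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise InvalidInputError("non-finite values on data cells")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def data_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def same_frame(self, other: "EnvGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.xllcorner, other.xllcorner, abs_tol=1e-9)
            and math.isclose(self.yllcorner, other.yllcorner, abs_tol=1e-9)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
        )

    def require_same_frame(self, other: "EnvGrid") -> None:
        if not self.same_frame(other):
            raise MismatchError(
                f"grids {self.variable!r} and {other.variable!r} are not on "
                "the same spatial frame"
            )

    # -- geometry ----------------------------------------------------

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.n_cols * self.cell_size,
            self.yllcorner + self.n_rows * self.cell_size,
        )

    def contains(self, lon: float, lat: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= lon <= xmax and ymin <= lat <= ymax

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Map a point to (row, col); top/right boundary maps inward."""
        if not self.contains(lon, lat):
            raise InvalidInputError(f"point ({lon}, {lat}) outside extent")
        col = int((lon - self.xllcorner) / self.cell_size)
        row_from_bottom = int((lat - self.yllcorner) / self.cell_size)
        col = min(col, self.n_cols - 1)
        row_from_bottom = min(row_from_bottom, self.n_rows - 1)
        return self.n_rows - 1 - row_from_bottom, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xllcorner + (col + 0.5) * self.cell_size
        lat = self.yllcorner + (self.n_rows - row - 0.5) * self.cell_size
        return lon, lat

    def value_at(self, lon: float, lat: float) -> float:
        r, c = self.cell_of(lon, lat)
        return float(self.values[r, c])


@dataclass
class OccurrenceSet:
    species: str
    points: list[tuple[float, float]]  # (lon, lat)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class VariableSet:
    names: list[str]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.names) & set(self.excluded)
        if overlap:
            raise InvalidInputError(f"variables both retained and excluded: {overlap}")


# ---------------------------------------------------------------- grids


def write_env_grid(grid: EnvGrid, path, nodata_value: float = -9999.0) -> None:
    """Serialize as ESRI ASCII grid; floats use repr() so the round trip
    is bit-exact."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(grid.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(grid.yllcorner)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(nodata_value)!r}\n")
        for r in range(grid.n_rows):
            row = [
                repr(float(nodata_value))
                if grid.nodata_mask[r, c]
                else repr(float(grid.values[r, c]))
                for c in range(grid.n_cols)
            ]
            fh.write(" ".join(row) + "\n")


def read_env_grid(path, variable: str | None = None) -> EnvGrid:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"line {i + 1}: bad header value {parts[1]!r}") from exc
        else:
            break
    else:
        i += 1
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(f"line {i + 1}: incomplete header, missing {missing}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    body = [ln for ln in lines[i:] if ln.strip()]
    if len(body) != n_rows:
        raise FormatError(
            f"line {i + 1}: expected {n_rows} data rows, found {len(body)}"
        )
    values = np.empty((n_rows, n_cols), dtype=float)
    for r, line in enumerate(body):
        parts = line.split()
        if len(parts) != n_cols:
            raise FormatError(
                f"line {i + 1 + r}: expected {n_cols} columns, found {len(parts)}"
            )
        values[r] = [float(p) for p in parts]
    mask = values == nodata
    values[mask] = np.nan
    name = variable if variable is not None else _stem(path)
    return EnvGrid(
        variable=name,
        values=values,
        nodata_mask=mask,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cell_size=header["cellsize"],
    )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# ----------------------------------------------------------- occurrences


def write_occurrences(occs: list[OccurrenceSet], path) -> None:
    rows = []
    for occ in occs:
        prov = occ.provenance or [""] * len(occ.points)
        for (lon, lat), src in zip(occ.points, prov):
            rows.append((occ.species, lon, lat, src))
    df = pd.DataFrame(rows, columns=["species", "longitude", "latitude", "source"])
    df.to_csv(path, index=False)


def read_occurrences(path) -> dict[str, OccurrenceSet]:
    df = pd.read_csv(path)
    required = {"species", "longitude", "latitude"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"occurrence CSV must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    out: dict[str, OccurrenceSet] = {}
    for sp, sub in df.groupby("species", sort=True):
        prov = (
            sub["source"].fillna("").astype(str).tolist()
            if "source" in sub.columns
            else []
        )
        out[str(sp)] = OccurrenceSet(
            species=str(sp),
            points=list(zip(sub["longitude"].astype(float), sub["latitude"].astype(float))),
            provenance=prov,
        )
    return out


def validate_occurrences(
    occ: OccurrenceSet, frame: EnvGrid, report: list | None = None
) -> OccurrenceSet:
    """Keep only points inside the extent and on data cells.

    Dropped points are appended to ``report`` (if given) as
    ``(lon, lat, reason)`` with reason "out-of-extent" or "nodata".
    Raises :class:`EmptySpeciesError` when nothing survives.
    """
    kept: list[tuple[float, float]] = []
    kept_prov: list[str] = []
    prov = occ.provenance or [""] * len(occ.points)
    for (lon, lat), src in zip(occ.points, prov):
        if not frame.contains(lon, lat):
            if report is not None:
                report.append((lon, lat, "out-of-extent"))
            continue
        r, c = frame.cell_of(lon, lat)
        if frame.nodata_mask[r, c]:
            if report is not None:
                report.append((lon, lat, "nodata"))
            continue
        kept.append((lon, lat))
        kept_prov.append(src)
    if not kept:
        raise EmptySpeciesError(
            f"all {len(occ.points)} occurrences of {occ.species!r} were invalid"
        )
    return OccurrenceSet(occ.species, kept, kept_prov)


def haversine_km(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Great-circle distance in km between (lon, lat) points."""
    lon1, lat1, lon2, lat2 = map(math.radians, (*p, *q))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def dedup_per_cell(occ: OccurrenceSet, frame: EnvGrid) -> OccurrenceSet:
    """Keep the first point per grid cell (pixel-level deduplication)."""
    seen: set[tuple[int, int]] = set()
    kept, kept_prov = [], []
    prov = occ.provenance or [""] * len(occ.points)
    for (lon, lat), src in zip(occ.points, prov):
        cell = frame.cell_of(lon, lat)
        if cell in seen:
            continue
        seen.add(cell)
        kept.append((lon, lat))
        kept_prov.append(src)
    return OccurrenceSet(occ.species, kept, kept_prov)


def _mis_exact(n: int, adj: list[set[int]], vertices: frozenset[int]):
    """Max independent set on a small conflict graph by branch and bound.

    Returns the lexicographically smallest optimal set of vertex indices.
    """

    best: list[tuple[int, ...]] = [()]

    def better(cand: tuple[int, ...]) -> bool:
        cur = best[0]
        return len(cand) > len(cur) or (len(cand) == len(cur) and cand < cur)

    def rec(avail: frozenset[int], chosen: tuple[int, ...]) -> None:
        if len(chosen) + len(avail) < len(best[0]):
            return
        if not avail:
            if better(chosen):
                best[0] = chosen
            return
        # isolated vertices are always taken
        iso = sorted(v for v in avail if not (adj[v] & avail))
        if iso:
            rec(avail - set(iso), tuple(sorted(chosen + tuple(iso))))
            return
        v = min(avail, key=lambda u: (-len(adj[u] & avail), u))
        # include v
        rec(avail - {v} - adj[v], tuple(sorted(chosen + (v,))))
        # exclude v
        rec(avail - {v}, chosen)

    rec(vertices, ())
    return set(best[0])


def thin_occurrences(
    occ: OccurrenceSet, min_dist_km: float = 5.2, exact_limit: int = 25
) -> OccurrenceSet:
    """Spatial thinning to a minimum pairwise great-circle distance.

    Retains a maximum-size subset with all pairwise distances >=
    ``min_dist_km``: the conflict graph (edges join points closer than the
    threshold) is split into connected components; components up to
    ``exact_limit`` vertices are solved exactly (maximum independent set,
    deterministic lexicographic tie-break), larger ones greedily by
    repeatedly deleting the point with the most close neighbors (ties to
    the lowest input index).  Deterministic and idempotent.
    """
    if min_dist_km <= 0:
        raise InvalidInputError("min_dist_km must be positive")
    pts = occ.points
    n = len(pts)
    if n <= 1:
        return occ
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        if haversine_km(pts[i], pts[j]) < min_dist_km:
            adj[i].add(j)
            adj[j].add(i)
    # connected components
    unvisited = set(range(n))
    keep: set[int] = set()
    while unvisited:
        start = min(unvisited)
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for w in adj[v]:
                if w not in comp:
                    comp.add(w)
                    frontier.append(w)
        unvisited -= comp
        if len(comp) == 1:
            keep |= comp
        elif len(comp) <= exact_limit:
            keep |= _mis_exact(n, adj, frozenset(comp))
        else:
            alive = set(comp)
            while True:
                deg = {v: len(adj[v] & alive) for v in alive}
                worst = max(deg.values())
                if worst == 0:
                    break
                alive.discard(min(v for v in alive if deg[v] == worst))
            keep |= alive
    idx = sorted(keep)
    prov = occ.provenance or [""] * n
    return OccurrenceSet(occ.species, [pts[i] for i in idx], [prov[i] for i in idx])


def exclude_interactive_variables(vars: VariableSet) -> VariableSet:
    """Move bio8/bio9/bio18/bio19 (mixed temperature-precipitation
    quarter variables) to the excluded list."""
    retained = [v for v in vars.names if v not in INTERACTIVE_VARIABLES]
    newly = [v for v in vars.names if v in INTERACTIVE_VARIABLES]
    return VariableSet(names=retained, excluded=list(vars.excluded) + newly)


# ---------------------------------------------------------------- trees


def read_newick(path) -> DatedTree:
    with open(path) as fh:
        return DatedTree.from_newick(fh.read())


def write_newick(tree: DatedTree, path, label_internal: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(label_internal=label_internal) + "\n")
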