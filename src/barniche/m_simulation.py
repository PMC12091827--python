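"""Accessible-area (M) estimation by iterated dispersal.

A species' accessible area is the set of grid cells reachable from its
known occurrences by repeated dispersal over an environmental-suitability
surface.  Suitability is a truncated Mahalanobis-ellipsoid envelope fitted
to the occurrence environments (rescaled to [0, 1]); dispersal uses a
log-normal kernel with median displacement of one cell width, so the
kernel's log-SD is the single spread parameter.  Defaults follow the
standard parameterization for a ~35-year climate reference window: 35
dispersal events, at most 2 dispersers per colonized cell per event,
kernel SD 0.50 (screened candidates 0.25/0.50/0.75).

Species with too few records for a defensible envelope fall back to an
"occurrence only" area covering exactly the occupied cells.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidInputError, LowRecordError, MismatchError, NoHabitatError
from .geo_io import EnvGrid, OccurrenceSet

logger = logging.getLogger(__name__)

KERNEL_SD_CANDIDATES = (0.25, 0.50, 0.75)


@dataclass
class DispersalConfig:
    n_events: int = 35
    max_dispersers: int = 2
    kernel_sd: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise InvalidInputError("n_events must be >= 0")
        if self.max_dispersers < 1:
            raise InvalidInputError("max_dispersers must be >= 1")
        if not self.kernel_sd > 0:
            raise InvalidInputError("kernel_sd must be > 0")


@dataclass
class SuitabilitySurface:
    species: str
    values: np.ndarray  # [0, 1] on data cells, NaN at nodata
    frame: EnvGrid  # georeference donor (values ignored)


@dataclass
class AccessibleArea:
    species: str
    mask: np.ndarray  # boolean lattice on the shared frame
    status: str  # "simulated" | "occurrence_only"
    note: str = ""


def occupied_cells(occ: OccurrenceSet, frame: EnvGrid) -> np.ndarray:
    """Boolean lattice of cells containing occurrence points."""
    mask = np.zeros(frame.values.shape, dtype=bool)
    for lon, lat in occ.points:
        r, c = frame.cell_of(lon, lat)
        if frame.nodata_mask[r, c]:
            raise InvalidInputError(
                f"occurrence of {occ.species!r} on a nodata cell; validate first"
            )
        mask[r, c] = True
    return mask


def fit_suitability(
    occ: OccurrenceSet,
    grids: list[EnvGrid],
    truncation_q: float = 0.95,
    min_records: int = 5,
) -> SuitabilitySurface:
    """Truncated Mahalanobis-ellipsoid envelope in environment space.

    Suitability decreases linearly in squared Mahalanobis distance from
    the occurrence centroid; cells whose distance exceeds the chi-square
    quantile ``truncation_q`` (df = number of variables) get 0.  The
    surface is rescaled so its maximum over data cells is 1 (a cell at the
    centroid scores exactly 1).
    """
    if not 0 < truncation_q < 1:
        raise InvalidInputError("truncation_q must be in (0, 1)")
    if len(occ.points) < min_records:
        raise LowRecordError(
            f"{occ.species!r}: {len(occ.points)} records < min_records={min_records}"
        )
    frame = grids[0]
    for g in grids[1:]:
        frame.require_same_frame(g)
    env = np.array(
        [[g.value_at(lon, lat) for g in grids] for lon, lat in occ.points]
    )
    if not np.all(np.isfinite(env)):
        raise InvalidInputError(f"{occ.species!r}: occurrence on nodata cell")
    p = env.shape[1]
    mu = env.mean(axis=0)
    cov = np.cov(env, rowvar=False, ddof=1).reshape(p, p)
    diag = np.diag(cov).copy()
    try:
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned")
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"{occ.species!r}: singular environmental covariance; "
            "falling back to diagonal",
            stacklevel=2,
        )
        diag[diag <= 0] = 1e-12
        cov_inv = np.diag(1.0 / diag)

    stack = np.stack([g.values for g in grids], axis=-1)  # (r, c, p)
    delta = stack - mu
    d2 = np.einsum("rci,ij,rcj->rc", delta, cov_inv, delta)
    qcut = stats.chi2.ppf(truncation_q, df=p)
    with np.errstate(invalid="ignore"):
        raw = np.clip(1.0 - d2 / qcut, 0.0, None)
    data = frame.data_mask
    peak = np.nanmax(raw[data]) if data.any() else 0.0
    values = raw / peak if peak > 0 else raw
    values[~data] = np.nan
    return SuitabilitySurface(species=occ.species, values=values, frame=frame)


def dispersers_from_cell(suitability: float, max_dispersers: int) -> int:
    """Number of dispersers leaving a colonized cell per event.

    The suitability range (0, 1] is split into ``max_dispersers``
    equal-width upper-closed intervals; the count is the 1-based index of
    the interval containing the cell's suitability (ceil(s*m)); zero
    suitability sends no dispersers.
    """
    if not 0.0 <= suitability <= 1.0 or math.isnan(suitability):
        raise InvalidInputError(f"suitability {suitability} outside [0, 1]")
    if suitability == 0.0:
        return 0
    return min(max(math.ceil(suitability * max_dispersers), 1), max_dispersers)


def simulate_m(
    surface: SuitabilitySurface,
    occ: OccurrenceSet,
    cfg: DispersalConfig,
) -> AccessibleArea:
    """Iterated lattice dispersal from the occupied cells.

    Per event, every colonized cell with positive suitability emits
    ``dispersers_from_cell`` dispersers; each travels a log-normal
    distance (median 1 cell, sdlog = kernel_sd) in a uniform direction
    and colonizes its (rounded) landing cell if that cell has positive
    suitability.  Displacements leaving the grid are discarded.  The
    colonized set is monotone non-decreasing over events and fully
    determined by the seed.
    """
    frame = surface.frame
    occupied = occupied_cells(occ, frame)
    s = surface.values
    with np.errstate(invalid="ignore"):
        habitable = s > 0
    if not (occupied & habitable).any():
        warnings.warn(
            f"{occ.species!r}: no occupied cell has positive suitability; "
            "M reduced to occupied cells",
            stacklevel=2,
        )
        return AccessibleArea(occ.species, occupied.copy(), "simulated", "degenerate-start")

    rng = np.random.default_rng(cfg.seed)
    colonized = occupied & habitable
    n_rows, n_cols = s.shape
    counts = np.zeros(s.shape, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        counts[habitable] = np.minimum(
            np.maximum(np.ceil(s[habitable] * cfg.max_dispersers), 1),
            cfg.max_dispersers,
        ).astype(np.int64)

    for _ in range(cfg.n_events):
        src = np.argwhere(colonized)
        nd = counts[colonized]
        total = int(nd.sum())
        if total == 0:
            break
        origins = np.repeat(src, nd, axis=0)
        dist = rng.lognormal(mean=0.0, sigma=cfg.kernel_sd, size=total)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=total)
        land_r = np.rint(origins[:, 0] + dist * np.sin(theta)).astype(int)
        land_c = np.rint(origins[:, 1] + dist * np.cos(theta)).astype(int)
        ok = (0 <= land_r) & (land_r < n_rows) & (0 <= land_c) & (land_c < n_cols)
        land_r, land_c = land_r[ok], land_c[ok]
        good = habitable[land_r, land_c]
        colonized[land_r[good], land_c[good]] = True

    mask = colonized | occupied
    return AccessibleArea(occ.species, mask, "simulated")


def build_m_or_fallback(
    occ: OccurrenceSet,
    grids: list[EnvGrid],
    cfg: DispersalConfig,
    min_records: int = 5,
    truncation_q: float = 0.95,
) -> AccessibleArea:
    """Simulate M, or fall back to an occurrence-only area.

    Low-record species (and any species whose suitability fit or
    simulation fails for data reasons) get ``status="occurrence_only"``
    with the mask covering exactly the occupied cells; the reason is
    logged and kept on the area's ``note``.
    """
    try:
        surface = fit_suitability(
            occ, grids, truncation_q=truncation_q, min_records=min_records
        )
        return simulate_m(surface, occ, cfg)
    except (LowRecordError, NoHabitatError, InvalidInputError) as exc:
        logger.info("%s: falling back to occurrence-only M (%s)", occ.species, exc)
        mask = occupied_cells(occ, grids[0])
        return AccessibleArea(occ.species, mask, "occurrence_only", note=str(exc))


def extent_area(occ: OccurrenceSet, frame: EnvGrid) -> AccessibleArea:
    """M spanning the full data extent (no-truncation setting used by
    truth-scoring runs)."""
    occupied_cells(occ, frame)  # validates points
    return AccessibleArea(occ.species, frame.data_mask.copy(), "simulated", "extent")


def accessible_env_values(area: AccessibleArea, grid: EnvGrid) -> np.ndarray:
    """Environmental values available within an accessible area."""
    if area.mask.shape != grid.values.shape:
        raise MismatchError("accessible area and grid are not on the same frame")
    vals = grid.values[area.mask & grid.data_mask]
    return vals[np.isfinite(vals)]
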