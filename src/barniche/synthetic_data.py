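"""Synthetic study-system generator.

Every downstream stage of the pipeline is testable against ground truth
produced here: smooth spatially autocorrelated environmental fields, dated
Yule trees, interval-valued "true" niches evolved along branches with a
known event list, and occurrence samples drawn only from jointly suitable
cells.  All generators are pure functions of (specification, seed).

Defaults mirror the study system the pipeline is aimed at: a clade of
~40 species with a crown age of ~6.12 Myr, one temperature-like and one
precipitation-like variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, InvalidSpecError, NoHabitatError
from .geo_io import EnvGrid, OccurrenceSet
from .trees import DatedTree, TreeNode

DEFAULT_N_TIPS = 40
DEFAULT_DEPTH_MYR = 6.12

EVENT_TYPES = ("expansion_high", "expansion_low", "retraction_high", "retraction_low")


@dataclass(frozen=True)
class TrueNiche:
    """Ground-truth niche of a species or ancestral node: a closed
    interval of environmental values for one variable."""

    label: str
    variable: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise InvalidSpecError(
                f"niche interval must satisfy low < high, got [{self.low}, {self.high}]"
            )

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


@dataclass(frozen=True)
class TruthEvent:
    """A planted niche-change event on one branch for one variable."""

    parent: int
    child: int
    variable: str
    event: str  # one of EVENT_TYPES
    magnitude: float  # env units, > 0

    def __post_init__(self) -> None:
        if self.event not in EVENT_TYPES:
            raise InvalidSpecError(f"unknown event type {self.event!r}")
        if not self.magnitude > 0:
            raise InvalidSpecError("event magnitude must be > 0")


@dataclass
class NicheEvolution:
    """Result of evolving true niches along a tree for one variable."""

    niches: dict[int, TrueNiche]  # node id -> niche
    events: list[TruthEvent]
    clamped: list[tuple[int, str]] = field(default_factory=list)  # (node, end)


# ------------------------------------------------------------ env grids


def simulate_env_grid(
    n_rows: int,
    n_cols: int,
    gradient_spec: tuple[str, float, float],
    noise_sd: float,
    seed: int,
    variable: str = "env",
    nodata_mask: np.ndarray | None = None,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cell_size: float = 0.0416667,
    smooth_window: int = 5,
) -> EnvGrid:
    """Deterministic gradient plus seeded, spatially smoothed noise.

    ``gradient_spec`` is ``(direction, low, high)`` with direction "ns"
    (low at the top row, high at the bottom) or "we" (low at the left
    column).  Noise is a Gaussian field smoothed by a fixed-width
    moving-average kernel and rescaled so its marginal SD equals
    ``noise_sd`` (spatial-autocorrelation stand-in for real climate
    layers).
    """
    if n_rows < 2 or n_cols < 2:
        raise InvalidSpecError("grid must be at least 2x2")
    direction, low, high = gradient_spec
    if not (math.isfinite(low) and math.isfinite(high)):
        raise InvalidSpecError("gradient bounds must be finite")
    if direction not in ("ns", "we"):
        raise InvalidSpecError(f"gradient direction must be 'ns' or 'we', got {direction!r}")
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")

    if direction == "ns":
        base = np.linspace(low, high, n_rows)[:, None] * np.ones((1, n_cols))
    else:
        base = np.ones((n_rows, 1)) * np.linspace(low, high, n_cols)[None, :]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal((n_rows, n_cols))
        smooth = ndimage.uniform_filter(raw, size=smooth_window, mode="reflect")
        sd = smooth.std()
        noise = smooth * (noise_sd / sd) if sd > 0 else smooth
        values = base + noise
    else:
        values = base.copy()

    if nodata_mask is None:
        nodata_mask = np.zeros((n_rows, n_cols), dtype=bool)
    else:
        nodata_mask = np.asarray(nodata_mask, dtype=bool)
    values = values.astype(float)
    values[nodata_mask] = np.nan
    return EnvGrid(
        variable=variable,
        values=values,
        nodata_mask=nodata_mask,
        xllcorner=xllcorner,
        yllcorner=yllcorner,
        cell_size=cell_size,
    )


# ------------------------------------------------------------ Yule tree


def simulate_yule_tree(n_tips: int, depth: float, seed: int) -> DatedTree:
    """Pure-birth dated tree, rescaled so the root sits at ``depth`` Myr.

    Classic constant-rate Yule process: with k extant lineages the wait to
    the next split is Exp(k); the splitting lineage is chosen uniformly.
    The resulting tree is rooted, binary, and ultrametric by construction;
    tips are labeled sp01, sp02, ... in left-to-right order.
    """
    if n_tips < 2:
        raise InvalidSpecError("a tree needs at least 2 tips")
    if not depth > 0:
        raise InvalidSpecError("depth must be positive")
    rng = np.random.default_rng(seed)

    nodes: list[TreeNode] = [TreeNode(0)]
    birth_time = {0: 0.0}
    active = [0]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k) if k > 1 or nodes[0].children else 0.0
        # the root split happens at time 0; later splits after Exp waits
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        for _ in range(2):
            nid = len(nodes)
            nodes.append(TreeNode(nid, parent=parent))
            nodes[parent].children.append(nid)
            birth_time[nid] = t
            active.append(nid)
    t_end = t + rng.exponential(1.0 / n_tips)
    scale = depth / t_end if t_end > 0 else 1.0

    for node in nodes:
        if node.parent is not None:
            end = birth_time[node.children[0]] if node.children else t_end
            node.length = (end - birth_time[node.id]) * scale

    tree = DatedTree(nodes, 0)
    for i, tip in enumerate(tree.tips(), start=1):
        tree.nodes[tip].label = f"sp{i:02d}"
    tree.assign_ages()
    return tree


# ------------------------------------------------------ niche evolution


def _apply_event(low: float, high: float, event: str, mag: float, min_width: float):
    if event == "expansion_high":
        return low, high + mag
    if event == "expansion_low":
        return low - mag, high
    if event == "retraction_high":
        return low, max(high - mag, low + min_width)
    if event == "retraction_low":
        return min(low + mag, high - min_width), high
    raise InvalidSpecError(f"unknown event {event!r}")


def evolve_true_niches(
    tree: DatedTree,
    root_interval: tuple[float, float],
    event_rate: float,
    step_sd: float,
    seed: int,
    variable: str = "env",
    grid_range: tuple[float, float] | None = None,
    forced_events: dict[int, tuple[str, float]] | None = None,
    min_width: float = 1e-6,
) -> NicheEvolution:
    """Evolve interval niches along branches with at most one event each.

    Per branch, with probability ``event_rate`` one of the four
    expansion/retraction events is drawn (uniformly) with magnitude
    |N(0, step_sd)|.  ``forced_events`` maps child node id -> (event,
    magnitude) and overrides the random draw on that branch, so tests can
    plant events deterministically.  Intervals are clamped to
    ``grid_range`` with clamping recorded as metadata, not as events.
    """
    low0, high0 = root_interval
    if grid_range is not None:
        glo, ghi = grid_range
        if low0 < glo or high0 > ghi:
            raise InvalidSpecError("root interval outside grid range")
    if not 0 <= event_rate <= 1:
        raise InvalidSpecError("event_rate must be in [0, 1]")
    TrueNiche("root", variable, low0, high0)  # validate

    rng = np.random.default_rng(seed)
    forced = forced_events or {}
    niches: dict[int, TrueNiche] = {}
    events: list[TruthEvent] = []
    clamped: list[tuple[int, str]] = []

    for nid in tree.preorder():
        node = tree.nodes[nid]
        label = node.label or f"n{nid}"
        if node.parent is None:
            niches[nid] = TrueNiche(label, variable, low0, high0)
            continue
        parent_niche = niches[node.parent]
        low, high = parent_niche.low, parent_niche.high
        if nid in forced:
            ev, mag = forced[nid]
        else:
            ev, mag = None, 0.0
            if rng.random() < event_rate:
                ev = EVENT_TYPES[int(rng.integers(4))]
                mag = abs(rng.normal(0.0, step_sd))
                mag = max(mag, min_width)
        if ev is not None:
            new_low, new_high = _apply_event(low, high, ev, mag, min_width)
            events.append(TruthEvent(node.parent, nid, variable, ev, mag))
            low, high = new_low, new_high
        if grid_range is not None:
            if low < glo:
                low = glo
                clamped.append((nid, "low"))
            if high > ghi:
                high = ghi
                clamped.append((nid, "high"))
        niches[nid] = TrueNiche(label, variable, low, high)

    verify_truth_consistency(tree, niches, events, clamped, min_width)
    return NicheEvolution(niches, events, clamped)


def verify_truth_consistency(
    tree: DatedTree,
    niches: dict[int, TrueNiche],
    events: list[TruthEvent],
    clamped: list[tuple[int, str]] = (),
    min_width: float = 1e-6,
    tol: float = 1e-9,
) -> None:
    """Assert every child's interval is reconstructable from its parent's
    interval plus the event list (run after every generation)."""
    ev_by_child = {e.child: e for e in events}
    clamped_set = set(clamped)
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent is None:
            continue
        p = niches[node.parent]
        low, high = p.low, p.high
        if nid in ev_by_child:
            e = ev_by_child[nid]
            low, high = _apply_event(low, high, e.event, e.magnitude, min_width)
        c = niches[nid]
        ok_low = abs(c.low - low) <= tol or (nid, "low") in clamped_set
        ok_high = abs(c.high - high) <= tol or (nid, "high") in clamped_set
        if not (ok_low and ok_high):
            raise AssertionError(
                f"truth inconsistency at node {nid}: expected "
                f"[{low}, {high}], stored [{c.low}, {c.high}]"
            )


# ------------------------------------------------------------ sampling


def suitable_cells(
    grids: list[EnvGrid], niches: dict[str, TrueNiche]
) -> np.ndarray:
    """Boolean lattice of cells satisfying all variables' true intervals
    (nodata excluded)."""
    if not grids:
        raise InvalidInputError("need at least one grid")
    ok = grids[0].data_mask.copy()
    for g in grids:
        grids[0].require_same_frame(g)
        niche = niches[g.variable]
        with np.errstate(invalid="ignore"):
            ok &= (g.values >= niche.low) & (g.values <= niche.high)
    return ok


def sample_occurrences(
    grids: list[EnvGrid],
    niches: dict[str, TrueNiche],
    k: int,
    seed: int,
    species: str | None = None,
    ensure_range_coverage: bool = False,
) -> OccurrenceSet:
    """Sample ``k`` distinct suitable cells uniformly; coordinates are
    cell centers.

    With ``ensure_range_coverage`` the cells attaining the minimum and
    maximum value of each variable within the suitable set are always
    included (ceiling-fixture mode: the sampled occupied range then spans
    the realizable extent of the true niche on the grid).
    """
    name = species or next(iter(niches.values())).label
    ok = suitable_cells(grids, niches)
    cells = np.argwhere(ok)
    if len(cells) == 0:
        raise NoHabitatError(f"no suitable habitat cells for species {name!r}")
    if k > len(cells):
        raise NoHabitatError(
            f"species {name!r}: requested {k} occurrences but only "
            f"{len(cells)} suitable cells exist"
        )
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    if ensure_range_coverage:
        for g in grids:
            vals = g.values[ok]
            order = np.argsort(vals, kind="stable")
            for pick in (order[0], order[-1]):
                chosen.append(pick)
        chosen = sorted(set(chosen))
    remaining = [i for i in range(len(cells)) if i not in set(chosen)]
    need = k - len(chosen)
    if need < 0:
        chosen = chosen[:k]
        need = 0
    if need > 0:
        extra = rng.choice(len(remaining), size=need, replace=False)
        chosen += [remaining[int(e)] for e in sorted(extra)]
    pts = [grids[0].cell_center(int(r), int(c)) for r, c in cells[sorted(chosen)]]
    return OccurrenceSet(species=name, points=pts, provenance=["synthetic"] * len(pts))
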