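"""Binned-range (BR) character coding of climatic niches.

The clade-wide range of each variable is estimated within the union of
all accessible areas and cut into equal-width bins (target widths ~1 degC
for temperature, ~100 mm for precipitation; the bin count is rounded so
widths come out exactly equal).  Each species' niche is then a vector over
the bins with three states:

* present (1): the bin overlaps the species' occupied interval
  [min, max] of occurrence environments;
* absent (0): the bin lies inside the species' accessible environmental
  range but outside the occupied interval;
* uncertain (?): the bin lies beyond the accessible range - unsampled,
  hence unknowable - including every non-present bin of species whose M
  could not be simulated (occurrence-only species).

Present runs are contiguous by construction (interval niches at tips).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CodingError, InvalidInputError, MismatchError
from .geo_io import EnvGrid
from .m_simulation import AccessibleArea
from .trees import DatedTree

PRESENT, ABSENT, UNCERTAIN = "1", "0", "?"


@dataclass
class NicheSummary:
    """Order statistics of one species' environmental values from one
    source (occurrences or accessible area)."""

    species: str
    variable: str
    source: str  # "occurrences" | "M"
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    q1: float
    q3: float

    @property
    def range_width(self) -> float:
        return self.max - self.min


@dataclass
class BinScheme:
    variable: str
    edges: np.ndarray  # strictly increasing, equal interior widths
    target_width: float

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if len(self.edges) < 2 or not np.all(np.diff(self.edges) > 0):
            raise InvalidInputError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def global_min(self) -> float:
        return float(self.edges[0])

    @property
    def global_max(self) -> float:
        return float(self.edges[-1])

    def midpoints(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def bin_index(self, value: float) -> int:
        """Half-open bins [e_i, e_{i+1}); the last bin is closed so the
        global maximum belongs to it.  Out-of-range values raise."""
        if not self.global_min <= value <= self.global_max:
            raise CodingError(
                f"value {value} outside scheme range "
                f"[{self.global_min}, {self.global_max}]"
            )
        idx = int((value - self.global_min) / self.width)
        return min(idx, self.n_bins - 1)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "variable": self.variable,
                    "edges": self.edges.tolist(),
                    "target_width": self.target_width,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "BinScheme":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["variable"], np.array(d["edges"]), d["target_width"])


@dataclass
class BRMatrix:
    variable: str
    species: list[str]  # ordered as tree tip order
    states: np.ndarray  # (n_species, n_bins) of {"1","0","?"}

    def row(self, species: str) -> np.ndarray:
        return self.states[self.species.index(species)]

    def to_tsv(self, path, scheme: BinScheme | None = None) -> None:
        cols = (
            [repr(float(m)) for m in scheme.midpoints()]
            if scheme is not None
            else [f"bin{i}" for i in range(self.states.shape[1])]
        )
        df = pd.DataFrame(self.states, index=self.species, columns=cols)
        df.index.name = "species"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, variable: str) -> "BRMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(variable, list(df.index), df.to_numpy(dtype="<U1"))


# ------------------------------------------------------------- ranges


def union_mask(areas: list[AccessibleArea]) -> np.ndarray:
    """Union of accessible areas: true wherever any input mask is true."""
    if not areas:
        raise InvalidInputError("union of zero accessible areas")
    shape = areas[0].mask.shape
    out = np.zeros(shape, dtype=bool)
    for a in areas:
        if a.mask.shape != shape:
            raise MismatchError("accessible areas on different frames")
        out |= a.mask
    return out


def niche_summary(
    values, species: str = "", variable: str = "", source: str = "occurrences"
) -> NicheSummary:
    """Summary statistics (type-7 linear-interpolation quantiles, sample
    SD with n-1)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InvalidInputError("niche_summary needs at least one finite value")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return NicheSummary(
        species=species,
        variable=variable,
        source=source,
        n=int(vals.size),
        mean=float(vals.mean()),
        sd=sd,
        median=float(med),
        min=float(vals.min()),
        max=float(vals.max()),
        q1=float(q1),
        q3=float(q3),
    )


def build_bin_scheme(
    grid: EnvGrid, union: np.ndarray, target_width: float
) -> BinScheme:
    """Equal-width bins tiling the variable's range over the union of Ms.

    The bin count is ``round(range / target_width)`` (at least 1) and the
    width is adjusted to ``range / n_bins`` so the bins are exactly
    equal-sized and approximately the target width.
    """
    if not target_width > 0:
        raise InvalidInputError("target_width must be > 0")
    vals = grid.values[union & grid.data_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InvalidInputError("union mask contains no data cells")
    gmin, gmax = float(vals.min()), float(vals.max())
    if gmax == gmin:
        warnings.warn(
            f"{grid.variable!r}: zero range over union; degenerate single bin",
            stacklevel=2,
        )
        return BinScheme(grid.variable, np.array([gmin, gmin + target_width]), target_width)
    n_bins = max(1, round((gmax - gmin) / target_width))
    edges = np.linspace(gmin, gmax, n_bins + 1)
    edges[-1] = gmax
    return BinScheme(grid.variable, edges, target_width)


# -------------------------------------------------------------- coding


def code_br(
    occ_values, m_values, scheme: BinScheme
) -> np.ndarray:
    """Code one species' BR vector over {present, absent, uncertain}.

    ``m_values`` is None for occurrence-only species, whose non-present
    bins are all uncertain.  Bin/interval overlap conventions: the
    occupied interval is closed and point overlaps count (so an
    occurrence sitting exactly on a bin edge marks the bin it falls in);
    the accessible range must overlap a bin with positive length for the
    bin to count as sampled (absent-able).
    """
    occ = np.asarray(occ_values, dtype=float)
    occ = occ[np.isfinite(occ)]
    if occ.size == 0:
        raise InvalidInputError("code_br needs occurrence values")
    a, b = float(occ.min()), float(occ.max())
    if b < scheme.global_min or a > scheme.global_max:
        raise CodingError(
            f"occupied range [{a}, {b}] disjoint from scheme range "
            f"[{scheme.global_min}, {scheme.global_max}]"
        )
    lo = scheme.edges[:-1]
    hi = scheme.edges[1:]
    last = np.zeros(scheme.n_bins, dtype=bool)
    last[-1] = True
    # nonempty overlap of [lo, hi) (last bin closed) with closed [a, b]
    present = (lo <= b) & ((hi > a) | (last & (hi >= a)))

    out = np.full(scheme.n_bins, UNCERTAIN, dtype="<U1")
    out[present] = PRESENT
    if m_values is not None:
        mv = np.asarray(m_values, dtype=float)
        mv = mv[np.isfinite(mv)]
        if mv.size == 0:
            raise InvalidInputError("empty accessible-area values")
        ma, mb = float(mv.min()), float(mv.max())
        sampled = (lo < mb) & (hi > ma)  # positive-length overlap
        out[sampled & ~present] = ABSENT
    return out


def build_br_matrix(
    coded: dict[str, np.ndarray], tree: DatedTree, variable: str
) -> BRMatrix:
    """Assemble per-species vectors into a matrix in tree tip order."""
    tips = tree.tip_labels()
    missing = set(tips) ^ set(coded)
    if missing:
        raise MismatchError(
            f"species/tree mismatch for {variable!r}: {sorted(missing)}"
        )
    lengths = {len(v) for v in coded.values()}
    if len(lengths) != 1:
        raise MismatchError("BR vectors have differing lengths")
    states = np.stack([np.asarray(coded[sp], dtype="<U1") for sp in tips])
    return BRMatrix(variable=variable, species=tips, states=states)
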