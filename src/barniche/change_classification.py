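"""Branch-wise niche-change typology.

Comparing an ancestor's and a descendant's bin vectors gives, per bin:
retraction (certain present -> certain absent), expansion (certain absent
-> certain present), stasis (identical certain states), or indeterminate
(either state uncertain).  Events summarize where changes fall relative to
the ancestor's certainly-present run: expansions strictly above/below its
upper/lower limit are "expansion high"/"expansion low"; the retraction run
containing the ancestor's upper/lower present limit is "retraction high"/
"retraction low"; changes strictly inside the ancestral run are labeled
interior_* and reported separately.  A descendant sharing no
certainly-present bin with its ancestor is a complete retraction (which
subsumes the retraction high/low/interior labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .asr import AncestralNiche
from .bar_coding import ABSENT, PRESENT, UNCERTAIN, BRMatrix
from .errors import MismatchError
from .trees import DatedTree

STASIS = "stasis"
RETRACTION = "retraction"
EXPANSION = "expansion"
INDETERMINATE = "indeterminate"

CERTAIN_EVENT_CLASSES = (
    "expansion_high",
    "expansion_low",
    "retraction_high",
    "retraction_low",
)


@dataclass
class NicheChangeRecord:
    parent: int
    child: int
    species: str
    variable: str
    per_bin: np.ndarray
    events: set[str]
    n_changed_bins: int
    uncertainty_note: str = ""


def classify_bins(A, D) -> np.ndarray:
    """Per-bin change labels between ancestor vector A and descendant D."""
    A = np.asarray(A, dtype="<U1")
    D = np.asarray(D, dtype="<U1")
    if A.shape != D.shape:
        raise MismatchError(f"vector length mismatch: {A.shape} vs {D.shape}")
    out = np.full(A.shape, INDETERMINATE, dtype="<U16")
    certain = (A != UNCERTAIN) & (D != UNCERTAIN)
    out[certain & (A == D)] = STASIS
    out[certain & (A == PRESENT) & (D == ABSENT)] = RETRACTION
    out[certain & (A == ABSENT) & (D == PRESENT)] = EXPANSION
    return out


def _runs(idx: np.ndarray) -> list[np.ndarray]:
    """Split sorted indices into maximal consecutive runs."""
    if idx.size == 0:
        return []
    breaks = np.where(np.diff(idx) > 1)[0] + 1
    return np.split(idx, breaks)


def classify_events(A, D) -> set[str]:
    """Event labels for one branch (one variable).

    Anchored to the ancestor's certainly-present bins; an ancestor with
    none yields {"indeterminate_ancestor"}.
    """
    A = np.asarray(A, dtype="<U1")
    D = np.asarray(D, dtype="<U1")
    labels = classify_bins(A, D)
    pa = np.where(A == PRESENT)[0]
    if pa.size == 0:
        return {"indeterminate_ancestor"}
    a_lo, a_hi = int(pa[0]), int(pa[-1])
    events: set[str] = set()

    exp = np.where(labels == EXPANSION)[0]
    if np.any(exp > a_hi):
        events.add("expansion_high")
    if np.any(exp < a_lo):
        events.add("expansion_low")
    if np.any((exp > a_lo) & (exp < a_hi)):
        events.add("interior_expansion")

    ret = np.where(labels == RETRACTION)[0]
    for run in _runs(ret):
        if a_hi in run:
            events.add("retraction_high")
        if a_lo in run:
            events.add("retraction_low")
        if not (a_hi in run or a_lo in run):
            events.add("interior_retraction")

    pd_ = np.where(D == PRESENT)[0]
    if not np.intersect1d(pa, pd_).size:
        events.add("complete_retraction")
        events -= {"retraction_high", "retraction_low", "interior_retraction"}
    return events


def change_record(
    parent: int, child: int, species: str, variable: str, A, D
) -> NicheChangeRecord:
    per_bin = classify_bins(A, D)
    events = classify_events(A, D)
    n_changed = int(np.sum((per_bin == RETRACTION) | (per_bin == EXPANSION)))
    note = ""
    if "complete_retraction" in events and not np.any(
        np.asarray(D, dtype="<U1") == PRESENT
    ):
        note = "descendant has no certainly-present bin"
    return NicheChangeRecord(
        parent=parent,
        child=child,
        species=species,
        variable=variable,
        per_bin=per_bin,
        events=events,
        n_changed_bins=n_changed,
        uncertainty_note=note,
    )


@dataclass
class CladeSummary:
    """Per-variable and cross-variable change counts over terminal
    branches."""

    n_species: int
    changed_strict: dict[str, set[str]]  # variable -> species with certain events
    changed_inclusive: dict[str, set[str]]  # + complete retractions etc.
    both_strict: set[str] = field(default_factory=set)
    both_inclusive: set[str] = field(default_factory=set)


def summarize_clade(
    tree: DatedTree,
    ancestral: dict[str, AncestralNiche],
    tips: dict[str, BRMatrix],
) -> tuple[pd.DataFrame, CladeSummary, list[NicheChangeRecord]]:
    """One change record per terminal branch per variable, plus clade
    counts.

    Species counted "strict" have at least one of the four certain
    high/low event classes; the "inclusive" count adds complete
    retractions and interior changes; whether uncertain complete
    retractions belong in change totals is a judgment call, so both
    counts are reported.
    """
    records: list[NicheChangeRecord] = []
    variables = sorted(tips)
    for var in variables:
        br = tips[var]
        anc = ancestral[var]
        row_of = {sp: i for i, sp in enumerate(br.species)}
        for tid in tree.tips():
            sp = tree.nodes[tid].label
            parent = tree.nodes[tid].parent
            if sp not in row_of:
                raise MismatchError(f"tip {sp!r} missing from BR matrix {var!r}")
            A = anc.vector(parent)
            D = br.states[row_of[sp]]
            records.append(change_record(parent, tid, sp, var, A, D))

    changed_strict = {v: set() for v in variables}
    changed_inclusive = {v: set() for v in variables}
    for rec in records:
        certain = set(rec.events) & set(CERTAIN_EVENT_CLASSES)
        any_change = set(rec.events) & (
            set(CERTAIN_EVENT_CLASSES)
            | {"complete_retraction", "interior_expansion", "interior_retraction"}
        )
        if certain:
            changed_strict[rec.variable].add(rec.species)
        if any_change:
            changed_inclusive[rec.variable].add(rec.species)

    summary = CladeSummary(
        n_species=tree.n_tips,
        changed_strict=changed_strict,
        changed_inclusive=changed_inclusive,
    )
    if len(variables) >= 2:
        summary.both_strict = set.intersection(
            *(changed_strict[v] for v in variables)
        )
        summary.both_inclusive = set.intersection(
            *(changed_inclusive[v] for v in variables)
        )

    rows = [
        {
            "species": r.species,
            "variable": r.variable,
            "events": ";".join(sorted(r.events)),
            "n_changed_bins": r.n_changed_bins,
            "note": r.uncertainty_note,
        }
        for r in records
    ]
    table = pd.DataFrame(rows).sort_values(["species", "variable"]).reset_index(drop=True)
    return table, summary, records


def summary_table(summary: CladeSummary, variables: list[str]) -> pd.DataFrame:
    rows = []
    for v in variables:
        rows.append(
            {
                "variable": v,
                "species_changed_strict": len(summary.changed_strict[v]),
                "species_changed_inclusive": len(summary.changed_inclusive[v]),
                "n_species": summary.n_species,
            }
        )
    rows.append(
        {
            "variable": "both",
            "species_changed_strict": len(summary.both_strict),
            "species_changed_inclusive": len(summary.both_inclusive),
            "n_species": summary.n_species,
        }
    )
    return pd.DataFrame(rows)
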