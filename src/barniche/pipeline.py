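"""End-to-end pipeline: validate -> thin -> M -> bins -> BR -> ASR ->
classify -> project -> summarize.

Also home to the synthetic *study* generator (a full input set: grids,
tree, occurrences, planted truth) and the truth-recovery scorer used to
validate the change typology on synthetic runs.

Reproducibility contract: a config plus its seeds fully determines every
output byte; the manifest records a SHA-256 per output file so reruns can
be compared hash-for-hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import asr as asr_mod
from . import bar_coding as bar
from . import change_classification as cc
from . import geo_io
from . import geo_projection as proj
from . import m_simulation as msim
from . import synthetic_data as synth
from .errors import InvalidSpecError, MismatchError
from .geo_io import EnvGrid, OccurrenceSet
from .trees import DatedTree

logger = logging.getLogger(__name__)

STAGES = (
    "validate",
    "thin",
    "m",
    "bins",
    "br",
    "asr",
    "classify",
    "project",
    "summarize",
)


# ----------------------------------------------------------- config


@dataclass
class MConfig:
    mode: str = "simulate"  # "simulate" | "extent"
    n_events: int = 35
    max_dispersers: int = 2
    kernel_sd: float = 0.50
    truncation_q: float = 0.95
    min_records: int = 5
    seed: int = 0


@dataclass
class AsrConfig:
    theta: float = 0.8
    rate_min: float = 1e-8
    rate_max: float = 1e3


@dataclass
class PipelineConfig:
    grids: dict[str, str]  # variable -> ASCII grid path
    occurrences: str
    tree: str
    out_dir: str
    thin_km: float = 5.2
    bin_widths: dict[str, float] = field(
        default_factory=lambda: {"temperature": 1.0, "precipitation": 100.0}
    )
    m: MConfig = field(default_factory=MConfig)
    asr: AsrConfig = field(default_factory=AsrConfig)
    project: bool = True
    seed: int = 0

    def validate_paths(self) -> None:
        missing = [p for p in [self.occurrences, self.tree, *self.grids.values()]
                   if not os.path.exists(p)]
        if missing:
            raise InvalidSpecError(f"missing input paths: {missing}")
        for var in self.grids:
            if var not in self.bin_widths:
                raise InvalidSpecError(f"no bin width configured for {var!r}")
            if not self.bin_widths[var] > 0:
                raise InvalidSpecError(f"bin width for {var!r} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        m = MConfig(**raw.pop("m", {}))
        a = AsrConfig(**raw.pop("asr", {}))
        return cls(m=m, asr=a, **raw)

    def to_yaml(self, path) -> None:
        d = {
            "grids": dict(self.grids),
            "occurrences": self.occurrences,
            "tree": self.tree,
            "out_dir": self.out_dir,
            "thin_km": self.thin_km,
            "bin_widths": dict(self.bin_widths),
            "m": self.m.__dict__,
            "asr": self.asr.__dict__,
            "project": self.project,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


# ------------------------------------------------- synthetic studies


@dataclass
class VariableSpec:
    name: str
    direction: str  # "ns" | "we"
    low: float
    high: float
    noise_sd: float
    bin_width: float
    root_interval: tuple[float, float]


DEFAULT_VARIABLES = (
    VariableSpec("temperature", "ns", 0.0, 30.0, 0.5, 1.0, (10.5, 19.5)),
    VariableSpec("precipitation", "we", 0.0, 1500.0, 30.0, 100.0, (450.0, 1050.0)),
)

# magnitude cycles are capped well below each root interval's width so a
# planted retraction can never collapse a niche to zero width
DEFAULT_MAGNITUDES = {
    "temperature": (3.5, 4.5, 5.5),
    "precipitation": (3.5, 4.5),
}


@dataclass
class SyntheticStudy:
    grids: dict[str, EnvGrid]
    tree: DatedTree
    occurrences: dict[str, OccurrenceSet]
    truth: list[synth.TruthEvent]
    niches: dict[str, dict[int, synth.TrueNiche]]  # variable -> node -> niche
    occurrence_only: list[str]
    variables: list[VariableSpec]


def _subtree_tip_count(tree: DatedTree, nid: int) -> int:
    stack, n = [nid], 0
    while stack:
        v = stack.pop()
        if tree.nodes[v].children:
            stack.extend(tree.nodes[v].children)
        else:
            n += 1
    return n


def _select_distinct_parent_tips(
    tree: DatedTree, eligible: list[str], n: int, preferred: list[str] = ()
) -> list[str]:
    """Pick n tip labels suitable for planting recoverable events.

    Structural constraints keep a planted terminal-branch change
    identifiable from the rest of the clade: no two chosen tips share a
    parent node; the parent must not be the root (whose flat prior
    dilutes the reconstruction); the terminal branch must be between
    depth/15 and a third of the tree depth (on a near-zero branch the
    single change the event demands is so improbable that a diffuse
    infinite-rate model outcompetes it, while on a long branch the
    state information decays away); and a tip in a two-tip cherry - where
    the sibling's
    evidence exactly cancels the deviant tip's - is eligible only when
    the cherry's stem is short (<= depth/6), so the ancestor stays
    anchored to the grandparent.
    """
    tip_parent = {tree.nodes[t].label: tree.nodes[t].parent for t in tree.tips()}
    sib_size = {
        tree.nodes[t].label: _subtree_tip_count(tree, tree.sibling_of(t))
        for t in tree.tips()
        if tree.sibling_of(t) is not None
    }
    branch_len = {tree.nodes[t].label: tree.nodes[t].length for t in tree.tips()}
    chosen: list[str] = []
    used: set[int] = set()
    order = list(preferred) + [lb for lb in eligible if lb not in set(preferred)]
    for lb in order:
        if len(chosen) == n:
            break
        if lb not in tip_parent or tip_parent[lb] in used:
            continue
        if tip_parent[lb] == tree.root:
            continue
        if not (tree.depth / 15.0 <= branch_len[lb] <= tree.depth / 3.0):
            continue
        if sib_size.get(lb, 0) < 2:
            stem = tree.nodes[tip_parent[lb]].length
            if stem > tree.depth / 6.0:
                continue
        chosen.append(lb)
        used.add(tip_parent[lb])
    if len(chosen) < n:
        raise InvalidSpecError(
            f"cannot place {n} parent-distinct events among {len(eligible)} tips"
        )
    return chosen


def generate_synthetic_study(
    n_species: int = 40,
    n_rows: int = 100,
    n_cols: int = 100,
    depth: float = 6.12,
    variables: tuple[VariableSpec, ...] = DEFAULT_VARIABLES,
    plant_counts: dict[str, int] | None = None,
    plant_both: int = 0,
    n_occurrence_only: int = 8,
    occurrence_only_records: tuple[int, int] = (2, 4),
    records: tuple[int, int] = (6, 24),
    event_magnitudes_bins: dict[str, tuple[float, ...]] | tuple[float, ...] | None = None,
    event_rate: float = 0.0,
    seed: int = 0,
    ensure_range_coverage: bool = True,
) -> SyntheticStudy:
    """Generate a full synthetic study system with planted truth.

    ``plant_counts`` maps variable name -> number of species planted with
    one terminal-branch niche-change event; ``plant_both`` of them (taken
    from the first variable's selection) are also planted for the second
    variable.  Planted species never share a parent node with another
    planted species of the same variable, and the species destined for
    occurrence-only status (too few records to simulate an M) are never
    planted.  Event classes cycle through expansion high/low and
    retraction high/low; magnitudes (in target-bin-width units) cycle
    through ``event_magnitudes_bins``.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(6 + n_species * 2 + len(variables)).astype(np.int64)
    si = iter(int(s) % (2**31 - 1) for s in seeds)

    grids: dict[str, EnvGrid] = {}
    for vi, vs in enumerate(variables):
        grids[vs.name] = synth.simulate_env_grid(
            n_rows,
            n_cols,
            (vs.direction, vs.low, vs.high),
            vs.noise_sd,
            seed=next(si),
            variable=vs.name,
        )
    tree = synth.simulate_yule_tree(n_species, depth, seed=next(si))
    labels = tree.tip_labels()

    plant_counts = dict(plant_counts or {})
    var_names = [vs.name for vs in variables]
    for v in plant_counts:
        if v not in var_names:
            raise InvalidSpecError(f"plant count for unknown variable {v!r}")

    # choose planted species (never occurrence-only ones)
    planted: dict[str, list[str]] = {v: [] for v in var_names}
    if plant_counts:
        first = var_names[0]
        if plant_counts.get(first):
            planted[first] = _select_distinct_parent_tips(
                tree, labels, plant_counts[first]
            )
        for v in var_names[1:]:
            want = plant_counts.get(v, 0)
            if not want:
                continue
            pref = planted[first][:plant_both]
            pool = [lb for lb in labels if lb not in set(planted[first])]
            planted[v] = _select_distinct_parent_tips(
                tree, pool, want, preferred=pref
            )
    ever_planted = {lb for v in planted for lb in planted[v]}
    unplanted = [lb for lb in labels if lb not in ever_planted]
    # an occurrence-only species is coded uncertain outside its occupied
    # range; if every tip of a planted tip's sibling subtree went
    # occurrence-only, the local certain evidence the reconstruction of
    # that tip's ancestor relies on would vanish, so each planted tip
    # keeps at least one certainly-coded "witness" in its sibling subtree
    witnesses: set[str] = set()
    for lb in sorted(ever_planted):
        sib = tree.sibling_of(tree.tip_id(lb))
        if sib is None:
            continue
        stack = [sib]
        sib_tips: list[str] = []
        while stack:
            v = stack.pop()
            if tree.nodes[v].children:
                stack.extend(tree.nodes[v].children)
            else:
                sib_tips.append(tree.nodes[v].label)
        sib_tips.sort()
        if len(sib_tips) <= 2:
            # a small sibling subtree is the ancestor's whole local
            # evidence base; keep all of it certainly coded
            witnesses.update(sib_tips)
        elif not set(sib_tips) & (ever_planted | witnesses):
            witnesses.add(sib_tips[0])
    pool = [lb for lb in unplanted if lb not in witnesses]
    if n_occurrence_only > len(pool):
        raise InvalidSpecError(
            f"cannot reserve {n_occurrence_only} occurrence-only species "
            "away from planted cherries"
        )
    occ_only = pool[:n_occurrence_only]

    # evolve niches with forced planted events
    classes = list(synth.EVENT_TYPES)
    niches: dict[str, dict[int, synth.TrueNiche]] = {}
    truth: list[synth.TruthEvent] = []
    for vs in variables:
        if event_magnitudes_bins is None:
            mags = DEFAULT_MAGNITUDES.get(vs.name, (3.5, 4.5))
        elif isinstance(event_magnitudes_bins, dict):
            mags = event_magnitudes_bins[vs.name]
        else:
            mags = event_magnitudes_bins
        forced: dict[int, tuple[str, float]] = {}
        for i, lb in enumerate(planted[vs.name]):
            ev = classes[i % len(classes)]
            mag = mags[i % len(mags)] * vs.bin_width
            forced[tree.tip_id(lb)] = (ev, mag)
        evo = synth.evolve_true_niches(
            tree,
            vs.root_interval,
            event_rate=event_rate,
            step_sd=vs.bin_width,
            seed=next(si),
            variable=vs.name,
            grid_range=(vs.low, vs.high),
            forced_events=forced,
        )
        niches[vs.name] = evo.niches
        truth.extend(evo.events)

    # occurrence samples
    rng = np.random.default_rng(next(si))
    occurrences: dict[str, OccurrenceSet] = {}
    glist = [grids[v] for v in var_names]
    for lb in labels:
        tid = tree.tip_id(lb)
        sp_niches = {v: niches[v][tid] for v in var_names}
        if lb in occ_only:
            k = int(rng.integers(occurrence_only_records[0], occurrence_only_records[1] + 1))
        else:
            k = int(rng.integers(records[0], records[1] + 1))
        occurrences[lb] = synth.sample_occurrences(
            glist,
            sp_niches,
            k,
            seed=next(si),
            species=lb,
            ensure_range_coverage=ensure_range_coverage and lb not in occ_only,
        )

    return SyntheticStudy(
        grids=grids,
        tree=tree,
        occurrences=occurrences,
        truth=truth,
        niches=niches,
        occurrence_only=occ_only,
        variables=list(variables),
    )


def generate_feasible_study(seed: int = 0, max_tries: int = 100, **kwargs) -> SyntheticStudy:
    """Generate a study, advancing the seed until the sampled Yule tree
    structurally admits the requested event placement.

    Whether a tree has enough non-cherry tips for the planted-event
    counts is a property of its shape alone, so scanning is a
    feasibility check on the topology, independent of any downstream
    result.
    """
    last: Exception | None = None
    for s in range(seed, seed + max_tries):
        try:
            return generate_synthetic_study(seed=s, **kwargs)
        except InvalidSpecError as exc:
            last = exc
    raise InvalidSpecError(
        f"no feasible tree in {max_tries} seeds from {seed}: {last}"
    )


def write_study(study: SyntheticStudy, out_dir) -> dict[str, str]:
    """Serialize a synthetic study to disk; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    for name, grid in study.grids.items():
        p = os.path.join(out_dir, f"{name}.asc")
        geo_io.write_env_grid(grid, p)
        paths[f"grid:{name}"] = p
    occ_path = os.path.join(out_dir, "occurrences.csv")
    geo_io.write_occurrences(
        [study.occurrences[lb] for lb in sorted(study.occurrences)], occ_path
    )
    paths["occurrences"] = occ_path
    tree_path = os.path.join(out_dir, "tree.nwk")
    geo_io.write_newick(study.tree, tree_path)
    paths["tree"] = tree_path
    truth_path = os.path.join(out_dir, "truth_events.tsv")
    pd.DataFrame(
        [
            {
                "parent": e.parent,
                "child": e.child,
                "species": study.tree.nodes[e.child].label or "",
                "variable": e.variable,
                "event": e.event,
                "magnitude": e.magnitude,
            }
            for e in study.truth
        ],
        columns=["parent", "child", "species", "variable", "event", "magnitude"],
    ).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


# ----------------------------------------------------------- pipeline


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    manifest: dict[str, str]
    change_table: pd.DataFrame
    summary: cc.CladeSummary
    records: list[cc.NicheChangeRecord]
    areas: dict[str, msim.AccessibleArea]
    schemes: dict[str, bar.BinScheme]
    tree: DatedTree
    log: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages in order; abort with stage context on failure."""
    config.validate_paths()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict[str, str] = {}
    log: dict = {"stages": {}}

    def emit(path: str) -> None:
        manifest[os.path.relpath(path, out)] = _sha256(path)

    stage = "validate"
    try:
        grids = {
            var: geo_io.read_env_grid(p, variable=var)
            for var, p in sorted(config.grids.items())
        }
        frame = next(iter(grids.values()))
        for g in grids.values():
            frame.require_same_frame(g)
        tree = geo_io.read_newick(config.tree)
        occ_raw = geo_io.read_occurrences(config.occurrences)
        missing = set(tree.tip_labels()) ^ set(occ_raw)
        if missing:
            raise MismatchError(f"tree/occurrence species mismatch: {sorted(missing)}")
        dropped: list = []
        occ_valid = {
            sp: geo_io.validate_occurrences(o, frame, report=dropped)
            for sp, o in sorted(occ_raw.items())
        }
        log["stages"]["validate"] = {
            "species": len(occ_valid),
            "points_in": sum(len(o) for o in occ_raw.values()),
            "points_dropped": len(dropped),
        }

        stage = "thin"
        occ_thin = {}
        for sp, o in sorted(occ_valid.items()):
            o2 = geo_io.dedup_per_cell(o, frame)
            occ_thin[sp] = geo_io.thin_occurrences(o2, config.thin_km)
        thin_path = os.path.join(out, "occurrences_thinned.csv")
        geo_io.write_occurrences([occ_thin[s] for s in sorted(occ_thin)], thin_path)
        emit(thin_path)
        log["stages"]["thin"] = {
            "points_out": sum(len(o) for o in occ_thin.values()),
            "min_dist_km": config.thin_km,
        }

        stage = "m"
        glist = [grids[v] for v in sorted(grids)]
        areas: dict[str, msim.AccessibleArea] = {}
        m_dir = os.path.join(out, "m_masks")
        os.makedirs(m_dir, exist_ok=True)
        for i, sp in enumerate(sorted(occ_thin)):
            o = occ_thin[sp]
            if len(o) < config.m.min_records:
                areas[sp] = msim.AccessibleArea(
                    sp, msim.occupied_cells(o, frame), "occurrence_only",
                    note=f"{len(o)} records < min_records={config.m.min_records}",
                )
            elif config.m.mode == "extent":
                areas[sp] = msim.extent_area(o, frame)
            else:
                sp_seed = int(
                    np.random.SeedSequence(
                        entropy=config.m.seed, spawn_key=(i,)
                    ).generate_state(1)[0]
                    % (2**31 - 1)
                )
                cfg = msim.DispersalConfig(
                    n_events=config.m.n_events,
                    max_dispersers=config.m.max_dispersers,
                    kernel_sd=config.m.kernel_sd,
                    seed=sp_seed,
                )
                areas[sp] = msim.build_m_or_fallback(
                    o, glist, cfg,
                    min_records=config.m.min_records,
                    truncation_q=config.m.truncation_q,
                )
            mask_grid = EnvGrid(
                variable=f"M:{sp}",
                values=areas[sp].mask.astype(float),
                nodata_mask=frame.nodata_mask,
                xllcorner=frame.xllcorner,
                yllcorner=frame.yllcorner,
                cell_size=frame.cell_size,
            )
            p = os.path.join(m_dir, f"{sp}.asc")
            geo_io.write_env_grid(mask_grid, p)
            emit(p)
        n_occ_only = sum(1 for a in areas.values() if a.status == "occurrence_only")
        log["stages"]["m"] = {
            "mode": config.m.mode,
            "occurrence_only": n_occ_only,
            "simulated": len(areas) - n_occ_only,
        }

        stage = "bins"
        union = bar.union_mask(list(areas.values()))
        schemes: dict[str, bar.BinScheme] = {}
        bins_dir = os.path.join(out, "bins")
        os.makedirs(bins_dir, exist_ok=True)
        for var in sorted(grids):
            schemes[var] = bar.build_bin_scheme(
                grids[var], union, config.bin_widths[var]
            )
            p = os.path.join(bins_dir, f"{var}.json")
            schemes[var].to_json(p)
            emit(p)
        log["stages"]["bins"] = {v: schemes[v].n_bins for v in schemes}

        stage = "br"
        br_dir = os.path.join(out, "br")
        os.makedirs(br_dir, exist_ok=True)
        matrices: dict[str, bar.BRMatrix] = {}
        summaries: list[bar.NicheSummary] = []
        for var in sorted(grids):
            coded: dict[str, np.ndarray] = {}
            for sp in sorted(occ_thin):
                occ_vals = [grids[var].value_at(lon, lat) for lon, lat in occ_thin[sp].points]
                if areas[sp].status == "occurrence_only":
                    m_vals = None
                else:
                    m_vals = msim.accessible_env_values(areas[sp], grids[var])
                coded[sp] = bar.code_br(occ_vals, m_vals, schemes[var])
                summaries.append(
                    bar.niche_summary(occ_vals, sp, var, source="occurrences")
                )
                if m_vals is not None:
                    summaries.append(bar.niche_summary(m_vals, sp, var, source="M"))
            matrices[var] = bar.build_br_matrix(coded, tree, var)
            p = os.path.join(br_dir, f"{var}.tsv")
            matrices[var].to_tsv(p, schemes[var])
            emit(p)
        sum_path = os.path.join(out, "niche_summaries.tsv")
        pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
            sum_path, sep="\t", index=False
        )
        emit(sum_path)

        stage = "asr"
        asr_dir = os.path.join(out, "asr")
        os.makedirs(asr_dir, exist_ok=True)
        ancestral: dict[str, asr_mod.AncestralNiche] = {}
        for var in sorted(grids):
            ancestral[var] = asr_mod.reconstruct_matrix(
                matrices[var], tree, theta=config.asr.theta,
                rate_bounds=(config.asr.rate_min, config.asr.rate_max),
            )
            ps = os.path.join(asr_dir, f"{var}_states.tsv")
            pp = os.path.join(asr_dir, f"{var}_probs.tsv")
            ancestral[var].to_tsv(ps)
            ancestral[var].probs_to_tsv(pp)
            emit(ps)
            emit(pp)
        tree_annot = os.path.join(asr_dir, "tree_node_ids.nwk")
        geo_io.write_newick(tree, tree_annot, label_internal=True)
        emit(tree_annot)

        stage = "classify"
        table, summary, records = cc.summarize_clade(tree, ancestral, matrices)
        ch_dir = os.path.join(out, "changes")
        os.makedirs(ch_dir, exist_ok=True)
        tbl_path = os.path.join(ch_dir, "change_table.tsv")
        table.to_csv(tbl_path, sep="\t", index=False)
        emit(tbl_path)
        sm_path = os.path.join(ch_dir, "clade_summary.tsv")
        cc.summary_table(summary, sorted(grids)).to_csv(sm_path, sep="\t", index=False)
        emit(sm_path)
        log["stages"]["classify"] = {
            v: len(summary.changed_strict[v]) for v in sorted(grids)
        }

        stage = "project"
        if config.project:
            pr_dir = os.path.join(out, "projections")
            os.makedirs(pr_dir, exist_ok=True)
            changed = {
                (r.species, r.variable): r
                for r in records
                if set(r.events) & set(cc.CERTAIN_EVENT_CLASSES)
                or "complete_retraction" in r.events
            }
            for (sp, var), rec in sorted(changed.items()):
                A = ancestral[var].vector(rec.parent)
                D = matrices[var].row(sp)
                pg = proj.project_change(sp, areas[sp], grids[var], schemes[var], A, D)
                p = os.path.join(pr_dir, f"{sp}_{var}.asc")
                proj.export_category_grid(pg, p)
                emit(p)
                emit(f"{p}.legend.json")
            log["stages"]["project"] = {"grids_written": len(changed)}

        stage = "summarize"
        log_path = os.path.join(out, "run_log.json")
        with open(log_path, "w") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
        emit(log_path)
        man_path = os.path.join(out, "manifest.json")
        with open(man_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return PipelineResult(
        manifest=manifest,
        change_table=table,
        summary=summary,
        records=records,
        areas=areas,
        schemes=schemes,
        tree=tree,
        log=log,
    )


# ----------------------------------------------------- truth scoring


@dataclass
class RecoveryScore:
    per_class: dict[str, dict[str, float]]
    sensitivity: float  # pooled over the four certain classes
    fdp: float  # pooled false-discovery proportion
    n_true: int
    n_reported: int
    n_branches: int


def score_recovery(
    records: list[cc.NicheChangeRecord],
    truth: list[synth.TruthEvent],
    tree: DatedTree,
) -> RecoveryScore:
    """Match reported terminal-branch events against planted truth on
    (species, variable, event class) for the four certain classes."""
    tip_ids = set(tree.tips())
    truth_keys = {
        (tree.nodes[e.child].label, e.variable, e.event)
        for e in truth
        if e.child in tip_ids and e.event in cc.CERTAIN_EVENT_CLASSES
    }
    reported_keys = {
        (r.species, r.variable, ev)
        for r in records
        for ev in r.events
        if ev in cc.CERTAIN_EVENT_CLASSES
    }
    per_class: dict[str, dict[str, float]] = {}
    for cls in cc.CERTAIN_EVENT_CLASSES:
        t = {k for k in truth_keys if k[2] == cls}
        r = {k for k in reported_keys if k[2] == cls}
        per_class[cls] = {
            "sensitivity": len(t & r) / len(t) if t else float("nan"),
            "fdp": len(r - t) / len(r) if r else 0.0,
            "n_true": len(t),
            "n_reported": len(r),
        }
    n_true = len(truth_keys)
    n_rep = len(reported_keys)
    return RecoveryScore(
        per_class=per_class,
        sensitivity=len(truth_keys & reported_keys) / n_true if n_true else float("nan"),
        fdp=len(reported_keys - truth_keys) / n_rep if n_rep else 0.0,
        n_true=n_true,
        n_reported=n_rep,
        n_branches=len(records),
    )
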