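# barniche

Climatic niche evolution on dated phylogenies, for comparative ecologists
and biogeographers who want to know *where* and *when* a clade's species
expanded or retracted their temperature and precipitation niches — while
being honest about what unsampled environments cannot tell us.

The package re-implements, as a tested and reusable pipeline, the
binned-ancestral-range approach to ancestral niche reconstruction:

1. **Occurrence hygiene** — validate records against the raster frame and
   spatially thin them to a minimum pairwise great-circle distance
   (default 5.2 km), retaining as many points as possible.
2. **Accessible areas (M)** — per species, simulate the region reachable
   by dispersal over a suitability surface (truncated
   Mahalanobis-ellipsoid envelope in environment space): 35 dispersal
   events, up to 2 dispersers per colonized cell per event, a log-normal
   dispersal kernel (median one cell; SD ∈ {0.25, 0.50, 0.75}, default
   0.50). Species with too few records fall back to an occurrence-only
   area.
3. **Binned-range (BR) coding** — estimate the clade's niche range within
   the union of all Ms, cut it into equal-width bins (~1 °C, ~100 mm),
   and code each species per bin: present `1` (bin overlaps the occupied
   interval), absent `0` (accessible but unoccupied), uncertain `?`
   (beyond the accessible range — unknowable).
4. **Ancestral reconstruction** — each bin is an independent binary
   character under a symmetric two-state Markov chain
   (P(stay) = ½ + ½·e^(−2rt), stationary root prior). The rate *r* is
   fitted by maximum likelihood per bin; marginal ancestral probabilities
   come from the standard two-pass pruning computation; states are
   discretized at θ = 0.8 (else `?`).
5. **Change typology** — per branch, bins flip as *expansion* (0→1),
   *retraction* (1→0), *stasis*, or *indeterminate* (any `?`), and
   branch events are placed relative to the ancestor's niche limits:
   `expansion_high/low`, `retraction_high/low`, interior changes, and
   `complete_retraction` when nothing certain is shared.
6. **Geographic projection** — each species' change categories are
   painted back onto its accessible area as an integer-coded raster
   (both / ancestral-only / current-only / neither / indeterminate).

A first-class synthetic-data module generates the whole study system —
spatially autocorrelated environmental grids, dated Yule trees (default
40 tips, 6.12 Myr crown age), interval niches evolved along branches with
a known event list, and occurrence samples — so every stage can be scored
against planted ground truth.

## Worked example

Generate a 12-species synthetic clade with eight planted terminal-branch
events (≥ 3 bin widths each), run the pipeline, and score recovery:

```python
from barniche.pipeline import (
    MConfig, PipelineConfig, VariableSpec, generate_feasible_study,
    run_pipeline, score_recovery, write_study,
)

CLEAN = (
    VariableSpec("temperature", "ns", 0.0, 30.0, 0.0, 1.0, (10.5, 19.5)),
    VariableSpec("precipitation", "we", 0.0, 1500.0, 0.0, 100.0, (450.0, 1050.0)),
)
study = generate_feasible_study(
    seed=1, n_species=12, n_rows=100, n_cols=100, variables=CLEAN,
    plant_counts={"temperature": 4, "precipitation": 4}, plant_both=2,
    n_occurrence_only=0, records=(20, 40))
paths = write_study(study, "study")
cfg = PipelineConfig(
    grids={v: paths[f"grid:{v}"] for v in ("temperature", "precipitation")},
    occurrences=paths["occurrences"], tree=paths["tree"], out_dir="out",
    thin_km=0.1, m=MConfig(mode="extent"))
res = run_pipeline(cfg)
print(res.change_table[res.change_table.events != ""].to_string(index=False))
sc = score_recovery(res.records, study.truth, study.tree)
print("sensitivity", sc.sensitivity, "fdp", sc.fdp)
```

which prints:

```
species      variable          events  n_changed_bins note
   sp03 precipitation  expansion_high               3
   sp03   temperature  expansion_high               3
   sp05 precipitation   expansion_low               4
   sp05   temperature   expansion_low               4
   sp06   temperature retraction_high               6
   sp07   temperature  retraction_low               4
   sp08 precipitation retraction_high               2
   sp09 precipitation  retraction_low               3
sensitivity 1.0 fdp 0.0
```

Every planted event is recovered on the correct branch, in the correct
variable, at the correct niche limit (`n_changed_bins` counts the bins
that flipped), with no spurious events — sensitivity 1.0 at a
false-discovery proportion of 0.0.

The same workflow is available from the shell:

```sh
barniche simulate-data --out study --seed 1 --n-species 40
barniche run-all --config config.yaml
barniche score --changes out/changes/change_table.tsv \
               --truth study/truth_events.tsv --tree study/tree.nwk
```

Each pipeline run writes a `manifest.json` of SHA-256 hashes; the same
config and seeds reproduce every output byte.

## Layout

```
src/barniche/
  synthetic_data.py        grids, Yule trees, true niches, occurrences
  geo_io.py                ASCII grids, CSV, Newick, thinning, validation
  m_simulation.py          suitability envelope + dispersal simulation
  bar_coding.py            union range, bin schemes, BR coding
  asr.py                   two-state ML reconstruction with '?' tips
  change_classification.py branch-wise event typology + clade summaries
  geo_projection.py        categorical change rasters
  pipeline.py              orchestration, synthetic studies, truth scoring
  cli.py                   `barniche` command-line interface
docs/methods.md            model, assumptions, parameter choices, limits
```
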