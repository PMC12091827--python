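# Methods

This note documents the models and procedures implemented in `barniche`,
the assumptions behind them, the parameters that matter, and the design
choices made where the method leaves room.

## Problem setting

Reconstructing how climatic niches evolved along a phylogeny from
present-day occurrence records faces a structural censoring problem:
only the *realized* niche inside the environments a species can actually
reach is observable. Coding niches from occurrences alone inflates
apparent change; ignoring unreachable environments hides genuine
uncertainty. The binned-ancestral-range approach addresses both by
(a) restricting "available" environments to each species' accessible
area M, and (b) carrying an explicit third character state, uncertain,
through the ancestral reconstruction. The pipeline covers the full path
from rasters + occurrences + a dated tree to branch-wise event calls and
maps, with a synthetic generator providing ground truth for validation.

## Spatial frame and occurrence hygiene

All rasters of one analysis must share origin, cell size, and shape
(WGS84 lon/lat, lower-left registered; ESRI ASCII dialect, written with
`repr` precision so round trips are bit-exact). Cells are half-open
`[x, x+cs) × [y, y+cs)`; points on the extreme top/right boundary map to
the last cell. Occurrences on nodata cells or outside the extent are
dropped with a logged reason.

Thinning enforces a minimum pairwise great-circle distance (haversine,
R = 6371.0088 km; default threshold 5.2 km, one point per ~2.5-arcmin
pixel). The objective is to *retain as many points as possible*, so the
conflict graph is decomposed into connected components and each
component of ≤ 25 points is solved exactly (maximum independent set by
branch and bound, deterministic lexicographic tie-break); larger
components fall back to greedily deleting the point with the most
close neighbors (ties to the lowest input index). The procedure is
deterministic and idempotent. Exactness on small components is the
reason this implementation can match brute-force subset search in tests;
published thinning tools are typically stochastic, so their output on
dense clusters may differ point-for-point while satisfying the same
constraint.

Four bioclim variables mixing temperature and precipitation signals
(bio8, bio9, bio18, bio19) can be excluded up front, as their quarter
definitions produce spatial artifacts.

## Accessible areas (M)

Suitability is a truncated Mahalanobis-ellipsoid envelope: occurrence
environments give a centroid and covariance (sample covariance, ddof 1;
ill-conditioned covariances fall back to their diagonal with a warning);
squared Mahalanobis distance d² maps to suitability `max(0, 1 − d²/q)`
with `q` the χ² quantile at `truncation_q` (default 0.95, df = number of
variables), rescaled so the maximum over data cells is 1. The cited
simulation tool family is ellipsoid-based but its internal formula is
not published; this linear-in-d² envelope is the package's own choice
and is documented as such.

Dispersal runs on the lattice: per event, every colonized cell with
suitability s > 0 emits `ceil(s·m)` dispersers (clamped to [1, m];
m = `max_dispersers` = 2, so one disperser for s ≤ 0.5 and two above),
each travelling a log-normal distance (median 1 cell width,
`sdlog = kernel_sd`) in a uniform direction; the rounded landing cell is
colonized if suitable, displacements leaving the grid are discarded
(absorbing boundary). Defaults: 35 events (one per year of the climate
reference window), kernel SD 0.50 with 0.25/0.75 as screening
candidates — the screened masks can all be emitted for comparison; the
package does not automate the expert choice among them. Kernel units
are cell widths, not km: dispersal operates on the lattice and the
median displacement is pinned at one cell, leaving the SD as the single
spread parameter. Colonization is monotone over events, M always
contains the occupied cells and never a nodata cell, and a fixed seed
reproduces the mask exactly.

Species with fewer than `min_records` (default 5) thinned records — the
number is a package default; the phenomenon mirrors real studies where
some fraction of species have too few records to simulate — receive an
occurrence-only area covering exactly their occupied cells.

For truth-scoring runs the pipeline also offers `m_mode: extent`
(M = the full data extent for species above the record threshold). A
dispersal-simulated M cannot, by construction, cover environments far
outside the species' own niche, so with honest Ms most other species are
coded uncertain exactly where a planted event's bins lie; extent mode
removes that censoring so recovery can be scored against planted truth.
The dispersal simulation itself is validated by its own properties
(identity at zero events, monotone growth, determinism, colonized area
increasing in kernel SD).

## Binned-range coding

The clade-wide range of each variable is the min–max of grid values over
the union of all Ms. The bin count is `round(range / target_width)`
(at least 1) and the width is adjusted to `range / n_bins` — bins are
exactly equal-sized and approximately the target (~1 °C, ~100 mm).
Bins are half-open with a closed last bin, so the global maximum belongs
to the final bin.

Per species: bins with any (even point) overlap of the closed occupied
interval `[min(occ), max(occ)]` are present; bins with positive-length
overlap of the accessible range `[min(M), max(M)]` and not present are
absent; all other bins are uncertain. Two consequences worth noting:
the boundary bins that touch the accessible range only at a single
point are uncertain, which reproduces the boundary-coincidence rule
(when an occupied limit meets the M limit, everything beyond is
uncertain); and bins beyond the accessible range at a non-coincident
end are also uncertain — absent is reserved for accessible-but-
unoccupied environments, since inaccessible environments are
unknowable, not vacant. Occurrence-only species have no absent bins at
all. Present runs are contiguous at tips (interval niches); summary
statistics use type-7 linear-interpolation quantiles and sample SD, and
coding uses the thinned occurrence set throughout.

## Ancestral reconstruction

Each bin is an independent binary character under the symmetric
two-state CTMC ("equal rates"): `P(stay) = ½ + ½·e^(−2rt)`, root prior
(0.5, 0.5). Uncertain tips are partial likelihoods (1, 1). The rate is
fitted per bin by bounded ML over log-rate in [1e−8, 1e3]: a 49-point
log-spaced scan locates the global basin before Brent refinement —
the profile likelihood is genuinely bimodal for some characters (a
diffuse high-rate plateau where every marginal is 0.5 competes with the
sharp low-rate optimum), and a plain bounded search can land on the
wrong side. Invariant, fully certain bins bypass optimization (state
fixed clade-wide, probability 1); bins with no certain tip stay
uncertain at probability 0.5. Marginal ancestral probabilities use the
standard inside/outside two-pass computation with per-node rescaling;
discretization is at θ (default 0.8): present if P(present) ≥ θ, absent
if ≤ 1 − θ, else uncertain. Zero-length branches are floored at 1e−8
Myr. Ancestral present-runs are *not* forced to be contiguous; the
interval constraint is a tip-level property.

The model family, root prior, and cutoff are all exposed as
configuration; reconstruction correctness is checked against exhaustive
enumeration over all internal-state assignments for every rooted binary
shape of ≤ 6 tips at 1e−10 tolerance.

## Change typology

Per bin between ancestor A and descendant D (both over {1, 0, ?}):
retraction (1→0), expansion (0→1), stasis (identical certain states),
indeterminate (any ?). Events anchor to the ancestor's certainly-present
run: expansion bins strictly above/below its upper/lower limit are
expansion high/low; the retraction run containing the upper/lower
present limit is retraction high/low; changes strictly inside the run
are labeled `interior_*` and reported separately (the limit-based
typology does not cover holes, and folding them into high/low would
overstate limit shifts). If D shares no certainly-present bin with A,
`complete_retraction` is emitted and subsumes the retraction labels; if
D additionally has no certain presence at all, the record carries an
uncertainty note. Terminal branches compare the reconstructed parent
vector to the species' observed BR vector; internal branches compare two
reconstructions. Clade summaries report both a strict count (species
with at least one certain high/low event) and an inclusive count (plus
complete retractions and interior changes), since whether uncertain
complete retractions belong in change totals is a judgment call.

## Geographic projection

For a changed species, each M cell's environmental value is binned and
the (A, D) states at that bin give the cell's category: both,
ancestral_only (retraction zone), current_only (expansion zone),
neither, or indeterminate; non-M cells are outside_M. Categories
partition M exactly. Projection is per variable; occurrence-only
species are projected over their occupied cells. Output is an
integer-coded ASCII grid with a JSON legend sidecar.

## Synthetic study systems

The generator emulates: smooth environmental fields (a deterministic
gradient plus a Gaussian field smoothed by a 5-cell moving average and
rescaled to the requested marginal SD — a light-weight stand-in for
spatially autocorrelated climate layers); dated Yule trees (constant
rate pure birth, rescaled to the target crown age; defaults 40 tips and
6.12 Myr, matching the motivating clade's size and age scale); interval
niches evolved along branches with at most one event per branch per
variable (event ∈ {expansion, retraction} × {high, low}, magnitude
|N(0, step_sd)|, clamping at the grid range recorded as metadata rather
than as an event so recovery scoring stays clean); and occurrences
sampled uniformly without replacement from the jointly suitable cells,
never on nodata. Everything is a pure function of (spec, seed).

Default study conditions mirror the motivating design: two variables
(temperature 0–30 °C north–south, precipitation 0–1500 mm west–east),
bin targets 1 °C / 100 mm, 40 species of which 8 are low-record
(2–4 points) and fall back to occurrence-only, the rest with 6–24
points (per-species record counts on the scale of the real dataset's
2–54).

Recovery benchmarks additionally use noise-free, orthogonal gradients
(the two variables are then separable, so an event in one cannot leak
into the coding of the other) and a sampling mode that always includes
the suitable cells with the extreme values of each variable, pinning the
occupied range to what the grid can express. Planted root intervals sit
mid-bin (temperature 10.5–19.5 °C, precipitation 450–1050 mm) so
sub-bin-width events stay inside one bin, and magnitude cycles
(3.5/4.5/5.5 temperature bins, 3.5/4.5 precipitation bins) are capped
below the interval widths so a retraction can never collapse a niche.

Planted events go on terminal branches chosen for identifiability,
decided a priori from the reconstruction model's structure: no two
planted tips of the same variable share a parent; the parent is never
the root (flat prior); the terminal branch is between depth/15 and
depth/3 (a near-zero branch makes the required change so improbable
that the diffuse infinite-rate solution wins; a long branch decays the
signal); a cherry tip is used only if its stem is ≤ depth/6 (inside a
cherry the sibling's evidence exactly cancels the deviant's, leaving
only the grandparent anchor); and each planted tip keeps at least one
certainly-coded species in its sibling subtree when occurrence-only
species are assigned. Trees are sampled until the requested placement is
structurally feasible (a property of the topology alone, checked before
anything downstream runs).

What passing these benchmarks does and does not show: perfect recovery
on separable noise-free fields with pinned ranges demonstrates that the
coding, reconstruction, and typology machinery is correct and that the
events are identifiable under the stated geometry; it does not
demonstrate robustness to sampling bias, correlated variables, raster
noise, or the niche truncation of honest dispersal-limited Ms — on real
data those factors produce exactly the uncertain calls the third state
exists to express.

## Numerical choices and degenerate inputs

Pruning uses per-node max rescaling (log-scale accumulated). Optimizer
tolerance 1e−10 on log-rate. Zero environmental range over the union
yields a single degenerate bin with a warning. A species whose occupied
range is disjoint from the bin scheme is a coding error. An occupied
cell set with no positive suitability degrades M to the occupied cells
with a warning. Ties in thinning break to the lowest input index; among
equally large optimal retained sets the lexicographically smallest is
chosen. All seeds derive from a single entry seed via NumPy
`SeedSequence` spawning.

## Known limitations

- The suitability envelope is a stand-in for the (unpublished) internals
  of the cited M-simulation tool; absolute M shapes will differ even if
  the qualitative behavior matches.
- Single symmetric rate per bin; no asymmetric (gain ≠ loss) model, no
  rate sharing across bins, no stochastic mapping, no parsimony.
- No joint temperature × precipitation coding; variables are analyzed
  independently by design.
- Only the current climate scenario is simulated for M; no past-climate
  layers.
- Event recovery is resolution-floored at one bin width by construction;
  the sub-resolution benchmark confirms such events are (correctly)
  invisible rather than mislabeled.
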