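# Methods

## Profiles

A phenotypic profile condenses the single-cell feature distributions of one
treatment in one cell line into a D-dimensional vector of signed two-sample
Kolmogorov–Smirnov statistics against matched DMSO control cells. For
feature j, with treated ECDF `F_t` and control ECDF `F_c`, let
`D+ = sup_x [F_c(x) − F_t(x)]` and `D− = sup_x [F_t(x) − F_c(x)]`, both
evaluated over the pooled sample points (where the supremum of an ECDF
difference is always attained). The profile entry is `+D+` if `D+ ≥ D−`,
else `−D−`; positive entries mean the treated population is stochastically
larger. Consequences of this definition:

* every entry lies in [−1, 1], with |entry| equal to the classical
  two-sided KS statistic;
* entries are invariant under strictly monotone transforms of a feature, so
  no per-feature standardisation is applied (or needed) before profiling;
* at the exact tie `D+ = D− > 0` the sign convention returns the positive
  branch from either argument order, so antisymmetry under swapping samples
  holds everywhere except at ties. The sign is read off the dominant ECDF
  branch rather than a mean or median shift: it is determined by the same
  object (the ECDF difference) that defines the magnitude, and is therefore
  assertable without further choices.

**Control matching** pools all DMSO cells on the plate(s) hosting the
treatment's wells (`control_policy="plate"`); global pooling is available
but mixes plate effects into every profile. Replicate wells of one compound
are pooled into a single profile (one point per compound in profile space);
a per-well mode exists behind a flag for QC use.

**DMSO self-profiles.** The control point cloud must be non-degenerate —
phenoactivity compares against the spread of DMSO around its own centroid.
Each DMSO well is profiled leave-one-well-out against the remaining DMSO
cells on its plate. Profiling a well against a pool that included itself
would bias every self-profile toward zero; leave-one-well-out instead
captures genuine well-to-well variability. Plates with a single DMSO well
cannot support this and are skipped with a warning. Under the null (all
wells from one distribution, 200 cells/well) self-profile entries
concentrate well inside ±0.25, which the suite checks by simulation.

## Phenoactivity

For a cell line and an MOA with n annotated, profiled compounds:

1. centroid `c` = coordinate-wise mean of the DMSO self-profiles (median
   optional);
2. `d_DMSO` = Euclidean distances of each DMSO self-profile to `c`;
   `d_MOA` = distances of each MOA compound profile to `c` (cosine
   available via config);
3. score = `max(0, sup_x [F_dDMSO(x) − F_dMOA(x)])`, the one-sided KS
   statistic: 0 when MOA distances are stochastically no larger than DMSO
   distances, 1 when every MOA compound lies beyond every DMSO replicate.

The one-sided-KS functional was chosen because it is bounded in [0, 1],
reads directly off the distance-distribution plots the framework produces,
and stays within the KS toolkit the profiles themselves use. It should be
read as this package's operationalisation of "how far above the control
distance distribution does the MOA sit", not as a calibrated p-value.

**Small-sample bias.** The supremum of an empirical process over few points
has positive expectation under the null: with 5 MOA compounds against ~40
DMSO wells the null score level sits near 0.3 (the suite measures it by
simulation), not at 0. Scores are therefore comparable *across cell lines
and MOAs at matched set sizes* — exactly how the framework uses them — and
not across very different MOA sizes. This also motivates reporting MOAs
with at least 5 compounds.

**Outside-cloud rule.** A compound is "outside" the DMSO cloud when its
centroid distance strictly exceeds `median(d_DMSO) + IQR(d_DMSO)`.
Quartiles use linear interpolation (numpy's default); the threshold value
depends on this choice, so it is fixed and documented. With a constant DMSO
distance multiset the IQR is 0 and any strictly larger distance counts as
outside.

## Phenosimilarity

For an MOA with n ≥ 2 compounds, `within` = all C(n,2) pairwise distances
among its profiles; `neighbor` = for each member, its distances to its k
nearest compound profiles in the whole library (self excluded, ties broken
by compound identifier). Score =
`1 − max(0, sup_x [F_neighbor(x) − F_within(x)])`.

* k defaults to n − 1 so the two multisets have comparable size (n·(n−1)
  vs n(n−1)/2 elements) and so that a perfectly tight MOA — every member's
  nearest neighbors are exactly its fellow members — attains score 1
  identically. A fixed k is available.
* DMSO self-profiles never enter the neighbor search: proximity to control
  is phenoactivity's business; phenosimilarity asks whether the MOA is
  tight *relative to the library's local density*.
* The score is invariant under global isometries and rescaling of profile
  space, and is flat at 1 while an MOA remains mutually-nearest — it only
  reacts once dispersion pushes members into neighborhoods dominated by
  other compounds. This is intended: a compact cluster's internal spread is
  uninformative below the library's resolution scale.

Multi-MOA compounds contribute their profile to each annotated class.

## Panel optimization

A line set S scores MOA m as `max_{l in S} score(l, m)` — the set detects
(or clusters) an MOA if its best line does. The set summary is the mean of
per-MOA maxima over MOAs eligible in every line of S (median optional). Max
aggregation makes summaries monotone: adding a line never lowers a set's
summary (the suite asserts this for all subsets of every synthetic run).
Percent improvement between summaries is `100·(s_set − s_base)/s_base`.

Subset search is exhaustive up to `max_set_size` (2^p − 1 subsets for p
lines — exact and cheap for the panel sizes screens use); ties are ordered
by fewer lines, then lexicographic names, giving a deterministic total
order. A greedy forward search with the same tie-break exists for large
panels.

**Subsampling.** Robustness of summaries to library composition is
estimated by drawing `floor(fraction · N)` of the profiled, annotated
compounds without replacement (defaults: 50 draws, fraction 2/3) and
re-scoring. Draw d uses the RNG stream `seed + d`, so distributions are
reproducible and extendable. MOAs that fall below the eligibility size
inside a draw drop out of that draw (logged, never an error); a draw with
no eligible MOA contributes NaN and is excluded from the subsample
mean/sd. Compounds, not MOAs, are resampled — the question is sensitivity
to which compounds were screened.

## Synthetic screens

`generate_screen` emulates the screen hierarchy: per line, plates carrying
compound wells plus `n_dmso_wells_per_plate` control wells, `cells_per_well`
cells each. DMSO cells are `Normal(mu_l, sigma)` per feature; compound `c`
cells are shifted by the ground-truth effect

    v[c, l] = a[moa(c), l] · u[moa(c), l] + tau[moa(c)] · eps_c

* `u[m, l]` — sparse unit direction (`n_active_features` of `n_features`,
  default 8 of 77): an MOA perturbs a subset of features, with
  line-specific geometry;
* `a[m, l] ≥ 0` — planted effect magnitude, the phenoactivity dial;
* `eps_c` — per-compound latent (`Normal(0, I)/√D`, so ‖eps‖ ≈ 1), drawn
  once and shared across lines: a compound's off-target identity travels
  with it;
* `tau[m] ≥ 0` — within-MOA heterogeneity, the phenosimilarity dial.

Gaussian cell noise is the default (`cell_noise_sd`, 1.0); a Student-t
option (`noise_df`) stress-tests the rank-based profiles under heavy tails.
All draws derive from one `SeedSequence(seed)`, spawned per cell line, so
identical configs give byte-identical tables. Defaults are desk-scale study
conditions — 6 lines × 20 MOAs × 5 compounds/MOA × 200 cells/well × 77
features (~10 s end to end on one CPU).

What the generator does *not* emulate: plate/batch artifacts (a config hook
is reserved), dose–response structure, correlated feature blocks, cell-count
toxicity effects, or segmentation noise. Passing tests therefore show the
*scoring machinery* is correct and responsive to planted structure; they do
not certify behaviour under batch confounding on real screens.

**Recovery harness.** `parameter_recovery_report` sweeps an effect grid and
a heterogeneity grid (≥ 2 values each, ≥ 10 seeds per point) and reports
Spearman trends of mean scores on grid means. Each swept value multiplies a
fixed per-MOA potency ramp (0.25–1.75 over the panel): real MOA classes
differ widely in potency, and the ramp keeps part of the panel in the
partial-separation regime at every sweep value, so grid means respond
smoothly instead of saturating at 1 all at once. On the shipped
configurations the phenoactivity trend is exactly monotone (Spearman 1.0)
and the phenosimilarity trend exactly antitone (−1.0).

## Problem sizes and numerical choices

* Test and acceptance runs use scaled-down screens (2–3 lines, 6–10 MOAs,
  4–5 compounds/MOA, 50–100 cells/well, 12–24 features), chosen so the
  statistical effects under test (null bias level, monotone recovery,
  best-line ranking) are well-resolved while the whole suite stays
  desk-scale; the generator's defaults remain the larger study conditions
  above.
* All ECDF suprema are evaluated over pooled sample points via sorted
  search (`searchsorted`), which is exact; the suite cross-checks against
  exhaustive enumeration and against an independent two-sided KS
  implementation.
* Ties: nearest-neighbor ties break by compound identifier; ranking ties by
  set size then name; the signed-KS sign tie returns the positive branch.
* Degenerate inputs: empty samples, single DMSO wells, single-compound
  MOAs, missing line score tables and zero baselines all have defined
  behaviour (error, skip-with-warning, or exclusion) exercised in tests.

## Known limitations

* The score functionals operationalise distribution overlap with one-sided
  KS statistics; other reductions (AUC, energy distance) would order cell
  lines similarly but produce different absolute values, so absolute scores
  should not be compared across implementations.
* Small-MOA scores carry the positive null bias discussed above.
* Per-plate control pooling assumes controls on each plate are
  representative; no explicit batch correction is applied.
* Exhaustive subset enumeration is exponential in panel size; beyond ~15
  lines use the greedy mode.
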