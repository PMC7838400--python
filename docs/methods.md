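# Methods

This note documents the models and procedures implemented in `lesionconn`,
the parameters that matter, the design decisions taken where the procedure
left latitude, and what the synthetic cohorts do and do not establish.

## Pipeline

### Background connectivity

Functional connectivity is estimated on task-run residuals: every node's
time series is replaced by its least-squares residual against
`[task | nuisance | intercept]`, residuals are correlated pairwise
(Pearson), and correlations are Fisher-z transformed
(`z = arctanh(r)`, with `r` clipped to ±(1 − 1e−7) so perfectly correlated
residuals map to a large finite value rather than infinity). Run-level
matrices are averaged entrywise **in z space** — the variance-stabilized
scale on which averaging is well behaved. The intercept is always included
in the residualizing design; otherwise Pearson centering absorbs it
inconsistently across nodes. Regressors are assumed already convolved;
no preprocessing (filtering, motion estimation) is re-implemented.

### Graph construction

Connectomes are binarized by **proportional thresholding**: the
`round(p · n_pairs)` most positive upper-triangle z entries become edges.
Choices within that rule:

* **Signed ranking.** Entries are ranked by signed z (most positive kept),
  not absolute value — the standard construction for binarized
  functional-connectome hub analyses.
* **Rounding.** Half-away-from-zero rounding of `p · n_pairs`, for exact
  determinism across platforms.
* **Tie rule.** Ties at the cut are broken by larger z first, then
  lexicographically smaller (i, j). With this total order the edge set at a
  smaller p is always a subset of the edge set at a larger p.
* **Lesioned matrices.** The proportion is taken over *retained-node* pairs,
  so smaller matrices keep proportionally fewer edges.
* **Threshold set.** Metrics are averaged across p ∈ {0.10, 0.20, 0.25,
  0.30, 0.40} for stability, except hub-topography analyses, which use the
  single p = 0.25 graph.
* **Hemispheric modularity.** The connectome is restricted to one
  hemisphere **first** and then thresholded at the same p — "within-
  hemisphere connections only" is read as defining a self-contained
  hemispheric graph. Restricting an already-thresholded whole-brain graph is
  also supported (`hemisphere_subgraph` accepts a `BinaryGraph`).

### Fixed-partition metrics

All modularity values are computed against a single **reference partition**;
there is no per-graph community detection, and lesioned nodes are simply
absent from the graph being scored. The reference partition is agglomerative
Ward clustering of the healthy group-average z matrix, cut at the desired
module count. Each node's profile is its matrix row with the diagonal
replaced by the row's maximum off-diagonal value (self-similarity carries no
information). Profiles are compared by **correlation distance**
(1 − Pearson r between rows) by default: it clusters nodes by the *shape* of
their connectivity profile and is insensitive to uniform offsets, which
matters because a connector hub's row is its module's profile plus a raised
baseline — under raw Euclidean distance such rows split off into spurious
clusters (recovery of planted modules drops from ~97% to ~86% at the default
conditions). Euclidean profile distance remains available
(`distance="euclidean"`).

For an undirected binary graph with L edges and modules s:

* Newman's modularity `Q = Σ_s [l_s/L − (d_s/2L)²]` with `l_s` the
  within-module edge count and `d_s` the module's summed degree.
* Participation coefficient `PC_i = 1 − Σ_s (κ_is/k_i)²`; `PC_i = 0` for
  isolated nodes by convention.
* Within-module degree z-score `WD_i = (κ_i − μ_m)/σ_m`; `WD_i = 0` when
  `σ_m = 0`.

**Population (divide-by-n) standard deviations** are used throughout (WD and
the hub cut), matching the classical within-module-degree formulation;
sample SD is available via `ddof=1`. Group **hub templates** average each
node's PC/WD over the subjects retaining it (`n_contributing` is recorded so
low-coverage nodes can be filtered); hubs are nodes **strictly** more than
one SD above the template mean, so a constant template yields no hubs.

### Lesioning

A voxel mask resolves to lesioned nodes by rasterizing a sphere (default
radius 5 mm; a voxel belongs to the sphere iff its *center* lies within the
radius) at each node's coordinate and applying the strict rule
*damaged fraction > threshold* (default 0.25; the 0.10/0.20/0.30 sensitivity
values are plain parameters). A fraction exactly at the threshold does not
lesion the node. The source methods state a 5 mm node radius in one place
and 10 mm in another; 5 mm is the default here and the radius is an explicit
parameter. Node subtraction removes the lesioned rows/columns and nothing
else. The pseudo-lesion cohort applies every mask to every control
(n_masks × n_controls connectomes); targeted lesions remove a hub set
instead. A mask's **PC/WD damage scores** are the mean healthy-template
PC/WD over its nodes.

### Inference

* **Mask-permutation test.** For the pseudo group, the statistic is the mean
  over controls of the per-control correlation between the 25 damage scores
  and that control's 25 modularity values. The null permutes the mask-level
  damage vector once per permutation, shared across controls — masks are the
  exchangeable units and the dependence between controls is preserved. The
  real group's single correlation is tested by permuting the same damage
  vector. p-values carry the add-one correction
  `(1 + #extreme)/(n_perm + 1)` and are never zero.
* **Sidedness.** The default reports a one-sided p in the direction of the
  observed correlation, the convention that reproduces the printed
  values this pipeline emulates (e.g. r = −0.37 with p = 0.038 at n = 25
  back-computes to a one-sided, not two-sided, probability). Note that a
  sign-adaptive one-sided test is identically a two-sided test at twice the
  level, so its null rejection rate at α is ≈ 2α; pre-specified directions
  (`side="greater"`/`"less"`) and `side="two_sided"` are exactly calibrated
  and are what the calibration checks assert.
* **Bootstrap comparison.** The real group's correlation is compared against
  the bootstrap distribution of the pseudo group's mean correlation
  (resample the 10 per-control values with replacement, 10,000 times),
  two-sided by tail doubling, capped at 1. This published procedure ignores
  the single value's own sampling variance and is therefore strongly
  anticonservative as a two-sample test (same-population rejection ≈ 0.6 at
  α = 0.05 in simulation); the test suite asserts this property explicitly
  rather than pretending calibration. The procedure remains informative here
  because the effects it is asked to detect are sign reversals far outside
  the bootstrap distribution.
* **Group tests.** Two-sided paired/independent t-tests with Bonferroni
  correction; exactly-constant contrasts are flagged degenerate (NaN t)
  instead of raising or silently propagating.
* **Laterality.** The hub-set chi-square is the 1-df goodness-of-fit of a
  group's left/right hub counts against an even split, without continuity
  correction.

## Synthetic cohorts

The generator emulates the *statistical* structure of a healthy-control
task-fMRI cohort and a left-hemisphere stroke series — not anatomy, BOLD
biophysics or vascular territory. The default world is a desk-scale
analogue of a 235-node, 10-module, 10-control study: 60 nodes, 6 bilateral
modules, 10 controls, 25 masks.

### Node space

Left-hemisphere nodes sit on a jittered ~18 mm grid in an MNI-like box
(x < 0, never on the midline); right-hemisphere nodes are their x-mirrors,
and a mirrored pair shares a module, so every module is bilateral.
**Modules interleave spatially** rather than forming contiguous blocks:
functional systems are spatially distributed, so a contiguous lesion samples
many systems partially. This matters mechanically — if modules were spatial
blocks, a contiguous mask would swallow whole modules, and because WD is
z-scored within module, the mean WD of a near-complete module is ≈ 0: the
WD damage score would cancel by construction.

### Connectomes

Per-subject matrices are generated directly in Fisher-z space:
block means (`arctanh(r_within)` within modules, `arctanh(r_between)`
between) + a cohort-level pair-heterogeneity field + hub boosts +
independent per-subject noise, symmetrized, zero diagonal. No positive-
definiteness is enforced: downstream analyses use only ranks and thresholds,
which are invariant to the projection that would restore it.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `r_within` / `r_between` | 0.50 / 0.10 | separated blocks whose weight distributions still overlap at the thresholds; with complete separation the proportional cut never lands inside a block and modularity becomes insensitive to hub removal (the edge count is fixed by p, so Q moves only if the within/between composition at the cut moves) |
| `pair_sd` (= `pair_sd_within`) | 0.25 | pair-level heterogeneity of the cohort's "true" connectome, shared by all subjects; reproduces the heavy overlap of real edge-weight distributions |
| `noise_sd` | 0.10 | per-subject deviation around the cohort matrix |
| `n_global_hubs` / `n_local_hubs` | 6 / 8 | ≈ 10–13% of nodes, comparable to the hub fractions real templates produce |
| `hub_boost` / `hub_boost_local` | 0.40 / 0.45 | additive z boosts sized so hub rows dominate their stratum at the thresholds while leaving the two damage channels of comparable strength — a much stronger global boost drowns the WD channel in shared modularity variance |
| masks | 25, sizes 6–12 of 30 L nodes | the emulated study's masks removed up to ~22% of nodes; a narrow size range keeps the mean-based damage scores aligned with the count-based modularity effects |

Hub planting is structured, not uniform: hubs are planted as **homotopic
mirrored pairs** (equal hub counts per hemisphere — contiguous left
lesions need left-hemisphere hubs to hit), **one pair per module**
round-robin (crowding several hubs into one module deflates each one's WD
z-score), with global and local hubs **segregated into disjoint module
halves and spatially separated** (connector hubs concentrate in particular
territory in real connectomes; without separation a contiguous mask hits
both kinds at once and the PC and WD damage scores become collinear).
Each global hub's boost targets a random half of the foreign modules —
real connectors bridge particular systems, and a uniformly elevated row has
no profile shape for the clustering to latch onto.

Lesion masks grow breadth-first over the 6-nearest-neighbour adjacency of
the left-hemisphere nodes, seeds cycling through all L nodes in shuffled
order (a patient series tiles the vascular territory; purely random seeding
occasionally leaves hub neighbourhoods unsampled), sizes uniform on
[6, 12], ties in the BFS by node id. Voxel-form masks rasterize a node set
onto a grid with a configurable fraction of each sphere covered, leaving
other nodes' spheres untouched.

Synthetic **patients** share the population structure of the controls —
same base matrix and planted hubs, independent subject noise
(`CohortParams.noise_seed`). Without this the patients' actual hubs would
be unrelated to the healthy template used for damage scoring, which is both
biologically wrong and statistically fatal to the real-group analyses.

### Re-organization transform

The transform makes the "subtraction + re-organization" hypothesis
concrete. Given a subtracted connectome and its mask's damage scores:

* **Damage-coupled compensation.** Every between-module entry gains
  `−pc_coupling · (pc_damage − pc_ref)` (z units), and every within-module
  entry `−wd_coupling · (wd_damage − wd_ref)`. With `pc_coupling < 0`,
  masks with heavier connector-hub damage acquire proportionally more
  inter-module connectivity — compensatory recruitment of new connector
  routes — which lowers their modularity and flips the PC-damage/Q
  correlation negative. The reference levels default to the cohort-mean
  damage, so the coupling tilts the damage-modularity slope without
  depressing the whole group's modularity.
* **Hub promotions.** `new_hub_count` surviving nodes are promoted to
  hub-level connectivity (alternating local/global, additive
  `promotion_boost` on the relevant row entries), each landing in the right
  hemisphere with probability `rh_bias`. The promoted set is drawn once per
  parameter seed and shared across the cohort: group hub templates average
  over subjects, so only *consistent* re-organization can create
  group-level new hubs. This instantiates systematic (not idiosyncratic)
  re-organization.
* With all parameters zero the transform is exactly the identity.

The study defaults (`STUDY_REORG`: pc_coupling −2.0, wd_coupling 0,
new_hub_count 12, rh_bias 0.9, promotion_boost 0.6) are chosen to reproduce
the qualitative post-stroke pattern — PC-relationship reversal, more global
hubs in the real group, right-lateralized new local hubs — unambiguously at
desk scale. They are a hypothesis instrument, not an inference about
mechanism or effect size; in particular the synthetic real group's
modularity drop relative to controls is larger than a real cohort would
show.

### What passing tests do and do not show

The synthetic world demonstrates that the *pipeline* recovers planted
structure and separates subtraction from re-organization when they are
present by construction. It does not validate the biological hypothesis, and
several features of real data are absent: positive-definite correlation
structure, spatial autocorrelation of the BOLD signal, distance-dependent
connectivity, anatomical hub topography, heterogeneous lesion etiology, and
between-subject variability beyond additive Gaussian noise.

## Problem sizes and determinism

Every source of randomness flows from one master seed through named SHA-256
child seeds (< 2³¹), so worlds, analyses and resampling reproduce exactly.
The test suite exercises: metric-oracle equivalence on 200 random graphs
(n ≤ 30) at 1e−12; targeted-attack directionality over 100 cohorts;
the subtraction-phase pattern and the re-organization reversal over 50
replicate worlds each; permutation calibration over 2000 null simulations at
n = 25 (with an exhaustive-enumeration oracle at n = 6); and exact plumbing
(250 = 25 × 10 pseudo connectomes, the strict >25% voxel rule, empty hub
sets for constant templates, hemispheric Q of a single-hemisphere graph).
These sizes keep the full suite at a few minutes on one core while leaving
the pattern checks far from their pass thresholds.

## Limitations

* Q is always evaluated against the fixed reference partition; no
  Q-optimizing community detection is provided, by design.
* Only binary graphs and proportional thresholds; no weighted metrics or
  absolute thresholds.
* The bootstrap group comparison inherits the published procedure's
  anticonservativeness (documented above).
* Hub identity is sensitive to the mean+1SD cut when the template
  distribution is flat; `n_contributing` and the raw template values are
  exported so users can apply stricter criteria.
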