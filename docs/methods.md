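# Methods

## The model

`funcatlas` operates on binary fROI membership defined per subject on a
shared analysis space. Two space types implement one minimal protocol
(`n_elements`, `neighbors(e)`):

- **SurfaceMesh** — a triangulated cortical surface; two vertices are
  neighbors iff they share a triangle edge. Neighborhoods are purely
  graph-topological (steps, not millimetres); no geodesic distances are
  computed. Vertex coordinates are optional and only used for surface-area
  statistics (each vertex owns one third of every incident triangle's area).
- **VolumeGrid** — a 3-D voxel grid with 6-connectivity (face-adjacent
  voxels; one step along exactly one axis). 26-connectivity was rejected:
  a diagonal voxel differs in two or three coordinates and is not
  "immediately adjacent in one dimension". Linear indices are 0-based
  row-major; any 1-based external file is converted at the I/O boundary.

### Probabilistic maps

For ROI *r*, the map value at element *e* is `k_e / N_r`, where `k_e` counts
the subjects whose fROI contains *e* and `N_r` counts the subjects
possessing the fROI at all. Using the per-ROI denominator (rather than the
cohort size) means a probability of 1 always denotes full agreement among
the subjects in whom the region exists. Thresholding is inclusive
(`>= t`), so the "all subjects" endpoint `t = 1` is realizable; `t = 0` is
defined as the liberal at-least-one-subject map (identical to
`t = 1/N_r`). Atlas inclusion uses the prevalence rule: an ROI enters the
atlas only if defined in strictly more than half of the cohort.

### Maximum probability map (MPM)

1. Threshold every probabilistic map at the chosen level.
2. Elements claimed by several ROIs go to the ROI with the highest
   probability there.
3. Exact ties are resolved by averaging each tied ROI's probabilities over
   the elements within graph distance ≤ d, for d = 1, 2, …, until one ROI
   has the strictly highest mean. Elements outside a map's support count as
   probability 0 — the support boundary is informative; averaging over
   support only would let a single high-probability stray dominate. For
   pathologically symmetric inputs the expansion is capped at d = 10 and
   the lexicographically smallest ROI name wins, keeping the tiling
   deterministic (the cap is unreachable on any realistic input; symmetric
   cases arise only in constructed tests).
4. Cleanup of isolated elements: a labeled element violates the
   connectivity rule when no same-label element lies within the rescue
   radius — graph distance ≤ 3 on surfaces ("a same-ROI third-degree
   neighbor", read as *within* three steps: reading it as *exactly*
   distance 3 would penalize immediately adjacent same-label vertices),
   distance ≤ 1 (the 6-connected shell) on volume grids, where third-degree
   shells grow much faster. Violators are detected on a frozen snapshot and
   reassigned simultaneously — sequential in-place updates would make the
   result depend on iteration order — each going to the
   highest-probability *other* ROI that both claims the element with
   probability > 0 and has same-label elements in the immediate
   neighborhood. If no ROI satisfies both conditions the element becomes
   background (the natural completion of the reassignment rule; leaving
   such orphans labeled would defeat the cleanup). The scan repeats until
   no violators remain, with an iteration bound of the labeled-element
   count guaranteeing termination.

The tiling is fully deterministic: identical inputs yield identical MPMs.

### Evaluation

- **Dice**: `2|a ∩ b| / (|a| + |b|)`, 0 when both sets are empty.
  Surface Dice counts vertices and volume Dice counts voxels (set
  cardinalities, not areas).
- **LOOCV predictability**: folds iterate over the subjects possessing the
  ROI (subjects without it contribute no fold — the individual fROI *I* must
  exist to be predicted). Default per-fold threshold grid: `k/(N−1)` for
  `k = 0…N−1` with `N` holders, spanning "at least one subject" through
  "all remaining subjects". A fixed decimal grid can be passed instead for
  cross-ROI and cross-cohort comparability (the acceptance script uses
  0.00–1.00 in steps of 0.05). Per-threshold summaries report mean and
  `SE = SD/√folds`.
- **Threshold selection**: the grand mean over all provided records (all
  ROIs, factors, folds) per threshold level; ties go to the lower, more
  liberal threshold.
- **Incremental subject count**: for each n, seeded random size-n subsets
  of the ROI's holders (so every subset supports LOOCV), each scored by
  mean LOOCV Dice at a fixed threshold; mean ± SE across repetitions.
- **Reproducibility**: per subject, the mean Dice over all unordered pairs
  of thresholded single-run contrast maps, after intersection with an
  anatomical region mask. Thresholding (liberal t > 0 or a fixed t cutoff)
  happens upstream of this function.
- **Size–Dice correlation**: Pearson r between per-ROI mean size and mean
  Dice; requires ≥ 3 ROIs and nonzero variance in both variables.
- **Paired permutation test**: statistic = mean paired difference,
  two-sided; null by independent sign flips. With ≤ 20 pairs and
  `2^n ≤ n_permutations` the 2^n patterns are enumerated exactly;
  otherwise seeded Monte-Carlo with the +1 correction
  `p = (1 + hits)/(1 + n_permutations)`, so p is never 0. Defaults
  (10,000 permutations, two-sided, mean difference) are the standard
  paired choices.

### Winner-map responsivity

Per left-out subject, an MPM is built from the other N−1 subjects; within
each MPM fROI every element is assigned the condition with the maximal
response amplitude in the left-out subject's data (exact ties broken by
condition order — ties have measure zero for continuous amplitudes but the
rule keeps the analysis deterministic). Percentages are per (subject, ROI)
and sum to 100 for non-empty fROIs; empty leave-one-out fROIs are recorded
as NaN for that fold. Elements lacking amplitudes raise a missing-data
error rather than being silently dropped. Amplitude estimation (GLM /
trial-wise betas) is upstream; this package consumes amplitude tables.

## Synthetic cohorts

The generator emulates exactly the variability the analyses measure:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 19 | cohort size |
| `jitter_sd` | 1.5 steps | SD of the seed displacement per subject |
| `size_sd` | 1.0 steps | SD of the region-radius perturbation |
| `presence_prob` | 0.85 | probability a subject expresses an ROI |
| `selectivity_effect` | 3.0 | preferred-condition amplitude offset (in noise-SD units at the default `noise_sd`) |
| `noise_sd` | 1.0 | amplitude noise SD |

Regions are graph-geodesic balls (breadth-first expansion to the target
radius), which unifies surface and volume generation; Euclidean balls were
rejected because meshes need no coordinate frame. Volume jitter is a
per-axis rounded Gaussian displacement (redrawn up to 8 times if it lands
off-grid, then clamped); surface jitter is a random walk of
`|round(N(0, jitter_sd))|` steps. Within-subject overlaps after jitter are
resolved by nearest-jittered-seed in graph distance, ties to the
lexicographically smaller ROI name, so every element belongs to at most one
ROI per subject. `selectivity_effect` is an additive amplitude offset;
with `noise_sd = 0` and a positive effect the preferred condition wins
every in-region element exactly. Run maps keep each region element whose
underlying contrast plus run-specific Gaussian noise exceeds a cutoff
(defaults: contrast 1.0, cutoff 0.5) — zero noise reproduces the subject's
map in every run, and growing noise drives run-pair Dice toward the
random-overlap baseline.

The default ground truth (`default_volume_atlas`) places eight regions —
two each preferring faces, bodies, places and characters — as radius-3–4
balls on a 20³ grid, spaced so the nominal regions are disjoint. The
defaults were chosen once as a plausible desk-scale emulation of a
19-subject occipito-temporal localizer cohort: with them, the LOOCV sweep
selects a threshold near 0.2 with peak mean Dice ≈ 0.3–0.4 and marked
between-ROI spread — the regime the pipeline is designed to operate in.

All stochastic routines consume explicit integer seeds; cohort, response
and run generation draw from independent children of one `SeedSequence`,
so identical configurations are bit-reproducible and the three products
can be regenerated independently.

### What the generator does not emulate

No cortical folding or anatomical geometry, no hemodynamics, no spatial
autocorrelation of noise, no alignment error structure beyond isotropic
jitter, and no anisotropic or ROI-dependent variability. Passing tests
therefore demonstrate the correctness and calibration of the *computation*
(probability arithmetic, tiling rules, Dice analytics, rank-order recovery
of jitter/size/noise effects) — not that real fMRI cohorts meet these
idealized assumptions.

## Numerical choices and degenerate inputs

- Probability-tie detection and neighbor-mean comparisons use an absolute
  tolerance of 1e-12 (probabilities are small-integer ratios; genuine ties
  are exact and distinct fractions differ by far more).
- Dice of two empty sets is 0 (no evidence of overlap).
- Empty ROIs raise `EmptyROIError`; single-holder LOOCV, single-run
  reproducibility and < 3 correlation pairs raise `InsufficientDataError`;
  zero-variance correlation raises `UndefinedCorrelationError` instead of
  returning NaN.
- CSV output uses a fixed float format (`%.10g`), making pipeline reruns
  byte-identical.

## Problem sizes

The test suite and acceptance script run desk-scale configurations chosen
to exercise every code path with comfortable statistical margins: grids of
10³–26³ voxels, meshes of ~150 vertices, cohorts of 3–19 subjects, 5
repetitions per point of the jitter/radius recovery sweeps, 1,000
simulations for permutation-test calibration. The full suite completes in
well under a minute on one CPU.

## Known limitations

- The surface random-walk jitter has a slightly different displacement
  distribution than the volumetric rounded-Gaussian jitter; both are
  controlled by the same `jitter_sd` but are not numerically comparable
  across modes.
- `run_pipeline` simulates volumetric cohorts only; surface cohorts are
  built through the synthetic module directly.
- The MPM cleanup's reassignment rule can, in rare configurations, leave a
  reassigned element violating the connectivity rule again; the iterated
  snapshot scan resolves this, but a pathological chain may end with
  elements dropped to background rather than reassigned.
- No plotting: analyses return tidy DataFrames intended for downstream
  visualization.
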