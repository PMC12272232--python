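# Methods

## The analysis model

The pipeline estimates the topographic organization of functional
connectivity between a subcortical seed nucleus (the pulvinar) and the
ipsilateral cortex. Its object of inference is, per cortical voxel, the
*position along an anatomical axis* of the nucleus sector the voxel is most
strongly correlated with at rest, and, per sulcus, the linear gradient of
that position along the sulcus.

Assumptions, stage by stage:

- **Grid contract.** All volumes live on one voxel grid; geometry checks
  compare dims exactly and affines to 1e-4 mm per element. Voxel indices
  are 0-based; all anatomical-axis logic uses world-mm RAS+ coordinates
  through the affine, never array indices, because the axes of interest are
  anatomical, not array-aligned.
- **Slabs.** `slice_mask` bins voxel centers into half-open intervals
  [c_min + k·t, c_min + (k+1)·t) along the axis coordinate, anchored at the
  mask's own minimum (mask-relative, since nucleus masks are adjusted per
  subject in practice). LM is hemisphere-aware (lateral → medial in both
  hemispheres: +x for left, −x for right masks), so mirrored masks receive
  identical labels. Empty bins — possible for masks that are not connected
  along the axis — are compacted so labels are contiguous. An extent
  smaller than one thickness yields a single slab.
- **Nuisance model.** Each voxel's time series is residualized by OLS on
  [intercept, linear trend, six motion regressors]; seed series are taken
  from the cleaned data, so seed–voxel correlations are partial
  correlations given the design. Near-constant motion columns are dropped
  with a warning rather than inverting a rank-deficient design. Smoothing
  (separable Gaussian, sd = FWHM/2√(2 ln 2), `nearest` boundary so constant
  images are fixed points) and the nuisance projection commute exactly —
  one is linear in space, the other in time — so their order is a
  convention, not a modeling choice.
- **Across-run inference.** Per-run Fisher z maps are combined with a
  voxelwise one-sample t-test, df = n_runs − 1, two-sided by default (a
  one-sided option exists). No multiple-comparison correction is applied;
  the gate is deliberately an uncorrected per-voxel α. Voxels with zero
  variance across runs but nonzero mean are declared significant (p
  recorded as 0): that configuration is the noiseless limit, not evidence
  of absence. Voxels with missing correlations (zero-variance series) in
  any run stay missing throughout.
- **Winner-take-all.** Among slabs passing the gate, the winner is the slab
  with the largest across-run **mean Fisher z** — the correlation strength
  itself, matching the definition "the sector the voxel is maximally
  correlated with". Ranking by the t statistic instead (available as
  `winner_take_all(stat="t")`) is unstable at small run counts: with
  df = 1, t = 2·z̄/|z₁−z₂|, and the ordering of two genuinely correlated
  slabs is dominated by the heavy-tailed 1/|z₁−z₂| factor rather than by
  effect size. Exact ties go to the smaller label (deterministic; ties have
  measure zero on real data but occur in tests).
- **Consensus.** Subjects are averaged on *normalized slab positions*
  (k-th slab center mapped to [0,1]), not raw labels, so subjects whose
  masks yield different slab counts are commensurable. The support rule
  keeps voxels with assignments from at least ⌈n/2⌉ subjects.
- **Consistency.** Pairwise Spearman ρ is computed over the intersection of
  assigned voxels (at least 10; pairs below that are recorded as missing).
  The Friedman statistic is the classic 12/(nk(k+1))·ΣR² − 3n(k+1) on
  tie-averaged ranks with df = k − 1 = 2 for three axes, without tie
  correction, so fully tied data give χ² = 0, p = 1 instead of an
  indeterminate ratio; post-hoc comparisons are two-sided Wilcoxon
  signed-rank tests, Bonferroni-adjusted over the three axis pairs.
- **Gradients.** Points are pooled voxels across subjects (x = normalized
  sulcus position, y = normalized winning-slab position); the fit is OLS
  with the two-sided slope p from t(n−2). Polarity requires p < 0.05.
  Axis selection requires significance in both hemispheres with agreeing
  slope signs and picks the largest min(|r_L|, |r_R|). A two-segment
  broken-line fit that beats the single line by BIC flags the fit as
  non-monotone (detection only — no segment inference), for sulci with
  dual gradients.

## Significance gate and run count: a power analysis

The pipeline default is α = 0.001, the regime appropriate for cohorts with
many runs (8–61 per subject). The desk-scale validation cohorts use 2 runs
per subject, hence df = 1, where the two-sided critical value at α = 0.001
is t ≈ 636.6: the gate passes essentially no voxel regardless of effect
size, and the few that pass are 1/sd flukes. The validation harnesses
(tests and `scripts/acceptance.py`) therefore gate desk-scale cohorts at
α = 0.05 (critical t ≈ 12.7 at df = 1, which a true shared latent reaches
with high probability at T = 200 volumes). This is a property of the df,
established from the t quantiles, not a tuning knob; the t-test's
calibration at α = 0.001 is verified separately on a million null voxels
with 6 runs.

## The synthetic cohort

What it emulates: multi-run resting-state series (TR 2 s, ~1-mm voxels,
hundreds of volumes per run) in which each 2-mm nucleus slab shares a
unit-variance AR(1) latent with one cortical band of each planted sulcus;
independent AR(1) voxel noise; a motion-correlated global nuisance
(standardized first motion regressor times `motion_leak`); per-subject
Gaussian jitter of band boundaries in mm along the sulcus axis
(inter-individual variability); and two planted sulci per hemisphere — an
IPS-like *direct* antero-posterior band and an ACC-like *reversed* one —
plus a dorsal strip of pure-noise cortex for calibration.

Key parameters (defaults = the standard study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_subjects` / `runs_per_subject` / `volumes_per_run` | 4 / 2 / 200 | cohort size |
| `tr_s` | 2.0 s | repetition time |
| `grid_dims`, `voxel_size_mm` | 24³, 1 mm | desk-scale grid, midline at x = 0 |
| `nucleus_center_mm`, `nucleus_radii_mm` | (±5.5, −3.5, 0.5), (2.5, 4.5, 3.5) | per-hemisphere ellipsoid; AP extent 9 mm → five 2-mm slabs |
| `slab_axis`, `slab_thickness_mm` | AP, 2.0 | planted gradient axis |
| `signal_sd`, `noise_sd` | 1.0, 1.0 | latent and noise scale (SNR 1) |
| `ar1_phi` | 0.4 | lag-1 autocorrelation of latents and noise |
| `motion_leak` | 0.5 | global motion-coupled nuisance amplitude |
| `subject_jitter_sd` | 0.5 mm | band-boundary jitter per subject |
| `shared_topography` | True | False scrambles the band→slab map per subject |

Everything is deterministic given `(rng_seed, subject_index)`; AR(1) series
use a 64-sample burn-in of the stationary recursion.

What it does **not** emulate — and what passing tests therefore do not
show about real data: no hemodynamic response or contrast-agent (MION)
polarity (sign conventions cancel in correlation topology), no
cardiac/respiratory physiology, no cortical folding or geodesic sulcus
geometry (sulci are boxes, positions are linear in world mm), no
registration error, and cortical bands map to exactly one slab each,
whereas real projection fields overlap. Band widths (~1.8 mm for five
bands over a 9.2-mm box) are deliberately comparable to the 2-mm smoothing
kernel, so adjacent-band mixing at boundaries is the dominant residual
error, as in the real acquisition regime.

## Numerical choices

- Boundary voxels between slabs are decided by the half-open bin of their
  center coordinate — deterministic and partition-preserving; how the
  original analyses assigned them is unknown, so this is flagged for
  sensitivity analysis.
- Near-noiseless data can round |r| to exactly 1; the connectivity stack
  clips r to 1 − 1e-12 before the Fisher transform (z ≈ 14.2). The
  `fisher_z` primitive itself rejects |r| ≥ 1.
- `seed_resolution="voxel"` reproduces the literal per-voxel-seed procedure
  and keeps, per slab and cortical voxel, the best seed voxel by across-run
  t; the slab-resolution default computes one seed per slab directly and
  coincides with it in the noiseless limit at a fraction of the cost.
- Consensus means are computed only over assigned subjects; support below
  ⌈n/2⌉ yields NaN (serialized as −1 in NIfTI outputs).

## Problem sizes

The test suite and the acceptance script run: one fixed-seed 4-subject
cohort (2 runs × 200 volumes, 24³ grid) for slab recovery and scale
equivariance; 50 replicate cohorts for axis/polarity recovery; 1000
20-block null replicates for Friedman calibration; 10⁶ null voxels
(6 runs × 60 volumes) for the t-test false-positive rate; and three
fixed-seed cohorts at SNR 0.25/1/4 for the consistency ordering. These
sizes make the full validation run in minutes on one CPU while keeping
binomial uncertainty well inside the asserted bounds.

## Known limitations

- The Friedman blocks (subject pairs × hemispheres) are not independent —
  pairs share subjects — so the axis-comparison p-value is optimistic; the
  block count is surfaced in the report for that reason.
- Gradient fits pool voxels across subjects, so subjects with more assigned
  voxels weigh more; a per-subject aggregation mode would trade that bias
  for variance and is a natural extension.
- Spatial autocorrelation inflates the nominal significance of map-level
  Spearman correlations; no spin-test or variogram correction is applied.
- Head-motion correction, slice timing, template registration and atlas
  adjustment are upstream of this package: inputs are assumed coregistered
  on one grid.
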