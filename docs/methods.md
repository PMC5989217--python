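# Methods

`memrsa` implements an item-centric analysis of recognition memory: it asks
where in the brain multivoxel BOLD pattern similarity tracks the intrinsic
*memorability* of a stimulus, as opposed to the observer's own memory
outcome, and whether memorability is represented as a continuous quantity.
Because the pipeline is meant to be exercised without any external dataset,
it ships a first-class synthetic-data generator whose planted structure the
analysis stages must recover.

## Memorability scoring

Workers in a continuous-recognition stream press a key whenever they think
an image repeated.  Per image i,

- `HR_i` — fraction of workers pressing on the image's long-lag *target*
  repeat,
- `FA_i` — fraction pressing on its first presentation,
- `Pr_i = HR_i − FA_i` — corrected recognition, the memorability score,
- `d'_i = z(HR_i) − z(FA_i)` with extreme rates clamped to `1/(2n)` and
  `1 − 1/(2n)` (n = contributing workers; the clamping rule is a package
  choice, the standard correction for empirical rates of 0 or 1).

HR and FA for one image may come from different worker subsets, so the
table stores `n_hr` and `n_fa` separately.  Workers are excluded before
scoring when their *filler* (short-lag) false-alarm rate or miss rate
exceeds 50% — strict inequalities, so exactly 50% is retained.

### Split-half consistency

Consistency of the per-image ranking across observers is the mean Spearman
rho between image scores computed from two random halves of the workers
(10,000 split iterations by default; an odd worker joins half 1; ties get
average ranks).  Chance is the same quantity with the second half's image
assignment shuffled.  A calibration subtlety: the observed statistic is an
*average over splits*, so a valid permutation test must compare it against
averages, not single draws.  Each of the `n_null` (default 200) chance
values therefore fixes one image permutation, applies it across all split
iterations, and averages; under the no-consistency null the true labeling
and any fixed permutation are exchangeable, which makes the one-sided
add-one p-value `(1 + #{chance ≥ observed}) / (1 + n_null)` essentially
exact.  Comparing the mean against single-split chance draws instead is
severely conservative (the package deliberately does not do this).
Images that cannot be scored in both halves (fewer than two contributing
workers for a needed rate) are dropped up front.

## Behavioral statistics

Each scanner trial's image carries a crowd-sourced Pr; trials are grouped
by the subject's 5-level response (recollected / high-confidence old /
low-confidence old / low-confidence new / high-confidence new).  A response
category enters the group analysis only when at least 5 subjects have at
least 5 trials of it (both thresholds configurable); this data-driven rule,
not response correctness, decides inclusion.  The per-subject category
means go into a one-way repeated-measures ANOVA (delegated to `pingouin`):

- Mauchly's W on `k(k−1)/2 − 1` df tests sphericity;
- when Mauchly rejects at 0.05, Greenhouse–Geisser ε multiplies both df and
  the corrected p is reported, with uncorrected values kept alongside;
- effect size is partial η² = `df1·F / (df1·F + df2)`, and is labeled as
  partial;
- post-hoc paired t-tests over all category pairs are Bonferroni corrected
  (`p_corr = min(1, p_raw · n_pairs)`).

Degrees of freedom always reflect the subjects actually analyzed
(complete-case over included categories).

## Pattern preparation

Voxel time courses are, in order: high-pass filtered, linearly detrended,
and z-scored over time.  The high-pass is a regression against a drift set
of unit-norm discrete-cosine regressors with period above the cutoff
(default 128 s; `K = floor(2·N·TR / cutoff)` components) plus a linear
ramp, orthonormalized — the ramp is included because a DCT-only set leaves
projection ripple on polynomial drifts, which the later z-score would
otherwise amplify into spurious structure.  Voxels constant after filtering
(relative tolerance `1e-8` of the raw time-course SD) are zeroed and
flagged rather than producing NaNs.

A trial's pattern is the average of the 3rd and 4th volumes after stimulus
onset (offsets +2 and +3 with the onset volume counted first): at TR = 2 s
this spans 4–8 s post-stimulus, the hemodynamic peak.  Onsets are assumed
locked to volume boundaries.  No spatial smoothing exists anywhere in the
package.

## Representational similarity analysis

Model RSMs:

- **memorability model** — entry (i, j) = `(Pr_i + Pr_j)/2` over *all*
  trials regardless of history or response; identical across subjects.
  Under this model the most memorable images are predicted to share the
  most similar neural patterns, and forgettable images are more similar to
  memorable ones than to each other (a memorability-centric geometry).
- **memory model** — for previously studied (old) trials only, entry
  (i, j) = mean of the two binary remembered flags: 1 / 0.5 / 0 for
  both / one / neither remembered.  One matrix per subject.  "Remembered"
  is any correct old response (recollection or high/low-confidence old);
  the boundary is configurable.

Data RSMs are Pearson correlations between trial voxel vectors.  Model and
data are compared with Spearman's rho over the lower off-diagonal triangle
only (the diagonal never enters; using the full symmetric matrix would
double-count pairs), then Fisher z-transformed.  |r| = 1 is clipped at
`1 − 1e−12` before `atanh` so group statistics stay finite.

The searchlight moves a sphere of 7-voxel diameter (radius 3, 123 lattice
voxels when fully interior; membership is squared Euclidean distance
≤ radius² in voxel units) over every in-mask voxel; spheres with fewer
than 10 in-mask voxels are undefined.  For efficiency, one pass computes
the sphere's full trial-correlation matrix once and evaluates all
requested models (memorability, memory, balanced hits, balanced correct
rejections) on their own trial subsets.  Data-RSM triangles are ranked
ordinally (no tie averaging): ties in continuous correlations occur with
probability zero and ordinal ranking is several times faster; model
triangles, which are heavily tied, use average ranks.

Group maps are per-voxel one-sample t statistics of the subject Fisher-z
maps against zero, pairwise-complete over subjects; voxels defined in
fewer than two subjects or with zero variance are undefined rather than
infinite.  Map pairs are characterized by the overlap of their top-N
voxels by t (ties at the cutoff broken by voxel index, deterministic),
with an overlap-vs-N sweep written alongside.

Condition-specific RSAs balance trial counts: hits are old trials with any
correct old response, correct rejections new trials with a correct new
response; the larger set is subsampled without replacement to the smaller
set's size m (seeded), and the analysis refuses to run when m < 10.

ROI analyses replace the sphere with the voxels of a probabilistic ROI
thresholded at ≥ 25% cohort share; per-ROI group p-values are
Benjamini–Hochberg corrected across the ROI family at q = 0.05.

## SVR decoding

Memorability scores are logit-transformed to support linear statistics;
because observed Pr can be ≤ 0 (FA above HR), rates are clamped to
`[1e−3, 1 − 1e−3]` first.  Decoding runs 100 iterations of a fresh random
80/20 train/test partition (without replacement, every trial on exactly one
side — independent draws, not a fold rotation), standardizes features with
training-set statistics only, fits a linear ε-insensitive support vector
regression (C = 1.0, ε = 0.1; no hyperparameter search), and scores the
mean Pearson correlation between predicted and actual values on the test
set.  The solver is liblinear's linear SVR capped at 200 iterations:
signal-bearing fits converge well below the cap, while pure-noise fits
have no stable optimum and only waste time past it.  Iterations with a
constant test-score vector are undefined and excluded from the mean.

## Synthetic-data generator

The generator defines the study conditions; its defaults emulate the
design the pipeline targets and are not tuned per analysis.

**Online study.** 400 images, 200 workers.  Per worker, 20% of images are
targets repeating 91–109 images after first presentation; the rest are
fillers, a quarter of which repeat at lag 1–7 as vigilance probes.  Target
assignment rotates across workers so every image is a target for roughly
`n_workers × target_frac` of them (~40 at defaults; workers-per-image is
its own knob rather than being derived from a counterbalancing scheme).
Press probabilities are `sigmoid(theta_i + skill_w)` on target repeats and
`sigmoid(phi_i + skill_w − criterion)` on target firsts, with latent
memorability `theta ~ N(−0.05, 0.35²)` and false-recognition propensity
`phi ~ N(−1.95, 0.62²)` correlated at ρ = 0.3 (the correlation strength is
a free parameter; both rates are known to vary across images but their
coupling is not pinned down).  These values were calibrated once so the
*scored* distributions land at Pr ≈ 0.35 ± 0.13, HR ≈ 0.48 ± 0.11,
FA ≈ 0.14 ± 0.09 at defaults — the scored SDs include binomial measurement
noise from ~40 workers per image on top of the latent spread.  Streams are
built by scattering target first-presentations over the early stream and
drawing each repeat lag uniformly from the window (falling back to any
free slot in the window; the whole worker is retried on infeasibility).

**Scanner study.** 16 subjects rate 200 old + 200 new items on the 5-level
scale by thresholding `theta + noise` (old) or `phi + noise` (new) against
fixed cutpoints shifted by a per-subject criterion (noise SD 0.8, criterion
SD 0.25).  The cutpoints were calibrated once against the target marginal
rates (hit rate ≈ 0.67, correct-rejection rate ≈ 0.69, rare extreme-wrong
responses), which also reproduces per-subject hit counts in roughly the
93–168 range.  Confidence is monotone in the latent by construction, so
mean Pr ordered by response category is a planted, recoverable effect.

**BOLD patterns.** On a 24³ grid with a centered ellipsoidal brain mask
(semi-axes 9 voxels, ~3,100 in-mask voxels), two disjoint 200-voxel
spherical regions are planted.  In region A the pattern of trial t is
`a_t·u + sqrt(1 − a_t²)·ε_t` with a per-subject unit-variance template u,
iid noise ε, and `a_t = sqrt(g·m_t)` where `m_t` is the trial's theta
min-max scaled to [0, 1] and g = 0.5 is the signal gain; the expected
pairwise pattern correlation is then `g·sqrt(m_i·m_j)`, increasing in both
items' memorability.  Region B uses the subject's remembered indicator as
`m_t` (new trials carry m = 0).  All other in-mask voxels are independent
noise.  Note the planted coupling uses a geometric mean while the analysis
model uses the arithmetic mean of Pr — deliberate: the Spearman comparison
must be robust to monotone model misspecification, and this gap exercises
that.

For recovery checks, planted regions are evaluated at top-N = region size
(200) rather than the 1000-voxel default used for real-scale maps: with a
~3,100-voxel mask and 200-voxel regions, a top-1000 map cannot exceed
3.1× enrichment by arithmetic, so N is matched to the planted scale.
`n_top_voxels = 1000` remains the analysis default.

What the generator does *not* emulate: hemodynamic convolution and
autocorrelated noise, physiological artifacts, subject motion, spatial
smoothness of real BOLD fields, serial-position or lag effects in the
online stream, and worker demographics.  Passing recovery tests therefore
demonstrates the correctness of the estimators on data satisfying their
assumptions, not robustness to fMRI noise structure.

## Reproducibility and problem sizes

All randomness flows from one root seed; each pipeline stage derives a
child seed from a CRC of the root and the stage name (logged, < 2³¹).
Rerunning with the same configuration reproduces every table bitwise and
every map to floating tolerance.

The shipped validation exercises the pipeline at the full planted-study
scale (16 subjects, 24³ grid, 400 trials, four searchlight maps per
subject) and uses scaled-down instances (smaller grids, shorter lag
windows, fewer workers) for unit-level properties; null calibrations use
200 replicate simulations.  The problem sizes are stated in the test
suite and acceptance script and were chosen as the package's own
validation budget.

## Known limitations

- The searchlight correlates RSMs over all trials jointly; per-run
  blocking is not implemented (run structure is not modeled at all).
- Undefined searchlight centers (mask edges) are dropped, not padded.
- Group analysis assumes subject maps are already on a common grid; no
  spatial normalization is provided.
- Only Spearman model-data comparison and Pearson data RSMs are offered;
  alternative distance metrics are out of scope.
- The ANOVA module implements Greenhouse–Geisser only (no Huynh–Feldt).
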