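# Methods

## The estimator

SampEn(m, r, N) is computed exactly as integer template-pair counts
followed by a single logarithm. Conventions:

- **Template index range.** Both the length-m and length-(m+1) counts run
  over start indices 1 … N − mτ (Richman–Moorman convention). Every
  counted m-template therefore has an (m+1)-point extension, the two
  printed normalizers are identical and cancel in the ratio, and the
  statistic reduces to −ln(B/A) on raw ordered-pair counts.
- **Matching** is Chebyshev (max over components) and inclusive (≤ r).
  Self-pairs (j = i) are excluded — the defining difference from
  approximate entropy, whose self-matches bias it low on short records.
- **Tolerance.** r is multiplied by the series' sample SD (ddof = 1) in
  the default `sd_scaled` mode, making SampEn exactly invariant under
  affine rescaling of the signal; an `absolute` mode exists for testing.
  A zero-variance series has no sd-scaled tolerance and is reported as
  undefined (`zero_variance`).
- **Undefined results.** A = 0 (`no_m_matches`) or B = 0
  (`no_m1_matches`) yields an undefined value with an explicit reason,
  never ±inf or NaN arithmetic. This is the expected failure mode of very
  short records and propagates through maps and subject summaries as a
  policy decision rather than silently.
- τ defaults to 1; m ≥ 1 and τ ≥ 1 are supported generally.

Counting is vectorized: distance profiles D_m and D_{m+1} are built once
per chunk of series/voxels and compared against any number of tolerances.
Because truncation keeps the *head* of a series, the profiles at the
longest data length contain every shorter length as a leading sub-block,
so per-subject means at all seven data lengths (and across a whole
r-grid) cost barely more than one pass. The fast paths are tested for
exact (1e−12) agreement with the one-voxel-at-a-time route, and the
counts for exact agreement with a brute-force O(N²·m) pair enumeration
written independently in the test suite.

## Analytic oracle

For i.i.d. data the conditional probability that a matching template
still matches one point later is P(|X − Y| ≤ rσ) for fresh draws X, Y;
for unit-variance Gaussians this is 2Φ(r/√2) − 1, independent of m, so

    SampEn_iid(r) = −ln(2Φ(r/√2) − 1)

(≈ 2.1851 at r = 0.2, ≈ 1.7838 at r = 0.3). This closed form anchors the
convergence tests, the bias experiment, and the i.i.d. limit of
voxel-wise maps.

## The short-record bias experiment

`bias_curve` draws n_reps i.i.d. standard-Gaussian series per data length
(replicate k from seed + k) and estimates SampEn(2, 0.2, N). Because
SampEn is −ln of a conditional probability, the ensemble estimate
averages the per-realization probability estimates B/A — a realization
with m-matches but no extended match contributes probability zero; only
A = 0 leaves it undefined — and then takes −ln. At 10,000 replicates this
deviates from the analytic limit by ≈ 1.3% at N = 102 and ≈ 24% at
N = 15, where 44% of realizations are undefined outright.

The alternative of averaging per-realization −ln(B/A) over the defined
replicates is reported alongside (`mean_sampen_per_series`). It is much
more biased at small N — Jensen's inequality pushes E[−ln(B/A)] above
−ln E[B/A], and conditioning on B > 0 truncates the high-entropy tail —
reaching ≈ 62% deviation at N = 15. We treat the ensemble
probability-average as the headline statistic because it estimates the
quantity SampEn is defined on; the per-series column documents how much
the averaging convention matters for short records.

The √N "averaging effect" noise-reduction factor (9.22 at N = 85, 11.31
at N = 128) is provided as `noise_reduction_factor`.

## Preprocessing

Order: discard initial volumes → temporal high-pass → spatial smoothing →
mask → per-voxel standardization. Motion correction is deliberately
absent (synthetic data has no motion; the stage order records its slot).

- **High-pass** regresses out an orthonormal DCT basis, components
  k = 1 … K with K = floor(2·T·TR/cutoff) (SPM-style; K = 4 at T = 128,
  TR = 2 s, cutoff 128 s). The basis is orthogonal to the constant, so
  voxel means are preserved. Only drift exactly on a basis frequency is
  removed completely: a 512 s period vanishes, while an off-basis 300 s
  sinusoid retains ≈ 9% of its SD. White noise loses only the K/T
  variance fraction of the projection.
- **Smoothing** is separable Gaussian per time point,
  σ_axis = FWHM_axis / (2√(2 ln 2)) / voxelsize_axis, truncated at 4σ,
  zero-padded edges. No mask-aware renormalization is attempted; edge
  voxels attenuate.
- **Mask**: temporal-mean intensity ≥ fraction × its global maximum
  (default 0.1), minus zero-variance voxels. Smoothing precedes masking.
- **Standardization** to mean 0, SD 1 (ddof = 1) per in-mask voxel makes
  the sd-scaled and absolute tolerance modes coincide, so one r value
  serves all voxels regardless of amplitude.

## Whole-brain summaries and exclusion policy

A subject's mean whole-brain SampEn at data length N averages the
defined in-mask voxel values. Under the default `propagate` policy the
mean is undefined as soon as any in-mask voxel is undefined — the
behaviour of subjects that "return no value" at short lengths — and a
data length enters the report tables only when *every* subject returns a
value (roster-level rule). `ignore_undefined` instead averages defined
voxels and reports the undefined fraction. Truncation to N keeps the
first N post-preprocessing volumes (the steady-state head of the scan).

## Group statistics

- **Orientation** is fixed: higher SampEn ⇒ younger.
- **ROC area** is the Mann–Whitney probability (ties half-weighted),
  computed via `sklearn.metrics.roc_auc_score` and cross-checked against
  pair enumeration. Bands: ≥ 0.90 excellent, 0.80–0.89 good, 0.70–0.79
  fair, 0.60–0.69 poor, 0.50–0.59 bad, < 0.50 below chance.
- **Operating point** (no convention prescribes one): candidate
  thresholds are midpoints between consecutive distinct pooled scores;
  classify score ≥ threshold as younger; maximize accuracy, tie-break by
  maximal Youden index, then by the lowest threshold.
- **t-tests** default to the pooled-variance Student form
  (df = n₁ + n₂ − 2), with a Welch option.
- **Age correlation**: Pearson r with the two-tailed t-transform p;
  interpretive category per the Dancey–Reidy bands on |r| rounded to one
  decimal (0 zero, 0.1–0.3 weak, 0.4–0.6 moderate, 0.7–0.9 strong,
  1 perfect).
- **FDR**: Benjamini–Hochberg step-up q-values (statsmodels), applied
  across data lengths in the report tables and across voxels in the group
  maps; significance at q < 0.05.
- **Voxel-wise group map**: a pooled two-sample t per voxel where all
  subjects are defined, BH-FDR across tested voxels. This deliberately
  replaces cluster-level family-wise inference — no spatial model is
  fitted, so regional claims are voxel-wise only.
- **Tolerance sweep**: mean whole-brain SampEn per subject is recomputed
  at each r in 0.05 … 0.50 (step 0.05) and the group ROC area tabulated;
  an r at which any subject is undefined is flagged and excluded from the
  optimum; the optimum maximizes area with ties broken toward the
  *larger* r (larger tolerances are more robust to noise).

## Synthetic cohort: what it emulates, and what not

Each in-brain voxel carries
`baseline + amplitude · AR(1)(φ) + drift · sin(2πt·TR/period + phase)`
on an ellipsoidal brain over a dark background. AR(1) was chosen as the
minimal process whose regularity is tunable by one parameter: SampEn
falls monotonically as φ rises (verified by simulation), and φ = 0
reduces to i.i.d. Gaussian noise with the closed-form check above, which
the full pipeline reproduces to within ~1%.

Defaults state the emulated world: 133 volumes at TR = 2 s; grid
32×32×12 (a reducible stand-in for 64×64×23), 4 mm voxels;
φ_young = 0.30 vs φ_old = 0.55 with subject jitter SD 0.05 (clipped to
[0, 0.95)); an elderly-only effect region of +0.15 φ for the group-map
tests; baseline 1000 in-brain vs 10 outside; fluctuation amplitude 20
(≈ 2% of baseline, BOLD-like); 300 s drift of amplitude 10, removed by
the 128 s high-pass; ages uniform on 20–30 vs 60–80 years. Ages are
metadata only — the entropy–age correlation arises through group
membership, mirroring a two-group design.

With these defaults the 10 vs 10 cohort separates *perfectly*
(ROC area 1.0): averaging ~3800 voxels makes subject means nearly
noiseless, so the 5σ φ-gap is never misordered. A green recovery test
therefore establishes the pipeline's direction and consistency, not a
realistic effect size. Also absent by design: hemodynamic response
shape, motion, physiological (cardiac/respiratory) noise, 1/f spectra,
and spatial heterogeneity beyond the single effect region. For the same
reason the ROC-vs-r sweep has no interior optimum on synthetic cohorts —
subject ranking is essentially r-invariant because every subject's mean
is a monotone function of its φ at any tolerance — so the sweep's tests
cover its contract (flagging, argmax, tie-break), not the recovery of a
particular optimal r.

## Numerical notes

- Counts are exact integers; ties at the tolerance boundary are matches
  (inclusive ≤). The logarithm is the only floating-point step of the
  estimator.
- Monotonicity of SampEn in r holds for the population quantity and for
  ensemble means, but **not** strictly per realization: where B is small
  the estimate's noise (∼ 1/√B) produces occasional inversions. Tests
  assert monotonicity at the three levels where it holds (analytic curve;
  ensemble mean; per-series with B ≥ 100).
- Dancey–Reidy and ROC band edges use round-half-even floating-point
  rounding of Python's `round`; tests avoid exact .x5 boundaries.
- All randomness flows from explicit seeds: cohort subject k uses
  master_seed + k, i.i.d. replicate k uses seed + k; identical seeds give
  bit-identical volumes and reports.
- Replicate-heavy checks are scaled to a single CPU: the repeated-cohort
  consistency test uses 8 seeded 12×12×6 cohorts of 3 vs 3 subjects, and
  the bias experiment's full 10,000-replicate version runs once in the
  acceptance tests.

## Known limitations

- Realignment, slice timing, template normalization and atlas labeling
  are out of scope; maps live in subject space on synthetic grids.
- The voxel-wise group comparison controls FDR per voxel only; no
  cluster-extent or random-field inference.
- The DCT high-pass attenuates, but does not annihilate, drift at
  frequencies between basis lines (see above).
- Undefined-value handling below N ≈ 85 follows the propagate policy;
  whole data lengths drop out rather than individual subjects, which is
  conservative but faithful to the roster-level rule.
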