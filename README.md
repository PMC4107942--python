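# sampenmap

Voxel-wise **sample entropy (SampEn)** mapping for short BOLD fMRI time
series, with ROC-based tolerance selection, data-length consistency
analysis, and two-group statistics — plus a synthetic AR(1) cohort
generator so the whole pipeline is testable without any imaging data.

## Who this is for

Resting-state fMRI runs are short: after discarding dummy scans a typical
acquisition leaves on the order of 100 volumes per voxel. Entropy measures
are attractive probes of BOLD signal complexity (which declines with
ageing in fixed-point-attractor systems), but approximate entropy is badly
biased at such lengths. SampEn, which excludes self-matches, remains
usable — at the cost of an explicit failure mode (undefined estimates when
no template pairs match) and a short-record bias that this package
quantifies. `sampenmap` is for researchers who want that analysis chain as
a tested, reproducible library rather than a pile of scripts.

## The statistic

For a series \(x_1,\dots,x_N\), templates of length \(m\) with delay
\(\tau\) are \(X_i = (x_i, x_{i+\tau}, \dots, x_{i+(m-1)\tau})\),
\(i = 1 \dots N - m\tau\). Two templates match when their Chebyshev
distance is at most \(r\) (in units of the series SD). With \(A\) the
number of ordered matching pairs \((i, j)\), \(j \neq i\), at length
\(m\) and \(B\) the number still matching at length \(m+1\),

\[ \mathrm{SampEn}(m, r, N) = -\ln\frac{B}{A}. \]

Lower values mean a more regular, self-similar signal. When \(A = 0\) or
\(B = 0\) the estimate is *undefined* — reported as such, never as an
infinity. For i.i.d. Gaussian noise the large-\(N\) limit is
\(-\ln(2\Phi(r/\sqrt{2}) - 1)\), which serves as the package's analytic
oracle.

The analysis pipeline mirrors a standard protocol: discard 5 initial
volumes (133 → 128), 128 s DCT high-pass, 8 mm FWHM Gaussian smoothing,
brain mask at 0.1 × the maximum mean intensity, per-voxel standardization;
then voxel-wise SampEn maps (m = 2, r = 0.30, τ = 1) at data lengths
N ∈ {85, 90, 95, 100, 110, 120, 128}, per-subject mean whole-brain SampEn,
and group ROC / t-test / age-correlation tables with Benjamini–Hochberg
FDR across data lengths.

## Worked example

Simulate a small two-group cohort (5 younger vs 5 elderly subjects,
16×16×8 grid, 133 volumes at TR = 2 s; elderly voxels carry a larger AR(1)
coefficient, hence more regular signals) and run the full analysis:

```bash
sampenmap simulate --out cohort/ --tiny --seed 7
sampenmap analyze cohort/ --out report/ --data-lengths 85,100,128
```

`report/table_group.csv` (group means of mean whole-brain SampEn):

```
  N  younger_mean  younger_sd  elderly_mean  elderly_sd      t      p      q
 85        1.8115      0.0177        1.7065      0.0497 4.4509 0.0021 0.0034
100        1.7982      0.0153        1.6936      0.0507 4.4122 0.0022 0.0034
128        1.7825      0.0160        1.6847      0.0510 4.0955 0.0035 0.0035
```

The younger group's whole-brain entropy is higher at every data length
(the designed loss-of-entropy-with-age direction), the difference is
significant after FDR (q < 0.05), and both groups' values fall as N grows
from 85 to 128 — the short-record noise/bias effect. `table_roc.csv`
reports the operating point (here the groups separate perfectly, area
1.0), and `table_correlation.csv` the SampEn–age Pearson correlation
(negative at every N; r ≈ −0.77, "strong" on the Dancey–Reidy scale).

The short-data-length bias experiment (10,000 i.i.d. Gaussian series per
length):

```bash
sampenmap bias-curve --out bias.csv --lengths 15,25,50,102 --n-reps 10000 --seed 1
```

```
  N  mean_sampen  ...  frac_undefined  rel_dev_pct
 15     2.714578  ...          0.4403    24.229476
 25     2.521854  ...          0.0545    15.409695
 50     2.279238  ...          0.0000     4.306664
102     2.212932  ...          0.0000     1.272228
```

`rel_dev_pct` is the percent deviation of the ensemble SampEn estimate
from the analytic i.i.d. limit 2.1851: about 1% at N = 102, growing
sharply as records shorten, with 44% of 15-point series returning no
estimate at all.

Library use follows scikit-learn conventions — preprocessing stages are
transformers, composable with `sklearn.pipeline.Pipeline`:

```python
from sampenmap import CohortSpec, RunConfig, analyze_cohort, simulate_cohort

subjects, roster = simulate_cohort(CohortSpec())   # 10 vs 10, 32x32x12
report = analyze_cohort(subjects, RunConfig())     # full protocol
print(report.table_group)
```

## Acceptance script

`scripts/acceptance.py` recomputes the bias-experiment deviations from
scratch — 10,000 i.i.d. standard-Gaussian series per data length
(N = 102 and N = 15), SampEn(m = 2, r = 0.2) with sd-scaled tolerance,
deviation of the ensemble estimate from the analytic limit:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It writes one JSON object with the deviation (percent) and replicate
count per quantity.

## Layout

- `sampenmap.core` — the SampEn estimator, analytic i.i.d. oracle, bias
  curve, √N noise-reduction factor
- `sampenmap.preprocessing` — discard / DCT high-pass / smooth / mask /
  standardize transformers
- `sampenmap.mapping` — voxel-wise entropy maps, whole-brain means,
  fast multi-length and multi-tolerance paths
- `sampenmap.stats` — ROC area and operating point, t-tests, Pearson with
  age, BH-FDR, voxel-wise group maps
- `sampenmap.simulate` — synthetic AR(1) cohorts and i.i.d. series
- `sampenmap.pipeline` / `sampenmap.cli` — orchestration and the
  `sampenmap` command

See `docs/methods.md` for the model, parameter choices and limitations.
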