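# transperf

Transmural myocardial-perfusion analysis for pixel-wise MBF maps:
endo/epicardial layer decomposition, AHA 16-segment parcellation, transmural
perfusion metrics, and cohort normative values.

## The problem

Quantitative perfusion CMR delivers pixel-wise maps of myocardial blood flow
(MBF, mL/min/g) at rest and under adenosine stress. Because ischaemia strikes
the subendocardium first, the clinically interesting signal is often *trans-
mural*: how flow in the inner (ENDO) half of the left-ventricular wall
compares with the outer (EPI) half. `transperf` implements the full analysis
chain from contoured short-axis MBF maps to the layer-specific normative
statistics a reading physician needs:

1. **Layer geometry** — the LV blood-pool centre is the endocardial-contour
   centroid; 360 rays at 1° increments are cast from it; the map is
   resampled to 1 mm; a midventricular line is placed equidistantly between
   the endocardial and epicardial contours on every ray; pixels inside the
   midline polygon form the ENDO layer, the rest of the myocardium the EPI
   layer.
2. **AHA parcellation** — six 60° sectors on basal and mid slices (segments
   1–6, 7–12), four 90° sectors apically (13–16), anchored at the anterior
   RV-insertion point, grouped into coronary territories
   LAD {1,2,7,8,13,14}, RCA {3,4,9,10,15}, LCX {5,6,11,12,16}.
3. **Metrics** — per layer/segment/territory/slice/global:

   | symbol | definition |
   |---|---|
   | sMBF, rMBF | mean stress / rest MBF over a region (mL/min/g) |
   | MPR, MPR_ENDO, MPR_EPI | sMBF / rMBF per wall or layer |
   | sGRAD, rGRAD | sMBF_ENDO / sMBF_EPI and rMBF_ENDO / rMBF_EPI |
   | RPP | heart rate × systolic blood pressure (bpm·mmHg) |
   | rMBF_c | rMBF / (RPP/10 000) — workload-normalised rest flow |
   | MPR_c | sMBF / rMBF_c = MPR × RPP/10 000 |

   Slice-specific gradients and reserves are unweighted means of the
   corresponding per-segment values; global and territory MBF are pooled
   pixel means.
4. **Cohort normative statistics** — a statsmodels-style model/results pair.
   `TransmuralNormals(data).fit(seed=...)` applies a Shapiro–Wilk gate
   (α = 0.05) that selects both the presentation (mean ± SD vs median ± IQR)
   and the test family (t-test/ANOVA/Pearson vs Mann–Whitney/Wilcoxon/
   Friedman/Spearman), computes 95% cohort ranges (2.5th–97.5th
   percentiles), bootstrap CIs of the median, sex comparisons, age
   correlations and Bonferroni-adjusted slice contrasts.

Because no public per-subject dataset accompanies this kind of analysis, the
package ships first-class synthetic generators: annular phantoms with
analytically known layer means, and a cohort simulator reproducing the
structure reported for healthy adults (female > male absolute MBF, stress-
only age decline, rGRAD > 1 ≳ sGRAD, mid-slice reserves lowest).

## Worked example

```python
import transperf as tp

records = tp.make_cohort(tp.CohortSpec(n_subjects=40, seed=7))
df = tp.cohort_to_frame(records)
res = tp.TransmuralNormals(df).fit(seed=7, n_boot=500)
print(res.summary())
```

```text
Transmural perfusion normative report
=====================================================
subjects analysed: 40

metric                 value      95% cohort range
-----------------------------------------------------
rMBF             0.56 ± 0.16          [0.20, 0.86]
sMBF             2.15 ± 0.51          [1.26, 2.96]
MPR             3.77 ± 1.55*          [2.45, 7.25]
rMBF_c           0.77 ± 0.27          [0.30, 1.31]
MPR_c           2.77 ± 1.15*          [1.34, 6.80]
rMBF_ENDO        0.59 ± 0.16          [0.21, 0.84]
rMBF_EPI         0.54 ± 0.16          [0.19, 0.85]
sMBF_ENDO        2.12 ± 0.50          [1.24, 3.01]
sMBF_EPI         2.18 ± 0.53          [1.29, 3.07]
MPR_ENDO        3.40 ± 1.62*          [2.32, 7.19]
MPR_EPI         4.12 ± 1.77*          [2.37, 7.99]
sGRAD            0.98 ± 0.08          [0.84, 1.12]
rGRAD            1.10 ± 0.07          [1.00, 1.24]
-----------------------------------------------------
* median ± IQR (Shapiro–Wilk p < 0.05); MBF in mL/min/g

age correlations:
  MPR_ENDO     r = -0.64  p = 9.99e-06  (spearman)
  ...
```

Reading it: rest flow sits near 0.56 mL/min/g and rises ~4-fold under
stress; the rest gradient rGRAD > 1 (endocardium better perfused at rest)
flips to sGRAD ≈ 0.98 under stress, which is why the endocardial reserve
MPR_ENDO (3.40) trails the epicardial MPR_EPI (4.12); stress flow and the
reserves fall with age while rest flow does not. The bracketed intervals are
the 95% cohort ranges proposed as normal limits.

Per-subject analysis of measured maps goes through `subject_pipeline`
(six contoured slice maps → one `SubjectRecord` with all 170+ metrics), or
from the shell:

```bash
transperf simulate cohort --seed 7 --n 40 --out cohort.csv
transperf cohort --metrics cohort.csv --seed 7 --out report/
transperf run --seed 42 --out demo/          # end-to-end 20-subject demo
```

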