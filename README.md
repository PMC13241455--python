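# fatmap

Spatial analysis of multifidus fat infiltration from quantitative water–fat
MRI. The package converts segmented axial fat-fraction slices into radial
fat-distribution curves, tests where along the muscle's depth a clinical
covariate associates with elevated fat using one-dimensional statistical
parametric mapping (SPM) with random-field-theory (RFT) cluster inference,
and models scalar fat metrics across lumbar levels with linear mixed-effects
regression. A synthetic-cohort generator with exactly known spatial effects
makes every stage verifiable end to end.

**Who it is for.** Researchers quantifying paraspinal muscle degeneration
(myosteatosis) in chronic low back pain: given fat-fraction images with
left/right multifidus masks at L4L5 and L5S1, a per-level center of rotation
(CoR), and a covariate table (age, sex, BMI, pain NRS, chronicity, weekly
MET-minutes, Pfirrmann disc grades), it answers *where* in the muscle —
deep (near the CoR) versus superficial — fat infiltration tracks a covariate
such as symptom chronicity or physical activity.

## Method

1. **Radial fat-mapping.** Each muscle mask is partitioned into
   non-overlapping regions of interest (ROIs) radiating outward from the CoR
   at two-pixel increments. The per-ROI mean fat fraction, with depth
   normalized to 0–100 % of the radial muscle width (0 % = deepest), gives a
   fat-distribution curve on a 101-node grid; left/right muscles over two
   slices per level are averaged node-wise. Two scalars summarize each
   level: overall FI% (pixel-weighted mean over the cross-section) and
   deep15 FI% (curve mean over the deepest 15 %).

2. **1D SPM.** At every node, FI% is regressed on a covariate of interest
   adjusting for age, sex and BMI, giving the t-field SPM{t}. The critical
   threshold u* controls the familywise error over the field via the
   expected Euler characteristic of a smooth t-field:

       P(max T > u) ≈ P(T_ν > u) + R₁ · √(4 ln 2)/(2π) · (1 + u²/ν)^(−(ν−1)/2)

   with ν = n − p residual degrees of freedom and R₁ the resel excess of the
   search interval, estimated from residual smoothness (FWHM). Maximal runs
   with |t| > u* are reported as signed clusters with endpoints interpolated
   to the exact crossing and an RFT extent-based p-value.

3. **Cohort models.** OLS regressions of chronicity (on mean FI metric, mean
   disc degeneration, age, sex, BMI) and of physical activity (on
   chronicity, pain, age, sex, BMI), plus linear mixed models of per-level
   deep15/overall FI% with a subject random intercept (REML), fixed effects
   z-scored.

## Worked example

The numbered drivers under `analysis/` regenerate the full demonstration:
a 223-subject synthetic cohort with a chronicity-linked fat excess injected
in the deepest 24 % of the muscle at L4L5 (1.5 FI% per SD) and an inverse
activity-linked effect in the deepest 10 % (1.2 FI% per SD):

```sh
python analysis/01_generate_cohort.py   # render images + covariates
python analysis/02_extract_fat_maps.py  # radial curves + FI metrics
python analysis/03_spm_inference.py     # SPM{t} + RFT clusters
python analysis/04_cohort_models.py     # regressions + mixed models
```

`03_spm_inference.py` prints:

```
chronicity L4L5: t_crit=2.02 fwhm=93.2 -> [0.0%, 28.2%] sign=+1 p=0.0229
activity   L4L5: t_crit=2.03 fwhm=91.3 -> [0.0%, 10.4%] sign=-1 p=0.0244
chronicity L5S1: t_crit=1.98 fwhm=99.3 -> no clusters
activity   L5S1: t_crit=1.97 fwhm=99.9 -> no clusters
```

Both injected depth windows are recovered as supra-threshold clusters of the
right sign and location, and the level without injected effects stays null.
The mixed model of deep15 FI% agrees: the standardized chronicity
coefficient is 1.03 ± 0.20 (p < .001) while disc degeneration, pain and the
L5S1 level indicator — none of which were linked to deep fat in the
generator — stay non-significant.

The same stages are available as a CLI (`fatmap all --config demo.yaml`,
plus `generate`, `extract`, `spm`, `models` subcommands) for use on real
curve/covariate tables.

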