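# fmfct — CT fatty muscle fraction and outcome analysis

Skeletal muscle quality is a strong prognostic factor in critically ill
patients, but grip strength, electromyography and ultrasound are impractical
on venovenous ECMO. A routine CT, however, is often available around ECMO
initiation. `fmfct` implements an opportunistic muscle-quality biomarker
from a single axial CT slice — the **fatty muscle fraction (FMF)** — plus
everything needed to study its association with survival.

On the slice at the origin of the superior mesenteric artery, with the
bilateral paraspinal compartment outlined by a mask, pixels are classified
by attenuation:

- skeletal muscle: −29 ≤ HU ≤ 100
- fatty (myosteatotic) muscle: −29 ≤ HU ≤ 29
- lean muscle: 30 ≤ HU ≤ 100

and

```
FMF (%) = 100 · A_fatty / (A_fatty + A_lean)
```

where areas are pixel counts times pixel area. The cohort analysis
dichotomises subjects at the median FMF (high iff FMF > cutoff, strictly),
compares groups (χ², Fisher, pooled-variance t, Mann–Whitney U with a
Shapiro–Wilk normality gate), estimates Kaplan–Meier curves with a log-rank
test, and fits a multivariable Cox proportional-hazards model
h(t|x) = h₀(t)·exp(βᵀx) reporting adjusted hazard ratios exp(β) with Wald
95% CIs.

Because the patient data behind the original cohort are not public, the
package ships two fully tested synthetic generators:

- **phantom_generator** — axial CT phantoms whose compartments have an
  exactly known fatty/lean/bone composition, so the measurement loop can be
  verified pixel-for-pixel;
- **cohort_simulator** — subject tables with covariate distributions
  calibrated to the published cohort (n = 87, median FMF 44%, median BMI
  28.6 kg/m², 36% one-year survival) and exponential proportional-hazards
  survival with a configurable per-percent-FMF hazard ratio.

## Worked example

```sh
fmf phantom --fmf 40 --seed 7 --out-image p.nii.gz --out-mask m.nii.gz --out-truth t.json
fmf measure --image p.nii.gz --mask m.nii.gz --height-m 1.70
```

prints (the phantom's compartment holds 952 pixels at 1 mm², 381 of them
fatty: truth 40.02% by integer rounding, recovered exactly):

```json
{
  "compartment_area_cm2": 9.52,
  "muscle_area_cm2": 9.52,
  "fatty_area_cm2": 3.81,
  "lean_area_cm2": 5.71,
  "fmf_percent": 40.02100840336134,
  "mean_attenuation_hu": 29.957044469881332,
  "smi_cm2_m2": 3.294117647058824
}
```

(The SMI is tiny because a 128 mm phantom holds far less muscle than a
patient; on real slices it lands in the published ~25 cm²/m² range.)

A full synthetic cohort analysis:

```sh
fmf cohort simulate --n 500 --seed 3 --out cohort.csv
fmf cohort analyze --cohort cohort.csv --out report.json --km-plot km.png
# FMF hazard ratio per percent: 1.015 (1.010-1.020), p = 0.000
```

The report JSON contains the group-comparison table, both Kaplan–Meier
curves with one-year mortality per FMF group, the log-rank test and the
full Cox table. With 500 simulated subjects at the default generating
hazard ratio of 1.017 per percent FMF, the fitted 1.015 (1.010–1.020)
is the expected sampling wobble around the truth.

Batch measurement goes through a manifest CSV (`image,mask[,slice_index,
height_m,id]`): `fmf run --manifest subjects.csv --out measurements.csv`.
Per-row failures are logged and skipped; the exit status reports them.

## Scope notes

Masks are inputs: the thoracolumbar fascia is traced upstream (the
interactive segmentation step is out of scope), and clinical scores
(CCI, SAPS II, RESP) are taken as given covariates, never recomputed.
Slices are analysed in stored orientation; files without HU rescale or
pixel-spacing metadata are rejected rather than guessed at.
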