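# rat — real-time assessment of fetal brain and placental T2*

`rat` quantifies the effective transverse relaxation time T2* of the
fetal brain and placenta from whole-uterus multi-echo gradient-echo MRI.
T2* falls with gestation in both organs and is depressed in placental
insufficiency (fetal growth restriction, preeclampsia), which makes an
organ-mean T2* read out *during* the scan clinically actionable: a low
value can trigger an immediate repeat acquisition (e.g. after a uterine
contraction) or extra sequences before the patient leaves the scanner.
The package implements the complete quantification chain for such a
real-time workflow — fitting, organ summarization, normative centiles,
and the robustness metrics used to validate it — together with a
synthetic uterine phantom so the whole pipeline runs and is tested
without any clinical data.

## Model

Each voxel of a multi-echo acquisition (echo times TE₁ < … < TE_E)
follows a monoexponential decay

```
S(TE) = S0 · exp(−TE / T2*)
```

fitted per voxel by unweighted least squares, either in closed form on
log-signal (`loglinear`) or by bound-constrained nonlinear least squares
on the untransformed signal (`nlls`, the default, initialized from the
log-linear solution). Organ means are taken over mask voxels with valid
fits and T2* at or below an organ threshold (500 ms placenta, 900 ms
fetal brain) that screens out fluid-dominated partial-volume voxels;
organ volume is mask voxel count × voxel volume.

Normative curves over gestational age (GA) are fitted to a control
cohort: ordinary least squares for the mean trend (linear in GA, except
quadratic for fetal-brain mean T2*) and quantile regression (pinball
loss) for the 5th/95th centile curves. A new exam is classified *low /
normal / high* against the centiles at its GA. Robustness is assessed
with Bland–Altman agreement (mean difference ± 1.96 SD limits), Dice
overlap of segmentations, and repeat-acquisition consistency (all
pairwise mean-T2* differences plus per-repeat centile bands).

## Worked example

```python
import numpy as np
from rat import (FitOptions, fit_volume, generate_phantom, generate_control_cohort,
                 build_normative_models, classify, summarize_exam)
from rat.phantom import PhantomSpec, spec_with_snr

# a 64x64x48 synthetic uterus at 38 weeks, first-echo SNR 20
spec = spec_with_snr(PhantomSpec(ga_weeks=38.0, seed=1), 20.0)
volume, masks, truth = generate_phantom(spec)

t2map = fit_volume(volume, FitOptions(method="nlls"))
for s in summarize_exam(t2map, masks, volume.voxel_dims, ga_weeks=38.0):
    print(s.organ, round(s.mean_t2star, 1), "ms,", round(s.volume_mm3), "mm3")

models = build_normative_models(generate_control_cohort(n=88, seed=7))
band = classify(models[("placenta", "mean_t2star")], 38.0, 185.0).band
print("placenta band:", band)
```

prints

```
placenta 186.1 ms, 143291 mm3
fetal_brain 253.9 ms, 40049 mm3
placenta band: normal
```

i.e. at SNR 20 the fitted organ means recover the phantom's generating
T2* values (185.0 / 252.6 ms at 38 weeks) to within ~1 ms, the volumes
are pure mask geometry, and a placental mean of 185 ms sits inside the
5th–95th centile band of the 88-case synthetic control cohort.

The same flow is available from the shell:

```bash
rat phantom --seed 1 --out exam/            # synthetic acquisition
rat cohort --n 88 --seed 7 --out cohort.csv # synthetic control table
rat normative --table cohort.csv --out models.json
rat exam --input exam/phantom.nii.gz \
         --mask placenta=exam/mask_placenta.nii.gz \
         --mask fetal_brain=exam/mask_fetal_brain.nii.gz \
         --ga 38 --models models.json --out summary.csv
```

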