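# washmap

Dual-timepoint contrast **wash-out mapping** for brain-tumor MRI, with the
full statistical evaluation used to separate glioblastoma from brain
metastases, and a synthetic contrast-kinetics phantom generator with voxel
ground truth.

Glioblastoma tissue reaches peak contrast enhancement early (~3–8 min after
injection) and then clears the agent quickly; metastases accumulate contrast
slowly and peak late (~15 min). Acquiring two post-contrast 3-D T1-weighted
volumes — at about 5 and 25 min — makes this kinetic difference measurable:
after rigid co-registration and intensity normalization, the signed
percentage map

```
percent(v) = 100 · (S_early(v) − S_late(v)) / S_early(v)
```

is positive where signal *dropped* between the acquisitions (rapid wash-out,
red in overlays) and negative where it *rose* (late enhancement, green). A
dead-band ε (default 5%) absorbs residual noise; everything inside it is
neutral. Per lesion, the package measures compartment volumes and the

```
wash-out ratio = V(wash-out) / (V(wash-out) + V(late enhancement))
```

together with the rCBV ratio (mean of three single-slice tumor ROI means
over a contralateral ROI, from a DSC perfusion map) and the ADC ratio
(tumor over contralateral mean diffusivity). The statistics layer provides
Welch's unequal-variance t-test, tie-aware empirical ROC analysis with
Youden's J operating point and DeLong (or seeded bootstrap) confidence
intervals, ICC(2,k) inter-rater reliability with Koo–Li interpretation
bands, and the 0/1-coded linear (probability) model
`tumor-type ~ wash-out-ratio + rCBV-ratio + ADC-ratio + tumor-volume`.

Because clinical scans cannot ship with a package, the `phantom` module
generates fully synthetic test beds: an ellipsoidal, left–right symmetric
brain with tissue-like texture, ventricle- and falx-like structures,
spherical lesion compartments following gamma-variate enhancement curves
`E(t) = A · (t/t_p)^a · exp(a(1 − t/t_p))`, rigid inter-scan motion, smooth
multiplicative bias fields, and seeded noise — plus the exact ground-truth
masks, volumes, and transform. Cohort-level tables are simulated from
truncated-normal group distributions.

## Worked example

Render a phantom with a two-compartment lesion (one early-peaking, one
late-peaking sphere), 4/−3/2 mm translation plus 3/−2/4° rotation between
the scans, 2% noise and a ±10% bias field, then run the full pipeline:

```python
import numpy as np
from washmap import (PhantomSpec, RigidTransform, two_compartment_lesion,
                     measure_phantom_subject)

lesion = two_compartment_lesion("L0", (18.0, 12.0, 8.0), 16.0, 15.0,
                                separation_mm=36.0)
spec = PhantomSpec(
    lesions=(lesion,),
    motion=RigidTransform(rotation_deg=(3.0, -2.0, 4.0),
                          translation_mm=(4.0, -3.0, 2.0)),
    noise_sigma=0.02, bias_amplitude=0.10, seed=42,
)
result, diag = measure_phantom_subject(spec, epsilon=5.0,
                                       trace_band=(1.35, np.inf))
```

which prints (via the snippet in this repository's test suite):

```
recovered rotation (deg): (-3.111, 1.679, -3.827)
recovered translation (mm): (-3.751, 3.12, -1.952)
normalization gain/offset: 0.9950 / 0.0167
phantom-42-L00: v_washout=15648 mm^3  v_late=0 mm^3      washout_ratio=1.000  rcbv_ratio=3.000  adc_ratio=1.400
phantom-42-L01: v_washout=336 mm^3    v_late=13696 mm^3  washout_ratio=0.024  rcbv_ratio=2.972  adc_ratio=1.386
subject washout ratio: 0.539  (truth 0.556)
dice washout/late: 0.992 / 0.977
```

Reading this: registration recovered (approximately the inverse of) the
applied motion; the normalization gain is ~1 as both scans share units; the
early-peaking compartment is pure wash-out (ratio 1.000), the late-peaking
one almost pure late enhancement (0.024); the subject-level wash-out ratio
0.539 sits within 0.02 of the geometric truth, and the per-compartment label
maps overlap truth with Dice ≥ 0.977 despite motion, noise and bias.

Cohort statistics from a simulated measurement table:

```python
from washmap import reference_cohort_spec, simulate_cohort, cohort_report
table = simulate_cohort(reference_cohort_spec(seed=1))   # 29 + 53 lesions
report = cohort_report(table, seed=1)
print(report.roc_rows[["score", "subset", "auc", "threshold"]])
```

## Command line

```bash
washmap simulate     --config phantom.yaml --out phantom/
washmap register     --fixed early.nii.gz --moving late.nii.gz --metric ncc --out reg/
washmap map          --early early.nii.gz --late reg/registered.nii.gz --epsilon 5 --out map/
washmap run          --config subject.yaml
washmap cohort-stats --table cohort.csv --exclude-below-1cm3 off --seed 1 --out report/
```

Exit codes: 0 success, 2 input/configuration error, 3 numerical or
convergence error.

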