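# t1knn

Quantitative T1 maps of the brain from routine clinical MRI — a T1-weighted
MPRAGE and a T2-weighted FLAIR — by voxel-wise one-nearest-neighbour
classification, with the gold-standard inversion-recovery fitter and the
agreement-analysis suite used to validate it, all exercisable on a built-in
synthetic brain phantom.

## The problem and the method

Clinical neuroimaging is dominated by relaxation-*weighted* images; direct
T1 maps require dedicated research sequences. Yet a T1 map can be inferred
from clinical contrasts: for each voxel a nine-element feature vector

```
x = [ S_MPRAGE / S̄_WM,  S_FLAIR / S̄_WM,  p_WM, p_GM, p_CSF, p_Cau, p_GP, p_Tha, p_Put ]
```

(WM-normalized intensities plus seven tissue probabilities) is matched by
Euclidean distance to a stored library of training voxels whose T1 is known
from a reference quantitative map, and the voxel inherits its nearest
neighbour's label. Labels live on a discrete class grid, T1 = 400 … 3980 ms
in 10 ms steps. The learner is *lazy* — training merely stores the
exemplars — and k = 1 ("fine" kNN) is the operating point: larger
neighbourhoods smooth away small structures such as lesions. WM
normalization makes the whole pipeline invariant to scanner intensity
scaling.

Validation follows relaxometry practice: a seven-point inversion-recovery
FSE series (TI = 50–3000 ms, TR = 7 s) is fitted per voxel with the signed
two-parameter recovery model

```
s(TI) = s0 · (1 − 2·e^(−TI/T1) + e^(−TR/T1))
```

with exhaustive polarity restoration for magnitude data, and the predicted
and fitted maps are compared by per-tissue mean absolute percent
difference, SSIM, Bland–Altman bias/limits of agreement, and regression.

Because clinical study data cannot be redistributed, the package ships a
seeded digital brain phantom (concentric cortex/WM/CSF, paired deep-GM
nuclei, ventricles, FLAIR-hyperintense WM lesions with elevated T1,
partial-volume boundaries, Rician noise, optional bias field) that renders
all contrasts from closed-form signal equations.

## Worked example

Train on one synthetic subject, predict a held-out subject, and compare
against that subject's IR-fitted gold standard (48³ voxels, WM SNR 50):

```python
from t1knn.phantom import PhantomSpec
from t1knn.workflow import cross_phantom_validation

result = cross_phantom_validation(
    PhantomSpec(shape=(48, 48, 48), seed=1),
    PhantomSpec(shape=(48, 48, 48), seed=2),
)
print(result.report.summary())
```

```
T1 map agreement report
==================================
tissue  mean_t1_ref  mean_t1_test  mean_abs_pct_diff  voxel_count  n_excluded_zero_ref
    wm       869.28        868.06               1.45         9884                    0
    gm      1334.35       1354.50               2.19          160                    0
   csf      4190.12       3980.00               5.07         1832                    0
   cau      1253.47       1262.50               1.45           16                    0
    gp       982.18        982.50               1.28           16                    0
   tha      1145.97       1146.00               1.07           40                    0
   put      1119.93       1116.00               0.95           40                    0

SSIM:                0.9622
Bland-Altman bias:   -0.05 %
limits of agreement: [-4.05, +3.95] %
regression:          test = 0.941 * ref +51.2 ms (R^2 = 0.9688)
```

`mean_abs_pct_diff` is the voxel-wise |predicted − IR| / IR × 100 averaged
within each tissue (probability > 0.95); CSF is the worst tissue — its true
T1 (4200 ms here) lies above the class-grid ceiling of 3980 ms, so
predictions clamp to the boundary class — and it is excluded from the
pooled Bland–Altman/regression. SSIM is computed with a fixed 4000 ms data
range over the brain mask.

The same pipeline is available from the shell:

```bash
t1knn simulate  --out study --seed 3
t1knn preprocess --study-dir study
t1knn fit-ir     --study-dir study
t1knn train      --study-dir study --out model.npz
t1knn predict    --study-dir study --model model.npz
t1knn evaluate   --study-dir study     # writes report.csv + summary.json
```

All stages read one YAML configuration (see
`src/t1knn/data/default_config.yaml`); unknown keys are rejected by name,
and every random draw descends from the single configured seed.

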