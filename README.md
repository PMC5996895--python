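# strokeseg

Automatic segmentation of the acute ischemic core lesion on diffusion MRI.

In acute stroke triage the volume of irreversibly damaged tissue — the
hyperintense lesion on diffusion-weighted imaging (DWI) with reduced
apparent diffusion coefficient (ADC) — drives treatment decisions, and
manual outlining is slow and operator-dependent. `strokeseg` implements a
fully automatic, adaptive voxel classifier for this task, aimed at
researchers working with co-registered DWI (b = 1000 s/mm²), ADC and b0
volumes in NIfTI format.

## Method

Each brain voxel is described by four features:

1. **DWI**, standardized per axial slice by the mean intensity over the
   contralateral (lesion-free) hemisphere,
2. **ADC**, kept on its absolute scale (mm²/s),
3. **mirror-corrected DWI**, and
4. **mirror-corrected ADC**.

Mirror correction reflects the image across the mid-sagittal plane (a flip
composed with a rigid correction estimated by registering the b0 image to
its own flip), smooths the reflection with an isotropic Gaussian, takes
the most *critical* value in a small neighborhood (highest for DWI, lowest
for ADC), and subtracts it from the original. Bilaterally symmetric
anatomy and artifacts cancel; unilateral anomalies stand out.

Voxels are classified by a bespoke decision tree. At each node, for each
feature, the threshold maximizing Youden's index

    J = sensitivity + specificity − 1

is found; the best feature splits the data into a ≥-branch and a <-branch,
recursively until leaves are pure. Every node `N` carries the pseudo-count
probability

    p(N) = (n₁ + 1) / (n + 2),

where `n₁` of the node's `n` voxels are inside the lesion — shrinking
toward 0.5 in small nodes. Overfitting is controlled by depth pruning: for
`n` training patients, `n` leave-one-patient-out trees are grown, each
held-out patient's voxels are scored at every depth `d` by the ROC AUC of
the depth-truncated probabilities `p_d(x)`, and the tree is cut at the
median of the per-patient AUC-optimal depths. The probability map is then
smoothed, thresholded at 0.25 and morphologically closed and opened to
form the final mask.

Evaluation follows the matching protocol: outer leave-one-out
cross-validation, Dice overlap `2TP/(2TP+FP+FN)`, lesion-volume residuals,
and a per-patient *optimal two-threshold* baseline — the best achievable
intensity band on DWI or ADC for each patient, an upper bound for any
threshold-based method — compared by paired Wilcoxon signed-rank tests.

Because clinical cohorts cannot be redistributed, the package ships a
synthetic-cohort generator (`strokeseg.synthetic`) producing bilaterally
quasi-symmetric brain phantoms with unilateral graded lesions, symmetric
tissue texture, mirrored artifact pairs, per-slice intensity drift and
Gaussian noise; every stage of the pipeline is developed and tested
against it.

## Worked example

```python
import warnings
warnings.simplefilter("ignore")
from strokeseg import SyntheticConfig, generate_cohort, run_loocv

cfg = SyntheticConfig(n_patients=12, seed=7)
cohort = generate_cohort(cfg)
result = run_loocv(cohort)

for method, stats in result.summary["methods"].items():
    lo, hi = stats["dice_iqr"]
    print(f"{method:14s} median Dice {stats['median_dice']:.3f} "
          f"IQR [{lo:.3f}, {hi:.3f}]  residual SD {stats['residual_sd_ml']:.2f} ml")
w = result.summary["wilcoxon"]["atlas_vs_threshold_adc"]
print(f"Wilcoxon atlas vs ADC band: p = {w['p_value']:.2e}")
print("selected depths:", sorted(result.summary["chosen_depths"].values()))
```

prints

```
atlas          median Dice 0.857 IQR [0.850, 0.868]  residual SD 0.25 ml
threshold_adc  median Dice 0.631 IQR [0.596, 0.803]  residual SD 1.58 ml
threshold_dwi  median Dice 0.902 IQR [0.851, 0.954]  residual SD 0.47 ml
Wilcoxon atlas vs ADC band: p = 2.44e-03
selected depths: [7, 8, 8, 8, 8, 8, 8, 8, 9, 10, 10, 10]
```

`atlas` is the tree segmenter evaluated on held-out patients; the two
`threshold_*` rows are the per-patient *best possible* intensity bands
(optimistically tuned on each test patient, so they are upper bounds, not
deployable methods). The tree beats the ADC band decisively and tracks
expert lesion volumes with a residual spread of a quarter millilitre; the
per-patient optimal DWI band remains high here because the synthetic DWI
lesion contrast is strong relative to the texture. The pipeline is fully
deterministic given the seed.

The same workflow is available from the shell:

```bash
strokeseg simulate --out cohort/ --n 12 --seed 7
strokeseg train    --manifest cohort/manifest.csv --out model.json
strokeseg predict  --model model.json --dwi c_dwi.nii.gz --adc c_adc.nii.gz \
                   --b0 c_b0.nii.gz --out pred/
strokeseg evaluate --manifest cohort/manifest.csv --out results/
```

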