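# Methods notes

## Model and assumptions

The segmenter treats lesion delineation as voxelwise binary
classification with spatial pre- and post-regularization. Its assumptions
are:

* all channels of a patient (DWI at b=1000 s/mm², ADC, b0, masks) are
  already resampled to one grid; volumes are reoriented to canonical RAS
  order on load so array axis 0 is the left–right axis and every "mirror"
  operation flips axis 0;
* the brain is bilaterally quasi-symmetric and the lesion essentially
  unilateral, so the contralateral hemisphere provides a patient-specific
  reference both for slice-wise DWI standardization and for mirror
  correction;
* DWI intensities are only meaningful relative to normal tissue (hence
  slice-wise division by the contralateral mean), while ADC is absolute
  and is used in native units (mm²/s);
* expert masks are the ground truth being imitated, including their
  biases.

## Pipeline stages and defaults

**Brain mask** (unstated in the source protocol, chosen here): Otsu
threshold on b0, largest connected component, binary closing with a
2-voxel ball. Parameter-light and exactly invariant to positive affine
intensity rescaling.

**Contralateral side** (`auto`): after a provisional whole-brain
slice-wise normalization, the hemisphere with the smaller count of voxels
above the 98th intensity percentile is taken as contralateral; a warning
flags counts within 10% of each other. Explicit `left`/`right` overrides
exist.

**Mirror transform**: the b0 is registered to its own midplane flip
(rigid 6-DOF, mean-squared metric inside the brain mask, linear
interpolation, dense sampling — fully deterministic). Failure falls back
to the pure flip with a warning; near-identity fits (< 0.05 mm, < 1e-4
rad) are snapped to the exact flip so perfectly symmetric inputs incur no
interpolation. Note the geometry: if the anatomical midplane is offset
δ from the grid midplane, the rigid component carries ~2δ of translation.

**Mirror correction**: `v − critical_filter(smooth(mirror(v)))` with
Gaussian σ = 2 mm (suppresses registration/interpolation noise without
erasing anatomy) and a 3×3×3 critical-intensity neighborhood (radius 1
voxel, max for DWI, min for ADC — minimal tolerance to residual
asymmetry). Both are configurable. Mirror-corrected DWI is computed from
the *normalized* DWI; ADC stays absolute.

**Tree growth**: candidate thresholds are midpoints between consecutive
distinct sorted values; Youden's J is evaluated in both orientations
(lesions are high on DWI, low on ADC); J is computed with a single
exact-integer division so equal rational values compare equal in floating
point. Ties break toward the smallest threshold, then the lowest feature
index — growth is deterministic and a given table always yields the
identical tree. Nodes whose feature vectors are all identical but whose
labels are mixed become *forced leaves* with fractional p (the purity
criterion is unreachable there; this guarantees termination).

**Depth selection**: every integer depth from 0 to each auxiliary tree's
height is scored; the per-patient argmax takes the smallest depth on
ties; the cohort depth is the lower median (conservative, deterministic,
integer). Patients whose held-out labels are single-class are excluded
from the vote with a warning. Because a tree grown with patients {i, j}
both excluded is the same object regardless of which of the two is the
"held-out" one, nested cross-validation shares trees through a cache
keyed by the training-patient set; this is a pure optimization with no
effect on results.

**Regularization**: masked (renormalized) Gaussian smoothing with σ =
2 mm — the same spatial scale as preprocessing — so cortical lesion
probability is not diluted by out-of-brain zeros; threshold 0.25
(inclusive ≥, deterministic at the boundary); closing then opening with a
1-voxel ball. With σ = 0 and radius 0 the stage reduces to plain
thresholding.

**Baselines**: the per-patient optimal two-threshold band is computed
exactly over all distinct observed in-brain values (an O(m²) cumulative
scan); ties prefer the widest band, then the smallest lower threshold,
and unbounded sides are reported as ±∞. A quantile-grid approximation
(`max_candidates`) exists for very large volumes but is off by default.
The DWI band uses normalized DWI (a config switch allows raw). The
Wilcoxon comparison uses scipy's signed-rank test (exact null for small
tie-free samples, tie-corrected normal approximation otherwise).

**Dice conventions**: both masks empty → 1.0; exactly one empty → 0.0
(continuity and determinism; the formula is otherwise undefined there).

## Synthetic cohort: what it emulates and what it does not

The generator produces, per case, deterministic in (seed, index):

* an ellipsoidal two-hemisphere brain (semiaxes 26×28×16 mm on a
  32×32×20 grid of 2 mm voxels — a scaled-down head keeping runtimes
  desk-sized; the problem sizes used throughout the tests and the
  acceptance script are ~6,100 brain voxels/case, 12 cases);
* one unilateral ellipsoidal lesion, 2–8 ml, with graded contrast (full
  at the core, 70% of the contrast deviation at the rim): DWI ×1.5–2.5,
  ADC ×0.4–0.7 at the core;
* smooth bilaterally symmetric tissue texture (an even cosine series in
  the left–right coordinate; sd 15% on DWI/ADC, 10% on b0) standing in
  for gray/white-matter structure — it defeats plain intensity bands but
  cancels under mirror correction, which is precisely the property the
  mirror maps are meant to buy;
* three mirrored artifact pairs per volume whose DWI (×1.4–2.2) and ADC
  (×0.4–0.75) contrasts overlap the lesion's ranges, so artifacts are
  *misinterpretable* as lesions by intensity alone;
* per-slice multiplicative intensity drift (amplitude 0.1), removed by
  slice-wise normalization;
* a small whole-head rigid offset (sd 0.5 mm) so the anatomical midplane
  is not the grid midplane;
* additive Gaussian noise at 5% of the tissue mean per channel.

DWI means ~100 (arbitrary units) and ADC ~0.8×10⁻³ mm²/s background were
chosen to exercise the absolute-scale handling of ADC.

Not modelled: real anatomy (no template), partial-volume effects at
boundaries (edges are sharp, which makes the synthetic task *easier* at
lesion borders than real data), scanner-specific noise spectra,
T2 shine-through, multi-focal lesions. Consequently, passing the
end-to-end tests demonstrates the pipeline's mechanics — leakage-free
cross-validation, the benefit of mirror correction over intensity bands
under symmetric confounders, volume fidelity — but absolute Dice levels
on this phantom say nothing quantitative about clinical performance.

## Numerical choices and degenerate inputs

* Empty normalization regions fall back to the whole-brain slice mean;
  all-zero slices map to zero; a non-positive mean with nonzero
  intensities is an error.
* `(n₁+1)/(n+2)` is exact in floating point for all practical counts;
  node bookkeeping (conservation of n and n₁ at every split) is asserted
  by tests.
* Lesions are rasterized at voxel centers; requested volumes whose
  in-brain rasterization falls below 70% after 25 placement attempts
  raise an infeasibility error.
* Registration is dense-sampled gradient descent — deterministic; all
  other randomness flows from one integer seed through
  `numpy.random.default_rng`.

## Known limitations

* The full-depth tree is grown exactly (no subsampling by default); on
  cohorts of clinical size (~10⁷ voxels) growth is the dominant cost and
  a non-lesion-voxel subsampling option would be the first lever.
* The per-patient optimal DWI band can rival the tree on phantoms whose
  DWI lesion contrast is strong and uniform; it is an oracle baseline,
  tuned on the test patient, not a competing method.
* The 0.25 probability threshold with 2 mm smoothing systematically
  dilates masks by roughly one voxel at this grid scale, visible as a
  positive volume bias (residual *spread* stays small).
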