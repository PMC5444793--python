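# Methods

## Quantification model

A CT slice is an integer grid of Hounsfield units (HU). Lung segmentation
thresholds at −500 HU and keeps the 8-connected sub-threshold components
that do not touch the image border (outside-patient air is border-connected)
and exceed a minimum area (default 50 px, dropping airway cross-sections).
Segmentation is seedless and deterministic; idempotence and recovery of the
phantom ground-truth mask (Dice ≥ 0.99 noise-free) are tested.

For a threshold *t*, the low-attenuation set is
LAA(t) = { p ∈ lung : HU(p) < t } — strictly below, so a pixel exactly at
the threshold is normal lung. As *t* grows the LAA sets are nested
(a filtration), so LAA% = 100·|LAA|/|lung| is non-decreasing in *t*.

Topology uses the standard dual connectivity pairing for binary images:
LAA foreground is 8-connected, background 4-connected. Then

- b₀ = number of 8-connected LAA components,
- b₁ = number of 4-connected background components containing no border
  pixel, i.e. normal-lung islands fully enclosed by LAA,

and nb₀ = b₀/|lung|, nb₁ = b₁/|lung| make slices of different lung area
comparable. Two independent cross-checks guard the implementation: an
exhaustive flood-fill oracle (all 65 536 4×4 grids) and the Euler identity
χ = b₀ − b₁, where χ is counted as vertices − edges + faces of the union of
closed unit pixel squares. The 8/4 pairing is exactly the convention under
which that identity holds (diagonally touching pixels share a vertex, hence
are one component).

Hole counting is performed on the full image frame. On lung CT all non-lung
tissue and outside air belong to border-connected background components, so
the enclosed components are precisely the normal-lung islands surrounded by
LAA; an LAA ring that encircled non-lung tissue would also count, which we
accept as a known approximation of "surrounded normal lung".

### Threshold grid

Thresholds run over the half-open range [lower, upper) in 5 HU steps. The
canonical sweep [−1000, −700) therefore has exactly 60 levels
(−1000, −995, …, −705), which fixes the feature-vector lengths at 60 (LAA%)
and 120 (HEQ). An inclusive upper bound would give 61 levels and is
inconsistent with those lengths; the half-open convention is the design
choice that reconciles them, and the feature-length test pins it.

## Features and classification

- **C_LAA%**: LAA% at each level of a grid, ascending threshold order.
- **C_HEQ**: all nb₀ values by ascending threshold, then all nb₁ values.
  The block order (nb₀ first) is fixed; within-block ascending order is a
  reproducibility choice with no effect on tree models.

The range sweep evaluates all 21 ordered (lower, upper) pairs drawn from
{−1000, −950, −900, −850, −800, −750, −700} — a lower-triangular table per
classifier kind.

The classifier is a Random Forest over the 15-point grid
trees ∈ {10, 100, 1000} × feature-fraction ∈ {0.1, 0.3, 0.5, 0.7, 0.9},
where features-per-split = max(1, round-half-up(fraction × length)).
Evaluation is leave-one-patient-out: each fold trains on all other
patients' slices, so within-patient correlation cannot leak into the test
fold. Hyperparameters are selected by accuracy on the *same* CV used for
reporting; this mirrors the convention the package reproduces and is
optimistically biased — fold-internal nested selection would be the
unbiased alternative. Scores are treated as nominal classes; a training
fold lacking rare scores (4–5) simply cannot predict them in that fold.
One seed drives all forest randomness per experiment.

Optional importance-based feature selection runs inside each training fold
only: a forest fit on the fold ranks features by mean impurity decrease and
the top ⌈keep_fraction × length⌉ (keep_fraction ∈ {0.9, 0.7, 0.5}) are
refit; the held-out patient never influences the selection.

## Statistics

- **Spearman ρ**: Pearson correlation of mid-ranks (average ranks on ties);
  undefined and reported as such when either variable has zero rank
  variance. No p-values are attached.
- **Accuracy**: trace of the 6×6 true-score × prediction table over its
  total.
- **Quadratic-weighted κ**: κ = 1 − Σ wᵢⱼOᵢⱼ / Σ wᵢⱼEᵢⱼ with wᵢⱼ = (i−j)²
  and E the outer product of observed marginals. Categories are fixed at
  0–5 even when absent from a sample, so the weights always use the full
  ordinal scale. Undefined (and raised) when all mass sits in one cell.
- **Exact McNemar**: with b and c the discordant counts, the central
  two-sided p doubles the smaller binomial(b+c, ½) tail and caps at 1;
  b + c = 0 returns p = 1 by convention. The doubled-tail (central) variant
  is the default convention of the standard exact-test implementations.

## Synthetic phantoms

Phantoms are 256×256 int16 grids: air (−1000 HU) background, an elliptical
soft-tissue body (+40 HU), two elliptical lung fields (−780 HU), and
lesions at −980 HU. Lesions are solid disks (radius 5 px by default) or
annuli (wall 3 px) whose interior remains normal lung; placement is
rejection sampling (cap 1000 attempts per lesion) in the
distance-transform-eroded lung, keeping every lesion ≥ 2 px clear of the
lung boundary and pairwise disjoint. For any threshold strictly between
lesion and lung HU the LAA set is exactly the lesion set, so ground truth
is b₀ = disks + rings, b₁ = rings, and the LAA pixel count — the basis of
the exact end-to-end tests. Optional additive Gaussian HU noise (rounded to
integers) is the only noise model.

A cohort draws one visual score per patient from a distribution skewed
toward low scores (defaults 0.53/0.23/0.09/0.10/0.03/0.02 for scores 0–5,
matching the per-slice score marginals of the kind of screening cohort the
generator emulates), maps it to a central lesion count (0 for score 0,
otherwise 3·score), jitters each slice by ±1 lesion, and derives the slice
score through the monotone map score = min(5, ⌊(lesions+1)/3⌋). Slices of
one patient therefore share a severity band, which is what makes grouped
CV meaningful. Annular lesions appear from score 2 up so higher grades
carry nonzero b₁. Generation is a pure function of the seeds.

### What the synthetic experiments do and do not show

The end-to-end experiments (39 patients × 3 slices, noise σ = 25 HU — a
typical thin-slice parenchymal noise level) verify the machinery: exact
topology recovery, monotone LAA% curves, above-chance score recovery under
LOPO CV (accuracy ≥ 0.5), chance-level accuracy (≈ 1/6) after label
permutation on a balanced cohort (leave-group-out accuracy under permuted
labels tends to land slightly *below* Σpₖ² because train and test class
frequencies are anti-correlated in small resampled folds), and strong
LAA%–score correlation. They
do **not** emulate real emphysema morphology: real lesions are irregular,
coalescent, textured and scanner-dependent, and real visual scoring is far
noisier than the deterministic severity map here. Synthetic CV accuracies
(~0.95) are therefore much higher than what real cohorts yield (~0.55–0.66)
and say nothing about clinical performance — only that the pipeline
computes what it claims.

## Numerical and degenerate-input choices

- Strict `<` at every threshold; thresholds outside [−1024, 500] HU are
  rejected as implausible.
- Empty LAA set → (b₀, b₁) = (0, 0); empty lung mask is an error.
- Grid-search ties break toward fewer trees, then smaller feature
  fraction; feature-importance ties break toward the lower feature index.
- Curve CSVs are written with `%.17g` and parsed with round-trip float
  precision, so write→read is lossless.
- DICOM pixel data is converted to HU via rescale slope/intercept;
  non-integer HU after rescale are rounded with a warning. Multi-slice
  NIfTI volumes are addressed by slice index; all grids are row-major,
  origin top-left, 0-based.

## Problem sizes used by the shipped experiments

Tests and the acceptance script use the 39 × 3 synthetic cohort for the
end-to-end arm, a 12 × 3 balanced cohort with 20 permutation repeats and
trees ≤ 100 for the chance-level arm, the full 15-config grid elsewhere,
and 1000 random 32×32 grids plus the exhaustive 4×4 enumeration for the
topology oracles.

## Known limitations

- 2-D only; no 3-D cubical homology, no left/right lung separation, no
  airway tracking.
- No persistence barcodes or persistence-based metrics — only per-threshold
  Betti numbers.
- Segmentation equivalence with any particular clinical region-growing
  implementation is not claimed; on real scans the min-area and border
  rules are heuristics.
- The hyperparameter-on-evaluation-CV bias noted above.
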