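# Methods

This note records the modelling choices, parameter defaults, numerical
conventions and known limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Interstitial lung abnormalities (ILA) — ground glass, reticulation,
nodularity, linear scars, subpleural lines — are subtle CT findings that
can precede interstitial lung disease. The package classifies local lung
texture into eight classes (normal, five interstitial, two
emphysematous) from small patches centred on annotated points, then
extends point classification to whole lungs and to a scan-level ILA
burden score. Attenuation is in Hounsfield units (air −1000, water 0).

## Coordinates and ROI geometry

Volumes use 0-based voxel indices with axis order (x, y, z) =
(left-right, anterior-posterior, inferior-superior); annotations are in
voxel space. ROIs are extracted in voxel units — 48 px in-plane, 7 axial
slices for the 3D slab — not resampled to a fixed physical size; at
typical CT spacing the 48×48 axial patch covers a whole secondary
pulmonary lobule. A window of length 48 centred at index c spans
c−24 … c+23, so the centre voxel is shared exactly by the three
orthogonal 2.5D planes. Points nearer than half a window to the volume
border are handled by reflect padding (subpleural and paraseptal lesions
live at the lung edge); a strict mode raises instead. The multi-context
network's second input is the surrounding 96×96 axial window block-mean
downsampled to 48×48.

## Normalization

Patches are standardized by the pooled mean and *population* standard
deviation of all voxels of the training-plus-validation patches. The
population/sample distinction is negligible at these counts but is
pinned for bit-reproducibility. Zero variance raises rather than
dividing by zero. Augmentation happens in HU, before standardization;
the sponge rescaling would otherwise invalidate the pooled statistics.

## Augmentation

*Geometric.* Rotation (±180°), shifts (±4 px), horizontal/vertical
flips and shear (±8°), applied plane-wise with linear interpolation and
reflect boundary, about the patch centre. During class balancing each
under-represented class keeps all its originals and adds randomly
transformed copies (sources drawn with replacement) until the roster
reaches the 600-point target; classes at or above target are subsampled
without augmentation. Balancing is applied to the scarce interstitial
classes (GG, NOD, LINSC, SUBPL); any other class below target is filled
by reusing originals verbatim.

*Sponge model.* Lung mass is conserved over the respiratory cycle, so a
volume change ΔV rescales tissue density ρ = HU − air by V/(V+ΔV):

    HU' = (HU − air)·V/(V+ΔV) + air,    air = −1000 HU.

Mean density × volume is conserved to machine precision and air voxels
are a fixed point. ΔV defaults to Uniform(−100, +100) mL — mild
inspiratory fluctuation; the source literature prints both "±100 mL" and
"U(−1000, 1000)" for this range, and the ±100 mL reading is used, with
the range configurable. The density proxy HU + 1000 (attenuation above
air) is the standard relative-density convention; the scan-level volume
V is taken from the lung mask when present, else a configurable 5000 mL
default. Sponge augmentation applies to all classes.

## Architectures

All members share: two stacked 3×3 convolutions wherever a 5×5 would
appear (texture is local; small receptive fields avoid non-local
information), few pooling steps (two 2×2 max-pools) to limit spatial
information loss, batch normalization after every pooling step, a
dense hidden layer with dropout 0.5, and an 8-way softmax.

* **BCNN** (baseline): [conv–conv–pool–BN] ×2 → conv–conv → dense →
  softmax.
* **MSTAGE**: additionally branches the block-1 feature maps, global-
  average-pools them and concatenates the result with the flattened
  final features, mixing receptive-field scales before classification.
* **MCONTEXT** (2D only): a parallel trunk processes the larger-scale
  context view; features are concatenated before the dense layers.
* 2.5D members take the three orthogonal planes as a 3-channel input;
  3D members use 3×3×3 kernels on the 48×48×7 slab and pool only
  in-plane so the 7-slice z-extent survives to the classifier.

Filter counts are not uniquely determined by the source description;
the full-scale defaults are channels (32, 32, 64) and a 128-unit dense
layer, chosen to keep members small (roughly 1M parameters for the 2D
members) since deep architectures overfit patch-scale data. Weights are
He-uniform initialized from a seeded generator; everything is trained
from scratch.

## Training

Adam (η = 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e−8) minimizes the
L2-regularized categorical cross-entropy: mean negative log-probability
plus (λ/2)·Σw² over convolution and dense weights only (biases and
batch-norm parameters are not decayed), λ = 0.0025. Dropout 0.5 on the
dense hidden layer; batch size 128; early stopping restores the
parameters of the best-validation epoch once validation loss has not
improved for 30 consecutive epochs (patience 0 stops at the first
non-improving epoch). Per-epoch shuffling, dropout masks and
initialization all derive from explicit seeds; two runs with the same
seed produce identical training logs.

The engine is implemented in NumPy: convolutions are computed as one
GEMM per kernel offset ("shift-and-matmul"), which is exact and keeps
memory bounded. Max-pool gradients at ties are split evenly among the
tied positions — a valid subgradient that keeps the backward pass
deterministic. Softmax is stabilized by max subtraction; cross-entropy
clips probabilities at 1e−12.

## Ensemble

Member probabilities are fused as Y(x) = Σ wᵢPᵢ(x) with wᵢ ∈ [0, 1],
deliberately *not* renormalized (the argmax is scale-invariant; where a
normalized certainty is needed, Y is divided by its sum). Decisions are
argmax with ties to the lowest class index. Majority voting breaks ties
by the largest summed probability among tied classes, then lowest index.

The weight search minimizes 1 − macro balanced accuracy on validation
predictions (configurable to 1 − GM); members are never retrained inside
the search. TPE settings: γ = 0.25 quantile split, 24 candidate draws
per iteration, 200 trials, per-dimension Gaussian Parzen estimators with
a Scott-type bandwidth floor of 0.02. The first eight trials are a
deterministic warm start — the unweighted average and each one-hot
weight vector — so the returned ensemble provably never scores worse
than its best single member; random startup trials follow before the
TPE model takes over. The BO variant fits a Gaussian process (RBF +
white noise) and proposes by expected improvement over 256 uniform
candidates. The search space [0, 1]⁷ has no simplex constraint since
the fusion sum is not renormalized.

## Evaluation protocol

Per-class one-vs-rest SN, SP, GM = √(SN·SP), BA = (SN+SP)/2, macro
averaged with equal weight per class (the test set is heavily skewed
toward normal parenchyma). The source prints the geometric mean once as
√(TP·TN), but every published per-class row satisfies GM = √(SN·SP);
the rate form is implemented, and the printed results are taken as the
authority on intent. Undefined metrics (a class with no true samples)
raise rather than silently returning 0.

Split construction: classes with ≥ 800 points contribute exactly 600
training points (at most 75%); smaller classes contribute ⌈0.75·n⌉
flagged for augmentation to 600 (the ceiling is consistent with the
published 195→147/48 and 413→310/103 allocations); leftovers are the
test set. The balanced 4800-entry roster is split into 10 stratified
folds (60 per class per fold). The subject-level variant holds out whole
subjects (default 5), re-drawing until all eight classes appear in the
test side. In the published cohort table the nodular count is ambiguous
(116 vs 117); 117 is used, and the cohort total reconstructs to 37425
against stated totals of 37427/37424 — flagged, not resolved.

Macro ROC: per-class one-vs-rest curves on the renormalized fused
scores Y_c/ΣY, averaged on a common false-positive-rate grid, AUC by
trapezoid.

## Full-lung labelling and ILA score

Grid nodes (stride 5 voxels, anchored at index 0) inside the lung mask
are classified; every other in-mask voxel takes the label and certainty
of its nearest node — Euclidean distance in voxel units, ties to the
lowest node index (squared distances are integers, so tie-breaking is
exact; the k-nearest-neighbor shortlist is capped at 32 candidates).
Certainty is the probability of the predicted label under the
renormalized fused output. The ILA score is the percentage of lung
voxels labelled GG/RETIC/NOD/LINSC/SUBPL with certainty strictly
greater than the threshold (default 0.95); emphysema is excluded by
default but the class set is configurable. "Lung area" is interpreted
volumetrically (voxel fraction). A small utility fits a cross-validated
logistic regression of per-scan scores against a binary visual ILA
call; validating it needs a real cohort and is out of scope here.

## Synthetic phantoms

The generator emulates exactly what the pipeline needs and no more: an
ellipsoidal "lung" with −850 HU parenchyma plus Gaussian noise (σ = 30),
and eight parametric textures — GG: +150 Gaussian haze; RETIC: +300
line lattice; NOD: small +450 sphere; LINSC: +350 in-plane streak;
SUBPL: +450 curve within 5 voxels of the border; PS: −980 subpleural
pocket; CL: scattered central −980 holes. Lesions are placed without
overlap (class-specific clearance radii; a capacity error is raised
when counts do not fit), annotated points lie inside their lesions and
the mask, and the default per-phantom class counts mimic the cohort's
skew (normal dominates, ground glass and nodular are scarce). A "B35"
kernel toggle applies a mild Gaussian blur to emulate a soft
reconstruction filter.

What the phantoms do *not* emulate: real parenchymal texture spectra,
vessels and airways, reconstruction-kernel noise structure, scanner
heterogeneity, or inter-reader annotation noise. Passing tests on
phantoms therefore demonstrate that the machinery is correct and that
the architectures can learn separable textures — not clinical-grade
accuracy on CT data.

## Desk-scale problem sizes

Training-dependent checks run at a scale one CPU handles comfortably,
chosen once: 56 patches per class (40 train / 16 validation), channel
widths (8, 8, 16) for 2D/2.5D members and (4, 4, 8) for 3D members
(one 3D convolution costs ~20× its 2D counterpart), 32-unit dense
layers, batch 32, 18 epochs for 2D/2.5D and 8 for 3D, seeds pinned.
The full-scale defaults (Table-style hyper-parameters, 600-point
rosters, 10 folds) remain the package defaults for real use.

## Known limitations

* The exact filter counts, dense sizes and pooling plan of the original
  seven architectures are not recoverable from text; the defaults here
  are declared, not claimed to match.
* The NumPy engine is single-threaded-GEMM bound; full-scale training
  (600/class, 300 epochs, width-64 trunks) is feasible but slow — the
  design target is correctness and reproducibility, not throughput.
* Whether annotation coordinates in the source cohort were voxel or
  physical is unstated; voxel space is assumed throughout.
* 2D patches are taken from the axial plane only, for all three 2D
  members.
* The grid classifier's nearest-node tie rule (lowest node index) and
  the strict certainty inequality are conventions; both are documented
  and tested rather than derivable.
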