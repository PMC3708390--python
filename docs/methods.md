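# Methods

## The model

`kernelfield` classifies samples described by numeric feature vectors —
typically the 20-dimensional amino-acid composition of a protein sequence —
in three steps:

1. **Range scaling.** Every feature is mapped to [0, 1] by the min/max of
   the *training* data; test values outside the training range are clipped.
   Scaling is refitted inside every cross-validation fold, so no information
   about a held-out sample leaks into the model that predicts it.
2. **Kernel projection** into a k-dimensional space (k = 3 by default),
   by kernel PCA or kernel GDA.
3. **Classification** of a projected query by either a K-nearest-neighbour
   vote or the inverse-square *class intensity* field.

### Kernels

Four kernels are provided: linear `<x,y> + θ`, polynomial `(<x,y> + θ)^d`,
Gaussian `exp(−‖x−y‖²/σ²)`, and sigmoid `tanh(v<x,y> + r)`. The Gaussian
form divides by σ², **not** the more common 2σ²; callers comparing σ values
against other software should halve/double accordingly (for scikit-learn,
`gamma = 1/σ²`). The sigmoid kernel is not positive semi-definite for all
`(v, r)`; non-PSD sigmoid Gram matrices are accepted with a logged warning
because the eigensolvers below simply discard the negative spectrum.

### Kernel PCA

With Gram matrix **K** of the mapped training data, KPCA solves
`λ α = (1/n) K α` and keeps the top-k eigenpairs. Each direction
`v = Σ_i α_i Φ(x_i)` is scaled to unit feature-space norm
(`αᵀKα = 1`), so with a linear kernel and centering the training scores
coincide exactly with classical PCA scores (this limit is a test oracle).
A new sample projects as `Σ_i α_i K(x_i, x_new)`.

Centering: the PCA derivation assumes zero-mean mapped data, so KPCA
centers **K** by default (`K − 1ₙK − K1ₙ + 1ₙK1ₙ`, with the matching
cross-kernel formula at prediction time). A `center: false` switch gives
the literal uncentered behaviour for comparison, since published
kernel-projection results do not always state which was used.

### Kernel GDA

GDA maximizes the Fisher ratio `λ = (αᵀKDKα)/(αᵀKKα)` on the *uncentered*
Gram matrix, where **D** is block-diagonal with `1/n_c` blocks (an
orthogonal projector onto class-indicator score vectors). Because
`αᵀKKα` is singular whenever **K** is rank-deficient, the problem is
solved in the eigenbasis of **K**: eigendecompose `K = PΓPᵀ`, drop
eigenvalues below `1e-10 × max` (the numerical-rank tolerance), solve the
reduced symmetric eigenproblem `PᵀDP`, and map eigenvectors back through
`α = PΓ⁻¹β`. At most C − 1 discriminants are retained for C classes;
requesting more is an error rather than silently clamped.

Two numerical facts worth knowing:

* Fisher ratios lie in [0, 1] (D is a projector). With a full-rank kernel
  (e.g. Gaussian) up to C ratios equal 1 exactly and the classes project
  to near-point clusters — the familiar kernel-Fisher overfitting mode.
  Eigenvector choice inside a tied eigenvalue block is an arbitrary
  rotation of the projected space; distances, and therefore every KNN and
  intensity prediction, are unaffected, but raw coordinates can differ
  between platforms. Tests on permutation invariance therefore compare
  projected distance matrices.
* Discriminant directions are normalized to unit feature-space norm.
  Classification happens in the projected space, so this scaling choice
  (which the underlying formulation leaves open) does affect distances;
  fixing it keeps KNN/intensity results reproducible.

Eigenvector signs (both methods) are fixed by making the largest-magnitude
dual coefficient positive, so repeated fits are bit-identical.

### The class intensity field (EQPC / IEFP)

Each projected training point is a point charge; a class-C point carries
`EQPC_C = 1/n_C`, so every class holds unit total charge regardless of
size. The intensity a class exerts at a query is the Coulomb-style sum
`IEFP_C = Σ_{i∈C} EQPC_C / r_i²` over Euclidean distances in the projected
space, and the predicted class maximizes IEFP. Two conventions close the
formula's gaps:

* **r = 0.** The sum diverges as a query approaches a training point. A
  query within `epsilon_coincide` (default 1e-12) of a training point is
  assigned that point's class — the divergence's limit — which also keeps
  leave-one-out evaluation well defined under `refit: false`.
* **Ties.** Exact IEFP ties (and KNN vote ties, after a
  smallest-summed-distance tiebreak) go to the lowest class index, logged.

The field obeys an inverse-square homogeneity law — scaling all
coordinates by s multiplies every IEFP by 1/s² and never changes a
prediction — which the tests assert directly.

## Evaluation

LOOCV refits scaler, projection and classifier on each fold of n − 1
samples (`refit: true`, the default). `refit: false` fits the projection
once on all data and only excludes the held-out point from the classifier
state; it is cheaper and closer to what some published pipelines appear to
do, and each report records which mode produced it. GDA folds require
every class to keep ≥ 2 members, checked before the first fold runs.

The two-stage hierarchical pipeline first makes a binary target-vs-rest
decision (preset: KPCA, polynomial d=2 θ=0.1, KNN K=5), then routes
"rest" samples to a second model over the remaining classes (preset: GDA,
Gaussian σ=5, intensity). A sample flagged as the target never reaches
stage 2, and stage 2 is fitted lazily so an all-target training set never
needs it. This mirrors the published membrane-protein workflow, where the
dominant multi-pass type is peeled off first and the four rarer types are
resolved by GDA.

Named presets (`datasetA`, `datasetB`, `membrane-stage1`,
`membrane-stage2`) carry the published model configurations for the
protein tertiary-structure and membrane-type benchmarks.

## Synthetic data

Real benchmark sets for this method (two domain collections and a
2059-protein membrane set) are referenced in the literature but not
redistributable from it, so the package ships seeded generators producing
data with the statistical structure the method assumes:

* **Gaussian blobs** — isotropic clusters with configurable pairwise
  centre separation; the linearly separable sanity case (LOOCV 1.0 at
  separation ≫ spread, chance level at separation 0).
* **Concentric shells** — points on noisy hyperspheres of distinct radii,
  embedded in 10 ambient dimensions by default. The 10-D default matters:
  a 3-component linear projection of 3-D shells is lossless, whereas a
  linear 3-D projection of 10-D shells collapses the radii, so this
  fixture genuinely demonstrates what the Gaussian kernel buys (RBF-KPCA +
  3NN ≥ 0.95 LOOCV vs ≤ 0.75 for the linear kernel at radii 1 and 3,
  noise 0.1, n = 60).
* **Composition-biased proteins** — sequences drawn i.i.d. from per-class
  residue frequency profiles (default: four profiles boosting hydrophobic,
  charged, small/polar and aromatic 5-residue groups by +0.05 each, lengths
  uniform in 200–400). Residues are i.i.d. because the downstream
  representation is composition, which is order-free; no positional,
  phylogenetic or secondary-structure signal is emulated. Passing tests
  on this data show the pipeline recovers composition-level class
  structure end-to-end (FASTA → composition → scaling → projection →
  classifier); they do not certify accuracy on real proteins, whose
  class-conditional compositions overlap far more.

Default fixture sizes stay at n ≤ 200: LOOCV refits a dense
eigendecomposition per fold, and these sizes keep the full suite and the
reproduction script in the seconds-to-minutes range while leaving every
statistical assertion comfortably powered.

## Known limitations

* Dense n×n eigendecompositions bound practical training sizes to a few
  thousand samples; no Nyström or incremental variants.
* The projection dimension k is a parameter but only k = 3 is exercised
  by the shipped presets and tests.
* Hard class decisions only; IEFP magnitudes are not calibrated
  probabilities.
* The per-fold-refit LOOCV is O(n) eigendecompositions; `refit: false`
  trades leakage-freedom for speed.
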