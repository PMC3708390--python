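# kernelfield

Kernel-space projection and charge-field classification for protein
structural class and membrane protein type prediction.

## The problem

Protein domains fall into four coarse tertiary structural classes (all-α,
all-β, α/β, α+β) and membrane proteins into five types (two single-pass
orientations, multi-pass, lipid-anchored, GPI-anchored). Both attributes
can be predicted surprisingly well from nothing but the amino-acid
composition of the sequence — a 20-vector of residue frequencies — if the
classifier can exploit the *nonlinear* structure of composition space.

`kernelfield` implements a three-dimensional kernel approach to this
problem, for bioinformaticians who want a small, fully deterministic,
inspectable pipeline:

1. range-scale features to [0, 1];
2. project into 3-D kernel space by **kernel PCA** (top eigenvectors of
   the kernel matrix, `λα = (1/n)Kα`) or **kernel GDA** (discriminants
   maximizing the Fisher ratio `αᵀKDKα / αᵀKKα`);
3. classify a projected query by **K-nearest-neighbour** vote, or by the
   **class intensity model**: each training point of class C is a point
   charge `EQPC_C = 1/n_C`, the field a class exerts at a query is the
   Coulomb-style sum `IEFP_C = Σ EQPC_C / r²`, and the largest field wins.

Four kernels are available — linear `⟨x,y⟩+θ`, polynomial `(⟨x,y⟩+θ)^d`,
Gaussian `exp(−‖x−y‖²/σ²)` (note: σ², not 2σ²), sigmoid `tanh(v⟨x,y⟩+r)` —
plus a leave-one-out cross-validation harness, a two-stage hierarchical
pipeline for membrane typing (multi-pass vs rest, then the remaining four
types), seeded synthetic-data generators, and a CLI.

See `docs/methods.md` for the mathematical details and conventions.

## Worked example

Generate 120 synthetic protein sequences (4 classes × 30, classes biased
toward hydrophobic / charged / small-polar / aromatic residues), featurise
them, and evaluate the `datasetA` preset (KPCA, Gaussian σ=0.5, 3-NN) by
leave-one-out cross-validation:

```bash
kernelfield synth --spec demo_spec.yaml --out-dir demo
# demo_spec.yaml:
#   generator: biased_proteins
#   seed: 11
#   n_per_class: [30, 30, 30, 30]
#   length_range: [200, 400]
kernelfield featurize --fasta demo/sequences.fasta --labels demo/labels.tsv \
                      --out demo/features.csv
kernelfield loocv --features demo/features.csv --preset datasetA \
                  --out-prefix demo/run
```

which prints

```
wrote demo/sequences.fasta, demo/labels.tsv
wrote 120 x 20 feature table to demo/features.csv
running LOOCV over 120 folds ...
overall LOOCV success rate: 1.0000
  class 0: 1.0000
  class 1: 1.0000
  class 2: 1.0000
  class 3: 1.0000
```

Every one of the 120 held-out sequences was assigned its true class: with
a +0.05 frequency bias on five residues and 200–400 residues per sequence,
the four class clouds are cleanly separated in composition space. The run
writes `run.report.tsv` (per-class and overall rates), `run.report.json`
(full confusion matrix and config echo), `run.coords.tsv` (the 3-D kernel
coordinates, ready for any plotting tool), and a manifest sufficient to
re-run the command bit-identically.

Other presets: `datasetB` (GDA, polynomial d=4 θ=1.5, intensity model) and
the membrane pair `membrane-stage1` / `membrane-stage2`, used together in
a hierarchical config:

```yaml
stages: [membrane-stage1, membrane-stage2]
stage1_target_class: 2   # the class peeled off by stage 1
```

The same machinery is available as a library
(`kernelfield.fit_kpca / fit_gda / loocv / intensity_predict / ...`); the
CLI is a thin binding over it.

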