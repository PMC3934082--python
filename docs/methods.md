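# Methods

`sparsemc` detects clustered microcalcifications (MCs) in mammogram-like
image patches.  A microcalcification is a small calcium deposit that appears
as a bright spot roughly 0.1–1 mm across; a cluster of three or more such
spots within a ~5 mm × 5 mm region is an early radiological sign of breast
cancer.  The package implements two closely related detectors built on
sparse coding over a labelled patch vocabulary, together with the synthetic
phantom and evaluation harness used to exercise them.

## Sparse coding

Training patches are vectorized and collected as unit-norm columns of a
"vocabulary" matrix **A** ∈ R^{d×n} with per-column labels (+1 MC, −1 normal
tissue).  A test vector **y** (also unit norm) is coded by solving

    min_c  ‖A c − y‖₂² + λ‖c‖₁

The solver is a primal log-barrier interior-point method on the bound-split
reformulation (−u ≤ c ≤ u), with dense Cholesky inner Newton solves and a
Schur-complement elimination of the u-block.  At every iterate a duality gap
is computed from a scaled dual-feasible point, so each returned code carries
a certificate of near-optimality; the solver stops when
gap ≤ `gap_tol`·(1+|J|).  The barrier weight follows the standard
`t ← max(μ·min(2n/gap, t), t)` update with μ = 2.  The solver is
deterministic and flags (never hides) non-convergence.

Numerical notes: the Schur system receives a tiny ridge (`ridge`, default
1e−10); the case λ ≥ 2‖Aᵀy‖∞ is detected at the first gap check and returns
the exact zero solution without iterating.  Correctness is arbitrated in the
tests by an independent route: L-BFGS-B on the non-negative split
reformulation c = p − q, and the soft-threshold closed form for orthonormal
dictionaries.

Defaults: λ = 0.01 (library), `gap_tol` = 1e−4 (relative), `max_iter` = 500.
The detection pipeline overrides λ to 0.1 (below).

## MCs-SRC: classification by class-restricted residual

For each class i the class-restricted code δ_i(c) keeps only coefficients of
that class's columns, and the residual r_i(y) = ‖y − A δ_i(c)‖₂ measures how
well class i alone reconstructs the test vector.  The decision is
argmin_i r_i(y); ties go to +1 (the screening-sensitive choice).  The
continuous ROC score is r₋₁ − r₊₁, the natural monotone statistic of the
argmin rule.  There is no training step: the vocabulary is the model.

The method is exact under its structural assumption: when the two classes
span independent subspaces and test samples lie in their class span,
classification is perfect for small λ (verified on the noiseless
subspace fixture, dims 50, rank 5/class).

## TWSVM: twin support vector machines

The second detector feeds sparse codes into a twin SVM, which fits two
nonparallel planes, each close to its own class in least squares and pushed
to ≥ unit distance from the other:

    TWSVM1: min ½‖Aw⁽¹⁾+e₁b⁽¹⁾‖² + c₁e₂ᵀq  s.t. −(Bw⁽¹⁾+e₂b⁽¹⁾)+q ≥ e₂, q ≥ 0

and symmetrically for plane 2.  With H=[A e₁], G=[B e₂] the Wolfe duals are
box-constrained QPs in α ∈ R^{m₂} (0 ≤ α ≤ c₁) and γ ∈ R^{m₁} (0 ≤ γ ≤ c₂),
with primal recovery u = −(HᵀH)⁻¹Gᵀα and v = +(GᵀG)⁻¹Hᵀγ.  The sign of v is
fixed so class +1 patterns have positive margin with respect to plane 2, the
orientation the TWSVM2 constraint implies; the KKT test verifies this
orientation directly.  HᵀH and GᵀG are only positive
semidefinite, so both inverses carry a trace-scaled ridge
ε·(1 + tr(M)/k)·I with ε = `twsvm.ridge` = 1e−7 by default.

The box QPs are solved by L-BFGS-B followed by an active-set polish that
solves the free-variable KKT system exactly; correctness is defined by an
exhaustive active-set enumeration oracle and a KKT-residual certificate in
the tests, not by the algorithm choice.  A new sample goes to the class of
the nearer plane, distance |xᵀw+b|/‖w‖ (normalization toggleable via
`twsvm.normalize_distance`); the margin score d₂ − d₁ feeds the ROC.

Kernel mode: the standard operating point is an RBF kernel
K(x,z) = exp(−‖x−z‖²/(2σ²)) with σ = 15 and c₁ = c₂ = 1000 (the defaults).
The same dual algebra runs on kernel-mapped patterns H = [K(A,Cᵀ) e₁],
G = [K(B,Cᵀ) e₂] with C = [A;B] retained as the reference matrix, giving
surfaces K(xᵀ,Cᵀ)w + b = 0; plane-normal magnitudes use the kernel metric
√(wᵀK(C,C)w).  This is the kernel-surface generalization standard in the
TWSVM literature.

## The detection pipeline (TWSVMs-SR and MCs-SRC on patches)

Raw m×m patches (m = 115 px ≈ 5.0025 mm at the 43.5 µm DDSM pitch) pass
through a feature chain that is this package's own design — mammography CAD
preprocessing (artifact removal, background flattening, microcalcification
enhancement) is only loosely standardized, so the stages here are minimal,
deterministic and fully specified:

1. **Sharp channel** — difference-of-Gaussians band-pass, σ = 1 px vs 6 px,
   tuned to the 2.3–23 px spot scale; suppresses the tissue background and
   pixel noise while keeping calcification-scale structure.
2. **Density channel** — the same band-pass, half-wave rectified (bright
   responses only) and smoothed with σ = 16 px.  This turns the discrete
   spot pattern into a spatial density, so two patches whose clusters
   roughly coincide are close in Euclidean distance even when individual
   spot positions differ — the geometry a distance-based (RBF) classifier
   needs.
3. Each channel is 2-D block-mean downsampled by a factor of 5 (23×23
   values), centered, unit-normalized, concatenated, and the joint vector
   normalized again.  The downsampling is the linear compression transform
   D of the coding algorithm; it keeps each l1 solve small.

The pipeline codes with λ = 0.1 rather than the library default 0.01:
sparser codes concentrate on genuinely similar vocabulary columns and are
markedly more class-specific, which benefits both the residual rule and the
code-feature classifier.

Two composition details were found to be load-bearing:

* **Leave-self-out encoding.**  Training patches for TWSVMs-SR are coded
  against the vocabulary *minus their own column*.  Coding a patch against
  a vocabulary containing itself returns a one-hot self-representation
  (coefficient ≈ 0.995 on its own column) that carries no transferable
  structure; a classifier trained on such codes is perfect on the training
  set and at chance on held-out data.
* **Code scale.**  Unit-norm inputs give codes with pairwise distances ≤ 2,
  against which the fixed RBF width σ = 15 is inert (K ≈ 1 everywhere, the
  kernel degenerates to near-linear).  Codes are therefore multiplied by a
  fixed constant `pipeline.code_scale` = 30 before the twin SVM, placing
  typical code distances in the kernel's informative range.  This is
  ordinary feature conditioning: a fixed kernel width presupposes a feature
  scale.

## Synthetic phantom

The generator emulates DDSM-like patches, not anatomy:

* **Background** — base grey level 800 (12-bit range), stationary correlated
  texture (white noise smoothed at 8 px correlation length, rescaled to
  sd 40), plus a random planar gradient of amplitude 30 — the minimum
  structure that makes background flattening meaningful.
* **Spots** — Gaussian profiles (FWHM = diameter) rather than hard disks, to
  avoid aliasing at 2.3 px diameters and give a single contrast parameter.
  Diameters are log-uniform in 0.1–1 mm (small calcifications dominate real
  clusters); peak amplitude is `contrast_rel_sd` × texture sd, default 8.
  Centers snap to pixel centers and are rejection-sampled for pairwise
  separation ≥ 2.8·σ, so each peak reads back its configured amplitude.
* **Clusters** — 3–6 spots uniformly placed in a 3 mm box; positive patches
  contain exactly one cluster, centered with uniform jitter bounded so the
  cluster never clips; labels are re-derived through the ≥ 3-spots-in-window
  counting rule rather than trusted from construction.

Every generator is a pure function of (spec, seed).  What the phantom does
*not* model: anatomical tissue structure, spot morphology classes
(annular/punctiform/dusty/vermicular typing), malignancy grades, scanner
artifacts.  Passing tests therefore demonstrate the correctness and
statistical behaviour of the method on controlled spot-in-texture imagery,
not clinical performance.

## Evaluation

ROC curves sweep thresholds over unique scores (descending, ties grouped);
Az is the trapezoidal area, and an independent Mann–Whitney pair-counting
oracle (Az = (concordant + ½ ties)/(n₊·n₋)) must agree to 1e−12.
Sensitivity/specificity use the score ≥ threshold → +1 rule.  Stratified
k-fold (default k = 5) and stratified 75/25 splitting are seeded.  The
stability experiment holds out a fixed test pool and, for each of `repeats`
(default 50) × a training-fraction grid (default 1.00 down to 0.05 in steps
of 0.05, 20 rounds), retrains on a stratified subsample and aggregates
mean ± sd; per-repeat seed streams make the first k repeats invariant to the
total repeat count.

## Problem sizes and experiment defaults

The generator's dataset default (3000+3000 blocks, m = 115, 75/25 split)
matches a full DDSM-scale study.  The package's own experiments and acceptance
script run a scaled-down analogue — 200+200 patches for the main detection
experiment and 100+100 per level of a 4-level contrast ladder
({0.5, 2, 8, 32} × background sd, TWSVMs-SR, fixed seeds) — sizes chosen so
the full suite completes in minutes on one core while keeping Az estimates
stable to a few percent.

## Known limitations

* The residual formula is implemented with the class-restricted code
  δ_i(c); the class-independent variant (no δ_i) cannot discriminate and is
  not offered.
* The interior-point solver targets dictionaries up to a few thousand
  columns (dense Cholesky inner solves); it is not tuned for very large or
  sparse dictionaries.
* The box-QP active-set polish assumes a PSD quadratic term, which the dual
  construction guarantees.
* With c₁ = c₂ = 1000 the twin SVM is effectively hard-margin; on very noisy
  code features its generalization relies on the density channel making
  classes geometrically compact.
* The CLI's whole-image detection map scores sliding windows independently;
  no non-maximum suppression or cluster-level grouping is applied.
* Scoring a patch that is itself a vocabulary entry is degenerate: it codes
  to a one-hot self-representation, so TWSVMs-SR scores of the *training*
  dataset are not meaningful (training-time codes use leave-self-out
  encoding precisely for this reason).  Evaluate on held-out patches.
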