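# Methods

This note records the models, conventions and numerical choices behind
`polarlr`, in the spirit of a package methods appendix: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## Forward model and reconstruction

The instrument model is an ideal transmission Mueller polarimeter.  The
polarization state generator (PSG) is a linear polarizer followed by a
quarter-wave plate (QWP); the analyzer (PSA) is a QWP followed by a polarizer.
Optics are ideal: polarizers have infinite extinction, QWPs exactly
quarter-wave retardance and no diattenuation.  For acquisition state *k* the
detected intensity is

    I_k = a_kᵀ M s_k = Σ_ij (a_k)_i (s_k)_j m_ij ,

linear in the 16 elements of the pixel's Mueller matrix `M`.  The default
protocol is 24 frames: both polarizers fixed at 0°, PSG QWP ∈
{0°, 30°, 60°, 90°, 120°, 150°}, PSA QWP ∈ {0°, 30°, 60°, 120°} (all pairs).
The induced 24×16 design matrix has rank 16 and condition number ≈ 17, so the
per-pixel least-squares solve (one pseudo-inverse per manifest, applied to all
pixels at once) is well posed.  The protocol is serializable configuration,
not a constant: any published angle set with a rank-16, well-conditioned
design can be substituted.  An identity ("air") sample reconstructs to the
identity matrix to ~1e-14, which doubles as the calibration sanity check.
Frames are assumed co-registered upstream; the stack reader warns when the
intensity centroid drifts by more than 2 px between frames.

Intensity convention: an unpolarized unit-intensity input yields a generated
Stokes vector of intensity 0.5 (the polarizer's unavoidable loss), and an
analyzer aligned with a fully polarized beam passes it entirely; aligned
polarizers around an identity sample therefore detect intensity 0.5.

## Polarimetric parameters

All features are computed on the m00-normalized matrix so illumination scale
cancels.

**Lu–Chipman polar decomposition** `M = M_Δ · M_R · M_D`, computed
sequentially: `M_D` from the first row (diattenuation vector `D⃗`, 3×3 block
`√(1−D²) I + (1−√(1−D²)) D̂D̂ᵀ`); `M' = M M_D⁻¹`; the depolarizer block
`m_Δ` is the symmetric square root of `m' m'ᵀ` (eigenvalues clipped at zero
before the square root, overall sign from `det m'`); `m_R = m_Δ⁻¹ m'`.
Scalars (4×4 indices 0-based):

* total retardance `R = arccos(tr(M_R)/2 − 1)` ∈ [0, π];
* linear retardance
  `δ_L = arccos(√((M_R[1,1]+M_R[2,2])² + (M_R[2,1]−M_R[1,2])²) − 1)`;
* optical rotation `ψ = ½·arctan2(M_R[2,1]−M_R[1,2], M_R[1,1]+M_R[2,2])`,
  so a pure circular rotator by angle θ yields `ψ = ±θ` and a linear
  retarder yields 0;
* depolarization power `Δ = 1 − |tr(m_Δ)|/3` ∈ [0, 1].

Arccos arguments are clipped to [−1, 1] against floating-point overshoot.  A
diattenuation at the singular limit `D → 1` (ideal polarizer) would make
`M_D` non-invertible; `D` is clipped to 1−1e-6 and the result carries a
`singular_diattenuator` flag rather than NaNs.  A rank-deficient depolarizer
block falls back to a pseudo-inverse with a `singular_depolarizer` flag.

**Mueller-matrix-transformation (MMT) parameters** use the two central
linear-diagonal elements (the 1-based `m22, m33` of the MMT literature,
0-based `[1,1], [2,2]` here): `b` is their mean, `t1 =
√((m22−m33)² + (m23+m32)²)/2`, and the normalized anisotropy
`A = 2·b·t1/(b²+t1²)` (defined as 0 when `b = t1 = 0`).  With this indexing
`b`, `t1`, `A` are invariant to in-plane sample rotation — their defining
property — and `A = 1` for a pure linear retarder or diattenuator.  The
rotation-invariance property test pins this choice down: using the 0-based
elements `[2,2], [3,3]` instead changes the values by order 1 under rotation.

**Feature vector** (order fixed, serialized as the CSV header): the 16
normalized elements `m00..m33` plus `{D, P_L, Δ, R, δ_L, ψ, b, t1, A}`.
Decomposition warnings surface as flags on the record; outputs are always
finite.

## ROI aggregation

Each ROI is an axis-aligned rectangle (0-based, half-open) in Mueller-image
coordinates.  The 16 elements are reduced by an element-wise **median** over
the ROI's unmasked pixels (NaN pixels excluded whole; even counts use the
mean of the two middle values), and the 25 features are computed on that
single median matrix.  Computing per-pixel features first and taking their
median gives different numbers on heterogeneous tissue; a test constructs
such a case to document that the implemented order is median-first.  No
pixel-level physical-realizability filtering is applied before the median
(an optional flag exists but defaults off, since the median already resists
outlier pixels).

## Classification workflow

* **Folds**: patients, not ROIs, are the cross-validation unit.  Within each
  label class patients are shuffled and chunked, and each class's larger
  chunks are assigned to the currently smallest folds, so fold sizes differ
  by at most one patient while keeping the class mix as even as counts allow
  (with 27+8 patients and k=5: folds of 7, minority counts 2/2/2/1/1).
  Leakage is asserted exhaustively on every plan.
* **Learners**: library defaults with a fixed seed, no tuning loop.  Linear
  models (logistic, LDA, linear SVM) are standardized; tree ensembles
  (random forest, XGBoost with gain importances) are not.  Importances are
  absolute coefficients for linear models, impurity/gain importances for
  ensembles.
* **Patient call**: a patient is called LR when ≥ 50 % of their test-set
  ROIs are predicted LR.  The exact-tie case resolves to LR — the
  clinically conservative choice — and the threshold is configurable.
* **Metrics**: per fold, 2×2 confusion matrices at ROI and patient level;
  sensitivity, specificity and total accuracy with zero-denominator cases
  reported as NaN-with-flag; ROI-level ROC/AUROC (tie-corrected, equal to
  the normalized Mann–Whitney statistic, verified against an O(n²)
  pair-count oracle); fold curves vertically averaged on a fixed 101-point
  FPR grid.  Reports carry mean ± SD over folds and the fold-averaged
  (possibly fractional) confusion matrices.
* **Feature ranking**: each model's importance vector is min-max normalized
  to [0, 1]; the aggregate is the mean across models; the top-k (default 5)
  are selected with deterministic name-order tie-breaking.  Constant vectors
  normalize to zeros and are flagged.
* **Outlier elimination**: greedy leave-one-patient-out.  Each round scores,
  for every remaining patient, the cohort without that patient by pooled
  out-of-fold AUROC averaged over three fixed grouped-CV partitions; the
  best removal is applied if it improves the score by more than `tol`
  (default 0.005), up to `budget` removals (default 3).  Partitions are held
  fixed across candidates so comparisons measure the patient, not fold
  reshuffling; averaging over three partitions keeps one unlucky split from
  driving removals.  Exhaustive subset search over patients is combinatorially
  infeasible and deliberately not attempted.
* **Workflow**: optional elimination → all-features CV → ranking → top-k CV
  → optional T-stage-3 subgroup re-run.  Identical seeds give bit-identical
  reports.

## Synthetic cohorts

The generator emulates the *statistical* structure the analysis assumes, not
image content: per-pixel Mueller matrices are composed as
`M_Δ(Δ) · M_R(δ, θ) · M_D(D, θ)` (diattenuator axis aligned with the
retarder fast axis — both arise from the same fibers), with Gaussian
class → patient → ROI → pixel hierarchies for δ, D, Δ, clipped to physical
ranges, and uniform per-ROI fiber orientation with 10° per-pixel wobble.

Defaults encode the working hypothesis that mature stroma (no-LR) is more
birefringent: no-LR δ = 0.80 rad, D = 0.12, Δ = 0.30 vs LR δ = 0.50 rad,
D = 0.06, Δ = 0.45 (sd tiers 0.10/0.05/0.15, 0.03/0.02/0.04, 0.05/0.03/0.06
respectively).  The magnitudes are configuration, not claims about tissue.
Cohort shape defaults to 27 no-LR / 8 LR patients with 3–14 ROIs per patient
and 2500 pixels per ROI; `study_roi_counts()` pins per-patient counts to the
exact totals 263 + 70 = 333 ROIs.  Planted "outlier" patients are majority
class (no-LR) patients with their labels flipped to LR, recorded in the
ground-truth sidecar.  A `null_class_params()` preset (identical classes) and
a `separable_class_params()` preset (large δ/D gap, tightened sds) support
calibration and power checks.

Because classes differ only through these smooth parameter shifts, passing
tests demonstrate that the pipeline recovers planted signal and stays
calibrated under the null — not that real stroma carries that signal, nor
that the ideal-optics model matches any particular instrument.  Real tissue
adds fiber texture, spatially correlated noise, registration error and
instrument polarization artifacts that the generator does not model.

## Problem sizes and degenerate inputs

Test and acceptance runs use scaled problem sizes chosen to exercise every
code path in minutes on one CPU: 100–200 random physical matrices for
round-trip and containment properties, cohorts of 20–35 patients with
150–2500 pixels per ROI, and a study-shaped 333-ROI cohort for the full
workflow.  Degenerate inputs are contracts, not accidents: single-class
training folds, empty ROIs, rank-deficient manifests, all-zero confusion
matrices and infeasible elimination budgets all raise errors naming the
offending object; undefined metric ratios return NaN with a flag.

## Known limitations

* Ideal-optics calibration only (air identity); no instrument Mueller-matrix
  error compensation.
* Isotropic depolarizer in the generator and decomposition closed forms;
  anisotropic depolarization appears only through generic random matrices.
* The greedy elimination is order-dependent by construction and can stop
  early when a removal's benefit falls below `tol`.
* With 8 LR patients, patient-level sensitivity rests on 1–2 positives per
  fold; its fold-to-fold spread is intrinsically large.
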