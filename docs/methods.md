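# Methods

## The model

P-glycoprotein (P-gp) is a promiscuous efflux transporter: structurally
unrelated inhibitors bind a flexible protein that presents several distinct
binding-site conformations. A single 3D pharmacophore — one fixed
arrangement of chemical features — cannot describe such a target. The
pharmacophore-ensemble / support-vector-machine (PhE/SVM) scheme implemented
here therefore keeps a small ensemble of k distinct hypotheses, each standing
in for one protein conformation (or a family of similar conformations), and
lets a regression stage arbitrate among them:

1. **Conformer ensembles.** Each compound is expanded into its low-energy
   conformations (at most 255 within 83.7 kJ/mol ≡ 20 kcal/mol of the
   minimum). Generation is a pluggable contract; the default backend embeds
   with RDKit ETKDG distance geometry, minimizes with MMFF94 (UFF fallback),
   deduplicates at 0.5 Å heavy-atom RMSD and sorts by relative energy. The
   downstream machinery consumes only the resulting ensembles, so any
   conformer generator with the same contract can be substituted.

2. **Feature perception.** Hydrogen-bond donors (N/O/S bearing an H,
   anchored on the heavy atom), hydrogen-bond acceptors (N or O with an
   available lone pair; amide and aniline-type nitrogens and nitro oxygens
   excluded, pyridine-type aromatic N included) and hydrophobes (all-carbon
   ring centroids, halogen-bearing carbons, and maximal connected clusters
   of ≥ 3 aliphatic carbons with no heteroatom contact). The
   SMARTS-expressible patterns ship as an editable text file
   (`phesvm/data/feature_patterns.txt`); the ring/cluster hydrophobes are
   procedural because maximal connected components are not a SMARTS concept.
   Directional information is deliberately reduced to point features, and
   ring-aromatic is not a separate kind (aromatic rings are hydrophobes):
   the fit function below is distance-only.

3. **Fit.** A hypothesis is 3–10 typed feature spheres, each with a
   position, tolerance radius tol (default 1.6 Å) and weight w. For an
   injective kind-compatible mapping of hypothesis points to ligand
   features, the mapped features are superposed onto the hypothesis by
   least-squares rigid superposition (Kabsch, proper rotations only;
   collinear point sets are rejected), and

       fit = Σ_mapped  w_i · max(0, 1 − (d_i / tol_i)²)

   with d_i the residual displacement. Missed points (up to `max_misses`,
   default 1) contribute zero, so 0 ≤ fit ≤ Σ w. The search over conformers
   and mappings is exact enumeration in deterministic order, with a
   combinatorial cap (10⁵ mappings per conformer) beyond which ligand
   features of the most numerous kind are greedily pruned; drug-sized
   feature counts never reach the cap in practice. Ties break by lower
   mapped RMSD, then lower conformer index, then lexicographic mapping.
   Each hypothesis carries a linear activity map, pEC50 = α + β·fit.

4. **Induction (simplified).** Candidate hypotheses are generated in three
   transparent phases. *Construct*: 3–5-point arrangements are drawn from
   the feature sets of the most active training compounds (top quartile by
   default) and kept when every other top-active compound can realize the
   arrangement on some conformer with pairwise distances matching within
   ε_d = 1.5 Å. *Subtract*: candidates achieving ≥ 50 % of their maximum
   fit on at least half of the least-active compounds are discarded.
   *Optimize*: simulated annealing over point positions, tolerances
   (1.0–3.0 Å) and weights (0–3) maximizes the training r² of the
   calibrated estimates, keeping the best state seen (seeded,
   deterministic). This is an intentionally simple stand-in for proprietary
   commercial induction engines; its job here is to produce plausible,
   well-calibrated candidates, and its planted-arrangement recovery is
   tested directly.

5. **Calibration.** (α, β) per hypothesis by ordinary least squares of
   observed pEC50 on best-fit values; a negative slope is clipped to zero
   with a warning (an anti-predictive hypothesis is treated as
   uninformative rather than inverted), and constant fits are an error.

6. **Ensemble + SVR.** The descriptor vector of a compound is the k-vector
   of per-hypothesis activity estimates (k = 3 by default). Ensemble
   members are chosen greedily by training r² with a redundancy filter
   (pairwise prediction correlation ≤ 0.95). An ε-SVR (or ν-SVR) with RBF
   kernel is trained on the column-standardized descriptor matrix
   (scikit-learn / libsvm). Reference hyperparameters are γ = 0.008, C = 4,
   ε = 0.001; a systematic grid search (C ∈ 2⁻⁴…2⁸, γ ∈ 2⁻¹⁰…2²,
   ε ∈ {0.001, 0.01, 0.1}, ν ∈ {0.2, 0.4, 0.6, 0.8}) selects parameters by
   10-fold cross-validated RMSE, ties toward smaller C, larger ε, smaller
   γ. Folds are stratified by activity decile from a seeded RNG (default
   seed 20120316), which stabilizes q² at n ≈ 31.

   Standardizing before the RBF kernel makes γ transferable across
   descriptor scalings; note a useful exact invariance: per-column affine
   maps with non-zero slope leave the standardized matrix unchanged up to
   column sign, and the RBF kernel is sign-invariant, so predictions do not
   depend on the per-hypothesis (α, β) except through the degenerate β = 0
   clip.

7. **Validation.** With residual e = observed − predicted:
   r² (squared Pearson), RMSE = √mean e², MAE = mean|e|, Δ_max = max|e|,
   and s = √(mean e² − (mean|e|)²) — the population SD of the absolute
   residuals, so s² + MAE² = RMSE² identically. Internal validation is
   q² = 1 − PRESS/SS from out-of-fold predictions. External validation uses
   the through-origin criteria (slopes k = Σy·ŷ/Σŷ², k′ = Σy·ŷ/Σy²;
   determination coefficients r0², r0′²) and Roy's
   r_m² = r²·(1 − √max(0, r² − r0²)) (clamped to stay real when r0² > r²).
   Acceptability flags: r² > 0.6; q² > 0.5; (r² − r0²)/r² < 0.1 with
   0.85 ≤ k ≤ 1.15; |r0² − r0′²| < 0.3; r_m² > 0.5. Display rounding is
   half-up at 2 decimals; computation is full precision.

8. **Chemical space / applicability domain.** Eight physicochemical
   descriptors (MW, Crippen logP, TPSA, HBD/HBA counts, rotatable bonds,
   rings, heavy atoms) are standardized and decomposed by SVD-PCA (loading
   signs fixed by making each component's largest-magnitude entry
   positive). A compound is out-of-domain when its diagonal-Mahalanobis
   distance in the first three components exceeds the 0.99 quantile of the
   training distances. The distance quantile replaces a convex-hull test,
   which degenerates at n ≈ 31 in ≥ 3 dimensions.

## Synthetic data: what it emulates and what it does not

The generators in `phesvm.synthetic` produce ligands as bare 3D
feature-point sets — no molecules — so the alignment, induction, ensemble
and regression stages can be tested against exact planted ground truth.

* `make_hypothesis`: uniform points in a 10 Å box, pairwise ≥ 2 Å,
  tolerance 1.6 Å, unit weights; compositions default to a donor plus
  hydrophobes. The ensemble tests use the compositions 1 HBD + 4 HP,
  1 HBA + 1 HBD + 2 HP and 1 HBD + 3 HP.
* `make_ligand_set`: matching ligands are the hypothesis points jittered by
  an isotropic Gaussian (default sd 0.3 Å) under a random rigid transform,
  plus 0–3 distractor features; decoys are fully random feature sets.
  Activities are α + β·fit + N(0, noise_sd) with the true fit computed by
  the exhaustive oracle.
* `make_ensemble_dataset`: 130 ligands (31/88/11 partition shape), each
  planted on one of three hypotheses round-robin, with activity an
  equal-weight linear mix of its fits to all members plus N(0, 0.2).

Passing tests on this data demonstrate that the machinery inverts its own
generative model — alignment finds planted arrangements, calibration
recovers (α, β) within sampling error, the tuned SVR reaches the generative
noise floor on held-out compounds (the end-to-end check asserts hold-out
RMSE ≤ 1.5 × noise sd). They do **not** demonstrate chemistry: synthetic
features have no perception error, no conformational strain, no activity
cliffs, and the planted linear mixing makes ensemble members jointly —
though not necessarily marginally — predictive. Real-data behaviour of the
perception and conformer stages is covered separately by molecule-level
tests on known functional groups.

## Numerical choices and degenerate inputs

* Superposition requires ≥ 3 non-collinear points (second singular value
  > 1e−8 of the first); reflections are never allowed (det +1 enforced via
  the sign-corrected SVD).
* Fit ties are resolved by the documented deterministic key; the
  brute-force oracle implements the same key through an independent code
  path (itertools enumeration + SciPy `align_vectors`).
* EC50 values are converted to pEC50 = −log10(EC50 in molar); duplicate
  records average in log space (the modelled quantity; for the "very close"
  duplicates this averaging is intended for, linear and log averaging agree
  to rounding). Conflicting partition labels for one id are a hard error.
* No-fit compounds (no ≥ 3-point kind-compatible mapping) receive the
  hypothesis intercept as their estimate and are flagged; the flag
  propagates to predictions.
* Zero activity variance, constant descriptor columns and constant fits
  raise errors rather than returning NaN statistics; constant descriptor
  columns in PCA are dropped with a warning.
* Grid-search and q² fold assignments derive entirely from the seed;
  retraining with identical inputs is bit-reproducible (libsvm is
  deterministic).

## Problem sizes

Default test and acceptance runs use 130 synthetic compounds (31 train,
88 test, 11 outlier), three ensemble members, 10-fold cross-validation, a
507-point default hyperparameter grid, 500-instance oracle-equivalence
sweeps and 31-compound induction runs. These sizes exercise every code
path at the scale of the target application while keeping a full run in the
low minutes on one CPU.

## Known limitations

* The induction module is a simplified, documented stand-in: it recovers
  planted arrangements and calibrates well, but it does not reproduce any
  commercial cost function, and no claim is made that it would re-derive a
  published hypothesis from its original training set.
* Feature perception uses a fixed, editable pattern dictionary; exact
  feature counts on arbitrary chemistry depend on that dictionary and will
  differ from other software's feature definitions.
* Excluded volumes, directional (vector) features, flexible on-the-fly
  fitting, ionizable feature kinds, tautomer and stereoisomer enumeration
  are out of scope; compounds with ambiguous stereochemistry should be
  rejected upstream rather than enumerated.
* The applicability-domain flag is a distance heuristic in three principal
  components, not a statistical guarantee of prediction reliability.
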