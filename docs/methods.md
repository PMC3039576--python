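# Methods

## Model

`gotlm` classifies proteins into subcellular locations with a one-vs-one
multiclass SVM over a single precomputed kernel, built as a convex
combination of five Gaussian channel kernels:

- **AA** — amino-acid composition: 20 relative frequencies over the standard
  alphabet ACDEFGHIKLMNPQRSTVWY.
- **diAA** — di-peptide composition: 400 overlapping-dimer frequencies.
- **P / F / C** — binary indicator vectors over the biological-process,
  molecular-function and cellular-component GO terms observed in the
  training set.

Each channel uses K_e(x, y) = exp(−γ‖x−y‖²) with one γ shared across
channels, and the fusion weights are estimated from the data (below). The
model assumes single-location proteins, flat GO terms (no ancestor
propagation through the ontology graph), and that annotation noise — terms
transferred from homologs with genuinely different localization — behaves
like label-consistent feature noise the soft-margin SVM can absorb.

## Feature construction

Compositions are frequencies rather than raw counts, which makes the
Gaussian length scale independent of sequence length. Ambiguity letters
(B, Z, X, U, O, J) are excluded from numerator and denominator rather than
remapped — the simplest defensible rule. A sequence with no standard residue
produces an all-zero vector and a warning; a length-1 sequence has no
dimers and an all-zero diAA row. The alphabet and dimer orders are frozen
constants so serialized models are portable.

GO vocabularies are the sorted unique terms of each aspect **in the training
partition only**. At prediction time, terms absent from the stored
vocabulary are dropped and counted (logged), never retrained into the model;
a protein whose terms all drop is classified from its remaining channels. An
aspect with no training terms yields an empty vocabulary whose kernel
degenerates to all-ones (zero distances); this is deliberately a warning,
not an error, so partially annotated datasets still train, and the
uninformative channel's weight collapses to zero in the weighting step.

## Kernel-weight estimation

Given square train kernels K_AA … K_C and cvK ∈ {3, 5, 10}, each channel is
scored by cvK-fold cross-validation of a single-kernel SVM: the cvK held-out
folds pool into one confusion matrix M, from which

- SE = tr(M) / ΣM (identical to overall accuracy), and
- MCC = (pq − rs)/√((p+r)(p+s)(q+r)(q+s)), where p, q, r, s sum the
  per-class one-vs-rest TP/TN/FP/FN counts,

and the weight is w_e = SE_e·MCC_e / Σ_c SE_c·MCC_c. Negative products are
clamped to zero before normalizing: the fused kernel must stay PSD, and a
worse-than-random channel should contribute nothing rather than a negative
weight. If every product is zero the weights fall back to uniform with a
warning. Folds are plain random equal-size splits (no stratification); all
channels share one fold assignment so identical kernels receive identical
scores. The single-channel SVMs reuse the candidate (γ, C) of the enclosing
grid point, which avoids a second nested grid and keeps the cost linear in
the number of channels.

## Training, selection and evaluation protocols

`train()` grid-searches cvK ∈ {3, 5, 10}, γ ∈ {2⁻¹, 2⁻², 2⁻³, 2⁻⁴},
C ∈ {2¹ … 2¹¹} (any non-empty subsets may be configured). For each grid
point the weights are estimated on the full training set, and the fused
SVM's internal-CV overall accuracy over the same cvK folds is the selection
metric. Ties break toward the smallest C, then the largest γ, then the
smallest cvK — favouring smoother, less complex models. The winner's weights
and SVM are refit on all training data.

Folding follows the equal-size rule: a seeded permutation cut into K
contiguous blocks of ⌊n/K⌋, with the n mod K remainder appended to the last
fold (for K = 5, the last part has 0–4 extra examples). `cross_validate()`
runs the full `train()` — vocabularies, weights, grid — inside each outer
training partition, touching the held-out fold only for prediction, and
pools the K test folds into one confusion matrix. `holdout_evaluate()` is
the single fixed-partition variant. Per-class specificity is reported as
precision p_l/(p_l+r_l) — the dominant convention in the localization
literature — sensitivity as recall, and per-class MCC as the one-vs-rest
binary Matthews coefficient; degenerate denominators report 0 with an
`undefined` flag.

Masking channels (`ModelConfig.channels`) removes them from weight
estimation, which is exactly equivalent to forcing their weight to zero and
renormalizing over the rest — the construction used for ablation studies.

The multiclass engine is libsvm's one-vs-one voting via
`sklearn.svm.SVC(kernel="precomputed")`; vote ties resolve toward the class
earliest in the sorted class order stored in the model. All randomness flows
from the single configured seed, so identical seed + config + inputs
reproduce reports and prediction files byte-for-byte.

## Synthetic data generator

The generator emulates the statistical structure the model assumes, with
ground truth controllable per channel:

- Each class gets a residue distribution (1−b)·uniform + b·Dirichlet(1) with
  bias b = 0.05 by default — location-dependent composition so weak that the
  sequence channels are near-noise, matching the regime where GO evidence
  dominates sequence evidence.
- Each (aspect, class) pair owns a disjoint pool of 8 synthetic GO
  accessions. A protein is masked entirely for an aspect with the per-aspect
  missing rate; otherwise it emits each own-pool term with the per-aspect
  informativeness (at least one, so the empirical zero-term fraction tracks
  the configured missing rate), plus Binomial(pool, noise) wrong-class terms
  emulating erroneous homology transfer.
- Defaults (the `separable` preset): 5 classes × 50 proteins, lengths
  80–200, informativeness C 0.9 / P 0.6 / F 0.5, missing rates C 0.02 /
  P 0.25 / F 0.45, noise 0.05. The grading C > P > F in both coverage and
  informativeness mirrors the situation in real curated sets, where
  component terms are both best-covered and most directly indicative of
  location; it is the lever that lets tests check the weight ordering
  w_C > w_P > w_F against ground truth.
- Other presets: `noisy` (heavier noise and missing rates), `low-coverage`
  (0.6–0.8 missing everywhere), and `null` (5 × 60 proteins whose reported
  labels are an independent permutation of the latent classes that generated
  the features — accuracy must sit at chance 1/L).

What the generator does **not** emulate: real GO DAG structure (terms shared
between related classes, ancestor terms), sequence homology and motif
structure, multi-location proteins, and realistic class imbalance (available
via per-class counts but not default). Passing tests therefore demonstrate
the machinery — weighting, fusion, protocols — behaves correctly under the
model's assumptions, not field accuracy on curated benchmarks.

## Numerical choices and problem sizes

- Square train kernels are symmetrized exactly ((K+Kᵀ)/2, unit diagonal)
  after computation so downstream eigenvalue checks see clean matrices.
- MCC's zero-denominator convention (→ 0) keeps the weight formula defined
  for useless kernels.
- The acceptance script runs the synthetic study at 250/300 proteins with
  grid subsets cvK {3, 5}, γ {2⁻¹, 2⁻²}, C {2¹, 2⁴, 2⁸} — the package's
  chosen problem size for a complete, reproducible end-to-end demonstration;
  the full canonical grids remain the library defaults.

## Known limitations

- Single-label classification only; multi-location proteins are out of scope.
- No ontology reasoning: a test protein annotated with a parent of a
  training term gets no credit for it.
- One γ for all channels; per-channel bandwidths might suit channels of very
  different dimensionality better but would square the grid.
- The weighting scheme scores channels independently; complementary channels
  that are weak alone but strong jointly are under-weighted relative to
  jointly optimized schemes (semidefinite-programming multiple kernel
  learning), the price of the scheme's simplicity and speed.
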