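# Methods

## Model

The package predicts signed drug–drug interactions (DDIs) from binary
side-effect profiles with the bilinear model `A = F Θ F′`, fitted as a
triple factorization:

1. **Latent interaction space.** `A ≈ A_d A_d′` with `A_d = U_r √Λ_r` from
   the eigendecomposition of the (optionally scaled) adjacency. The signed
   adjacency is indefinite, so `√Σ` over the full spectrum is not real; the
   factorization keeps only the r largest **positive** eigenvalues. Over
   Gram factors `A_d A_d′` of rank ≤ r this is the exact Frobenius-norm
   minimizer (verified in the tests against brute-force enumeration over
   eigen-subsets), and it is the natural reading of a model in which inner
   products between drugs' latent coordinates are positively correlated with
   interactivity. Negative eigenvalues are discarded, not folded in by
   absolute value: folding them in would turn repulsive structure into
   attractive structure.

2. **Feature-to-latent bridge.** `A_d ≈ F B` by SIMPLS partial least
   squares. Ordinary least squares is unusable in the intended regime
   (p ≫ m and collinear side-effect columns); SIMPLS operates on the
   cross-product matrix `S = F′A_d`, extracting L latent factors with
   re-orthogonalization of the loading basis at each deflation step to
   control floating-point drift at large p. **No column centering or scaling
   is applied by default**: the predictor `F_x Θ F′` is a pure quadratic
   form with no intercept, and centering would introduce offsets that
   predictor cannot express. Centering remains available behind
   `simpls_fit(..., center=True)` for experimentation. In the full-rank
   limit (L = p ≤ m, rank(X) = p) SIMPLS coincides with least squares,
   which the tests check against a normal-equations oracle at 1e−8.

3. **Projection matrix.** `Θ = B B′`, symmetric PSD by construction.
   Predictions never materialize Θ: all bilinear products are evaluated as
   `(F_x B)(F_y B)′`, which is mathematically identical and O(p·r) instead
   of O(p²) in memory. Θ is formed (in streamed row blocks) only for the
   significance analysis. Eigenvector sign flips in step 1 propagate through
   B but cancel in Θ and in every prediction; a regression test asserts
   this.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `r` | `"auto"` | latent rank; auto keeps every eigenvalue > 1e−10 × largest, capped at m−1. The rank reflects the topological complexity of the network; fixing a small r acts as extra regularization. |
| `L` | 60 (`fit_tmfuf`); CV examples use 10 | PLS latent factors, the one tunable parameter. Tuned by binary-protocol CV1 over the fixed grid {1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 150}; ties resolve to the smallest L. 60 is the value selected at real-data scale (603 drugs × 9,149 features); desk-scale planted data peaks near 10. |
| `scale_factor` | 1.0 for prediction; 1000 for significance | multiplier on A before solving. With large p the entries of Θ are tiny; scaling by 1000 keeps them away from underflow and makes the significance threshold interpretable. AUC/AUPR and rankings are scale-invariant (covariance verified in tests). |
| `binary_mode` | off | fit on the binarized network (every interaction → +1), used by the conventional evaluation protocol and for binary-only screening. |
| significance `threshold` | 1.0 | paired with `scale_factor = 1000`; the two are meaningful only together and are recorded in output metadata. |

## Cross-validation and protocols

Drugs, not pairs, are held out (cold start). CV1: K rounds, test pairs =
held-out fold × training drugs. CV2: K within-group rounds (pairs inside one
fold) plus K(K−1)/2 between-group rounds (pairs between two folds, training
on the remaining K−2 folds); pairs linking test drugs to training drugs are
blind — excluded from both sides. Fold assignment shuffles drug indices with
the given seed and deals round-robin, so fold sizes differ by at most one.
In every round the model is refitted from scratch on the training-pair
submatrix.

Note a bookkeeping subtlety: within one round, train/test/blind pairs
partition all unordered pairs (asserted exhaustively in tests), and the
held-out drug groups are disjoint across CV1 rounds — but CV1 *test-pair*
sets overlap across rounds by construction: each cross-fold pair {a ∈ fold_i,
b ∈ fold_j} is tested twice, once with a as the new drug and once with b.
The tests assert this exact multiplicity.

The conventional protocol binarizes the training submatrix, labels test
pairs by interaction presence and scores raw confidence. The comprehensive
protocol fits the signed matrix and applies the degressive sign-flip:
degressive test pairs are relabeled positive with score negated, enhancive
pairs keep their score, non-interactions are negatives; the flipped problem
is scored as binary. One consequence worth knowing: scores tied at a nonzero
value are *not* tied after the flip (the flip negates degressive scores), so
tie-convention behaviour (AUC = 0.5) applies to all-zero scores.

AUC is the Wilcoxon rank-sum probability (ties one half); AUPR is the
step-curve sum of precision × recall increments over every distinct
threshold with no interpolation. Both are delegated to scikit-learn
(`roc_auc_score`, `average_precision_score`), which implements exactly these
definitions; the tests verify them against hand-written O(n²) pairwise and
exhaustive-threshold oracles. Every non-interacting pair in a test block is
a negative — no negative subsampling, so AUPR reflects the full class
imbalance. Rounds whose test block lacks a positive (or negative) are
skipped with a warning and excluded from the round average. Repeated
evaluation redraws the partition under seeds seed, seed+1, … and reports
mean, SD and SEM.

## Synthetic data

The generator plants the model's own structure: `F ~ Bernoulli(0.2)` per
cell; `B_true` (p × r_true) sparse with 10% nonzero entries, signs ±1,
magnitudes uniform on [0.5, 1.5] — so the planted Θ is dominated by
near-zero entries with a few large ones for the significance scan to find;
raw scores `S = F B_true B_true′ F′`; two empirical-quantile thresholds on
the off-diagonal scores set so the requested interaction density (default
0.12) and enhancive fraction (default 18710/24114 ≈ 0.776, the class ratio
of a curated real comprehensive-DDI network) are met regardless of feature
density; optional label noise resamples a pair's label uniformly from
{−1, 0, +1}; symmetrize, zero the diagonal. One `numpy` Generator seeded from
the single config seed drives all draws in a fixed order, so datasets are
bitwise reproducible.

What it does *not* emulate: real side-effect co-occurrence semantics,
frequency heterogeneity across drugs (hub drugs), or any pharmacology.
Passing tests show the pipeline recovers planted bilinear structure under
controlled noise; they do not certify real-data accuracy.

Problem sizes used throughout the tests and the reproduction script —
m = 60 drugs, p = 80 features, r_true = 3, K = 5 folds, 10 seeds per noise
level — were chosen as the package's standard desk-scale study conditions;
they keep every experiment in seconds while preserving the p > m regime the
method targets.

## Numerical choices and degenerate inputs

- Eigenvalue retention tolerance 1e−10 × largest; no positive eigenvalue →
  `"no latent structure"` error (e.g. the zero matrix, or a non-positive
  definite all-negative spectrum).
- SIMPLS stops early (with a warning) when the deflated cross-product is
  numerically exhausted, so requesting L beyond the extractable components
  on tiny fixtures degrades gracefully; an all-zero predictor is an error.
- Significance tie-break: equal |θ| resolves by ascending feature-index
  pair, making top-k lists deterministic.
- Diagonal entries: self-pairs are never scored as DDI candidates, are
  excluded from the reconstruction error, and θ_rr self-pairs are excluded
  from the significance report by default (flagged `is_self_pair` when
  explicitly included); the Θ histogram covers the upper triangle including
  the diagonal.
- Duplicate identical edges in input dedupe with a warning; conflicting
  signs for the same pair are a hard error; self-loops are rejected.

## Known limitations

- Cold-start generalization is sample-limited: at the standard desk-scale
  conditions each CV1 round trains on 48 drugs against 80 collinear
  predictors, and mean comprehensive CV1 AUC plateaus around 0.85 even at
  zero noise (scoring with the planted true bilinear form gives ≈0.985, and
  the same pipeline reaches ≈0.95 at m = 120). More drugs, not more tuning,
  is what closes that gap.
- The latent factorization discards the negative spectrum; networks whose
  structure is predominantly "repulsive" (large negative eigenvalues) are
  represented only through what the PSD part captures.
- L is tuned globally (one pass, binary CV1), not nested per round; this
  mirrors standard practice for this model family but mildly optimistic
  relative to fully nested tuning.
- No integration of other feature sources (chemical structure, targets);
  features are a single binary matrix.
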