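# Methods

## Problem and model

`superfelt` predicts binary drug response (sensitive vs. resistant) for
cancer cell lines from three omics layers per drug: gene expression
(continuous), somatic mutation (binary), and copy-number aberration
(continuous or binary). Panels of this kind are heavily imbalanced —
typically ~85% resistant — and have tens of thousands of features for a
few hundred samples, so the model is deliberately shallow and heavily
regularized. Training runs in three independent stages:

1. **Feature selection.** Each layer `X_o` (N x M) is reduced to its
   high-variance columns, `X'_o = F(X_o)` (N x M'), on the assumption
   that near-constant features carry little response-relevant signal.
   The cutoff is chosen by a knee rule on the descending sorted variance
   curve (below).
2. **Supervised embedding.** One encoder per layer,
   `E_O(X'_o) = relu(X'_o W_o)` with `W_o : M' x M̃_o`, is trained with
   the batch-all triplet hinge loss
   `L(a,p,n) = max(d(E(a),E(p)) - d(E(a),E(n)) + alpha, 0)` (Euclidean
   `d`), pulling same-class samples together and pushing opposite-class
   samples at least `alpha` apart. Encoder widths are ordered
   `M̃_expression > M̃_cna > M̃_mutation`, reflecting the layers' relative
   predictive value for drug response.
3. **Classification.** The embeddings are concatenated in the fixed
   order expression + mutation + cna and a single-layer head
   `p = sigmoid(X̂ w + b)` is trained with binary cross-entropy. The
   encoders are frozen during this stage; the package byte-checks this
   independence in its tests.

Ablation modes reuse the same machinery: `expression_only` and `mut_cna`
restrict the active layers; `no_encoder` skips stage 2 and feeds the
selected features directly to the head (the
neural-net-after-feature-selection baseline).

## Elbow rule for the variance threshold

Variances are sorted descending and both axes min-max scaled to [0, 1],
giving a scree-like curve from (0, 1) to (1, 0). The bend is located at
the point farthest (perpendicular distance) from the chord joining the
endpoints. Two profile shapes occur: when the farthest point lies above
the chord (flat plateau, then cliff) it is itself the knee; when it lies
below (the cliff precedes it) the knee is taken as the point just before
it, so the threshold keeps the high-variance plateau only. Ties break
toward the smaller index (fewer features). Collinear or all-equal
profiles have no knee and raise a degenerate-curve error; `fit_mask`
then falls back to keeping every feature. Scaling both axes makes the
choice unit-invariant. A fixed `top_k` per layer can override the rule.
Masks are always fit on the training split of a fold, never globally —
the only leakage-safe reading of per-fold evaluation.

## Triplet mining and loss normalization

Within each mini-batch every valid (anchor, positive, negative) index
triple is enumerated (batch-all mining): for each class, all ordered
same-class pairs (anchor != positive) against every opposite-class
negative, so anchors come from both classes. The reported loss is the
*mean* over triplets rather than the sum: averaging makes the value
invariant to batch composition and rescales gradients uniformly without
changing minimizers. Zero-loss triplets are included in the mean. A
single-class batch yields an empty triplet set (warning, loss 0) and
contributes no gradient. For whole-split evaluation the identical
quantity is computed from the pairwise distance matrix
(`batch_all_loss`) without materializing index triples.

## Optimization and regularization

Both trainable stages use a hand-written Adam (beta1 0.9, beta2 0.999)
with L2 weight decay added to the gradient, mini-batches of 32 by
default, and fan-in-scaled uniform initialization from a seeded
generator. Dropout is applied during training only: to the ReLU output
in the encoders (the only location a single-layer architecture offers)
and to the classifier input. Early stopping monitors validation triplet
loss (encoders) and validation AUC (classifier, matching the protocol's
AUC-based model selection); the best-validation epoch's weights are
returned. The minority class is oversampled to parity once per training
run — indices drawn with replacement, every original sample retained,
majority never duplicated — rather than per epoch, so validation
comparisons across hyperparameter sets see a stable training multiset.
The distance in the triplet loss is non-squared Euclidean; a
squared-distance variant is selectable in `EncoderConfig`.

The sigmoid head includes an intercept by default (`include_bias=False`
restores the pure bias-free linear score). BCE probabilities are clipped
at 1e-7; predicted probabilities are clamped to stay strictly inside
(0, 1) even when the linear score saturates in floating point.

## Evaluation protocol

`nested_split` builds, per repeat, a stratified 5-fold partition; each
fold's 20% is the test set and the remaining 80% is split 80/20 into
training and validation — 64% / 16% / 20% overall. Stratification is
required because with ~15% sensitive samples unstratified folds can be
single-class, leaving the AUC undefined. `cross_validate` trains every
hyperparameter set in every (repeat, fold) cell and reports, per cell,
the test AUC of the set with the highest validation AUC (ties to the
first listed set); `selection="global"` instead picks one set by mean
validation AUC across cells. `external_validate` trains/validates on
internal folds and scores every model on a full external panel,
reporting the mean external AUC of the best-mean-validation set. AUC is
the exact Mann-Whitney probability with tie half-credit, computed from
average ranks; sensitive (label 1) is the positive class. A master seed
deterministically derives every per-(repeat, fold, hp-set, stage)
sub-seed via `SeedSequence` over CRC32-hashed stage names, so any cell
is re-runnable in isolation and whole runs are byte-reproducible
(model archives are written with fixed zip timestamps for this reason).

## ln(IC50) binarization

Continuous ln(IC50) values are dichotomized by: (i) drawing 100 values
per cell line from Normal(ln_ic50_i, sigma) with sigma = 0.5 — the
"interval" is read as the resampling sd directly; an alternative reading
(a full 95% CI width, sigma = interval/3.92) is selectable; (ii) a
Gaussian KDE with fixed absolute bandwidth 0.5 over the pooled draws,
evaluated on 512 grid points spanning the pool plus three bandwidths per
side; (iii) the threshold at the density minimum strictly between the
two highest local maxima. Samples below the threshold (responding at low
concentration) are sensitive. When the pooled density is unimodal the
threshold falls back to pooled mean minus one pooled sd, so only the
low tail is called sensitive. The between-modes minimum rule is a
documented stand-in for dichotomization procedures whose exact rule is
not fully published; it is isolated behind `find_threshold` so it can be
swapped. An input table with zero spread raises a degenerate-density
error.

## Synthetic data

`simulate_dataset` emulates the per-drug panel regime: n = 400 samples,
15% sensitive, expression/mutation/CNA widths 1000/500/500 with
30/20/20 informative features placed at known leading positions (so
recovery is directly assertable). Informative continuous features are
unit-variance noise plus a class mean shift of `effect_size` (default
1.5 sd); non-informative features are zero-mean with per-feature sd
drawn uniformly in [sqrt(variance floor), 0.5] (floor 0.01), keeping
every noise variance well below the informative ~1.3 so the variance
curve has a detectable knee. Mutations are Bernoulli: background rate
0.02 everywhere, 0.4 on informative features in sensitive samples —
rates chosen so the informative-column variance (~0.07) clearly exceeds
background (~0.02) at realistic panel sizes. `simulate_ic50` draws from
a two-component normal mixture, by default 0.2 N(-3, 0.5) + 0.8 N(1, 0.5)
(a sensitive minority at low ln(IC50)), recording true membership.

What the simulator does *not* model: gene-gene correlation, batch or
platform effects, dose-response measurement error structure, and
feature-dependent missingness. Passing tests therefore demonstrate that
the machinery recovers a planted, independent-feature signal under
realistic imbalance — not that the published cross-dataset accuracy on
real pharmacogenomic panels is reproduced, which would require the
original resources.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at
n = 400 with 2000 total features, one repeat of 5 folds, encoder widths
64/32/16, up to 50 encoder and 100 classifier epochs with patience 8/15
— sizes at which the planted signal is comfortably recoverable and a
full run completes in well under a minute on one core. Degenerate-case
behavior is pinned by tests: empty triplet batches (loss 0 with a
warning), knee-less variance profiles (keep-all fallback), single-class
splits (explicit training errors), all-tied AUC (0.5).

## Known limitations

- Published per-drug hyperparameter values live in the original
  supplementary material; the defaults here (alpha = 1.0, widths
  256/64/32 for expression/cna/mutation) are sensible placeholders
  exposed through `HyperParams`, not tuned values.
- Whether hyperparameter selection in the reference protocol happened
  per fold or once overall is ambiguous; both are implemented
  (`selection="per_cell"` / `"global"`), per-cell being the default.
- The no-encoder mode feeds raw selected features to the head without
  standardization; on data whose features are far from unit scale a
  preprocessing step would be advisable.
- Training is plain NumPy on one core; panels vastly larger than the
  cell-line regime (tens of thousands of samples) would warrant a GPU
  implementation.
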