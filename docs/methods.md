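# Methods

This note documents the models and procedures implemented in
`deepchronnect`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic experiments do and do
not demonstrate.

## Sliding-window dynamic connectivity

A run is a time-major matrix `X ∈ R^{T×N}` of region-averaged signals with
sampling interval TR. Windows are rectangular (untapered), half-open
`[k·s, k·s + w)`, giving `W = ⌊(T−w)/s⌋ + 1` windows. Within each window
the Pearson correlation of every region pair is Fisher-transformed,
`z = atanh(r)`, and the upper triangle is vectorized in row-major order
`(i < j)`; this edge order is the single indexing convention used by the
model, the surrogate tests and the attribution maps.

Numerical choices:

* correlations are clipped to `±(1 − 1e−7)` before `atanh`, so duplicated
  channels (`r = ±1` exactly) stay finite;
* an edge whose signal has zero variance inside a window gets `z = 0` for
  that window and a warning, rather than propagating NaN;
* a window width requested in seconds is converted to samples by
  nearest-integer rounding of `width/TR`.

The reference configuration is 55-sample windows (39.6 s at TR = 0.72 s)
with stride 5. The stride value is the unique one for which 1200-sample
runs yield 230 windows, and it is configurable. Windowed series are fed to
the model raw by default; an optional per-edge normalization (`"center"`,
subtracting each edge's within-run mean, or `"zscore"`) is available.
Centering removes the static baseline — which carries no class information
in a matched design — while leaving fluctuation amplitude untouched;
z-scoring would also erase the variance signal and is therefore never the
default.

The per-edge summary feature dFC-Str is the mean absolute Fisher-z across
windows (strategies `mean` and `std` are available; the literature is not
explicit about the collapse, so it is exposed as an option).

## CNN+LSTM architecture

Input is one dFC sequence `Z ∈ R^{W×E}` per run, edges as channels. Three
1-D convolutions along the window axis (kernels 4, 8, 16; 32 channels
each; length-preserving zero padding) are rectified and concatenated on
the feature axis into `W × 96`; dropout (rate 0.5) is applied after the
conv bank; non-overlapping temporal max-pooling (kernel 5, remainder
dropped) yields `⌊W/5⌋ × 96`; a two-layer stacked LSTM (32 hidden units,
zero initial states) consumes the pooled sequence; its output sequence is
averaged over time and an affine head produces two-way softmax logits
(classification) or a scalar (regression).

Open points resolved as package defaults:

* concatenation of the three conv outputs is along the *feature* axis —
  the only reading consistent with a `W × 96` feature map;
* `'same'` padding for all kernels so the three outputs share length `W`
  (even kernels pad one extra sample on the right);
* a rectifier follows each convolution; dropout sits between the conv bank
  and pooling (position configurable);
* the two LSTM layers form a plain stack by default; DenseNet-style skip
  wiring (layer 2 sees the pooled conv features concatenated onto layer
  1's outputs) is available behind `dense_lstm=True`;
* weights initialize uniformly with fan-in scaling, from a seed.

The implementation is pure NumPy with hand-written backpropagation
(im2col convolutions, BPTT through the gates) and an Adam optimizer. On a
single CPU every training run is bit-reproducible from its seed, which the
surrogate experiments require; gradients are verified against central
finite differences in the test suite.

## Training protocol

Subject-grouped k-fold cross-validation: subjects are shuffled (optionally
stratified by label) into k folds; fold i is the test set, fold (i+1) mod k
the validation set, the rest train. All runs of a subject stay together. A
subject's prediction is the mean of its runs' predicted probabilities or
scores.

Optimization: Adam, mini-batches, initial learning rate multiplied by a
decay factor after each epoch, early stopping on validation loss with a
patience, best-validation weights restored. An epoch only counts as an
improvement if it beats the previous best by `min_delta`; without this
margin, chance dips of the validation loss on an unlearnable problem
(e.g. phase-randomized data) select overfit weights and push null
accuracies systematically below chance. The reference defaults mirror the
headline protocol (batch 64, lr 1e−4, decay 0.1/epoch, dropout 0.5); the
decay sentence in the source protocol is read as multiplicative
learning-rate decay, with an optimizer L2 penalty available separately
(`weight_decay`).

For continuous targets, nuisance covariates (sex, age, mean frame-wise
displacement) are removed by OLS fitted on training subjects only and
applied unchanged to validation and test subjects. Classification labels
are never confound-regressed. Every experiment records an audit trail
(which subjects each fold's confound fit, training, and early stopping
touched); `audit_leakage` asserts train/validation/test disjointness
mechanically.

Metrics: accuracy and AUC for classification; Pearson r pooled over all
subjects across folds plus per-fold MAE (mean ± sd) for regression.
Constant predictions make r undefined; it is reported as 0 with a warning.

## MVPR surrogates and the two null procedures

One Hermitian-symmetric random phase vector `φ` (`φ[0] = 0`,
`φ[T−k] = −φ[k]`, `φ[T/2] = 0` for even T, else uniform on `[0, 2π)`) is
applied multiplicatively (`e^{iφ}`) to the DFT of *every* region, and the
transform inverted. Signals are demeaned first and their means restored,
so the DC term is never randomized. Because all regions share `φ`,
per-region amplitude spectra and all cross-spectral phase differences —
hence circular cross-correlations and, up to edge effects, the static
Pearson matrix — are preserved exactly, while the temporal ordering of
connectivity states is destroyed. A complex residual above `1e−9` after
the inverse transform raises (it can only arise from a non-symmetric
phase vector).

Per-edge test: the default dynamics statistic is the sample variance
(ddof 1) of the edge's windowed Fisher-z series; the observed value is
compared against the same statistic on `n` surrogate copies with the
plus-one rule `p = (1 + #{null ≥ obs})/(1 + n)`, so `p ≥ 1/(n+1)` and a
p-value of zero is impossible. The statistic is a strategy hook (a range
statistic is included) because the underlying framework is not pinned to
one choice; raw p-values are reported with optional Benjamini–Hochberg
adjustment. Fewer than 19 copies trigger a warning (p cannot resolve
α = 0.05).

Model-level null: every run in the cohort is replaced by an independent
MVPR copy and the *identical* cross-validated pipeline — same window
configuration, normalization, architecture, optimizer and early stopping —
is re-run from scratch; repeating this for `n` copies yields a null
distribution of accuracies and an empirical plus-one p-value for the real
accuracy.

## Synthetic cohort generator

The generator emulates the one mechanism the surrogate logic is designed
to detect: piecewise-stationary covariance. Hidden states follow a
two-state symmetric Markov chain (geometric dwell times; symmetric switch
probability ⇒ stationary occupancy 1/2 for every class). State 0 raises
the correlation of a designated 8-region block to ρ; state 1 is the
identity. Classes share the states and occupancy and differ **only** in
mean dwell time, so their time-averaged covariance is identical by
construction — a static-FC classifier is at chance and any class
separation must come from dynamics. Draws are smoothed with a
variance-preserving AR(1) (a stand-in for hemodynamic autocorrelation;
full HRF convolution is out of scope) and observation noise is added. A
continuous trait is `β · z(switch rate) + ε`, and age/motion covariates
are generated with a configurable correlation to the trait to exercise
confound regression.

Defaults (the desk-scale study conditions): 20 regions, T = 300 samples at
TR = 0.72 s, ρ = 0.8, dwell means 30 samples (≈22 s, slow class) vs. 4
samples (≈3 s, fast class), AR coefficient 0.1, noise sd 0.1. The dwell
contrast and window are designed together: a 20-sample window (14.4 s) is
shorter than the slow class's typical regime and much longer than the fast
class's, so windowed correlations fluctuate strongly for slow switchers
and average out for fast ones. A design power analysis with an oracle
feature (mean windowed variance over the dynamic block + logistic
regression) puts the oracle's cross-validated accuracy near 0.95 under
these conditions; conditions where the slow dwell is comparable to the
window (or exceeds T/5) leave even the oracle near 0.8 because slow
switchers often traverse too few regimes per run to be recognized.

In the trait-regression demonstration the nuisance set is the designed
age/motion covariates; the class label is *not* residualized there, because
the synthetic trait and the class label share one mechanism (switch rate)
and removing the label would remove the signal by construction. On real
cohorts, where sex is a confound rather than the mechanism, the standard
covariate set (sex, age, motion) applies and is the CLI default.

Desk-scale experiment configuration (`training.DESK_SCALE_*`): window 20,
stride 5, per-edge centering, Adam at 1e−3 (no decay), batch 16, ≤ 50
epochs, patience 10, `min_delta` 0.02, stratified 5-fold CV. Under these
conditions the CNN+LSTM reaches pooled accuracies of ~0.86–0.89 across
cohort seeds while the same pipeline on MVPR copies collapses to a
constant-predictor regime near exactly 0.5.

What the synthetic cohort does *not* emulate: empirical fMRI spectra,
hemodynamic response shapes, spatial autocorrelation of parcels,
inter-subject covariance heterogeneity, scanner/motion artifacts. Passing
these experiments shows the pipeline's machinery is correct and that it
detects regime-switching dynamics at realistic SNR; it does not certify
performance numbers on real neuroimaging cohorts.

## Deconvolution attribution

For one conv scale, the rectified activation map is projected back to
input space through the transposed filters (deconvnet-style; pooling and
LSTM stages are not part of the back-projection). The `W × E`
reconstruction is averaged over windows into one signed per-edge strength
per run; a subject's map is the mean over its runs; the group strength is
the **absolute value of the across-subject mean** (mean-then-abs, so
sign-inconsistent edges cancel). With the rectifier disabled the
reconstruction equals the input gradient of `½‖Z‖²`, which the tests
verify against finite differences.

Attribution is computed per scale; the cross-scale summary normalizes each
scale's group map to unit L2 norm before averaging, because the scales'
reconstructions have incommensurate magnitudes and an unnormalized mean is
dominated by whichever scale produces the largest activations. Downstream:
edges strictly above the 75th percentile of strengths are "high-weight";
intra/inter-network means are computed without thresholding over a node
partition (a network with fewer than two nodes has no intra cell and
reports NaN); overlap with the surrogate-significant edge set is
summarized as the fraction of significant edges above the threshold, with
0.25 the independence baseline at the 75th percentile.

## Known limitations

* The CNN+LSTM at reference scale (E = 35 778) trains slowly on a single
  CPU; the desk-scale experiments use 20-region cohorts, and the
  reference-scale configuration is exercised for shape/arithmetic
  correctness rather than end-to-end training.
* Null accuracies of the surrogate experiment have irreducible binomial
  spread of ≈ ±0.035 (n = 200 subjects); the constant-predictor collapse
  induced by `min_delta` keeps them much tighter in practice, but a copy
  whose model escapes the collapse can land near the edge of the chance
  band.
* The per-edge test statistic and its multiple-comparison handling are
  documented defaults, not uniquely determined by the underlying
  framework.
* Attribution back-projects from the conv bank only; gradients through
  pooling, LSTM and head are deliberately out of scope.
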