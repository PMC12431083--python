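# Methods

## Problem and scope

`ecgattn` classifies annotated heartbeats from multi-lead ECG recordings into
the five AAMI classes — Normal (N), Supraventricular ectopic (S), Ventricular
ectopic (V), Fusion (F) and Unknown/paced (Q). The unit of analysis is a
fixed-length window of raw signal anchored at an expert-annotated beat
fiducial (≈ R-peak); R-peak detection itself is out of scope, as is any
filtering or noise removal — the classifier consumes raw millivolt traces.

The package supports two acquisition regimes end to end: 2-lead Holter
recordings at 360 Hz (MIT-BIH-style, 720-sample windows) and 12-lead
recordings at 257 Hz (INCART-style, 514-sample windows). Real accessions are
read from the PhysioNet WFDB layout; all tests run on records from the
package's own synthetic generator.

## Segmentation and splitting

Each beat whose symbol maps to an AAMI class under the dataset's symbol
profile yields one window of `L = round(2 s × fs)` samples **centred** on the
beat (start = anchor − ⌊L/2⌋). Centring is a design choice — window placement
relative to the anchor is not uniquely determined by a 2 s window containing
"approximately two heartbeats" — and it makes the anchor beat's class the
unambiguous label even when neighbouring beats fall inside the window
(overlapping windows are permitted, one window per beat).

Beats whose window would cross a record boundary are **discarded** by default
(`edge_policy="discard"`); zero-padding is available but inflates counts.
Windows keep raw amplitudes: no normalisation or baseline correction.

The pooled dataset is shuffled by a seeded `numpy.random.default_rng`
permutation and cut into contiguous train/validation/test slices of sizes

    n_train = floor(0.6·N),  n_val = round(0.2·N),  n_test = remainder.

The `round` (rather than `floor`) on the validation slice is deliberate: for
the full MIT-BIH segment count N = 109,373 it yields 65,623 / 21,875 / 21,875
and for INCART's N = 175,694 it yields 105,416 / 35,139 / 35,139 — the
published protocol totals — whereas floor-everything gives 21,874/21,876 for
the last two MIT-BIH slices. The split is pooled (intra-patient), matching
the study protocol; it mixes segments of the same subject across splits, so
its accuracies are optimistic relative to inter-patient evaluation.

## Network

Four blocks of `Conv1D(f_i, k_i, stride 1, same padding, ReLU)` with filters
(16, 32, 64, 128) and kernels (21, 23, 25, 27), each followed by a channel
attention gate and `AvgPool1D(pool 3, stride 2, same padding)`; the fourth
block's pooling is global average pooling over time. The pooled 128-vector
feeds `Dense(128, ReLU)` and `Dense(5, softmax)`.

The channel attention is the CBAM channel branch. For a feature map
F ∈ R^{L×C} the gate is

    A = σ( W₁·relu(W₀·avg_t F) + W₁·relu(W₀·max_t F) ),   A ∈ (0,1)^C,

with a shared bias-free bottleneck MLP (W₀ ∈ R^{C/r×C}, W₁ ∈ R^{C×C/r},
r = 8) applied to the temporal-average and temporal-max channel descriptors
separately and summed **before** the sigmoid. The refined map is
F′[t,c] = A[c]·F[t,c].

Choices the architecture description leaves open, and how they were fixed:

- **Attention MLP has no bias terms and a ReLU hidden activation.** The
  bias-free form makes the attention parameter count 2·ΣC²/r = 5,440, which
  is exactly the difference between the published per-layer ledger total
  (302,229) and the published whole-model count (307,669); ReLU hidden
  follows the original CBAM design.
- **"Same" average pooling with stride 2 uses ceil-mode lengths
  (L_out = ⌈L/2⌉) with edge windows averaging only in-bounds samples.** This
  reproduces the published odd-length chain 514 → 257 → 129 → 65 (and
  720 → 360 → 180 → 90).
- **Dense(128) uses ReLU** (activation is parameter-count-neutral).
- **Global average pooling is over the temporal axis**, forced by the final
  dense layers' parameter counts (16,512 = 128·128 + 128).
- **Reduction-ratio bottleneck width is ⌊C/r⌋.** Only r = 8 divides all four
  channel counts exactly; the ablation grid r ∈ {6..10} requires the floor,
  as a `Dense(C // r)` layer would give.

With 2 leads × 720 samples the model has 307,669 trainable parameters; with
12 leads × 514 samples, 311,029 (the lead count enters only conv1:
21·C_in·16 + 16).

The compute backend is a self-contained NumPy layer engine (float32, im2col
GEMM convolutions, explicit backward passes); every layer's gradient is
verified against central finite differences in the test suite.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷) at a fixed learning rate of 0.001,
categorical cross-entropy, batch size 32, 30 epochs, per-epoch batch
reshuffling from the run seed. No early stopping, no schedule, and no class
re-weighting or oversampling: training uses the natural imbalanced
distribution, which is why S/F sensitivity trails the other classes. The
retained checkpoint maximises validation accuracy, ties broken by minimum
validation loss, then earliest epoch. Weight initialisation is
Glorot-uniform from an explicit seed; determinism holds for a fixed BLAS
backend (float32 reductions may reorder across backends).

## Evaluation

Rows of the 5×5 confusion matrix are true classes, columns predictions. Per
class, one-vs-rest TP/FN/FP/TN give accuracy, sensitivity, specificity,
precision and F1 (percent). Conventions for degenerate cells: any 0/0 ratio
is defined as 0 (a never-present, never-predicted class scores 0/0/0 with
specificity 100). The TOTAL row pools one-vs-rest counts (micro averaging),
under which sensitivity = precision = F1 = overall accuracy = trace/total for
single-label data; the TOTAL accuracy column reports that overall accuracy.
Display rounding is half-away-from-zero at 2 decimals (metrics) and
3 decimals (chi-square); full precision is kept internally.

The per-class association test is the Pearson chi-square **without Yates
continuity correction** on the one-vs-rest 2×2 table (1 df). The uncorrected
form is a reconstruction validated against the published statistics (e.g.
N-class 20,864.053 on the MIT-BIH reference matrix; the corrected statistic
does not reproduce them). The test is flagged inapplicable when any marginal
is zero (the INCART Q class). ROC curves are one-vs-rest per class from the
class's probability column, with tied scores grouped and trapezoidal AUC;
`scikit-learn` computes the curve, and an independent pair-counting oracle
checks it in the tests.

Two published reference confusion matrices (MIT-BIH and INCART test sets)
ship with the package (`load_reference_confusion`) as golden inputs for the
metric pipeline. Two cells of the corresponding published metric tables are
internally inconsistent with their own matrices (INCART F sensitivity:
14/44 → 31.82, printed 31.83; MIT-BIH Q chi-square: exactly
21,613.18249… → 21,613.182, printed 21,613.183); the package reports the
values derived from the matrices.

## Synthetic generator

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with
class-conditional centres (ms relative to the R peak), widths (Gaussian σ,
ms) and amplitudes (mV). Class morphology: N is a full PQRST complex;
S is premature (RR scale 0.65) with an inverted, broadened P; V lacks a P
wave and has QRS waves at least twice normal width with an enlarged R and
discordant T; F is the element-wise average of the N and V wave parameters;
Q is a narrow 1.6 mV spike with blunted P/T. Beats are placed at RR
intervals `max(0.3 s, Normal(0.8 s, 0.05 s)) × rr_scale(class)`, classes
drawn i.i.d. from a (0.70, 0.10, 0.10, 0.05, 0.05) mixture. A fixed per-lead
projection vector scales the waveform per lead (lead 2 = 0.6 × lead 1 by
default; sign flips among the 12-lead defaults), plus 0.05 mV sinusoidal
baseline wander at 0.3 Hz and 0.05 mV additive Gaussian noise. The R-peak
lands exactly on the annotated sample.

The generator is a test bench, not a physiological simulator: it has no
rhythm context (bigeminy, runs, compensatory pauses), no realistic noise
spectra (powerline, muscle, electrode motion), no inter-lead timing or
morphology differences beyond amplitude scaling, and intra-class variability
comes only from RR jitter and additive noise. Consequently, passing the
end-to-end test shows the pipeline (segmentation → training → evaluation)
learns class-separable morphology from annotated raw signal; it does not
certify performance on real Holter data, whose class boundaries are far
less separable.

An independent separability oracle — nearest rendered template by normalized
correlation over the central 0.7 s of lead 1 — scores ≥ 0.95 on the default
generator, so the ≥ 0.95 bar for the trained network is demanded of a
dataset that a trivial classifier already separates at that level. The
central-window restriction exists because neighbouring beats at jittered
offsets are uninformative for the anchor's class and would dilute the
correlation.

## Problem sizes used in the checked runs

The end-to-end check trains on one generated 2-lead 360 Hz record of 2,000
beats (≈ 1,994 interior segments; 60/20/20 split) for the full 30 epochs —
chosen as the smallest dataset at which both the oracle and the network
comfortably clear the 0.95 bar (the measured best validation accuracy is
≈ 0.99). Unit and property tests use a low-rate 90 Hz regime (180-sample
windows, same 4-block topology) so that training-behaviour tests stay cheap.
One deliberate deviation: the single-batch overfit sanity check runs 150
single-batch epochs rather than 30, because one epoch over one batch is a
single Adam update and 30 updates at lr 0.001 cannot reach training accuracy
1.0 from random initialisation (measured 0.75); 150 updates suffice at the
protocol learning rate.

## Known limitations

- The intra-patient split overstates generalisation; an inter-patient
  protocol would need patient-wise holdout, which the split module does not
  implement as a default.
- The NumPy backend targets clarity and testability; it is single-threaded
  BLAS-bound and roughly an order of magnitude slower than a GPU framework,
  so full-accession training (100k+ segments × 30 epochs) is supported but
  slow.
- WFDB support covers headers, signal formats 16 and 212, and MIT-format
  beat annotations — the subset the two target accessions use — not the full
  format zoo (multi-frame, skew, compressed variants).
- Chi-square on one-vs-rest tables treats each class's table as an
  independent 2×2 design; it is reported per class exactly as in the source
  protocol, not as a joint test.
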