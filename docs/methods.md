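# Methods

`tsradiomics` models the probability that a prostate-cancer patient on
active surveillance will show histopathological progression, from the full
longitudinal sequence of quantitative imaging (radiomic) features and PSA
density collected over serial MRI visits. This note records the model, the
protocol, the synthetic data the package ships for testing, and the design
choices that were genuinely open.

## The classification model

Each patient *i* contributes K parallel, synchronised feature streams
(default K = 3: T2WI-derived radiomics, ADC-derived radiomics, PSA density,
with widths d = 17, 27, 1). Stream *k* is a sequence of d_k-vectors
x_{i1k}, …, x_{iT_i k} observed at the patient's T_i visits. Visit counts
vary per patient; the model consumes visit *order* only, not the real time
offsets (a documented limitation — the recurrence is index-based, not
time-aware).

Each stream feeds its own LSTM with H_k hidden units (default 16):

    i_t = σ(h_{t-1} U_i + x_t W_i + b_i)        input gate
    f_t = σ(h_{t-1} U_f + x_t W_f + b_f)        forget gate
    o_t = σ(h_{t-1} U_o + x_t W_o + b_o)        output gate
    g_t = tanh(h_{t-1} U_c + x_t W_c + b_c)     candidate cell
    c_t = f_t ⊙ c_{t-1} + i_t ⊙ g_t
    h_t = o_t ⊙ tanh(c_t)

The last hidden states of the K streams are concatenated into
h_i = [h_{iT_i 1}, …, h_{iT_i K}], passed through dropout (training only)
and a 1-unit dense sigmoid head: ô_i = σ(W_l · h̃_i + b_l). The loss is
mean binary cross-entropy against the binary outcome (1 = progressor).

An audit switch `tied_input_forget_recurrence` makes the input gate reuse
U_f in place of U_i, reproducing a variant occasionally printed in the
literature; the default is the standard four-kernel cell.

### Initialisation, optimisation, masking

* Input kernels W: Glorot-uniform with fan_in = d_k, fan_out = H_k (so
  |W| ≤ √(6/(d_k+H_k))); recurrent kernels U: random orthogonal per gate;
  all biases zero.
* Training is full-batch gradient descent: one Adam update per epoch over
  all training patients (β₁ = 0.9, β₂ = 0.999, ε = 1e-7), default learning
  rate 0.002, 130 epochs, dropout 0.2 on h_i with the inverted convention
  (inference needs no rescaling).
* Variable lengths are handled by post-padding to T_max with value 0.0 and
  a prefix-ones mask; masked steps carry h and c through unchanged, so a
  patient's output is provably independent of the amount of padding (an
  acceptance test holds this to 1e-12).

Forward, backward (BPTT through the mask) and Adam are implemented in
numpy: no deep-learning framework is assumed. The backward pass is
validated against central finite differences (relative error < 1e-5) and
the forward pass against a literal scalar-loop evaluation of the gate
equations (< 1e-10). For repeat-averaged cross-validation an ensemble
trainer runs the M per-fold repeats through batched GEMMs; a regression
test pins it to the sequential path at 1e-12.

### Hyperparameter defaults

| parameter | default | meaning |
|---|---|---|
| hidden_units | 16 per stream | LSTM state size H_k |
| dropout_rate | 0.2 | dropout on concatenated h_i, training only |
| learning_rate | 0.002 | Adam step size |
| epochs | 130 | full-batch updates |

These defaults are the tuned operating point of the motivating analysis;
`tune_random_search` reproduces the selection protocol (random sampling
scored by mean held-out binary cross-entropy under LOOCV).

## Evaluation protocol

* **LOOCV**: one fold per patient. Per fold, feature standardization
  (per-feature mean/sd pooled over all scan rows of the N−1 training
  patients, population 1/N denominator) is fitted on the training side only
  and applied unchanged to the held-out patient. The fitted-on id set is
  recorded per fold and asserted disjoint from the held-out id — a hard,
  never-disabled leakage guard.
* **Repeats**: the network is retrained M times per fold (protocol default
  100) with seeds derived deterministically from (base_seed, fold, repeat),
  so any single repeat is re-runnable in isolation; the held-out
  probability is summarised by its mean and population variance.
* **Delta-radiomics (DR) baseline**: per fold, standardized last-minus-first
  feature vectors Δf = f_final − f_base are classified with an
  L2-regularised logistic regression (liblinear), the regularisation grid
  C ∈ {0.01, 0.1, 1, 10} chosen by inner LOOCV on held-out BCE. This head
  *substitutes* the network-based classifier used in the delta-radiomics
  literature (out of scope here) and is labelled "substituted head" in all
  outputs. It is deterministic, so repeats collapse to one fit.
* **Discrimination**: empirical (Mann-Whitney, ties = 1/2) AUC with DeLong
  asymptotic 95% CI; paired model comparison by the two-sided DeLong test
  (degenerate zero-variance difference reported as p = 1);
  sensitivity/specificity/PPV/NPV with Wilson CIs. The dichotomisation
  threshold for the confusion matrix defaults to the Youden point of the
  LOOCV ROC — an artifact decision (the original analysis does not state
  its rule) recorded in every report; a fixed threshold is available, and
  external binary scores (e.g. a dichotomised expert rating) are accepted
  directly as {0,1} probabilities.

## Synthetic cohorts

The real cohort is private, so a generator ships as first-class code. It
emulates the *structure* the analysis assumes, not real radiomic marginals:

* Defaults mirror the study: 76 patients (28 progressors), 3–5 visits each
  (expected 304 scans, near the study's 297 — emulated in expectation, not
  forced, to keep the visit-count distribution honest), stream widths
  17/27/1, visit gaps uniform on 6–12 months.
* Feature law per stream: class-dependent linear latent trend
  label·(baseline_shift + drift_effect·j)·noise_sd plus equicorrelated
  Gaussian noise (within-stream correlation 0.3, sd 1.0), independent
  across visits. A linear trend + Gaussian noise is the simplest structure
  consistent with monotone class-separating smoothed trajectories.
* Free magnitudes (nowhere stated by the source material) were fixed once:
  drift_effect 0.5 sd/visit and baseline_shift 0.25 sd as a "moderate,
  detectable but imperfect" default; noise correlation 0.3 reflecting that
  radiomic features from one ROI are substantially collinear.
* A second generator builds an endpoint-matched cohort in which progressors
  follow a half-sine excursion (amplitude 1.5 sd) that returns exactly to
  baseline by the final visit: two-point delta features are pure noise
  there while the full series separates the classes. This is the
  constructed counter-example for the series-model-vs-delta comparison.

What a green test does **not** establish: anything about real MRI data —
the generator has no scanner effects, no feature-specific distributions, no
informative visit timing, no label noise, and its class signal is exactly
the linear/shape structure described above.

## Numerical choices

* Probabilities are clipped to [1e-12, 1−1e-12] inside the BCE only.
* Standardization uses the population (1/N) sd; constant features are
  rejected, not dropped silently. Missing values are an ingestion error —
  the modelling assumes complete series and imputation would be
  unvalidated.
* Pad value 0.0 equals the standardized mean, limiting damage if a masking
  bug were ever introduced; the padding-invariance test makes the pad value
  unobservable in correct operation.
* Youden ties break toward the lower threshold (higher sensitivity).
* DR deltas are computed on *standardized* values with train-fold
  statistics, mirroring the sequence pipeline's scaling contract (whether
  the original analysis standardized before or after differencing is
  unstated; this choice is ours and is documented, not inferred).
* Everything is seeded and single-threaded by default; identical inputs and
  seeds reproduce `predictions.csv` bitwise.

## Known limitations

* The LSTM ignores inter-visit spacing; irregular intervals only affect the
  realism of written files.
* LOOCV held-out probabilities are negatively biased under the null (the
  held-out patient's class is under-represented in its own training fold),
  so null AUCs centre slightly below 0.5 — visible in the null-behaviour
  acceptance band.
* The DR baseline's substituted logistic head bounds what the comparison
  can claim: it shows the value of full-series modelling over two-point
  summaries, not superiority over the specific published delta-radiomics
  classifier.
* With 130 full-batch epochs on ~75 patients the network typically
  memorises its training fold; generalisation rests entirely on the LOOCV
  protocol, as in the motivating analysis.
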