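# Methods

`symrec` turns speech transcripts into character-level symbolic time series,
renders their repetition structure as recurrence plots, learns a
discriminative embedding of those plots with a contrastively trained
twin-branch convolutional encoder, and quantifies how much cognitive-status
signal the embeddings carry under a leakage-safe cross-validation protocol.
This note documents the model, its assumptions, the tunable parameters, the
synthetic data, and the numerical choices.

## Symbolic encoding

A cleaned transcript (participant speech only; see below) is NFC-normalized,
lowercased, and mapped character-by-character to small positive integers:
`a`..`z` → 1..26, space → 27, `.` → 28, then a fixed deterministic extension
(comma 29, apostrophe 30, `?` 31, hyphen 32, digits 33..42, anything else
43). The integers are pure symbol indices: recurrence downstream is defined
by symbol *equality*, never by numeric distance between codes, so the
extension only needs to be injective and stable.

Sequences are standardized to a common length `target_length` (default 512
characters) by truncating at the end — transcript openings carry the densest
descriptive content in picture-description tasks — and padding shorter
sequences with the reserved code 0 at the end. The pad suffix is recoverable
exactly, so no downstream statistic ever mixes padding with speech.
Lowercase folding is a switch (`lowercase=False` assigns capitals to the
unknown code rather than inventing codes silently).

## Recurrence plots

For a sequence x₁..x_N the recurrence matrix is R_ij = Θ(ε − |x_i − x_j|)
with Θ the Heaviside step (Θ(0) = 1) and ε = 0.1 × the population standard
deviation of the non-pad codes. Because codes are integers at least 1 apart,
any ε < 1 reduces this to symbolic equivalence R_ij = 1 ⟺ x_i = x_j. Both
modes are implemented; `exact` is the default, and `heaviside` logs a
warning when ε ≥ 1, where arbitrary numeric adjacency of codes (e.g. `y` and
`z`) would begin to count as recurrence.

Numerical choices:

- ε's standard deviation excludes pad zeros, so padding cannot shift the
  threshold with transcript length.
- Pad rows/columns are forced to 0. A pad-pad block would otherwise form a
  solid artificial recurrent square in every short transcript's plot.
- Plots are resized to 128×128 with area (box) averaging by default, which
  preserves local recurrence density; bilinear and nearest are selectable.
  Pixels are clipped into [0, 1]; an all-zero matrix maps to an all-zero
  image rather than dividing by a zero maximum.

RQA summaries (recurrence rate, determinism, longest diagonal) are
diagnostics only; the pipeline feeds the full image to the encoder.
Determinism is the fraction of off-main-diagonal recurrent points lying on
diagonal segments of length ≥ `l_min` (default 2), the standard definition
with a Theiler window of one. Note this makes even a fully recurrent plot
score below 1, since its corner points sit on length-1 diagonals.

## Twin-branch contrastive encoder

The encoder is fixed — it is part of the method, and deviating
architectures are rejected: input 128×128×1 → Conv 32×(3×3), ReLU → MaxPool
2×2 → Conv 64×(3×3), ReLU → MaxPool 2×2 → Flatten → Dense 128, ReLU. Two
branches share all parameters; a pair of images (X₁, X₂) yields embeddings
with Euclidean distance D, trained with the contrastive loss

    L = (1 − Y)·½·D² + Y·½·max(0, m − D)²

where Y = 0 marks a same-class pair and Y = 1 a different-class pair (the
algebra forces this convention: the distance term must be active for similar
pairs). The margin is m = 1.0 and the optimizer Adam with learning rate
0.001. D is the plain (unsquared) Euclidean norm, since the loss squares it
explicitly.

The network is implemented directly in numpy: convolutions are lowered to
GEMM via an im2col buffer built from nine strided slice copies, pooling uses
strided views, and backpropagation is hand-written. Convolution padding is
"valid" (hence the 30×30×64 = 57 600-unit flatten). Glorot-uniform
initialization, pair sampling and batch shuffling all derive from one master
seed, so training is bit-reproducible on a fixed BLAS backend. Max-pool
routes gradient to every maximal element of a window; ties between positive
activations are measure-zero, and ties at zero are annihilated by the ReLU
mask, so the subgradient choice is inconsequential. Within a minibatch each
distinct image is forwarded once and its gradient contributions accumulated,
which is algebraically identical to the naive two-branch pass.

Unstated-by-necessity training defaults, all surfaced in `TrainConfig`:
batch size 32 pairs, at most 20 epochs, and 4 pairs per training image,
balanced 50/50 between same-class pairs (split evenly across the two
classes) and different-class pairs, sampled without replacement while enough
distinct pairs exist and never pairing an image with itself.

With only on the order of a hundred training images the contrastive
objective memorizes them within a few epochs: training loss keeps falling
while held-out images embed progressively worse. Training therefore holds
out a stratified 20% of the images, monitors the contrastive loss of pairs
drawn from that held-out set, stops when it fails to improve by 1e-4 for 3
consecutive epochs, and restores the weights of the best-validation epoch.
When a class is too small to spare two validation images, all images are
used and the training loss is monitored instead.

## Evaluation protocol

Cross-validation is participant-grouped and class-stratified with k = 5:
every transcript of a participant travels into a single fold, so speaker
identity can never leak across the split; a runtime assertion enforces this
in every fold. Within each fold the encoder is trained on the training
transcripts only — training it once on all data would leak test images into
the embedding space; a config flag (`retrain_per_fold=False`) reproduces
that optimistic variant for comparison.

Training-fold embeddings feed an XGBoost classifier (regularized additive
trees: per-example loss plus per-tree complexity penalty). Learning rate,
maximum depth and L2 regularization are selected by inner 3-fold
cross-validated AUC over the grid {0.05, 0.1, 0.3} × {3, 5, 7} × {0, 1, 10}
(100 trees, histogram method), then the winner is refit on the full
training split and the held-out fold is scored. AUC uses the rank statistic
with midrank ties.

Fold AUCs are summarized by arithmetic mean, sample (n−1) standard
deviation, and extremes. The 95% confidence interval for the mean is a
nonparametric bootstrap: the k fold AUCs are resampled with replacement
10,000 times, each resample's mean is taken, and the 2.5th/97.5th
percentiles are the bounds. A single-fold list reports std 0 with a warning.

The word-level reference is TF–IDF (smoothed idf, unigrams, word-boundary
tokenization) followed by logistic regression with C chosen by inner CV over
{0.01, 0.1, 1, 10}. It reuses the identical fold-assignment object and fits
its vocabulary per fold on training documents only.

## Synthetic data

Real picture-description corpora with clinical labels are access-restricted,
so the generator emits CHAT files whose two classes differ along the
disfluency dimensions the method targets: per-word filler insertion
(`&-uh`/`&-um`), immediate word repetition, pause marks `(.)`, early
utterance fragmentation, and utterance length. Default profiles — control:
filler .02, repetition .01, pause .05, fragment .05, 8–15 words/utterance;
impaired: filler .15, repetition .10, pause .20, fragment .25, 3–8
words/utterance — were calibrated once to create a detectable but
non-trivial contrast and are treated as the package's study condition. Both
classes share one Cookie-Theft scene vocabulary of 15 nouns/verbs, so
separation comes from temporal structure, not word choice; a per-profile
vocabulary override supports constructing keyword-separable corpora for
baseline checks. Word sampling never produces accidental immediate
duplicates, so doubled words come only from the repetition mechanism and the
rate parameters have exact semantics. Transcripts are spread over fewer
participants than transcripts (default 40 per class for 60 transcripts), so
the grouping logic is genuinely exercised.

What the generator does **not** model: syntax, semantic content, word-order
coherence, demographic covariates, transcription noise, or the
length/vocabulary distributions of real clinical speech. Passing tests on
synthetic corpora therefore demonstrate that the pipeline detects
fluency-structure contrasts under its own assumptions — not that it attains
any particular performance on real clinical data.

## Problem sizes used in the test suite

The end-to-end checks run on the default 120-transcript corpus (60+60 over
40+40 participants) with a reduced training budget chosen as a deliberate
compute/fidelity trade-off: 480 contrastive pairs per fold and a 5-epoch cap
(validation early stopping, best weights restored) for the separability run. The permutation-null run (labels permuted across
participants, which keeps grouping and stratification well-defined) uses 240
pairs, 1 epoch and a single-configuration classifier grid: under the null
the expected AUC is ½ regardless of training intensity, so the reduction
does not bias that check. Longer budgets only sharpen the learned contrast.

## Known limitations

- CHAT parsing covers main-tier extraction with the documented cleaning
  policy (pause marks, fillers, bracket codes, retracing, timing bullets);
  it is not a CHAT validator and ignores `%mor`/`%gra` tiers by design.
- The `heaviside` mode with ε ≥ 1 is deliberately permitted (with a warning)
  for studying the thresholded formulation, but mixes symbol adjacency into
  recurrence and should not be used for inference.
- Bit-reproducibility of training holds for a fixed numpy/BLAS build;
  across backends, results match only to floating-point accumulation order.
- Bootstrapping k = 5 fold AUCs is a coarse uncertainty estimate; its bounds
  cannot fall outside the observed fold range by construction.
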