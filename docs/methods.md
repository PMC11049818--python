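# Methods

This note records the models implemented in `druggability`, the
assumptions and defaults behind them, the numerical choices that were
genuinely open, and what the synthetic benchmarks do and do not
establish.

## Problem setting

Druggability prediction is cast as binary classification of protein
sequences (1 = druggable, 0 = undruggable). Two feature routes feed
the classifiers: evolutionary profiles (PSSMs produced externally by
PSI-BLAST) and protein-language-model embeddings. A third route skips
features entirely: a decoder transformer consumes the tokenized
sequence itself.

## Sequence handling

The token vocabulary is the 33-symbol ESM-style alphabet — specials
`<cls> <pad> <eos> <unk>` first, then the 20 standard amino acids with
extended residue codes (X, B, U, Z, O) and gap-like symbols, then
`<mask>` — frozen as a versioned constant. Tokenization frames a
sequence as `[cls] … [eos]`; residues outside the alphabet map to
`<unk>` rather than erroring, because real FASTA contains non-standard
codes. Truncation (when a maximum length applies) drops C-terminal
residues so the `cls` context stays intact. Length summaries round
mean/median/population-σ half-away-from-zero to integers.

## PSSM encoders

Scores are the raw log-odds integers from the first 20 numeric columns
of the ASCII profile; an optional sigmoid normalization flag exists but
defaults to off, since the defining formulas apply `p` directly.
Row/column index `i` follows the profile header's amino-acid order, so
features are reproducible across files. Conventions worth stating:

- DPC-PSSM divides by `L − 1`; KSB-PSSM is an unnormalized sum, exactly
  as defined; with `L ≤ k` the KSB sum is empty and the block is all
  zeros with a warning rather than an error.
- S-FPSSM applies no upper cap to the negative-filtered values; rows
  whose residue is X (or any non-standard code) match no amino-acid row
  and contribute nothing.
- A sequence with no profile (PSI-BLAST found no hits) gets an all-zero
  profile and a logged warning, keeping batch pipelines total.

Each encoder is verified against an independently coded triple-loop
oracle, exactly, on random integer profiles.

## Embedding backends

The embedder contract fixes shapes and determinism, not values: per-
residue representations (`L × 320`), a pooled vector, and a symmetric
contact map in [0, 1]. Pooling is the arithmetic mean over residue
rows (specials excluded) — the community convention where only the
representation layer and its width are prescribed. The default `stub`
backend draws one 320-D codebook row per alphabet symbol from the seed,
making the pooled embedding a randomized linear image of amino-acid
composition: deterministic, download-free, and separable whenever class
compositions differ. The `esm2_t6_8M` backend (layer-6, 320-D) is
optional configuration and requires externally installed weights; tests
never touch it.

Fine-tuning appends a fully connected layer and a 1-unit sigmoid head
over the pooled backbone representation and trains everything with BCE
on length-sorted batches of two (minimal padding waste). Downstream
embeddings are the activations entering the fully connected layer. The
reduced contact head (input width 24) is a trainable logistic map over
a fixed down-projection of pairwise representation products, symmetrized
and clipped. Learning rate, epochs and hidden width are configuration;
the paper-level protocol fixes only the batch size and loss.
Fine-tuning at learning rate 0 is an exact no-op on extracted
embeddings (a tested invariant).

## Deep classifiers

All four neural models run on a compact in-repo reverse-mode autodiff
engine (float64, single-threaded, bit-for-bit reproducible given a
seed), with Adam as the optimizer. Gradients are validated against
finite differences in the test suite.

- **DNN**: hidden layers 180/60/30, ReLU, inverted dropout 0.5,
  sigmoid output, BCE, learning rate 1e-3, batches of 10. For 320-D
  input this is exactly 70,501 trainable parameters.
- **CapsNet**: the feature vector is a single-channel 1-D signal; two
  kernel-3/stride-1 convolutions (no pooling anywhere, asserted
  structurally) build 8-D primary capsules; per-primary-capsule vote
  transforms feed two 16-D class capsules through 3 routing
  iterations. Two numerical choices differ from the textbook recipe
  and matter for BCE training: (1) vote aggregation inside routing is
  the **mean** over primary capsules, because with hundreds of primary
  capsules a raw sum saturates the squash at norm ≈ 1 and kills the
  gradient; (2) each primary capsule has its **own** vote transform —
  position-shared transforms were tried and cannot express per-feature
  weightings over the flat input, which showed up as a training
  plateau. Class probabilities are capsule norms (each in [0, 1) by
  the squash bound); training penalizes both norms with BCE.
- **BiLSTM**: input 320, hidden 64 per direction, final hidden states
  concatenated (width 128) into a 2-unit softmax; the druggable
  probability is the class-1 component; batches of 16. The flat
  feature vector is framed as a length-1 sequence by default
  (configurable `n_steps × step_dim` reshaping), since the protocol
  feeds fixed vectors to a recurrent net without stating a framing.
- **Decoder transformer (GPT-2 style)**: vocabulary 33, learned token
  + position embeddings summed, pre-norm causal self-attention blocks,
  defaults 4 layers / 4 heads / width 128 / block 512 (all
  configuration — the reduced values are not prescribed anywhere), a
  2-logit softmax head reading the last non-pad position (which, under
  causal attention, has seen the whole sequence). Padding is masked
  out of attention, so appending pads never changes outputs (tested).
  Over-long sequences are C-terminally truncated with a warning. No
  pretrained weights exist anywhere in this path; training is 2-class
  cross-entropy from random init. Epoch defaults are 100 with
  optional early stopping (patience 10) when validation data is
  supplied; the overfit checks train the full budget.

## Evaluation protocol

Balancing samples the larger class down to the smaller without
replacement via Python's `random.Random(seed)` (default seed 42).
Splitting is per class with floor rounding at both 80:20 stages —
the unique simple convention that reproduces the published per-class
counts (784/845, 196/211, 244/263 from totals 1224/1319; 452/112/140
from 704/704); it is derived, not stated, in the source protocol.
K-fold plans are stratified with near-equal folds. MCC returns 0 when
any denominator factor is zero (standard convention, logged decision).
AUC is the exact Mann–Whitney pair statistic computed by ranking; the
trapezoidal area under the tie-handled ROC curve equals it to 1e-9
(tested). Fold aggregation reports mean ± sample standard deviation.
Feature-group importance takes mean |attribution| per feature, then the
mean within each group; computing the attributions themselves (e.g.
SHAP) is an input, not a responsibility, of this package.

Baseline hyperparameter defaults (SVM C=10/RBF/scale, RF 1000 trees of
depth 3, Gaussian NB with 1e-9 smoothing, XGBoost depth 15 / 2000
estimators / η 0.1 etc.) are the tuned settings of the source protocol,
loaded verbatim and overridable per run. The SVM's ROC scores come
from its decision function rather than probability calibration.

## Synthetic benchmark: what it shows

The generator emulates a balanced two-class set with two independent
signal channels: positives carry a planted `WWWWW` motif at a random
position plus a K/R composition weight of 4 (K+R frequency ≈ 0.31 vs
0.10 in negatives); every record gets a synthetic profile scoring its
own residue at +5 against integer noise in ±2, and in positives the
motif's positions score +10 — the profile analogue of a conserved
functional motif. Lengths are uniform on 50–150; defaults are 100+100
records, seed 7. Both signal strengths were set so that the Bayes
accuracy of each route is ≈ 1: the fixture's contract is separability
*by construction*, so a pipeline failure indicates a bug rather than
sampling noise. Two constructions that look reasonable fail this
contract and were rejected: a composition weight of 2 leaves the
embedding route at Bayes accuracy ~95% (indistinguishable from a defect
on a 40-sample test split), and a uniform profile signal leaves the
encoder route confounded — the encoders' unnormalized sums scale with
sequence length, so a short positive's K/R counts overlap a long
negative's, and chance W-W adjacencies in long negatives overlap the
diluted motif dipeptide signal in long positives. A single master seed
drives per-record hashed substreams, so records are order-independent.

What passing does **not** show: the fixtures are statistical stand-ins
— real evolutionary profiles are not i.i.d. noise around the identity,
real druggability signal is not a motif or a composition shift, and
the stub embedder is not a trained language model. Results on the
benchmark validate the plumbing, determinism and optimization of the
stack, never biological performance; published benchmark accuracies
require the real datasets and pretrained weights and are out of scope
here. The null benchmark (no motif, identical compositions) pins the
whole pipeline at chance (CV accuracy 0.5 ± 0.1, mean AUC 0.5 ± 0.02),
guarding against label leakage.

## Problem sizes

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen
to make every check decisive yet quick on a single CPU core: 40
training samples for the overfit checks (200 epochs), 20 sequences for
the transformer overfit (150 epochs), 200 random profiles / 1000
confusion quadruples / 50 score sets for the oracle comparisons, 200
null records with 30 shuffle repeats for calibration, and the 100+100
default benchmark for signal recovery.

## Known limitations

- The real ESM-2 backend is untested here by design; only its contract
  is pinned.
- The capsule network's mean aggregation and per-capsule transforms are
  package choices where the source protocol is silent; results for
  other conventions may differ.
- The PSSM parser targets the PSI-BLAST `-out_ascii_pssm` layout; other
  profile dialects are not recognized.
- Deep-model training is pure numpy: fine at desk scale, not tuned for
  thousands of long sequences.
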