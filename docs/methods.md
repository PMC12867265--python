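# Methods

## Problem and data model

The package classifies whether the central cytosine of a 41-nt RNA window
carries the 5-hydroxymethylcytosine (5hmC) modification. Windows are strings
over {A, C, G, U} with the candidate C fixed at 0-based position 20; positions
0–19 are the upstream flank and 21–40 the downstream flank. Labels are binary
(1 = 5hmC site). The benchmark this task comes from is balanced (662 windows
per class, hMeRIP-seq-derived, *Drosophila melanogaster*), split 90/10 into a
training and an independent test partition (595+595 / 67+67) with a further
80/20 training/validation split for model selection. The package reproduces
those partition sizes with a seeded, per-class floor-stratified shuffle; the
original benchmark's redundancy reduction (external clustering at <20%
identity) is out of scope.

## Classifier

`InTrans5hmCClassifier` / `intrans5hmc.network` implement a dual-branch
network:

* **Inception branch.** The integer-encoded window (A→0, C→1, U→2, G→3) is
  mapped by a trainable embedding to 41 × 32 word vectors, then passed through
  three inception modules. Each module runs four parallel length-preserving
  paths — a 1×1 convolution; 1×1 then kernel-3; 1×1 then kernel-5; max-pool
  then 1×1 — concatenated on the channel axis and batch-normalized. Channel
  widths are 16 per path (64 per module); the published architecture does not
  state internal widths, so these were chosen once for a CPU-trainable model
  that still ends in the stated 256-dim branch output (max-pool kernel 2
  stride 2 → 64 × 20 → flatten → linear 256).
* **Transformer branch.** Fixed per-nucleotide provider embeddings
  (41 × 1280 by default) pass through a stack of 6 post-norm transformer
  encoder layers (8 heads, feed-forward width 2048, dropout 0.3; no added
  positional encoding since provider embeddings are already positional), then
  a max pool over the *feature* axis with kernel 3 and stride 2
  (1280 → 639 per position), flatten (41 × 639 = 26 199), and two fully
  connected layers (512 → 256).
* **Fusion head.** The two 256-vectors are concatenated (512) and passed
  through two consecutive linear layers (512 → 128 → 1) with ReLU, 1-D batch
  norm and dropout 0.3 between them, ending in a sigmoid probability.
  Probability ≥ 0.5 classifies positive (ties positive).

Ablation modes keep a single branch and route its 256-vector to the same
head; LSTM / simple-RNN branch types (last hidden state → linear 256) cover
the recurrent alternatives used in model selection. The full-size default
model has ≈ 85 M trainable parameters (≈ 340 MB as float32).

The network is built on a small reverse-mode autodiff core over numpy
(`intrans5hmc.nn`) with dedicated forward/backward primitives for 1-D
convolution (im2col), max pooling and embedding lookup; every layer family
is gradient-checked against central finite differences in the test suite.
Weight init is fan-in uniform from a single per-run PCG64 seed; all
randomness in a run (init, batch shuffling, dropout masks) derives from that
seed, so runs are bit-reproducible on a platform.

## Training recipe

Defaults follow the published configuration: Adam, binary cross-entropy on
logits, initial learning rate 1e-5, 18 epochs, batch size 500, dropout 0.5
inside the inception branch and 0.3 elsewhere, and "maximum L2 norm 1"
interpreted as gradient-norm clipping at 1.0 (a per-matrix weight max-norm
constraint is available via `grad_clip_mode="weight"`).

A caveat discovered while validating the recipe: at benchmark-size datasets
(≈ 800–1200 training windows) the default recipe performs only ~36–54 Adam
updates in total, and Adam's per-step displacement is bounded by the
learning rate, so weights move O(1e-4) from initialization — too little for
the network to learn anything, which we confirmed empirically on strongly
separable synthetic data (balanced accuracy ≈ 0.55, i.e. chance). The
defaults are kept as documented for fidelity; for runs that are meant to
converge at desk scale the package provides
`network.compact_config()` — same topology and epoch count, transformer
branch shrunk to 32-dim embeddings / 2 encoder layers, learning rate 1e-3,
batch 64 — which trains to BACC ≥ 0.9 on the synthetic benchmark in under a
minute on one CPU. All heavy tests and the worked example use this compact
recipe; the methods' substance (architecture, loss, clipping, dropout
placement, threshold) is unchanged.

## Embedding providers

The transformer branch consumes per-nucleotide embedding matrices through a
provider contract; the 650 M-parameter RNA language model that produced the
original 1280-dim embeddings is never loaded here. An HDF5 cache adapter
serves externally extracted matrices by sample id (a missing id is a hard
error, never a silent fallback; which hidden layer was exported is a property
of the extraction run recorded in the cache manifest). For self-contained
runs, a deterministic synthetic provider builds row *i* from a seeded random
basis vector of the trinucleotide centred at *i* plus a small sinusoidal
positional term — enough structure that classifiers can recover sequence
signal from the matrices, while making no claim to model real language-model
geometry: contextual scope is 3 nt, there is no secondary-structure
information, and inter-row covariance is unrealistic. Passing tests on
synthetic embeddings therefore demonstrates pipeline correctness and
learnability of planted signal, not real-data performance.

## Descriptors

Fourteen sequence descriptors with fixed output lengths (NAC 4, DNC/Kmer 16,
TNC 64, RCKmer 10, ANF 41, binary 164, NCP 123, EIIP 41, PseEIIP 64,
ENAC 148, DAC 12, PseDNC/PCPseDNC 18). Parameters not stated alongside the
published sizes are pinned by the sizes themselves: k = 2 for Kmer/RCKmer,
ENAC window 5, DAC 6 properties × lag ≤ 2, λ = 2 for the pseudo
compositions. K-mer order is lexicographic with A < C < G < U everywhere.
EIIP constants (A 0.1260, C 0.1340, G 0.0806, U 0.1335) and the six RNA
dinucleotide helical parameters (Twist, Tilt, Roll, Shift, Slide, Rise) ship
as data files; property columns are standardized to mean 0 / variance 1 over
the 16 dinucleotides at load, making descriptor outputs invariant to affine
rescaling of the raw table. The pseudo-composition weight w defaults
to 0.05 (unstated in the source; the conventional default). PseDNC uses the
squared-difference ("series") correlation and PCPseDNC the per-property
product ("parallel"); with standardized properties the product correlation
can be slightly negative, so the non-negativity of pseudo components is only
guaranteed for the series variant. PseEIIP multiplies trinucleotide
frequencies by the *sum* of the three constituent EIIP values.

## Evaluation

Nine metrics: SN, SP, ACC, BACC = (SN+SP)/2, PREC, F1 (harmonic mean of
PREC and SN), MCC, AUC, AUPR. AUC uses midrank tie handling (a tied
positive–negative pair counts one half); AUPR is the step-interpolated area
under the precision–recall curve (the conservative convention). Metrics with
zero denominators are reported as 0 with an `undefined` flag instead of
raising, so experiment tables never abort mid-run; single-class truths flag
AUC/AUPR. Cross-validation uses seeded stratified k-fold (per-fold class
counts within ±1).

## Experiments

* Descriptor benchmark: one gradient-boosted-tree model (100 trees, depth 4)
  per descriptor under stratified 10-fold CV; provider embeddings enter
  mean-pooled along the sequence axis.
* Branch combinations: every requested (branch1, branch2) pair trained on a
  fresh seeded 80/20 split per repeat (default seeds 1..20), evaluated on
  the held-out 20%.
* Classical baselines: RBF-kernel SVM, XGB, logistic regression, 5-NN on
  mean-pooled embeddings under the same protocol. Baseline hyperparameters
  are fixed defaults recorded in the manifest.
* Ablation: inception-only / transformer-only / dual with identical seed
  lists on a fixed train/test split.
* Grid search: epochs {15, 18, 20} × inception dropout {0.3, 0.4, 0.5} ×
  other dropout {0.3, 0.4, 0.5} on an internal 80/20 validation split;
  "best in F1, MCC, AUC and AUPR jointly" is operationalized as minimum
  rank-sum over the four metrics, ties broken by F1 then MCC.
* Statistics: two-sided paired Wilcoxon signed-rank (zero differences
  dropped; exact enumeration for small n, verified against an independent
  2^n oracle) and the Friedman rank test across folds (constant ranks →
  statistic 0, p = 1).

Every experiment table carries a manifest (seeds, split fractions, config
JSON) sufficient to reproduce it bit-for-bit on the same platform.

## Neighbourhood analysis

Per-class positional nucleotide frequency profiles; region aggregation over
upstream [0, 20), center {20}, downstream [21, 41) and the motif block
[21, 27). Enrichment contrasts the two classes per position and nucleotide
with a pooled two-proportion z-test; p-values are unadjusted at α = 0.05 by
default (the convention of two-sample-logo plots), with Benjamini–Hochberg
available behind a flag. Cells with degenerate pooled proportions report
p = 1. The test's type-I error is calibrated on null simulations in the
acceptance suite (empirical rate required within [0.03, 0.07]).

Attribution uses a permutation-sampling Shapley approximation over the 41
positions of the sequence-branch input: the value function is the model
probability with a subset of positions restored from the sample into a
background built by shuffling the sample's own positions; marginal
contributions are averaged over seeded insertion orders (128 permutations by
default), absolute values averaged over samples and then within
position ranges (six equal blocks with 21–26 as its own block by default;
fully configurable). A gradient×input fallback over the word-embedding
activations is provided for speed. Only the sequence branch is attributed;
provider embeddings stay fixed.

The auxiliary A/G classifier trains a gradient-boosted tree on exactly two
features — counts of A and of G within positions 21–26 — as a direct probe
of how much class signal that block alone carries.

## Synthetic data generator

Positives carry an A-enriched / G-depleted block at positions 21–26;
negatives are pure background (uniform 0.25 by default). The motif
arithmetic composes additively: P(A) = bg + a_delta + g_delta,
P(G) = bg − g_delta, with C and U paying a_delta/2 each — so a_delta is
exactly the per-position A-frequency gap between classes. Invalid
configurations raise before sampling. Generation is a pure function of
(config, seed) via PCG64, producing identical FASTA bytes across platforms.
The generator emulates class balance, window geometry and the downstream
motif of the real benchmark; it does **not** model dinucleotide
autocorrelation, transcript context, or assay noise, so results on it bound
pipeline correctness, not real-data accuracy.

Study conditions used by the end-to-end acceptance checks: a_delta 0.4,
g_delta 0.2, 500 windows per class, 80/20 split, compact recipe, 18 epochs,
seeds 1–5. At these conditions the expected per-position A gap is 0.6, the
A-count gap over the block ≈ 3.6, and the measured test BACC of the compact
dual model is 0.91–0.95 across seeds.

## Numerical choices and degenerate inputs

* Probability exactly at threshold → positive (documented tie rule).
* Batch norm uses running statistics in eval mode, so predictions are
  independent of batch composition and sample order.
* BCE is computed from logits via a stable softplus form.
* Float32 parameters and activations; float64 for metric arithmetic.
* Checkpoints store weights, config JSON and seed; reload is bit-exact.

## Known limitations

* The compact recipe, not the published one, is what converges at desk
  scale (see Training recipe); full-size training at 1280-dim embeddings is
  computationally out of reach for this CPU-only implementation.
* Synthetic embeddings/data are structurally simple (see above); no claim
  about real hMeRIP-seq data follows from green tests here.
* The inception-branch channel widths and transformer-branch hidden sizes
  are package choices where the source architecture is underdocumented;
  only the 32-dim word embeddings, 6 encoder layers, 256-dim branch
  outputs and the 639-dim pooled feature axis are anchored.
* The Shapley approximation treats positions independently within a
  shuffled-background distribution; correlated-position effects are
  attributed jointly to whichever position enters first in an order.
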