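# intrans5hmc

Prediction of RNA 5-hydroxymethylcytosine (5hmC) sites from sequence, for
epitranscriptomics work where candidate cytosines come as fixed 41-nt
windows (candidate C at 0-based position 20, hMeRIP-seq-style benchmarks).
The package provides the full pipeline: a dual-branch deep classifier, a
14-descriptor feature suite, the model-selection and evaluation protocol
around it, a positional neighbourhood analysis of where the signal lives,
and a synthetic-data generator so everything is exercisable end-to-end
without any external dataset or pretrained model.

## The model

Two branches over each window *s* ∈ {A, C, G, U}⁴¹:

* **Inception branch** — integer encoding (A→0, C→1, U→2, G→3) → trainable
  32-dim word embeddings → three inception modules (parallel 1×1, 1×1→3,
  1×1→5 and pool→1×1 convolutions, concatenated and batch-normalized) →
  max-pool → linear → **h₁ ∈ ℝ²⁵⁶**. Captures local multi-scale motifs.
* **Transformer branch** — fixed per-nucleotide embeddings X ∈ ℝ⁴¹ˣ¹²⁸⁰
  from a pluggable provider (an RNA language model in production; a
  deterministic synthetic provider for self-contained runs) → six post-norm
  transformer encoder layers → max-pool over the feature axis (kernel 3,
  stride 2: 1280 → 639 per position) → fully connected → **h₂ ∈ ℝ²⁵⁶**.
  Captures long-range context.
* **Head** — concat(h₁, h₂) → two linear layers with ReLU, batch norm and
  dropout → sigmoid probability P(5hmC); P ≥ 0.5 classifies positive.

Training: Adam on binary cross-entropy with gradient-norm clipping at 1.
Evaluation: SN, SP, ACC, BACC = (SN+SP)/2, PREC, F1, MCC, AUC, AUPR.
Single-branch ablations and LSTM/RNN branch variants are built in, as are
the descriptor benchmark (XGB per descriptor under stratified 10-fold CV),
repeated 80/20 branch comparisons, epoch×dropout grid search, and Wilcoxon /
Friedman significance tests.

The neighbourhood module quantifies the A-rich / G-poor block at positions
21–26 downstream of the site: per-class positional frequency profiles,
two-proportion enrichment tests, permutation-sampling Shapley attribution
aggregated over position ranges, and a two-feature (A-count, G-count)
auxiliary classifier over that block.

The network runs on a small numpy autodiff core included in the package
(gradient-checked in the test suite) — no deep-learning framework needed.

## Worked example

Generate a balanced synthetic dataset whose positives carry the planted
downstream motif, train the compact dual model, and evaluate:

```python
from intrans5hmc.simulate import GeneratorConfig, MotifSpec, generate_split_bundle
from intrans5hmc.embeddings import SyntheticEmbeddingProvider
from intrans5hmc.network import compact_config
from intrans5hmc.training import train, evaluate
from intrans5hmc.neighbourhood import positional_profile, two_sample_enrichment

gen = GeneratorConfig(n_pos=200, n_neg=200, seed=7,
                      motif=MotifSpec(a_delta=0.4, g_delta=0.2))
train_set, test_set, _ = generate_split_bundle(gen, 0.8)
provider = SyntheticEmbeddingProvider(dim=32, seed=7)

model = train(train_set, provider, compact_config(), seed=1)
report = evaluate(model, test_set, provider)

enr = two_sample_enrichment(positional_profile(train_set, 1),
                            positional_profile(train_set, 0))
```

Output:

```
loss: 0.707 -> 0.015
   SN: 0.925
   SP: 0.925
  ACC: 0.925
 BACC: 0.925
 PREC: 0.925
   F1: 0.925
  MCC: 0.850
  AUC: 0.976
 AUPR: 0.981
significantly A-enriched positions: [21, 22, 23, 24, 25, 26]
```

Reading it: the training loss falls from chance (≈ 0.69) to near zero; on
the held-out 20% the model recovers the planted signal (balanced accuracy
0.925, AUC 0.976 — the planted effect makes classes nearly separable, so
high scores are expected); and the enrichment test localizes the A surplus
to exactly the six motif positions.

There is also a sklearn-style estimator (`InTrans5hmCClassifier`, with
`fit` / `predict_proba` / `get_params`, composable with sklearn tooling)
and a CLI:

```bash
intrans5hmc simulate --n-pos 200 --n-neg 200 --a-delta 0.4 --seed 7 --out data.fasta
intrans5hmc split --fasta data.fasta --fraction 0.9 --seed 1 --out-dir splits/
intrans5hmc features --fasta data.fasta --descriptor ENAC --out enac.tsv
intrans5hmc train --train splits/train.fasta --seed 1 --out model.npz
intrans5hmc evaluate --model model.npz --test splits/independent.fasta --out report.json
intrans5hmc neighbourhood --fasta data.fasta --out-dir nbh/
```

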