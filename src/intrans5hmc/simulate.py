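"""Synthetic labelled 41-nt datasets with a plantable positional motif.

The generator emulates the statistical structure of the hMeRIP-seq-derived
benchmark this method targets: balanced classes of 41-nt windows over
{A, C, G, U} with the candidate cytosine fixed at position 20, where the
positive class carries an A-enriched / G-depleted stretch at positions
21-26 (the downstream neighbourhood the analysis highlights) and negatives
are pure background.

Motif arithmetic, with background probabilities ``bg`` (uniform 0.25 by
default): within the motif range of positive sequences,

* ``P(A) = bg_A + a_delta + g_delta`` — the A surplus plus all probability
  mass removed from G,
* ``P(G) = bg_G - g_delta``,
* ``P(C) = bg_C - a_delta / 2`` and ``P(U) = bg_U - a_delta / 2`` — C and U
  pay for the A surplus in equal shares.

so ``a_delta`` is exactly the positive-minus-negative A-frequency gap per
motif position when ``g_delta = 0``, and the two deltas compose additively.
A configuration whose adjusted probabilities leave [0, 1] raises before any
sampling happens.  Generation is a pure function of the config (PCG64
seeded streams), so a config reproduces identical FASTA bytes anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .samples import ALPHABET, CENTER, SEQ_LENGTH, RnaSample, SampleSet, SplitSpec, split_dataset


@dataclass(frozen=True)
class MotifSpec:
    """Positional A-enrichment / G-depletion planted in positive samples."""

    start: int = 21
    stop: int = 27  # half-open: positions 21..26
    a_delta: float = 0.0
    g_delta: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop <= SEQ_LENGTH):
            raise ValueError(f"motif range [{self.start}, {self.stop}) out of bounds")
        if not 0.0 <= self.a_delta <= 0.75:
            raise ValueError(f"a_delta must be in [0, 0.75], got {self.a_delta}")
        if self.g_delta < 0.0:
            raise ValueError(f"g_delta must be >= 0, got {self.g_delta}")

    def positions(self) -> range:
        return range(self.start, self.stop)


@dataclass(frozen=True)
class GeneratorConfig:
    n_pos: int = 662
    n_neg: int = 662
    seed: int = 0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A, C, G, U
    motif: MotifSpec = field(default_factory=MotifSpec)

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be non-negative")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValueError(f"background must be a distribution, got {self.background}")

    def motif_probabilities(self) -> np.ndarray:
        """Adjusted (A, C, G, U) distribution at motif positions of positives."""
        bg_a, bg_c, bg_g, bg_u = self.background
        m = self.motif
        probs = np.array([
            bg_a + m.a_delta + m.g_delta,
            bg_c - m.a_delta / 2.0,
            bg_g - m.g_delta,
            bg_u - m.a_delta / 2.0,
        ])
        if probs.min() < -1e-12 or probs.max() > 1.0 + 1e-12:
            raise ValueError(
                f"motif deltas (a={m.a_delta}, g={m.g_delta}) leave [0, 1]: {probs}")
        return np.clip(probs, 0.0, 1.0)


def _sample_class(rng: np.random.Generator, n: int, base: np.ndarray,
                  motif_probs: np.ndarray | None, motif: MotifSpec,
                  prefix: str) -> list[RnaSample]:
    label = 1 if prefix == "pos" else 0
    alphabet = np.array(list(ALPHABET))
    out = []
    for i in range(n):
        codes = rng.choice(4, size=SEQ_LENGTH, p=base)
        if motif_probs is not None:
            for pos in motif.positions():
                codes[pos] = rng.choice(4, p=motif_probs)
        codes[CENTER] = 1  # central candidate cytosine
        out.append(RnaSample(id=f"{prefix}_{i}", sequence="".join(alphabet[codes]), label=label))
    return out


def generate_dataset(cfg: GeneratorConfig) -> SampleSet:
    """Draw n_pos motif-carrying positives and n_neg background negatives."""
    motif_probs = cfg.motif_probabilities()  # validates before sampling
    # A, C, G, U order matches the alphabet used for decoding below
    base = np.array(cfg.background)
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    planted = motif_probs if (cfg.motif.a_delta or cfg.motif.g_delta) else None
    positives = _sample_class(rng, cfg.n_pos, base, planted, cfg.motif, "pos")
    negatives = _sample_class(rng, cfg.n_neg, base, None, cfg.motif, "neg")
    return SampleSet(positives + negatives, tag="unsplit")


def generate_split_bundle(cfg: GeneratorConfig, fraction: float,
                          seed: int | None = None) -> tuple[SampleSet, SampleSet, dict]:
    """Generate, then stratified-split; returns (train, test, manifest)."""
    data = generate_dataset(cfg)
    spec = SplitSpec(fraction_first=fraction, seed=cfg.seed if seed is None else seed)
    first, second = split_dataset(data, spec)
    manifest = {
        "generator": {
            "n_pos": cfg.n_pos, "n_neg": cfg.n_neg, "seed": cfg.seed,
            "background": list(cfg.background),
            "motif": {"start": cfg.motif.start, "stop": cfg.motif.stop,
                      "a_delta": cfg.motif.a_delta, "g_delta": cfg.motif.g_delta},
        },
        "split": {"fraction_first": spec.fraction_first, "seed": spec.seed,
                  "stratified": spec.stratified},
        "train": {"n": len(first), **{f"label_{k}": v for k, v in first.label_counts().items()}},
        "test": {"n": len(second), **{f"label_{k}": v for k, v in second.label_counts().items()}},
    }
    return first, second, manifest
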