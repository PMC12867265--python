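"""Positional neighbourhood analysis around the candidate cytosine.

Tools for asking *where* in the 41-nt window the signal lives: per-position
nucleotide frequency profiles per class, aggregation over the upstream
(0-19) / center (20) / downstream (21-40) regions, a two-sample positional
enrichment test contrasting positive and negative sets (the statistic
behind two-sample-logo style plots), range-aggregated model attribution
over the sequence branch, and the two-feature A/G-count auxiliary
classifier for the 21-26 downstream stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from xgboost import XGBClassifier

from .metrics import MetricReport, compute_metrics
from .nn import autodiff as ad
from .samples import ALPHABET, SEQ_LENGTH, SampleSet, encode_matrix
from .training import TrainedModel
from .embeddings import EmbeddingProvider

DEFAULT_RANGES = ((0, 7), (7, 14), (14, 21), (21, 27), (27, 34), (34, 41))
MOTIF_RANGE = (21, 27)  # half-open: positions 21..26


@dataclass(frozen=True)
class RegionSpec:
    """Named half-open position ranges on 0-based window coordinates."""

    upstream: tuple[int, int] = (0, 20)
    center: tuple[int, int] = (20, 21)
    downstream: tuple[int, int] = (21, 41)
    motif: tuple[int, int] = MOTIF_RANGE

    def __post_init__(self) -> None:
        for name, (start, stop) in self.items():
            if not (0 <= start < stop <= SEQ_LENGTH):
                raise ValueError(f"region {name!r} [{start}, {stop}) out of bounds")

    def items(self):
        return [("upstream", self.upstream), ("center", self.center),
                ("downstream", self.downstream), ("motif", self.motif)]


@dataclass(frozen=True)
class PositionalProfile:
    """Per-position nucleotide frequencies over one class subset."""

    freq: np.ndarray  # (41, 4) in alphabet order A, C, G, U; rows sum to 1
    n_samples: int
    label: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, columns=list(ALPHABET)).rename_axis("position")


def positional_profile(data: SampleSet, label: int) -> PositionalProfile:
    """Nucleotide frequency at each of the 41 positions over one class."""
    idx = [i for i, s in enumerate(data) if s.label == label]
    if not idx:
        raise ValueError(f"no samples with label {label}")
    codes = encode_matrix(data.subset(idx))  # integer codes A=0,C=1,U=2,G=3
    freq = np.zeros((SEQ_LENGTH, 4))
    for col, nt in enumerate(ALPHABET):
        code = {"A": 0, "C": 1, "U": 2, "G": 3}[nt]
        freq[:, col] = (codes == code).mean(axis=0)
    return PositionalProfile(freq=freq, n_samples=len(idx), label=label)


def region_counts(profile: PositionalProfile,
                  regions: RegionSpec | None = None) -> pd.DataFrame:
    """Mean per-sequence nucleotide counts within each named region.

    Summing per-position frequencies over a range gives the expected count
    of each nucleotide per sequence in that range, so
    upstream + center + downstream equals the full-window totals.
    """
    regions = regions or RegionSpec()
    rows = {}
    for name, (start, stop) in regions.items():
        rows[name] = profile.freq[start:stop].sum(axis=0)
    rows["full"] = profile.freq.sum(axis=0)
    return pd.DataFrame(rows, index=list(ALPHABET)).T


def _two_proportion_p(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Two-sided pooled two-proportion z-test, elementwise.

    Cells where the pooled proportion is degenerate (both 0 or both 1) have
    no evidence against the null and report p = 1.
    """
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    return 2.0 * stats.norm.sf(np.abs(z))


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-position, per-nucleotide class contrast (positive minus negative)."""

    difference: np.ndarray  # (41, 4)
    p_value: np.ndarray  # (41, 4)
    adjusted: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in range(self.difference.shape[0]):
            for j, nt in enumerate(ALPHABET):
                rows.append({"position": pos, "nucleotide": nt,
                             "difference": self.difference[pos, j],
                             "p_value": self.p_value[pos, j]})
        return pd.DataFrame(rows)

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_value < alpha


def two_sample_enrichment(pos: PositionalProfile, neg: PositionalProfile,
                          n_pos: int | None = None, n_neg: int | None = None,
                          adjust: bool = False) -> EnrichmentResult:
    """Positional frequency differences with two-proportion z-test p-values.

    P-values are unadjusted by default (matching the usual two-sample-logo
    convention); ``adjust=True`` applies Benjamini-Hochberg across all
    41 x 4 cells.
    """
    n_pos = pos.n_samples if n_pos is None else n_pos
    n_neg = neg.n_samples if n_neg is None else n_neg
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes need at least one sample")
    if pos.freq.shape != neg.freq.shape:
        raise ValueError("profiles must share coordinates")
    diff = pos.freq - neg.freq
    p = _two_proportion_p(pos.freq, neg.freq, n_pos, n_neg)
    if adjust:
        flat = p.ravel()
        order = np.argsort(flat)
        m = flat.size
        adj = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            k = m - rank_from_end
            running = min(running, flat[idx] * m / k)
            adj[idx] = running
        p = adj.reshape(p.shape)
    return EnrichmentResult(difference=diff, p_value=p, adjusted=adjust)


@dataclass(frozen=True)
class RangeAttribution:
    """Mean absolute per-position attribution aggregated over ranges."""

    ranges: tuple[tuple[int, int], ...]
    values: np.ndarray  # one non-negative value per range
    per_position: np.ndarray  # (41,) mean |attribution|
    method: str

    def top_range(self) -> tuple[int, int]:
        return self.ranges[int(np.argmax(self.values))]


def _shapley_attribution(trained: TrainedModel, data: SampleSet,
                         provider: EmbeddingProvider | None,
                         n_permutations: int, rng: np.random.Generator,
                         max_samples: int) -> np.ndarray:
    """Permutation-sampling Shapley values over the 41 sequence positions.

    The value function is the model probability with a subset of positions
    taken from the sample and the rest from a background built by shuffling
    the sample's own positions; marginal contributions are averaged over
    seeded random insertion orders.  Only the sequence-branch input varies;
    provider embeddings stay fixed at the sample's own matrix.
    """
    model = trained.model
    needs_emb = model.branch2 is not None
    idx = rng.permutation(len(data))[:max_samples]
    subset = data.subset(list(idx))
    int_seqs = encode_matrix(subset)
    emb = provider.embed_set(subset).astype(np.float32) if needs_emb else None
    phi = np.zeros((len(subset), SEQ_LENGTH))
    for si in range(len(subset)):
        sample_codes = int_seqs[si]
        sample_emb = emb[si] if needs_emb else None
        contrib = np.zeros(SEQ_LENGTH)
        for _ in range(n_permutations):
            background = sample_codes[rng.permutation(SEQ_LENGTH)]
            order = rng.permutation(SEQ_LENGTH)
            # states[j] has the first j positions of `order` restored
            states = np.tile(background, (SEQ_LENGTH + 1, 1))
            for j, pos in enumerate(order):
                states[j + 1 :, pos] = sample_codes[pos]
            batch_emb = (np.repeat(sample_emb[None], SEQ_LENGTH + 1, axis=0)
                         if needs_emb else None)
            logits = model.predict_logits(states, batch_emb,
                                          batch_size=SEQ_LENGTH + 1)
            probs = 1.0 / (1.0 + np.exp(-logits))
            contrib[order] += np.diff(probs)
        phi[si] = contrib / n_permutations
    return phi


def _grad_input_attribution(trained: TrainedModel, data: SampleSet,
                            provider: EmbeddingProvider | None) -> np.ndarray:
    """Gradient x input on the word-embedding activations, summed over dims."""
    model = trained.model
    model.eval()
    int_seqs = encode_matrix(data)
    needs_emb = model.branch2 is not None
    emb = provider.embed_set(data).astype(np.float32) if needs_emb else None
    w = model.word_embed(int_seqs)
    w_leaf = ad.Tensor(w.data, requires_grad=True)
    logits = model.forward(int_seqs, emb, word_activations=w_leaf)
    logits.backward(np.ones(logits.shape, dtype=logits.data.dtype))
    return (w_leaf.grad * w_leaf.data).sum(axis=2)


def range_attribution(trained: TrainedModel, data: SampleSet,
                      ranges: tuple[tuple[int, int], ...] = DEFAULT_RANGES,
                      method: str = "shapley",
                      provider: EmbeddingProvider | None = None,
                      n_permutations: int = 128, seed: int = 0,
                      max_samples: int = 50) -> RangeAttribution:
    """Aggregate per-position attributions into mean absolute values per range."""
    for start, stop in ranges:
        if not (0 <= start < stop <= SEQ_LENGTH):
            raise ValueError(f"range [{start}, {stop}) out of bounds")
    if trained.model.branch1 is None:
        raise ValueError("attribution targets the sequence branch; none present")
    if method == "shapley":
        rng = np.random.default_rng(seed)
        phi = _shapley_attribution(trained, data, provider, n_permutations, rng,
                                   max_samples)
    elif method == "grad_input":
        phi = _grad_input_attribution(trained, data, provider)
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    per_position = np.abs(phi).mean(axis=0)
    values = np.array([per_position[start:stop].mean() for start, stop in ranges])
    return RangeAttribution(ranges=tuple(ranges), values=values,
                            per_position=per_position, method=method)


def ag_counts(data: SampleSet, region: tuple[int, int] = MOTIF_RANGE) -> np.ndarray:
    """Two features per sample: counts of A and of G within the region."""
    start, stop = region
    if not (0 <= start < stop <= SEQ_LENGTH):
        raise ValueError(f"region [{start}, {stop}) out of bounds")
    out = np.zeros((len(data), 2))
    for i, s in enumerate(data):
        seg = s.sequence[start:stop]
        out[i] = [seg.count("A"), seg.count("G")]
    return out


def ag_region_classifier(train_set: SampleSet, test_set: SampleSet,
                         region: tuple[int, int] = MOTIF_RANGE,
                         seed: int = 0) -> MetricReport:
    """Gradient-boosted-tree classifier on A/G counts in the motif region.

    A deliberately tiny two-feature model probing how much class signal the
    downstream 21-26 stretch alone carries.
    """
    overlap = set(train_set.ids) & set(test_set.ids)
    if overlap:
        raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
    clf = XGBClassifier(n_estimators=100, max_depth=3, learning_rate=0.3,
                        eval_metric="logloss", random_state=seed, n_jobs=1,
                        verbosity=0)
    clf.fit(ag_counts(train_set, region), train_set.labels)
    probs = clf.predict_proba(ag_counts(test_set, region))[:, 1]
    return compute_metrics(test_set.labels, probs)
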