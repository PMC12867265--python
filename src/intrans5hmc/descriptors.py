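"""Sequence-composition feature descriptors for fixed-window RNA sequences.

Fourteen descriptors are provided, each returning a fixed-length numeric
vector for a 41-nt input:

====== ======= ====================================================
name   length  description
====== ======= ====================================================
NAC        4   mononucleotide composition
DNC/Kmer  16   dinucleotide composition
TNC       64   trinucleotide composition
RCKmer    10   dinucleotide composition over reverse-complement classes
ANF       41   accumulated (prefix) nucleotide frequency per position
binary   164   one-hot encoding, 4 bits per position
NCP      123   3-bit chemical-property code per position
EIIP      41   electron-ion interaction pseudopotential profile
PseEIIP   64   trinucleotide frequencies weighted by summed EIIP
ENAC     148   nucleotide composition in 37 sliding windows of 5
DAC       12   dinucleotide auto-covariance (6 properties x 2 lags)
PseDNC    18   pseudo dinucleotide composition (lambda = 2)
PCPseDNC  18   parallel-correlation pseudo dinucleotide composition
====== ======= ====================================================

K-mers are ordered lexicographically with A < C < G < U throughout; feature
indices of every composition descriptor depend on this order.  Reverse
complementation pairs A with U and C with G.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import product
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .samples import ALPHABET, SampleSet, SequenceValidationError

_RC = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _validate(sequence: str) -> str:
    if not sequence:
        raise SequenceValidationError("empty sequence")
    for ch in sequence:
        if ch not in _RC:
            raise SequenceValidationError(f"invalid nucleotide symbol {ch!r}")
    return sequence


def _kmers(k: int) -> list[str]:
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def reverse_complement(sequence: str) -> str:
    return "".join(_RC[ch] for ch in reversed(sequence))


# ---------------------------------------------------------------------------
# shipped constant tables


@lru_cache(maxsize=1)
def eiip_table() -> dict[str, float]:
    """Per-nucleotide electron-ion interaction pseudopotential constants."""
    raw = json.loads(resources.files("intrans5hmc.data").joinpath("eiip.json").read_text())
    return {k: float(v) for k, v in raw.items() if k in _RC}


@dataclass(frozen=True)
class DinucPropertyTable:
    """Standardized dinucleotide physicochemical property matrix (16 x mu)."""

    property_names: tuple[str, ...]
    values: np.ndarray  # shape (16, mu), column-standardized

    def row(self, dinuc: str) -> np.ndarray:
        return self.values[_kmers(2).index(dinuc)]


@lru_cache(maxsize=1)
def dinuc_property_table() -> DinucPropertyTable:
    """Load and column-standardize the shipped property table."""
    text = resources.files("intrans5hmc.data").joinpath("dinuc_properties.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    names = tuple(header[1:])
    order = {d: i for i, d in enumerate(_kmers(2))}
    values = np.zeros((16, len(names)))
    for ln in lines[1:]:
        parts = ln.split("\t")
        values[order[parts[0]]] = [float(x) for x in parts[1:]]
    values = (values - values.mean(axis=0)) / values.std(axis=0)
    return DinucPropertyTable(property_names=names, values=values)


# ---------------------------------------------------------------------------
# composition descriptors


def kmer_composition(sequence: str, k: int) -> np.ndarray:
    """Normalized k-mer frequencies in lexicographic order (A<C<G<U)."""
    _validate(sequence)
    if not 1 <= k <= 3:
        raise ValueError(f"k must be in {{1, 2, 3}}, got {k}")
    if len(sequence) < k:
        raise SequenceValidationError(f"sequence shorter than k={k}")
    index = {m: i for i, m in enumerate(_kmers(k))}
    out = np.zeros(4**k)
    n = len(sequence) - k + 1
    for i in range(n):
        out[index[sequence[i : i + k]]] += 1.0
    return out / n


def nac(sequence: str) -> np.ndarray:
    return kmer_composition(sequence, 1)


def dnc(sequence: str) -> np.ndarray:
    return kmer_composition(sequence, 2)


def tnc(sequence: str) -> np.ndarray:
    return kmer_composition(sequence, 3)


@lru_cache(maxsize=4)
def _rc_classes(k: int) -> tuple[list[str], dict[str, int]]:
    reps: list[str] = []
    mapping: dict[str, int] = {}
    for m in _kmers(k):
        canon = min(m, reverse_complement(m))
        if canon not in reps:
            reps.append(canon)
    reps.sort()
    for m in _kmers(k):
        mapping[m] = reps.index(min(m, reverse_complement(m)))
    return reps, mapping


def rc_kmer(sequence: str, k: int = 2) -> np.ndarray:
    """K-mer frequencies merged over reverse-complement equivalence classes.

    The canonical representative of each class is the lexicographically
    smaller of the k-mer and its reverse complement; k=2 yields 10 classes.
    """
    _validate(sequence)
    reps, mapping = _rc_classes(k)
    out = np.zeros(len(reps))
    n = len(sequence) - k + 1
    if n < 1:
        raise SequenceValidationError(f"sequence shorter than k={k}")
    for i in range(n):
        out[mapping[sequence[i : i + k]]] += 1.0
    return out / n


# ---------------------------------------------------------------------------
# positional descriptors


def one_hot_binary(sequence: str) -> np.ndarray:
    """Concatenated per-position one-hot 4-vectors (order A, C, G, U)."""
    _validate(sequence)
    out = np.zeros((len(sequence), 4))
    for i, ch in enumerate(sequence):
        out[i, ALPHABET.index(ch)] = 1.0
    return out.ravel()


def anf(sequence: str) -> np.ndarray:
    """Accumulated nucleotide frequency: density of sequence[i] in the prefix 0..i."""
    _validate(sequence)
    out = np.zeros(len(sequence))
    counts = {ch: 0 for ch in ALPHABET}
    for i, ch in enumerate(sequence):
        counts[ch] += 1
        out[i] = counts[ch] / (i + 1)
    return out


def eiip_profile(sequence: str) -> np.ndarray:
    _validate(sequence)
    table = eiip_table()
    return np.array([table[ch] for ch in sequence])


def pse_eiip(sequence: str) -> np.ndarray:
    """Per-trinucleotide (EIIP_x + EIIP_y + EIIP_z) * normalized frequency."""
    _validate(sequence)
    table = eiip_table()
    freqs = kmer_composition(sequence, 3)
    weights = np.array([sum(table[ch] for ch in m) for m in _kmers(3)])
    return weights * freqs


_NCP_CODE = {"A": (1, 1, 1), "C": (0, 1, 0), "G": (1, 0, 0), "U": (0, 0, 1)}


def ncp(sequence: str) -> np.ndarray:
    """Nucleotide chemical property code (ring structure, H-bond, functional group)."""
    _validate(sequence)
    return np.array([_NCP_CODE[ch] for ch in sequence], dtype=float).ravel()


def enac(sequence: str, window: int = 5) -> np.ndarray:
    """Nucleotide composition within each sliding window of the given width."""
    _validate(sequence)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > len(sequence):
        raise ValueError(f"window {window} exceeds sequence length {len(sequence)}")
    blocks = []
    for start in range(len(sequence) - window + 1):
        seg = sequence[start : start + window]
        blocks.append([seg.count(ch) / window for ch in ALPHABET])
    return np.array(blocks).ravel()


# ---------------------------------------------------------------------------
# property-correlation descriptors


def _dinuc_property_rows(sequence: str, props: DinucPropertyTable) -> np.ndarray:
    order = {d: i for i, d in enumerate(_kmers(2))}
    idx = [order[sequence[i : i + 2]] for i in range(len(sequence) - 1)]
    return props.values[idx]  # (L-1, mu)


def dac(sequence: str, max_lag: int = 2, props: DinucPropertyTable | None = None) -> np.ndarray:
    """Dinucleotide auto-covariance over the property table.

    For property p and lag g: the average over window positions i of
    (P_p(D_i) - mean_p)(P_p(D_{i+g}) - mean_p), where D_i are the sequence's
    dinucleotides and mean_p is the per-sequence mean of property p.
    Output is ordered property-major: (p1,g1), (p1,g2), ..., (p_mu,g_max).
    """
    _validate(sequence)
    props = props or dinuc_property_table()
    rows = _dinuc_property_rows(sequence, props)  # (n_d, mu)
    n_d = rows.shape[0]
    if max_lag < 1 or n_d - max_lag < 1:
        raise ValueError(f"max_lag {max_lag} too large for {n_d} dinucleotides")
    centered = rows - rows.mean(axis=0)
    out = np.zeros((rows.shape[1], max_lag))
    for g in range(1, max_lag + 1):
        out[:, g - 1] = (centered[:-g] * centered[g:]).sum(axis=0) / (n_d - g)
    return out.ravel()


def pse_dnc(
    sequence: str,
    lam: int = 2,
    weight: float = 0.05,
    variant: str = "series",
    props: DinucPropertyTable | None = None,
) -> np.ndarray:
    """Pseudo dinucleotide composition with lambda sequence-order factors.

    The first 16 components are normalized dinucleotide frequencies and the
    last ``lam`` are weighted correlation factors theta_j, the mean
    correlation between dinucleotides j steps apart.  The ``series`` variant
    measures correlation as the property-averaged squared difference; the
    ``parallel`` variant (PCPseDNC) as the property-averaged product.  The
    full vector sums to 1.
    """
    _validate(sequence)
    props = props or dinuc_property_table()
    rows = _dinuc_property_rows(sequence, props)
    n_d = rows.shape[0]
    if lam < 1 or lam > n_d - 1:
        raise ValueError(f"lam {lam} invalid for {n_d} dinucleotides")
    if variant not in ("series", "parallel"):
        raise ValueError(f"unknown variant {variant!r}")
    freqs = kmer_composition(sequence, 2)
    thetas = np.zeros(lam)
    for j in range(1, lam + 1):
        a, b = rows[:-j], rows[j:]
        if variant == "series":
            corr = ((a - b) ** 2).mean(axis=1)
        else:
            corr = (a * b).mean(axis=1)
        thetas[j - 1] = corr.mean()
    denom = 1.0 + weight * thetas.sum()
    return np.concatenate([freqs / denom, weight * thetas / denom])


def pc_pse_dnc(sequence: str, lam: int = 2, weight: float = 0.05) -> np.ndarray:
    return pse_dnc(sequence, lam=lam, weight=weight, variant="parallel")


# ---------------------------------------------------------------------------
# registry


def descriptor_registry() -> dict[str, tuple[Callable[[str], np.ndarray], int]]:
    """The 14 named descriptors with their expected output lengths."""
    return {
        "ANF": (anf, 41),
        "binary": (one_hot_binary, 164),
        "DAC": (dac, 12),
        "DNC": (dnc, 16),
        "EIIP": (eiip_profile, 41),
        "ENAC": (enac, 148),
        "Kmer": (dnc, 16),
        "NAC": (nac, 4),
        "NCP": (ncp, 123),
        "PCPseDNC": (pc_pse_dnc, 18),
        "PseDNC": (pse_dnc, 18),
        "PseEIIP": (pse_eiip, 64),
        "RCKmer": (rc_kmer, 10),
        "TNC": (tnc, 64),
    }


def component_names(name: str) -> list[str]:
    """Column labels for a descriptor's TSV output (e.g. ``kmer_AA``)."""
    if name in ("NAC",):
        return [f"nac_{c}" for c in ALPHABET]
    if name in ("DNC", "Kmer"):
        return [f"kmer_{m}" for m in _kmers(2)]
    if name == "TNC":
        return [f"kmer_{m}" for m in _kmers(3)]
    if name == "RCKmer":
        reps, _ = _rc_classes(2)
        return [f"rckmer_{m}" for m in reps]
    if name == "binary":
        return [f"pos{i}_{c}" for i in range(41) for c in ALPHABET]
    if name == "ANF":
        return [f"anf_pos{i}" for i in range(41)]
    if name == "EIIP":
        return [f"eiip_pos{i}" for i in range(41)]
    if name == "PseEIIP":
        return [f"pseeiip_{m}" for m in _kmers(3)]
    if name == "NCP":
        return [f"pos{i}_{b}" for i in range(41) for b in ("ring", "hbond", "func")]
    if name == "ENAC":
        return [f"win{w}_{c}" for w in range(37) for c in ALPHABET]
    if name == "DAC":
        props = dinuc_property_table().property_names
        return [f"dac_{p}_lag{g}" for p in props for g in (1, 2)]
    if name in ("PseDNC", "PCPseDNC"):
        pre = name.lower()
        return [f"{pre}_{m}" for m in _kmers(2)] + [f"{pre}_theta{j}" for j in (1, 2)]
    raise KeyError(f"unknown descriptor {name!r}")


def featurize(samples: SampleSet | Sequence[str], name: str) -> np.ndarray:
    """Apply one registered descriptor to every sequence; returns (n, d)."""
    registry = descriptor_registry()
    if name not in registry:
        raise KeyError(f"unknown descriptor {name!r}; known: {sorted(registry)}")
    func, length = registry[name]
    seqs = samples.sequences if isinstance(samples, SampleSet) else list(samples)
    if not seqs:
        return np.empty((0, length))
    return np.stack([func(s) for s in seqs])


class DescriptorTransformer(BaseEstimator, TransformerMixin):
    """Sklearn transformer mapping sequences to one descriptor's features.

    Parameters
    ----------
    descriptor : str
        A name from :func:`descriptor_registry`.
    """

    def __init__(self, descriptor: str = "Kmer"):
        self.descriptor = descriptor

    def fit(self, X, y=None):
        registry = descriptor_registry()
        if self.descriptor not in registry:
            raise KeyError(f"unknown descriptor {self.descriptor!r}")
        self.n_features_out_ = registry[self.descriptor][1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_features_out_"):
            self.fit(X)
        return featurize(X, self.descriptor)

    def get_feature_names_out(self, input_features=None):
        return np.array(component_names(self.descriptor))
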