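"""Reading, validation, encoding and splitting of labelled 41-nt RNA sequence sets.

Every candidate site is represented as a fixed-length window of 41 nucleotides
over the RNA alphabet {A, C, G, U} with the candidate cytosine at 0-based
position 20.  Positions 0-19 are the upstream flank and positions 21-40 the
downstream flank.  Labels are binary: 1 marks an experimentally supported
5-hydroxymethylcytosine (5hmC) site, 0 a non-site.

Integer encoding follows the convention A -> 0, C -> 1, U -> 2, G -> 3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

SEQ_LENGTH = 41
CENTER = 20
ALPHABET = "ACGU"
NT_TO_INT = {"A": 0, "C": 1, "U": 2, "G": 3}
INT_TO_NT = {v: k for k, v in NT_TO_INT.items()}


class SequenceValidationError(ValueError):
    """A sequence record violates the fixed-window invariants."""


class FastaParseError(ValueError):
    """A FASTA record could not be parsed or labelled."""


def normalize_alphabet(raw: str) -> str:
    """Uppercase, strip whitespace and map DNA 'T' to RNA 'U'.

    Raises ``SequenceValidationError`` for any symbol outside
    {A, C, G, U, T} (case-insensitive); ambiguity codes are not supported.
    """
    cleaned = "".join(raw.split()).upper().replace("T", "U")
    for ch in cleaned:
        if ch not in NT_TO_INT:
            raise SequenceValidationError(f"invalid nucleotide symbol {ch!r}")
    return cleaned


@dataclass(frozen=True)
class RnaSample:
    """One labelled 41-nt candidate window with a central cytosine."""

    id: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if len(self.sequence) != SEQ_LENGTH:
            raise SequenceValidationError(
                f"sample {self.id!r}: length {len(self.sequence)}, expected length {SEQ_LENGTH}"
            )
        for ch in self.sequence:
            if ch not in NT_TO_INT:
                raise SequenceValidationError(
                    f"sample {self.id!r}: invalid nucleotide symbol {ch!r}"
                )
        if self.sequence[CENTER] != "C":
            raise SequenceValidationError(
                f"sample {self.id!r}: central position {CENTER} is "
                f"{self.sequence[CENTER]!r}, expected 'C'"
            )
        if self.label not in (0, 1):
            raise SequenceValidationError(
                f"sample {self.id!r}: label {self.label!r} not in {{0, 1}}"
            )


@dataclass
class SampleSet:
    """An ordered collection of :class:`RnaSample` with unique ids."""

    samples: list[RnaSample] = field(default_factory=list)
    tag: str = "unsplit"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceValidationError(f"duplicate sample ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[RnaSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> RnaSample:
        return self.samples[i]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def sequences(self) -> list[str]:
        return [s.sequence for s in self.samples]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def label_counts(self) -> dict[int, int]:
        labels = self.labels
        return {1: int((labels == 1).sum()), 0: int((labels == 0).sum())}

    def subset(self, indices: Sequence[int], tag: str | None = None) -> "SampleSet":
        return SampleSet([self.samples[i] for i in indices], tag=tag or self.tag)


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of a seeded stratified two-way split."""

    fraction_first: float
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_first <= 1.0:
            raise ValueError(f"fraction_first must be in [0, 1], got {self.fraction_first}")


def encode_integers(sample: RnaSample | str) -> np.ndarray:
    """Map a sequence to its integer vector (A=0, C=1, U=2, G=3)."""
    seq = sample.sequence if isinstance(sample, RnaSample) else sample
    try:
        return np.array([NT_TO_INT[ch] for ch in seq], dtype=np.int64)
    except KeyError as exc:
        raise SequenceValidationError(f"invalid nucleotide symbol {exc.args[0]!r}") from exc


def decode_integers(vec: Iterable[int]) -> str:
    """Inverse of :func:`encode_integers`."""
    try:
        return "".join(INT_TO_NT[int(v)] for v in vec)
    except KeyError as exc:
        raise SequenceValidationError(f"invalid integer code {exc.args[0]!r}") from exc


def encode_matrix(samples: SampleSet | Sequence[str]) -> np.ndarray:
    """Integer-encode a whole set into an (n, 41) array."""
    seqs = samples.sequences if isinstance(samples, SampleSet) else list(samples)
    return np.stack([encode_integers(s) for s in seqs]) if seqs else np.empty((0, SEQ_LENGTH), int)


def _label_from_header(record_id: str, description: str) -> tuple[str, int]:
    token = description.split()[0] if description else record_id
    if "|" in token:
        base, _, tail = token.rpartition("|")
        if tail in ("0", "1"):
            return base, int(tail)
    raise FastaParseError(
        f"record {record_id!r}: no trailing '|0'/'|1' label token and no label file given"
    )


def _labels_from_tsv(path: str | Path) -> dict[str, int]:
    table: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise FastaParseError(f"{path}: malformed label line {ln}: {line!r}")
        table[parts[0]] = int(parts[1])
    return table


def read_fasta(
    path: str | Path,
    labels: str | Path | Mapping[str, int] | None = None,
    tag: str = "unsplit",
) -> SampleSet:
    """Read a labelled FASTA file into a :class:`SampleSet`.

    Labels come either from a trailing ``|1`` / ``|0`` token on the header
    (default) or from ``labels``: a two-column id/label TSV file or mapping.
    Sequences are normalized (case, T->U) before validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label_map: Mapping[str, int] | None
    if labels is None:
        label_map = None
    elif isinstance(labels, (str, Path)):
        label_map = _labels_from_tsv(labels)
    else:
        label_map = labels

    out: list[RnaSample] = []
    for record in SeqIO.parse(str(path), "fasta"):
        if label_map is not None:
            rid = record.id
            if rid not in label_map:
                raise FastaParseError(f"record {rid!r}: missing from label file")
            label = label_map[rid]
        else:
            rid, label = _label_from_header(record.id, record.description)
        seq = normalize_alphabet(str(record.seq))
        out.append(RnaSample(id=rid, sequence=seq, label=label))
    return SampleSet(out, tag=tag)


def write_fasta(data: SampleSet, path: str | Path) -> None:
    """Write a SampleSet as FASTA with ``>id|label`` headers."""
    with open(path, "w") as fh:
        for s in data:
            fh.write(f">{s.id}|{s.label}\n{s.sequence}\n")


def split_dataset(data: SampleSet, spec: SplitSpec) -> tuple[SampleSet, SampleSet]:
    """Seeded (stratified) two-way split.

    Stratified mode gives the first partition exactly
    ``floor(fraction_first * n_class)`` samples of each class, chosen by a
    seeded shuffle; the remainder forms the second partition.  662+662 at
    fraction 0.9 therefore yields 595+595 / 67+67.  Partitions preserve the
    input ordering of the retained samples.
    """
    if len(data) == 0:
        raise ValueError("cannot split an empty SampleSet")
    rng = np.random.default_rng(spec.seed)
    first_idx: list[int] = []
    if spec.stratified:
        labels = data.labels
        for cls in (1, 0):
            cls_idx = np.flatnonzero(labels == cls)
            n_take = int(np.floor(spec.fraction_first * len(cls_idx)))
            chosen = rng.permutation(len(cls_idx))[:n_take]
            first_idx.extend(cls_idx[chosen].tolist())
    else:
        n_take = int(np.floor(spec.fraction_first * len(data)))
        first_idx = rng.permutation(len(data))[:n_take].tolist()
    first_set = set(first_idx)
    first = data.subset(sorted(first_set), tag="train")
    second = data.subset([i for i in range(len(data)) if i not in first_set], tag="independent")
    return first, second


def split_manifest(first: SampleSet, second: SampleSet, spec: SplitSpec) -> dict:
    """JSON-serializable record sufficient to audit a split."""
    return {
        "fraction_first": spec.fraction_first,
        "seed": spec.seed,
        "stratified": spec.stratified,
        "first": {"n": len(first), **{f"label_{k}": v for k, v in first.label_counts().items()}},
        "second": {"n": len(second), **{f"label_{k}": v for k, v in second.label_counts().items()}},
    }


def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
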