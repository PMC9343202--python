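"""Sequence reading, normalization, tokenization and padding.

All sequences are normalized onto the RNA alphabet {A, C, G, U} (uppercase,
T -> U) so that miRBase-style miRNA and RefSeq-style mRNA inputs share one
vocabulary.  Model inputs are right-padded to a fixed 30-nt window with a
dedicated PAD token, keeping the 5' seed region of the miRNA at fixed
positions 1-8.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Fixed model-input window, in nucleotides.  The longest human mature miRNA
#: is 26 nt and candidate target sites are at most 30 nt, so every input fits.
MODEL_INPUT_LENGTH = 30

NUCLEOTIDES = ("A", "C", "G", "U")
PAD_TOKEN = "PAD"
PAD_INDEX = 4

_NORMALIZE = {**{n: n for n in NUCLEOTIDES}, "T": "U"}


@dataclass(frozen=True)
class Alphabet:
    """The nucleotide vocabulary {A, C, G, U} plus a PAD token.

    ``unknown_policy`` decides what happens to characters outside the
    alphabet after normalization (e.g. ambiguity codes such as N):

    - ``"reject"``: raise a ``ValueError`` naming the offending position;
    - ``"skip"``: drop the character;
    - ``"map_to_random"``: substitute a uniformly random nucleotide (needs
      an ``rng`` at tokenization time).
    """

    unknown_policy: str = "reject"
    tokens: tuple[str, ...] = NUCLEOTIDES
    pad_token: str = PAD_TOKEN

    def __post_init__(self) -> None:
        if self.unknown_policy not in ("reject", "skip", "map_to_random"):
            raise ValueError(f"unknown_policy {self.unknown_policy!r} not recognised")
        if self.tokens != NUCLEOTIDES:
            raise ValueError("alphabet must consist of exactly A, C, G, U")

    @property
    def size(self) -> int:
        """Number of nucleotide tokens (PAD excluded)."""
        return len(self.tokens)

    def index_of(self, token: str) -> int:
        if token == self.pad_token:
            return PAD_INDEX
        return self.tokens.index(token)


@dataclass
class TokenSequence:
    """A tokenized sequence with explicit padding bookkeeping.

    ``tokens`` holds alphabet indices (A=0, C=1, G=2, U=3, PAD=4);
    ``original_length`` is the pre-padding length in nucleotides.
    """

    tokens: np.ndarray
    original_length: int

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        if self.original_length > len(self.tokens):
            raise ValueError("original_length exceeds token count")
        if np.any(self.tokens[: self.original_length] == PAD_INDEX):
            raise ValueError("PAD token inside the unpadded region")
        if np.any(self.tokens[self.original_length :] != PAD_INDEX):
            raise ValueError("non-PAD token in the padded region")

    @property
    def padded_length(self) -> int:
        return len(self.tokens)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TokenSequence):
            return NotImplemented
        return (
            self.original_length == other.original_length
            and np.array_equal(self.tokens, other.tokens)
        )


@dataclass
class SitePair:
    """One (miRNA, candidate target site) example with a binary label."""

    pair_id: str
    mirna: TokenSequence
    cts: TokenSequence
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        for name, seq in (("mirna", self.mirna), ("cts", self.cts)):
            if not 1 <= seq.original_length <= MODEL_INPUT_LENGTH:
                raise ValueError(
                    f"{name} of pair {self.pair_id!r} has length "
                    f"{seq.original_length}, outside [1, {MODEL_INPUT_LENGTH}]"
                )


@dataclass
class SiteDataset:
    """A collection of site pairs with optional fold assignments."""

    pairs: list[SitePair]
    fold_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate pair_id {dup!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=np.int64)

    def class_counts(self) -> dict[int, int]:
        labels = self.labels
        return {0: int(np.sum(labels == 0)), 1: int(np.sum(labels == 1))}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteDataset):
            return NotImplemented
        return self.pairs == other.pairs and self.fold_of == other.fold_of


def read_fasta(path, molecule: str = "miRNA") -> list[tuple[str, str]]:
    """Read a FASTA file into ``(identifier, raw sequence)`` records.

    Wrapped sequence lines are concatenated; records with an empty sequence
    are skipped with a warning.  ``molecule`` is a label used only for
    logging ("miRNA" or "mRNA").
    """
    records: list[tuple[str, str]] = []
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise ValueError(f"{path}: line 1 is not a FASTA header: {first.strip()!r}")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            if not seq:
                warnings.warn(f"skipping empty-sequence record {rec.id!r} in {path}")
                continue
            records.append((rec.description, seq))
    logger.info("read %d %s records from %s", len(records), molecule, path)
    return records


def normalize_and_tokenize(
    seq: str,
    alphabet: Alphabet,
    rng: np.random.Generator | None = None,
) -> TokenSequence:
    """Uppercase, map T to U, and convert a raw string to token indices.

    Characters outside {A,C,G,U,T} (case-insensitive) are handled per the
    alphabet's ``unknown_policy``.
    """
    if not seq:
        raise ValueError("cannot tokenize an empty sequence")
    out: list[int] = []
    for pos, ch in enumerate(seq):
        norm = _NORMALIZE.get(ch.upper())
        if norm is not None:
            out.append(NUCLEOTIDES.index(norm))
        elif alphabet.unknown_policy == "skip":
            continue
        elif alphabet.unknown_policy == "map_to_random":
            if rng is None:
                raise ValueError("map_to_random policy requires an rng")
            out.append(int(rng.integers(0, len(NUCLEOTIDES))))
        else:
            raise ValueError(
                f"unknown character {ch!r} at position {pos} (1-based {pos + 1})"
            )
    return TokenSequence(tokens=np.array(out, dtype=np.int64), original_length=len(out))


def detokenize(seq: TokenSequence) -> str:
    """Inverse of tokenization; PAD positions are stripped."""
    return "".join(NUCLEOTIDES[t] for t in seq.tokens[: seq.original_length])


def pad_to_length(seq: TokenSequence, length: int = MODEL_INPUT_LENGTH) -> TokenSequence:
    """Right-pad a token sequence with PAD up to ``length`` positions.

    Idempotent on already-padded input; sequences longer than ``length``
    are an error (site-level sequences are at most 30 nt).
    """
    if seq.original_length > length:
        raise ValueError(
            f"sequence of length {seq.original_length} exceeds window of {length}"
        )
    tokens = np.full(length, PAD_INDEX, dtype=np.int64)
    tokens[: seq.original_length] = seq.tokens[: seq.original_length]
    return TokenSequence(tokens=tokens, original_length=seq.original_length)


_TSV_COLUMNS = ("pair_id", "mirna_seq", "cts_seq", "label")


def read_site_pairs(path, alphabet: Alphabet | None = None) -> SiteDataset:
    """Read a site-pair TSV (columns pair_id, mirna_seq, cts_seq, label).

    Sequences are tokenized under a reject policy (labeled examples must be
    clean) and padded to the 30-nt model window.
    """
    if alphabet is None:
        alphabet = Alphabet(unknown_policy="reject")
    pairs: list[SitePair] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TSV_COLUMNS:
            raise ValueError(
                f"{path}: expected header {_TSV_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            pair_id, mirna_seq, cts_seq, label_str = fields
            if pair_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pair_id {pair_id!r}")
            seen.add(pair_id)
            if label_str not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {label_str!r}")
            for col, raw in (("mirna_seq", mirna_seq), ("cts_seq", cts_seq)):
                if len(raw) > MODEL_INPUT_LENGTH:
                    raise ValueError(
                        f"{path}:{lineno}: {col} of pair {pair_id!r} is "
                        f"{len(raw)} nt, exceeding {MODEL_INPUT_LENGTH}"
                    )
            pairs.append(
                SitePair(
                    pair_id=pair_id,
                    mirna=pad_to_length(normalize_and_tokenize(mirna_seq, alphabet)),
                    cts=pad_to_length(normalize_and_tokenize(cts_seq, alphabet)),
                    label=int(label_str),
                )
            )
    dataset = SiteDataset(pairs=pairs)
    counts = dataset.class_counts()
    logger.info(
        "read %d site pairs from %s (positive=%d, negative=%d)",
        len(pairs), path, counts[1], counts[0],
    )
    return dataset


def write_site_pairs(dataset: SiteDataset, path) -> None:
    """Write a SiteDataset as the four-column TSV exchange format."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for p in dataset.pairs:
            fh.write(f"{p.pair_id}\t{detokenize(p.mirna)}\t{detokenize(p.cts)}\t{p.label}\n")
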