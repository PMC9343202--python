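"""Synthetic (miRNA, candidate target site) pairs with seed structure.

The generator emulates the statistical signature the classifier must learn:
binding is dominated by Watson-Crick complementarity between the miRNA seed
region (nucleotides 2-8, 1-based) and the target site.  A positive pair's
CTS contains the exact reverse complement of the miRNA's seed heptamer at a
uniformly random offset inside otherwise random background; a negative
pair's CTS is resampled by rejection until it contains no such match.
Classes are generated at exact requested counts, miRNA lengths span the
human mature-miRNA range (19-26 nt, maximum 26), and CTS lengths stay
within the 30-nt site window.  ``label_noise`` flips labels at a given
rate to emulate annotation error.

The companion hand-coded ``seed_match_detector`` classifies by the same
substring rule, so at zero noise it scores accuracy 1.0 by construction —
the ceiling a learned model approaches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mirsite.sequence_io import (
    MODEL_INPUT_LENGTH,
    PAD_INDEX,
    SiteDataset,
    SitePair,
    TokenSequence,
    detokenize,
    pad_to_length,
)

#: Token-index complement map: A<->U, C<->G.
_COMPLEMENT = np.array([3, 2, 1, 0])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    ``seed_region`` is the 1-based inclusive interval of miRNA positions
    whose reverse complement defines a binding site (default 2-8, the
    canonical seed).  ``base_composition`` gives the i.i.d. nucleotide
    probabilities (A, C, G, U), uniform by default.
    """

    n_positive: int = 1000
    n_negative: int = 1000
    mirna_length_range: tuple[int, int] = (19, 26)
    cts_length_range: tuple[int, int] = (20, 30)
    seed_region: tuple[int, int] = (2, 8)
    label_noise: float = 0.0
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mirna_length_range
        if not (1 <= lo <= hi <= MODEL_INPUT_LENGTH):
            raise ValueError("miRNA length range must lie within [1, 30]")
        clo, chi = self.cts_length_range
        if not (1 <= clo <= chi <= MODEL_INPUT_LENGTH):
            raise ValueError("CTS length range must lie within [1, 30]")
        s, e = self.seed_region
        if not (1 <= s <= e <= lo):
            raise ValueError("seed region must fit inside every generated miRNA")
        if e - s + 1 > clo:
            raise ValueError("seed match must fit inside every generated CTS")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")
        comp = np.asarray(self.base_composition, dtype=np.float64)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must be a probability 4-vector")


def reverse_complement(seq: TokenSequence) -> TokenSequence:
    """Watson-Crick reverse complement (A<->U, C<->G, order reversed).

    An involution on unpadded sequences; PAD tokens are rejected.
    """
    if np.any(seq.tokens == PAD_INDEX):
        raise ValueError("cannot reverse-complement a padded sequence")
    rc = _COMPLEMENT[seq.tokens[::-1]]
    return TokenSequence(tokens=rc, original_length=len(rc))


def _contains(haystack: np.ndarray, needle: np.ndarray) -> bool:
    return needle.astype(np.uint8).tobytes() in haystack.astype(np.uint8).tobytes()


def _seed_rc(mirna_tokens: np.ndarray, seed_region: tuple[int, int]) -> np.ndarray:
    s, e = seed_region
    seed = mirna_tokens[s - 1:e]  # 1-based inclusive interval
    return _COMPLEMENT[seed[::-1]]


def seed_match_detector(
    mirna: TokenSequence, cts: TokenSequence, seed_region: tuple[int, int] = (2, 8)
) -> int:
    """Rule-based classifier: 1 iff the CTS contains the reverse complement
    of the miRNA seed region as an exact substring."""
    m = mirna.tokens[: mirna.original_length]
    c = cts.tokens[: cts.original_length]
    return int(_contains(c, _seed_rc(m, seed_region)))


def generate_pair(
    positive: bool, config: SyntheticConfig, rng: np.random.Generator,
    pair_id: str = "pair",
) -> SitePair:
    """Draw one labeled pair under the seed-complementarity model.

    The miRNA is i.i.d. from ``base_composition`` at a uniform length in
    range.  Positive: the seed heptamer's reverse complement is planted in a
    random CTS at a uniform offset.  Negative: the CTS is redrawn until it
    contains no exact seed match (rejection; for a random 30-nt uniform CTS
    a fixed heptamer occurs with probability ~0.0015, so this rarely
    iterates).  Finally the label is flipped with probability
    ``label_noise``.
    """
    comp = np.asarray(config.base_composition)
    mlo, mhi = config.mirna_length_range
    m_len = int(rng.integers(mlo, mhi + 1))
    mirna = rng.choice(4, size=m_len, p=comp)
    site = _seed_rc(mirna, config.seed_region)
    clo, chi = config.cts_length_range
    c_len = int(rng.integers(clo, chi + 1))
    if positive:
        cts = rng.choice(4, size=c_len, p=comp)
        offset = int(rng.integers(0, c_len - len(site) + 1))
        cts[offset:offset + len(site)] = site
    else:
        for _ in range(1000):
            cts = rng.choice(4, size=c_len, p=comp)
            if not _contains(cts, site):
                break
        else:
            raise RuntimeError(
                "rejection sampling failed 1000 times; base composition is "
                "pathological for seed-free sites"
            )
    label = int(positive)
    if config.label_noise > 0 and rng.random() < config.label_noise:
        label = 1 - label
    return SitePair(
        pair_id=pair_id,
        mirna=pad_to_length(TokenSequence(tokens=mirna, original_length=m_len)),
        cts=pad_to_length(TokenSequence(tokens=cts, original_length=c_len)),
        label=label,
    )


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[SiteDataset, list[str], list[str]]:
    """Generate a full dataset plus matched embedding corpora.

    Returns ``(dataset, mirna_corpus, cts_corpus)`` where the corpora are
    the raw sequence strings of every generated miRNA and CTS, usable to
    pretrain mi2vec and m2vec on data matching the classifier's inputs.
    Deterministic given ``config.rng_seed``; class counts are exact (before
    label noise).
    """
    if config.n_positive + config.n_negative < 2:
        raise ValueError("need at least two pairs")
    rng = np.random.default_rng(config.rng_seed)
    pairs: list[SitePair] = []
    width = len(str(config.n_positive + config.n_negative))
    for i in range(config.n_positive + config.n_negative):
        positive = i < config.n_positive
        pairs.append(generate_pair(positive, config, rng, pair_id=f"pair_{i:0{width}d}"))
    dataset = SiteDataset(pairs=pairs)
    mirna_corpus = [detokenize(p.mirna) for p in pairs]
    cts_corpus = [detokenize(p.cts) for p in pairs]
    return dataset, mirna_corpus, cts_corpus


def write_fasta(sequences: list[str], path, prefix: str = "seq") -> None:
    """Write raw sequences as an uncompressed FASTA file."""
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f">{prefix}_{i}\n{seq}\n")
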