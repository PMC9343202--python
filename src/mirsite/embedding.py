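"""Distributed nucleotide representations via the skip-gram model.

Each miRNA or mRNA sequence is treated as a sentence whose words are single
nucleotides.  A skip-gram model with negative sampling learns a dense vector
per nucleotide; training on the miRNA corpus is called mi2vec and on the
mRNA corpus m2vec.  A one-hot table is provided as the baseline encoder, and
cosine-similarity analytics support comparing the learned vectors.

The exact four-way softmax over the nucleotide vocabulary is also
implemented (``softmax_distribution``) as a reference path: with only four
words the full partition function is cheap, so tests can check the
negative-sampling surrogate against a properly normalized distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from mirsite.sequence_io import (
    PAD_INDEX,
    Alphabet,
    TokenSequence,
    normalize_and_tokenize,
)

logger = logging.getLogger(__name__)

#: Embedding dimensions explored when comparing encoders.
DIMENSION_GRID = (2, 4, 10, 20, 30, 50, 100)


@dataclass(frozen=True)
class SkipGramConfig:
    """Hyperparameters of skip-gram training.

    ``window`` is the maximum distance c between the center nucleotide and a
    predicted context nucleotide.  ``negative_samples`` is the number k of
    noise words per (center, context) pair.  The learning rate decays
    linearly from ``learning_rate`` to 1e-4 of it across all updates.
    """

    dim: int = 50
    window: int = 5
    min_count: int = 1
    epochs: int = 10
    negative_samples: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be a positive integer")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.negative_samples < 1:
            raise ValueError("negative_samples must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EmbeddingTable:
    """Per-nucleotide input vectors v_w and output vectors v'_w.

    ``input_vectors`` (shape 4 x dim, rows indexed A=0,C=1,G=2,U=3) are the
    representation handed to the classifier; ``output_vectors`` are the
    context-side parameters kept for training and auditing.  The PAD vector
    is identically zero and never trained.
    """

    molecule: str
    input_vectors: np.ndarray
    output_vectors: np.ndarray
    #: mean negative-sampling loss per training epoch (None if not trained)
    epoch_losses: list[float] | None = None

    def __post_init__(self) -> None:
        self.input_vectors = np.asarray(self.input_vectors, dtype=np.float64)
        self.output_vectors = np.asarray(self.output_vectors, dtype=np.float64)
        if self.input_vectors.shape != self.output_vectors.shape:
            raise ValueError("input and output vector arrays must share a shape")
        if self.input_vectors.shape[0] != 4 or self.input_vectors.ndim != 2:
            raise ValueError("expected one vector per nucleotide (4 x dim)")

    @property
    def dim(self) -> int:
        return self.input_vectors.shape[1]

    @property
    def pad_vector(self) -> np.ndarray:
        return np.zeros(self.dim)


def build_corpus(
    records: list,
    alphabet: Alphabet | None = None,
) -> list[np.ndarray]:
    """Turn raw sequences into token sentences for skip-gram training.

    ``records`` may be raw strings or ``(identifier, sequence)`` tuples as
    returned by :func:`mirsite.sequence_io.read_fasta`.  Sentences are not
    padded.  Under a skip policy, sequences that become empty (e.g. all-N)
    are dropped with a warning.
    """
    if alphabet is None:
        alphabet = Alphabet(unknown_policy="skip")
    sentences: list[np.ndarray] = []
    for rec in records:
        seq = rec[1] if isinstance(rec, tuple) else rec
        tok = normalize_and_tokenize(seq, alphabet)
        if tok.original_length == 0:
            warnings.warn(f"dropping sequence with no valid nucleotides: {seq[:20]!r}")
            continue
        sentences.append(tok.tokens)
    if not sentences:
        raise ValueError("corpus is empty after normalization")
    return sentences


def skipgram_pairs(sentence: np.ndarray, window: int) -> list[tuple[int, int]]:
    """Enumerate (center, context) token pairs within the window.

    For each position n the pairs (w_n, w_{n+m}) with -c <= m <= c, m != 0
    and n+m inside the sentence are emitted, n ascending then m ascending.
    Sentences shorter than 2 yield no pairs.
    """
    sentence = np.asarray(sentence)
    length = len(sentence)
    pairs: list[tuple[int, int]] = []
    for n in range(length):
        for m in range(-window, window + 1):
            if m == 0:
                continue
            j = n + m
            if 0 <= j < length:
                pairs.append((int(sentence[n]), int(sentence[j])))
    return pairs


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    # Numerically safe logistic: never exponentiates a positive argument.
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                    np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))


def skipgram_loss_and_grads(
    pair: tuple[int, int],
    table: EmbeddingTable,
    negatives: list[int],
) -> tuple[float, dict]:
    """Negative-sampling loss and analytic gradients for one pair.

    loss = -log sigma(v'_ctx . v_ctr) - sum_neg log sigma(-v'_neg . v_ctr).
    Gradients are returned only for the touched vectors: the center input
    vector, the context output vector, and each negative's output vector.
    """
    center, context = pair
    v = table.input_vectors[center]
    u_ctx = table.output_vectors[context]
    s_pos = float(_sigmoid(np.dot(u_ctx, v)))
    # -log sigma(x) computed stably as log(1 + exp(-x))
    x = np.dot(u_ctx, v)
    loss = float(np.logaddexp(0.0, -x))
    d_v = (s_pos - 1.0) * u_ctx
    d_ctx = (s_pos - 1.0) * v
    d_negs = []
    for neg in negatives:
        u_neg = table.output_vectors[neg]
        xn = np.dot(u_neg, v)
        loss += float(np.logaddexp(0.0, xn))
        s_neg = float(_sigmoid(xn))
        d_v = d_v + s_neg * u_neg
        d_negs.append(s_neg * v)
    return loss, {"center": d_v, "context": d_ctx, "negatives": d_negs}


def softmax_distribution(table: EmbeddingTable, center: int) -> np.ndarray:
    """Full-softmax P(w | center) over the four-nucleotide vocabulary.

    The reference distribution exp(v'_w . v_center) / sum_w' exp(...),
    practical here because the lexicon has only four words.
    """
    scores = table.output_vectors @ table.input_vectors[center]
    scores = scores - np.max(scores)
    e = np.exp(scores)
    return e / e.sum()


def _unigram_noise(sentences: list[np.ndarray]) -> np.ndarray:
    """Unigram distribution raised to the 3/4 power (word2vec convention)."""
    counts = np.zeros(4)
    for s in sentences:
        counts += np.bincount(s, minlength=4)[:4]
    powered = counts**0.75
    return powered / powered.sum()


def train_skipgram(
    corpus: list[np.ndarray],
    config: SkipGramConfig,
    molecule: str = "miRNA",
) -> EmbeddingTable:
    """Train an embedding table on a token-sentence corpus (mi2vec / m2vec).

    Stochastic gradient descent over all (center, context) pairs, one pass
    per epoch, with ``negative_samples`` noise words per pair drawn from the
    unigram^(3/4) distribution excluding the true context.  Deterministic
    given ``config.seed``.  Input vectors start uniform in [-0.5/d, 0.5/d];
    output vectors start at zero.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    counts = np.zeros(4)
    for s in corpus:
        counts += np.bincount(np.asarray(s), minlength=4)[:4]
    vocab = [w for w in range(4) if counts[w] >= config.min_count]
    if not vocab:
        raise ValueError("vocabulary empty after min_count filtering")

    rng = np.random.default_rng(config.seed)
    d = config.dim
    inp = rng.uniform(-0.5 / d, 0.5 / d, size=(4, d))
    out = np.zeros((4, d))
    # Tokens filtered out by min_count keep zero vectors and are never updated.
    mask = np.zeros(4, dtype=bool)
    mask[vocab] = True
    inp[~mask] = 0.0

    noise = _unigram_noise(corpus)
    noise[~mask] = 0.0
    noise = noise / noise.sum()

    all_pairs: list[tuple[int, int]] = []
    for s in corpus:
        kept = np.asarray(s)[mask[np.asarray(s)]]
        all_pairs.extend(skipgram_pairs(kept, config.window))
    if not all_pairs:
        raise ValueError("corpus yields no skip-gram pairs (sentences too short)")

    total_updates = len(all_pairs) * config.epochs
    lr0 = config.learning_rate
    lr_min = lr0 * 1e-4
    k = config.negative_samples

    # Per-context noise CDFs with the true context excluded, for fast
    # deterministic inverse-CDF sampling.
    cdfs = {}
    for ctx in vocab:
        p = noise.copy()
        p[ctx] = 0.0
        p = p / p.sum()
        cdfs[ctx] = np.cumsum(p)

    update = 0
    epoch_losses = []
    for epoch in range(config.epochs):
        total_loss = 0.0
        for center, context in all_pairs:
            lr = max(lr_min, lr0 * (1.0 - update / total_updates))
            update += 1
            negs = np.searchsorted(cdfs[context], rng.random(k)).tolist()
            v = inp[center]
            x = out[context] @ v
            loss = float(np.logaddexp(0.0, -x))
            g_pos = float(_sigmoid(x)) - 1.0
            d_v = g_pos * out[context]
            out[context] = out[context] - lr * g_pos * v
            for neg in negs:
                xn = out[neg] @ v
                loss += float(np.logaddexp(0.0, xn))
                g_neg = float(_sigmoid(xn))
                d_v += g_neg * out[neg]
                out[neg] = out[neg] - lr * g_neg * v
            inp[center] = v - lr * d_v
            total_loss += loss
        epoch_losses.append(total_loss / len(all_pairs))
        logger.info(
            "%s skip-gram epoch %d/%d mean loss %.6f",
            molecule, epoch + 1, config.epochs, epoch_losses[-1],
        )

    half = len(epoch_losses) // 2
    if half >= 1 and epoch_losses[-1] > epoch_losses[half] * 1.05:
        warnings.warn(
            f"skip-gram loss not decreasing over the final half of training "
            f"({epoch_losses[half]:.4f} -> {epoch_losses[-1]:.4f})"
        )
    return EmbeddingTable(molecule=molecule, input_vectors=inp, output_vectors=out,
                          epoch_losses=epoch_losses)


def one_hot_table(alphabet: Alphabet | None = None) -> EmbeddingTable:
    """The 4-dimensional one-hot baseline encoder (standard basis vectors)."""
    eye = np.eye(4)
    return EmbeddingTable(molecule="one-hot", input_vectors=eye, output_vectors=eye.copy())


def encode_sequence(seq: TokenSequence, table: EmbeddingTable) -> np.ndarray:
    """Replace each nucleotide with its vector; PAD rows are zero.

    Returns a (padded_length x dim) float matrix.
    """
    if seq.original_length == 0:
        raise ValueError("cannot encode an empty sequence")
    mat = np.zeros((seq.padded_length, table.dim))
    real = seq.tokens != PAD_INDEX
    mat[real] = table.input_vectors[seq.tokens[real]]
    return mat


def cosine_similarity_matrix(table: EmbeddingTable) -> np.ndarray:
    """Pairwise cosine similarity between the four nucleotide input vectors.

    Cosine distance is 1 minus this matrix.  Symmetric, unit diagonal.
    """
    from mirsite.sequence_io import NUCLEOTIDES

    norms = np.linalg.norm(table.input_vectors, axis=1)
    for i, n in enumerate(norms):
        if n == 0:
            raise ValueError(f"zero-norm vector for token {NUCLEOTIDES[i]}")
    unit = table.input_vectors / norms[:, None]
    sim = unit @ unit.T
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, -1.0, 1.0)


def save_cosine_matrix(table: EmbeddingTable, path, distance: bool = False) -> None:
    """Export the 4x4 cosine similarity (or distance) matrix as TSV.

    Suitable for plotting nucleotide-similarity heat maps.
    """
    from mirsite.sequence_io import NUCLEOTIDES

    m = cosine_similarity_matrix(table)
    if distance:
        m = 1.0 - m
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(NUCLEOTIDES) + "\n")
        for i, tok in enumerate(NUCLEOTIDES):
            fh.write(tok + "\t" + "\t".join(f"{v:.17g}" for v in m[i]) + "\n")


def save_table(table: EmbeddingTable, path) -> None:
    """Write the embedding table as diffable TSV (17 significant digits)."""
    from mirsite.sequence_io import NUCLEOTIDES

    with open(path, "w") as fh:
        fh.write(f"{table.molecule}\t{table.dim}\n")
        for arr, tag in ((table.input_vectors, "in"), (table.output_vectors, "out")):
            for i, tok in enumerate(NUCLEOTIDES):
                vals = "\t".join(f"{v:.17g}" for v in arr[i])
                fh.write(f"{tok}:{tag}\t{vals}\n")


def load_table(path) -> EmbeddingTable:
    """Read a table written by :func:`save_table` (bit-exact round trip)."""
    from mirsite.sequence_io import NUCLEOTIDES

    with open(path) as fh:
        molecule, dim_s = fh.readline().rstrip("\n").split("\t")
        dim = int(dim_s)
        inp = np.zeros((4, dim))
        out = np.zeros((4, dim))
        for line in fh:
            head, *vals = line.rstrip("\n").split("\t")
            tok, tag = head.split(":")
            row = NUCLEOTIDES.index(tok)
            arr = inp if tag == "in" else out
            arr[row] = [float(v) for v in vals]
    return EmbeddingTable(molecule=molecule, input_vectors=inp, output_vectors=out)
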