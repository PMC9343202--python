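"""Classifier training: weighted cross-entropy, Adam, deterministic loops.

Hyperparameter defaults follow the tuned operating point of the method:
Adam with learning rate 0.001, batch size 32, 100 epochs.  Embedding tables
are pretrained separately and stay frozen while the classifier trains; the
dataset is encoded once up front with the miRNA table on the miRNA branch
and the mRNA table on the CTS branch.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mirsite.embedding import EmbeddingTable, encode_sequence
from mirsite.model import CNN1d, SequenceClassifier, save_checkpoint, softmax
from mirsite.sequence_io import SiteDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``class_weights`` is a pair (weight of class 0, weight of class 1) or
    ``"auto"`` for inverse-frequency weights.  ``grad_clip`` optionally caps
    the global gradient norm (LSTM gradients can spike); off by default.
    """

    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    optimizer: str = "adam"
    class_weights: tuple[float, float] | str = "auto"
    seed: int = 0
    shuffle: bool = True
    grad_clip: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.learning_rate >= 0.01:
            warnings.warn(
                f"learning rate {self.learning_rate} is in the regime where "
                "training has been observed to collapse to chance accuracy"
            )


@dataclass
class TrainHistory:
    """Per-epoch training trace."""

    loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    seconds: list[float] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        # Wall times stay out of the file so that reruns with one seed
        # produce byte-identical artifacts; timing goes to the log instead.
        with open(path, "w") as fh:
            has_val = len(self.val_accuracy) == len(self.loss)
            cols = ["epoch", "loss", "train_accuracy"]
            if has_val:
                cols.append("val_accuracy")
            fh.write("\t".join(cols) + "\n")
            for e in range(len(self.loss)):
                row = [str(e + 1), f"{self.loss[e]:.17g}", f"{self.train_accuracy[e]:.17g}"]
                if has_val:
                    row.append(f"{self.val_accuracy[e]:.17g}")
                fh.write("\t".join(row) + "\n")


def weighted_cross_entropy(
    logits: np.ndarray, label: int, weights: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Class-weighted cross-entropy of one 2-class logit vector.

    loss = -weights[label] * log softmax(logits)[label], computed from the
    logits with the log-sum-exp trick so saturated logits neither overflow
    nor lose precision.  With weights (1, 1) this is plain cross-entropy.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if logits.shape != (2,):
        raise ValueError("expected a 2-class logit vector")
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    w = float(weights[label])
    if w <= 0 or float(weights[1 - label]) <= 0:
        raise ValueError("class weights must be positive")
    m = float(np.max(logits))
    log_z = m + float(np.log(np.sum(np.exp(logits - m))))
    return w * (log_z - float(logits[label]))


def auto_class_weights(dataset: SiteDataset) -> tuple[float, float]:
    """Inverse-frequency class weights: N_total / (2 * N_c), mean 1 when balanced."""
    counts = dataset.class_counts()
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present to derive class weights")
    total = counts[0] + counts[1]
    return (total / (2.0 * counts[0]), total / (2.0 * counts[1]))


def encode_dataset(
    dataset: SiteDataset, mi_table: EmbeddingTable, m_table: EmbeddingTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode every pair: miRNA branch with mi2vec, CTS branch with m2vec.

    Returns (X_mirna (N,30,d), X_cts (N,30,d), labels (N,)).
    """
    if mi_table.dim != m_table.dim:
        raise ValueError("mi2vec and m2vec tables must share a dimension")
    n = len(dataset)
    if n == 0:
        raise ValueError("dataset is empty")
    d = mi_table.dim
    length = dataset.pairs[0].mirna.padded_length
    X_m = np.zeros((n, length, d))
    X_c = np.zeros((n, length, d))
    for i, pair in enumerate(dataset.pairs):
        X_m[i] = encode_sequence(pair.mirna, mi_table)
        X_c[i] = encode_sequence(pair.cts, m_table)
    return X_m, X_c, dataset.labels


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8) over a param dict."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class SGD:
    """Plain stochastic gradient descent (offered for the optimizer ablation)."""

    def __init__(self, params: dict, lr: float):
        self.lr = lr

    def step(self, params: dict, grads: dict) -> None:
        for k, g in grads.items():
            params[k] -= self.lr * g


def _batch_loss_and_dlogits(logits, labels, weights):
    """Mean weighted CE over a batch and its gradient w.r.t. the logits."""
    B = logits.shape[0]
    m = np.max(logits, axis=1, keepdims=True)
    log_z = m[:, 0] + np.log(np.sum(np.exp(logits - m), axis=1))
    w = np.asarray(weights)[labels]
    loss = float(np.mean(w * (log_z - logits[np.arange(B), labels])))
    probs = softmax(logits)
    one_hot = np.zeros_like(logits)
    one_hot[np.arange(B), labels] = 1.0
    d_logits = (w[:, None] * (probs - one_hot)) / B
    return loss, d_logits


def train_model(
    dataset: SiteDataset,
    model,
    tables: tuple[EmbeddingTable, EmbeddingTable],
    config: TrainConfig,
    val_dataset: SiteDataset | None = None,
    out_dir=None,
):
    """Train a classifier on encoded site pairs.

    ``model`` is a built classifier (:class:`SequenceClassifier` or
    :class:`CNN1d`) or a constructor ``f(input_dim, seed)`` returning one.
    ``tables`` is the (mi2vec, m2vec) pair.  Shuffling is reseeded per epoch
    from the master seed, so the run is deterministic given (dataset,
    config, seed).  When ``out_dir`` is given, ``final.ckpt`` and
    ``best.ckpt`` (highest validation accuracy, or training accuracy when no
    validation set is supplied) are written there.

    Returns ``(model, TrainHistory)``.
    """
    mi_table, m_table = tables
    X_m, X_c, y = encode_dataset(dataset, mi_table, m_table)
    if callable(model) and not isinstance(model, (SequenceClassifier, CNN1d)):
        model = model(mi_table.dim, config.seed)

    weights = config.class_weights
    if weights == "auto":
        weights = auto_class_weights(dataset)
    weights = (float(weights[0]), float(weights[1]))

    if config.optimizer == "adam":
        opt = Adam(model.params, lr=config.learning_rate)
    else:
        opt = SGD(model.params, lr=config.learning_rate)

    val_enc = None
    if val_dataset is not None:
        val_enc = encode_dataset(val_dataset, mi_table, m_table)

    n = len(dataset)
    history = TrainHistory()
    best_acc = -1.0
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        if config.shuffle:
            order = np.random.default_rng([config.seed, epoch]).permutation(n)
        else:
            order = np.arange(n)
        total_loss = 0.0
        total_correct = 0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, cache = model.forward(X_m[idx], X_c[idx])
            loss, d_logits = _batch_loss_and_dlogits(logits, y[idx], weights)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss in epoch {epoch + 1}, batch {n_batches + 1}"
                )
            grads = model.backward(d_logits, cache)
            if config.grad_clip is not None:
                norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                if norm > config.grad_clip:
                    scale = config.grad_clip / norm
                    grads = {k: g * scale for k, g in grads.items()}
            opt.step(model.params, grads)
            total_loss += loss * len(idx)
            total_correct += int(np.sum(np.argmax(logits, axis=1) == y[idx]))
            n_batches += 1
        history.loss.append(total_loss / n)
        history.train_accuracy.append(total_correct / n)
        if val_enc is not None:
            vp = model.predict_proba(val_enc[0], val_enc[1])
            val_acc = float(np.mean(np.argmax(vp, axis=1) == val_enc[2]))
            history.val_accuracy.append(val_acc)
            monitor = val_acc
        else:
            monitor = history.train_accuracy[-1]
        history.seconds.append(time.perf_counter() - t0)
        logger.info(
            "epoch %d/%d loss %.4f train_acc %.4f%s",
            epoch + 1, config.epochs, history.loss[-1], history.train_accuracy[-1],
            f" val_acc {history.val_accuracy[-1]:.4f}" if val_enc is not None else "",
        )
        if out_dir is not None and monitor > best_acc:
            best_acc = monitor
            save_checkpoint(model, out_dir / "best.ckpt")
    if out_dir is not None:
        save_checkpoint(model, out_dir / "final.ckpt")
        history.to_tsv(out_dir / "history.tsv")
    return model, history
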