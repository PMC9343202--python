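"""End-to-end experiment orchestration.

One run executes: simulate (or load) site pairs -> pretrain mi2vec / m2vec
on matched corpora -> encode -> train the classifier -> evaluate, leaving a
self-contained run directory (config snapshot, embedding tables,
checkpoints, history, report, curves, log).  Stages whose outputs already
exist are skipped unless forced, so comparison grids reuse cached
embeddings.  Every run is deterministic given the master seed; reruns
produce byte-identical result artifacts (the timestamped log aside).

Per-stage seeds are derived from the master seed through
``numpy.random.SeedSequence`` so that stages draw independent streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from mirsite import evaluation as ev
from mirsite.embedding import (
    SkipGramConfig,
    build_corpus,
    load_table,
    one_hot_table,
    save_table,
    train_skipgram,
)
from mirsite.model import CNN1d, CNNConfig, ModelConfig, SequenceClassifier, load_checkpoint
from mirsite.sequence_io import SiteDataset, read_site_pairs, write_site_pairs
from mirsite.synthetic import SyntheticConfig, generate_dataset, write_fasta
from mirsite.training import TrainConfig, encode_dataset, train_model

logger = logging.getLogger(__name__)


def _sub_seed(master: int, tag: str) -> int:
    """Derive a deterministic child seed (< 2^31) for one pipeline stage."""
    digest = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence([master, digest]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Resolved configuration of one experiment run."""

    seed: int = 0
    out_dir: str = "run"
    pairs: str | None = None           # path to a site-pair TSV, or None
    simulate: dict = field(default_factory=dict)   # SyntheticConfig overrides
    embedding: dict = field(default_factory=dict)  # SkipGramConfig overrides
    model: dict = field(default_factory=dict)      # ModelConfig overrides
    train: dict = field(default_factory=dict)      # TrainConfig overrides
    k: int = 5
    threshold: float = 0.5
    cv: bool = False                   # full k-fold CV in addition to holdout

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.pairs is not None and not Path(self.pairs).exists():
            raise FileNotFoundError(f"pairs file {self.pairs!r} does not exist")
        # Constructing the sub-configs surfaces schema violations up front,
        # before any stage runs.
        SyntheticConfig(**{**self.simulate, "rng_seed": 0})
        emb = {k: v for k, v in self.embedding.items() if k != "one_hot"}
        SkipGramConfig(**{**emb, "seed": 0})
        ModelConfig(**{k: v for k, v in self.model.items() if k != "cnn1d"})
        TrainConfig(**{**self.train, "seed": 0})
        if self.k < 2:
            raise ValueError("evaluation needs k >= 2")

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def _stage_done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def build_model(config: RunConfig, input_dim: int, seed: int):
    """Construct the classifier named by the config's model section."""
    opts = dict(config.model)
    if opts.pop("cnn1d", False):
        return CNN1d(CNNConfig(input_dim=input_dim), seed=seed)
    return SequenceClassifier(ModelConfig(input_dim=input_dim, **opts), seed=seed)


def run_experiment(config: RunConfig, force: bool = False) -> Path:
    """Execute all pipeline stages, returning the run directory.

    Stages: data, embeddings, train (with a stratified holdout fold as
    validation), evaluate (holdout report; full cross-validation when
    ``config.cv``).  Existing stage outputs are reused unless ``force``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    (out / "config.yaml").write_text(
        f"# config_digest={digest}\n" + config.resolved_yaml()
    )
    log_fh = logging.FileHandler(out / "run.log")
    log_fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logging.getLogger("mirsite").addHandler(log_fh)
    t_start = time.perf_counter()
    try:
        # ---- stage: data -------------------------------------------------
        pairs_path = out / "pairs.tsv"
        mirna_fa = out / "mirna_corpus.fa"
        cts_fa = out / "cts_corpus.fa"
        if config.pairs is not None:
            dataset = read_site_pairs(config.pairs)
            from mirsite.sequence_io import detokenize
            mirna_corpus = [detokenize(p.mirna) for p in dataset.pairs]
            cts_corpus = [detokenize(p.cts) for p in dataset.pairs]
        elif force or not _stage_done([pairs_path, mirna_fa, cts_fa]):
            sim = SyntheticConfig(
                **{**config.simulate, "rng_seed": _sub_seed(config.seed, "simulate")}
            )
            dataset, mirna_corpus, cts_corpus = generate_dataset(sim)
            write_site_pairs(dataset, pairs_path)
            write_fasta(mirna_corpus, mirna_fa, prefix="mirna")
            write_fasta(cts_corpus, cts_fa, prefix="cts")
            logger.info("stage data: generated %d pairs", len(dataset))
        else:
            dataset = read_site_pairs(pairs_path)
            from mirsite.sequence_io import detokenize
            mirna_corpus = [detokenize(p.mirna) for p in dataset.pairs]
            cts_corpus = [detokenize(p.cts) for p in dataset.pairs]
            logger.info("stage data: reusing %s", pairs_path)

        # ---- stage: embeddings -------------------------------------------
        mi_path = out / "mi2vec.tsv"
        m_path = out / "m2vec.tsv"
        one_hot = bool(config.embedding.get("one_hot"))
        if one_hot:
            mi_table = m_table = one_hot_table()
        elif force or not _stage_done([mi_path, m_path]):
            sg = SkipGramConfig(
                **{**{k: v for k, v in config.embedding.items() if k != "one_hot"},
                   "seed": _sub_seed(config.seed, "embedding")}
            )
            mi_table = train_skipgram(build_corpus(mirna_corpus), sg, molecule="miRNA")
            m_table = train_skipgram(build_corpus(cts_corpus), sg, molecule="mRNA")
            save_table(mi_table, mi_path)
            save_table(m_table, m_path)
            logger.info("stage embeddings: trained mi2vec/m2vec (d=%d)", mi_table.dim)
        else:
            mi_table, m_table = load_table(mi_path), load_table(m_path)
            logger.info("stage embeddings: reusing tables")

        # ---- stage: train -------------------------------------------------
        fold_of = ev.stratified_kfold(dataset, k=config.k,
                                      seed=_sub_seed(config.seed, "folds"))
        dataset.fold_of = fold_of
        train_ds = SiteDataset([p for p in dataset.pairs if fold_of[p.pair_id] != 0])
        test_ds = SiteDataset([p for p in dataset.pairs if fold_of[p.pair_id] == 0])
        tconf = TrainConfig(**{**config.train, "seed": _sub_seed(config.seed, "train")})
        final_ckpt = out / "final.ckpt"
        if force or not _stage_done([final_ckpt, out / "history.tsv"]):
            model = build_model(config, mi_table.dim, tconf.seed)
            model, _ = train_model(train_ds, model, (mi_table, m_table), tconf,
                                   val_dataset=test_ds, out_dir=out)
            logger.info("stage train: %d epochs done", tconf.epochs)
        else:
            model = load_checkpoint(final_ckpt)
            logger.info("stage train: reusing %s", final_ckpt)

        # ---- stage: evaluate ----------------------------------------------
        report_path = out / "report.json"
        if force or not _stage_done([report_path]):
            X_m, X_c, y = encode_dataset(test_ds, mi_table, m_table)
            scores = model.predict_proba(X_m, X_c)[:, 1]
            report = ev.evaluate_scores(scores, y, config.threshold)
            payload = {"config_digest": digest, **report.to_dict()}
            if config.cv:
                ctor = lambda dim, seed: build_model(config, dim, seed)
                _, mean_report = ev.cross_validate(
                    dataset, ctor, (mi_table, m_table), tconf,
                    k=config.k, seed=_sub_seed(config.seed, "folds"),
                    threshold=config.threshold,
                )
                payload["cross_validation"] = mean_report.to_dict()
            with open(report_path, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")
            (pr, rc, thr), _ = ev.pr_curve_and_ap(scores, y)
            ev.write_curve_tsv(out / "pr_curve.tsv",
                               {"threshold": thr, "precision": pr, "recall": rc})
            (fpr, tpr, rthr), _ = ev.roc_curve_and_auc(scores, y)
            ev.write_curve_tsv(out / "roc_curve.tsv",
                               {"threshold": rthr, "fpr": fpr, "tpr": tpr})
            logger.info("stage evaluate: holdout acc %.4f", report.acc)
        else:
            logger.info("stage evaluate: reusing %s", report_path)
        logger.info("run complete in %.1f s", time.perf_counter() - t_start)
    except Exception:
        logger.exception("pipeline stage failed")
        raise
    finally:
        logging.getLogger("mirsite").removeHandler(log_fh)
        log_fh.close()
    return out


def compare_encodings(
    config: RunConfig,
    dims: list[int] = (2, 4, 10, 20, 30, 50, 100),
    include_one_hot: bool = True,
    models: tuple[str, ...] = ("bilstm",),
    out_path=None,
    force: bool = False,
) -> list[dict]:
    """Accuracy-versus-embedding-dimension grid (one-hot optional).

    Every cell shares the dataset, fold split and training seed (all runs
    use the master seed, so the simulate/fold streams coincide); only the
    encoder varies.  Returns rows of {model, encoding, dim, accuracy} and
    writes them as TSV when ``out_path`` is given.
    """
    rows = []
    base = dataclasses.asdict(config)
    for model_name in models:
        model_over = {**config.model, "cnn1d": model_name == "cnn1d"}
        encodings = [("one-hot", None)] if include_one_hot else []
        encodings += [("skip-gram", d) for d in dims]
        for enc, dim in encodings:
            over = dict(config.embedding)
            if dim is None:
                over["one_hot"] = True
                over.pop("dim", None)
            else:
                over["dim"] = dim
                over.pop("one_hot", None)
            sub = RunConfig(**{**base,
                               "embedding": over, "model": model_over,
                               "out_dir": str(Path(config.out_dir) /
                                              f"{model_name}_{enc}_{dim or 4}")})
            run_dir = run_experiment(sub, force=force)
            with open(run_dir / "report.json") as fh:
                acc = float(json.load(fh)["acc"])
            rows.append({"model": model_name, "encoding": enc,
                         "dim": dim if dim is not None else 4, "accuracy": acc})
    if out_path is not None:
        _write_rows(out_path, rows, config.digest())
    return rows


#: The two-layer architecture grid of the unit-type ablation.
ARCHITECTURE_GRID = [
    ("RNN", "RNN"), ("GRU", "GRU"), ("LSTM", "LSTM"),
    ("LSTM", "BiLSTM"), ("BiLSTM", "LSTM"), ("BiLSTM", "BiLSTM"),
]

#: The structure grid (hidden1, hidden2, linear1) of the width ablation.
STRUCTURE_GRID = [
    (8, 32, 32), (16, 32, 32), (32, 32, 32), (50, 32, 32), (64, 32, 32),
    (128, 32, 32), (50, 8, 8), (50, 16, 16), (50, 64, 64), (50, 128, 128),
]

#: The hyperparameter grid (learning rate, batch size) of the tuning study.
HYPERPARAMETER_GRID = [
    (0.0005, 32), (0.001, 32), (0.005, 32), (0.01, 32),
    (0.001, 8), (0.001, 16), (0.001, 64), (0.001, 128),
]


def compare_architectures(
    config: RunConfig,
    axis: str = "architecture",
    grid=None,
    out_path=None,
    force: bool = False,
) -> list[dict]:
    """Vary one model axis over a grid, holding data/split/seed fixed.

    ``axis`` is ``"architecture"`` (recurrent unit per layer),
    ``"structure"`` (layer widths) or ``"hyperparameters"`` (lr, batch).
    """
    base = dataclasses.asdict(config)
    rows = []
    if axis == "architecture":
        grid = grid if grid is not None else ARCHITECTURE_GRID
        for l1, l2 in grid:
            sub = RunConfig(**{**base,
                               "model": {**config.model, "layer1": l1, "layer2": l2},
                               "out_dir": str(Path(config.out_dir) / f"arch_{l1}_{l2}")})
            acc = _run_and_read_acc(sub, force)
            rows.append({"layer1": l1, "layer2": l2, "accuracy": acc})
    elif axis == "structure":
        grid = grid if grid is not None else STRUCTURE_GRID
        for h1, h2, lin in grid:
            sub = RunConfig(**{**base,
                               "model": {**config.model, "hidden1": h1, "hidden2": h2,
                                         "linear1_units": lin},
                               "out_dir": str(Path(config.out_dir) / f"struct_{h1}_{h2}_{lin}")})
            acc = _run_and_read_acc(sub, force)
            rows.append({"hidden1": h1, "hidden2": h2, "linear1": lin,
                         "linear2": 2, "accuracy": acc})
    elif axis == "hyperparameters":
        grid = grid if grid is not None else HYPERPARAMETER_GRID
        for lr, bs in grid:
            sub = RunConfig(**{**base,
                               "train": {**config.train, "learning_rate": lr,
                                         "batch_size": bs},
                               "out_dir": str(Path(config.out_dir) / f"hyper_{lr}_{bs}")})
            acc = _run_and_read_acc(sub, force)
            rows.append({"learning_rate": lr, "batch_size": bs, "accuracy": acc})
    else:
        raise ValueError(f"unknown comparison axis {axis!r}")
    if out_path is not None:
        _write_rows(out_path, rows, config.digest())
    return rows


def _run_and_read_acc(sub: RunConfig, force: bool) -> float:
    run_dir = run_experiment(sub, force=force)
    with open(run_dir / "report.json") as fh:
        return float(json.load(fh)["acc"])


def _write_rows(path, rows: list[dict], digest: str) -> None:
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write(f"# config_digest={digest}\n")
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(
                f"{r[c]:.17g}" if isinstance(r[c], float) else str(r[c])
                for c in cols) + "\n")
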