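"""Training and cross-validated evaluation.

The protocol: binary cross-entropy minimized with Adam (learning rate 0.001,
batch size 64 by default), stratified k-fold cross-validation (5 folds by
default), and AUC / AUPR / accuracy / precision / recall on each held-out
fold. Vocabularies and the protein BPE model are rebuilt per fold from the
training split only, so no information leaks from held-out pairs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .config import ModelConfig, TrainConfig
from .davis import InteractionRecord
from .metrics import auc, aupr, threshold_metrics
from .model import MCFDTI, bce_loss
from .tokenization import (
    AMINO_ACIDS,
    BpeModel,
    Vocabulary,
    build_protein_vocabulary,
    build_smiles_vocabulary,
    encode_bpe,
    tokenize_chars,
    train_bpe,
)

logger = logging.getLogger(__name__)

METRIC_NAMES = ("auc", "aupr", "precision", "recall", "accuracy")


class Featurizer:
    """Fits vocabularies/BPE on training records and tokenizes batches.

    Tokenization is cached per unique sequence, which matters because a
    dataset has far fewer unique drugs/targets than pairs.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.smiles_vocab: Vocabulary | None = None
        self.protein_vocab: Vocabulary | None = None
        self.bpe: BpeModel | None = None

    def fit(self, records: list[InteractionRecord]) -> "Featurizer":
        if not records:
            raise ValueError("cannot fit a featurizer on zero records")
        self.smiles_vocab = build_smiles_vocabulary([r.smiles for r in records])
        self.protein_vocab = build_protein_vocabulary()
        unique_proteins = sorted({r.sequence for r in records})
        self.bpe = train_bpe(unique_proteins, self.config.bpe_num_merges)
        return self

    @property
    def vocab_sizes(self) -> tuple[int, int, int]:
        return (self.smiles_vocab.size, self.protein_vocab.size,
                self.bpe.subword_vocab.size)

    def transform(self, records: list[InteractionRecord]) -> dict[str, np.ndarray]:
        if self.smiles_vocab is None:
            raise RuntimeError("featurizer must be fitted before transform")
        c = self.config
        drug_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        prot_cache: dict[str, tuple] = {}
        out = {k: [] for k in ("drug_idx", "drug_mask", "prot_idx", "prot_mask",
                               "bpe_idx", "bpe_mask")}
        for r in records:
            if r.smiles not in drug_cache:
                tok = tokenize_chars(r.smiles, self.smiles_vocab, c.smiles_max_len)
                drug_cache[r.smiles] = (tok.indices, tok.mask)
            if r.sequence not in prot_cache:
                ch = tokenize_chars(r.sequence, self.protein_vocab,
                                    c.protein_max_len, allowed=AMINO_ACIDS)
                bp = encode_bpe(r.sequence, self.bpe, c.bpe_max_tokens)
                prot_cache[r.sequence] = (ch.indices, ch.mask, bp.indices, bp.mask)
            di, dm = drug_cache[r.smiles]
            pi, pm, bi, bm = prot_cache[r.sequence]
            out["drug_idx"].append(di)
            out["drug_mask"].append(dm)
            out["prot_idx"].append(pi)
            out["prot_mask"].append(pm)
            out["bpe_idx"].append(bi)
            out["bpe_mask"].append(bm)
        return {k: np.stack(v) for k, v in out.items()}

    def to_json(self) -> str:
        return json.dumps({
            "smiles_vocab": json.loads(self.smiles_vocab.to_json()),
            "protein_vocab": json.loads(self.protein_vocab.to_json()),
            "bpe": json.loads(self.bpe.to_json()),
        })

    @classmethod
    def from_json(cls, text: str, config: ModelConfig) -> "Featurizer":
        doc = json.loads(text)
        obj = cls(config)
        obj.smiles_vocab = Vocabulary.from_json(json.dumps(doc["smiles_vocab"]))
        obj.protein_vocab = Vocabulary.from_json(json.dumps(doc["protein_vocab"]))
        obj.bpe = BpeModel.from_json(json.dumps(doc["bpe"]))
        return obj


def stratified_kfold(labels, k: int, seed: int) -> np.ndarray:
    """Fold assignment vector; per-class fold sizes differ by at most one."""
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(labels, labels)):
        assignment[test_idx] = fold
    return assignment


def _labels(records: list[InteractionRecord]) -> np.ndarray:
    if any(r.label is None for r in records):
        raise ValueError("all records must carry a binary label")
    return np.asarray([r.label for r in records], dtype=np.float32)


def train(records: list[InteractionRecord], model_config: ModelConfig,
          train_config: TrainConfig, featurizer: Featurizer | None = None,
          ) -> tuple[MCFDTI, Featurizer, list[float]]:
    """Fit the classifier; returns (model, featurizer, per-epoch loss history).

    All randomness (vocab-independent init, shuffling, dropout) derives from
    ``train_config.seed``; identical inputs give identical histories.
    """
    labels = _labels(records)
    if featurizer is None:
        featurizer = Featurizer(model_config).fit(records)
    arrays = featurizer.transform(records)
    model = MCFDTI(model_config, *featurizer.vocab_sizes, seed=train_config.seed)
    from .autograd import Adam
    optimizer = Adam(model.params, lr=train_config.learning_rate)
    shuffle_rng = np.random.default_rng(train_config.seed + 10_000)
    n = len(records)
    history: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(train_config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            batch = {k: v[idx] for k, v in arrays.items()}
            prob = model.forward(batch, train=True)
            loss = bce_loss(prob, labels[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        logger.info("epoch %d loss %.5f", epoch, epoch_loss)
        if train_config.early_stop_patience is not None:
            if epoch_loss < best - 1e-6:
                best, stale = epoch_loss, 0
            else:
                stale += 1
                if stale >= train_config.early_stop_patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
    return model, featurizer, history


def predict_scores(model: MCFDTI, featurizer: Featurizer,
                   records: list[InteractionRecord],
                   batch_size: int = 256) -> np.ndarray:
    """Deterministic evaluation-mode probabilities for a list of pairs."""
    arrays = featurizer.transform(records)
    scores = []
    n = len(records)
    for start in range(0, n, batch_size):
        batch = {k: v[start:start + batch_size] for k, v in arrays.items()}
        scores.append(model.forward(batch, train=False).data)
    return np.concatenate(scores)


def evaluate(model: MCFDTI, featurizer: Featurizer,
             records: list[InteractionRecord],
             threshold: float = 0.5) -> dict[str, float]:
    labels = _labels(records)
    scores = predict_scores(model, featurizer, records)
    tm = threshold_metrics(labels, scores, threshold)
    return {"auc": auc(labels, scores), "aupr": aupr(labels, scores),
            "precision": tm.precision, "recall": tm.recall,
            "accuracy": tm.accuracy}


@dataclass
class EvalReport:
    """Per-fold and averaged cross-validation metrics."""

    folds: list[dict[str, float]]
    mean: dict[str, float]
    n_eval: int
    decision_threshold: float
    loss_histories: list[list[float]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"folds": self.folds, "mean": self.mean,
                           "n_eval": self.n_eval,
                           "decision_threshold": self.decision_threshold},
                          indent=2)

    def table(self) -> str:
        header = "fold  " + "  ".join(f"{m:>9}" for m in METRIC_NAMES)
        rows = [header]
        for i, fold in enumerate(self.folds):
            rows.append(f"{i:>4}  " + "  ".join(
                f"{fold[m]:9.4f}" for m in METRIC_NAMES))
        rows.append("mean  " + "  ".join(
            f"{self.mean[m]:9.4f}" for m in METRIC_NAMES))
        return "\n".join(rows)


def crossval_evaluate(records: list[InteractionRecord],
                      model_config: ModelConfig,
                      train_config: TrainConfig) -> EvalReport:
    """k-fold cross-validation with per-fold refit of vocabularies and BPE."""
    labels = _labels(records)
    assignment = stratified_kfold(labels, train_config.folds, train_config.seed)
    fold_metrics: list[dict[str, float]] = []
    histories: list[list[float]] = []
    pooled_scores = np.empty(len(records))
    for fold in range(train_config.folds):
        test_mask = assignment == fold
        train_records = [r for r, m in zip(records, test_mask) if not m]
        test_records = [r for r, m in zip(records, test_mask) if m]
        fold_cfg = TrainConfig(**{**train_config.__dict__,
                                  "seed": train_config.seed + fold})
        model, featurizer, history = train(train_records, model_config, fold_cfg)
        scores = predict_scores(model, featurizer, test_records)
        pooled_scores[test_mask] = scores
        test_labels = _labels(test_records)
        tm = threshold_metrics(test_labels, scores,
                               train_config.decision_threshold)
        fold_metrics.append({
            "auc": auc(test_labels, scores), "aupr": aupr(test_labels, scores),
            "precision": tm.precision, "recall": tm.recall,
            "accuracy": tm.accuracy})
        histories.append(history)
        logger.info("fold %d: %s", fold, fold_metrics[-1])
    if train_config.pooled_metrics:
        tm = threshold_metrics(labels, pooled_scores,
                               train_config.decision_threshold)
        mean = {"auc": auc(labels, pooled_scores),
                "aupr": aupr(labels, pooled_scores),
                "precision": tm.precision, "recall": tm.recall,
                "accuracy": tm.accuracy}
    else:
        mean = {m: float(np.mean([f[m] for f in fold_metrics]))
                for m in METRIC_NAMES}
    return EvalReport(folds=fold_metrics, mean=mean, n_eval=len(records),
                      decision_threshold=train_config.decision_threshold,
                      loss_histories=histories)
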