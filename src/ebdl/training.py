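"""End-to-end training and evaluation of the band-dependent model.

One model = filter bank (M trainable band profiles) + shared encoder +
proxy bank (M x C class proxies).  All three parameter groups are updated
jointly by Adam through the sub-view contrastive loss, each group with its
own learning rate: the filter locations/scales take a much larger rate
(default 0.25) than the encoder weights (1e-4 for the vital recipe, 1e-3
for gait) because a filter has to travel across the whole normalized
frequency axis [-1, 1] within a few epochs.

Evaluation classifies by nearest proxy across sub-views and reports
accuracy, balanced accuracy (macro-averaged sensitivity) and per-class
precision/sensitivity from the confusion matrix.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as sk_confusion_matrix

from .autodiff import Tensor
from .contrast import ProxyBank, init_proxies, predict_batch, scloss_batch
from .nn import Adam, Module
from .representation import EncoderSpec, build_encoder
from .subband import FilterBank, init_filter_bank
from .tfr_pipeline import DatasetSplit, TFRSample, mix_augment

__all__ = ["TrainConfig", "EvalReport", "EBDLModel", "Checkpoint",
           "train", "evaluate", "select_filter_count", "loo_split",
           "train_crossentropy_baseline", "CrossEntropyModel"]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Default protocol: batch size 32, up to 15 epochs
    of Adam, encoder learning rate 1e-4 (vital recipe; use 1e-3 for gait),
    filter-parameter learning rate 0.25, seed 1024.  Proxies default to the
    encoder's rate.
    """

    filter_count: int = 3
    batch_size: int = 32
    epochs: int = 15
    lr_encoder: float = 1e-4
    lr_filters: float = 0.25
    lr_proxies: float | None = None
    optimizer: str = "adam"
    filter_optimizer: str = "sgd"  # plain steps keep the large filter rate stable
    seed: int = 1024
    beta: int = 8
    encoder: EncoderSpec = field(default_factory=lambda: EncoderSpec(
        backbone_kind="tiny_cnn", head_hidden=64, embed_dim=32,
        tiny_channels=(6, 12, 24)))
    selection_metric: str = "accuracy"  # or "balanced_accuracy"
    balance_with_mix: bool = False
    resting_class: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.filter_count < 1:
            raise ValueError("batch_size, epochs and filter_count must be >= 1")
        if self.lr_encoder <= 0 or self.lr_filters < 0:
            raise ValueError("lr_encoder must be positive and lr_filters nonnegative "
                             "(zero freezes the filter group)")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")

    @property
    def effective_lr_proxies(self) -> float:
        return self.lr_encoder if self.lr_proxies is None else self.lr_proxies


class EBDLModel(Module):
    """Filter bank -> shared encoder -> proxy bank, on one autodiff tape."""

    def __init__(self, bank: FilterBank, encoder, proxies: ProxyBank):
        super().__init__()
        self.bank = bank
        self.encoder = encoder
        self.proxies = proxies

    @classmethod
    def create(cls, m: int, n_classes: int, freq_axis: np.ndarray,
               cfg: TrainConfig) -> "EBDLModel":
        rng = np.random.default_rng(cfg.seed)
        bank = init_filter_bank(m, freq_axis, beta=cfg.beta)
        encoder = build_encoder(cfg.encoder, rng)
        proxies = init_proxies(m, n_classes, cfg.encoder.embed_dim, seed=cfg.seed)
        return cls(bank, encoder, proxies)

    def embed_batch(self, values: np.ndarray) -> Tensor:
        """(B, T, F) standardized TFRs -> (B, M, L) unit-norm embeddings."""
        b, t, f = values.shape
        m = self.bank.n_filters
        views = self.bank.filter_batch(Tensor(values))       # (B, M, T, F)
        z = self.encoder(views.reshape(b * m, 1, t, f))      # (B*M, L)
        return z.reshape(b, m, self.encoder.embed_dim)

    def predict_samples(self, samples: Sequence[TFRSample],
                        batch_size: int = 64) -> np.ndarray:
        self.eval()
        preds = []
        for start in range(0, len(samples), batch_size):
            chunk = samples[start:start + batch_size]
            values = np.stack([s.values for s in chunk])
            z = self.embed_batch(values).data
            preds.append(predict_batch(z, self.proxies))
        self.train()
        return np.concatenate(preds) if preds else np.array([], dtype=int)


@dataclass
class Checkpoint:
    """Best-validation model state plus the run's configuration and history."""

    model: EBDLModel
    config: TrainConfig
    n_classes: int
    history: list[dict]
    best_validation_accuracy: float

    def save(self, path: str) -> None:
        meta = {
            "n_classes": self.n_classes,
            "filter_count": self.model.bank.n_filters,
            "beta": self.model.bank.beta,
            "best_validation_accuracy": self.best_validation_accuracy,
            "config": _config_to_jsonable(self.config),
            "history": self.history,
        }
        arrays = {f"model.{k}": v for k, v in self.model.state_arrays().items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k[len("model."):]: data[k] for k in data.files
                      if k.startswith("model.")}
        cfg_d = meta["config"]
        cfg_d["encoder"] = EncoderSpec(**{**cfg_d["encoder"], "tiny_channels":
                                          tuple(cfg_d["encoder"]["tiny_channels"])})
        cfg = TrainConfig(**cfg_d)
        freq_axis = arrays["bank.freq_axis"]
        model = EBDLModel.create(meta["filter_count"], meta["n_classes"],
                                 freq_axis, cfg)
        model.load_state_arrays(arrays)
        return cls(model=model, config=cfg, n_classes=meta["n_classes"],
                   history=meta["history"],
                   best_validation_accuracy=meta["best_validation_accuracy"])


def _config_to_jsonable(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    d["encoder"]["tiny_channels"] = list(d["encoder"]["tiny_channels"])
    return d


@dataclass
class EvalReport:
    """Accuracy, balanced accuracy and per-class precision/sensitivity."""

    accuracy: float
    balanced_accuracy: float
    per_class: list[dict]
    confusion_matrix: np.ndarray

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         n_classes: int) -> "EvalReport":
        cm = sk_confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
        return cls.from_confusion_matrix(cm)

    @classmethod
    def from_confusion_matrix(cls, cm: np.ndarray) -> "EvalReport":
        cm = np.asarray(cm, dtype=np.int64)
        tp = np.diag(cm).astype(float)
        support = cm.sum(axis=1).astype(float)       # row c = true class c
        predicted = cm.sum(axis=0).astype(float)
        per_class = []
        sens = np.zeros(cm.shape[0])
        for c in range(cm.shape[0]):
            prec_undef = predicted[c] == 0
            sens_undef = support[c] == 0
            precision = 0.0 if prec_undef else tp[c] / predicted[c]
            sensitivity = 0.0 if sens_undef else tp[c] / support[c]
            sens[c] = sensitivity
            per_class.append({"precision": precision, "sensitivity": sensitivity,
                              "precision_undefined": bool(prec_undef),
                              "sensitivity_undefined": bool(sens_undef)})
        total = cm.sum()
        acc = float(tp.sum() / total) if total else 0.0
        observed = support > 0
        bal = float(sens[observed].mean()) if observed.any() else 0.0
        return cls(accuracy=acc, balanced_accuracy=bal, per_class=per_class,
                   confusion_matrix=cm)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _epoch_pool(train_samples: Sequence[TFRSample], cfg: TrainConfig,
                rng: np.random.Generator) -> list[TFRSample]:
    """Training pool for one epoch; optionally re-balanced via mix augmentation."""
    if not cfg.balance_with_mix:
        return list(train_samples)
    by_class: dict[int, list[TFRSample]] = {}
    for s in train_samples:
        by_class.setdefault(s.label, []).append(s)
    resting = by_class.get(cfg.resting_class)
    if not resting:
        return list(train_samples)
    target = max(len(v) for v in by_class.values())
    pool = list(train_samples)
    for label, members in by_class.items():
        if label == cfg.resting_class:
            continue
        for _ in range(target - len(members)):
            r = resting[rng.integers(len(resting))]
            m_s = members[rng.integers(len(members))]
            pool.append(mix_augment(r, m_s))
    return pool


def train(dataset: DatasetSplit, cfg: TrainConfig) -> Checkpoint:
    """Train filter bank + encoder + proxies end to end with SCLoss.

    Returns a checkpoint holding the parameters that achieved the best
    validation score (validation accuracy by default).
    """
    if not dataset.train:
        raise ValueError("training split is empty")
    labels = sorted({s.label for s in dataset.train})
    n_classes = max(labels) + 1
    if n_classes < 2:
        raise ValueError("need at least two classes to train")
    freq_axis = dataset.train[0].freq_axis
    model = EBDLModel.create(cfg.filter_count, n_classes, freq_axis, cfg)
    opt = Adam([
        {"params": list(model.encoder.parameters()), "lr": cfg.lr_encoder},
        {"params": [model.bank.mu, model.bank.sigma], "lr": cfg.lr_filters,
         "algo": cfg.filter_optimizer},
        {"params": [model.proxies.p], "lr": cfg.effective_lr_proxies},
    ])
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best_state: dict | None = None
    best_score = -np.inf
    for epoch in range(cfg.epochs):
        model.train()
        pool = _epoch_pool(dataset.train, cfg, rng)
        order = rng.permutation(len(pool))
        losses = []
        for bstart in range(0, len(pool), cfg.batch_size):
            idx = order[bstart:bstart + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs at least two samples
            batch = [pool[i] for i in idx]
            values = np.stack([s.values for s in batch])
            y = np.array([s.label for s in batch])
            z = model.embed_batch(values)
            loss, _ = scloss_batch(z, model.proxies, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {bstart // cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_report = evaluate(model, dataset.validation) if dataset.validation else None
        score = 0.0
        if val_report is not None:
            score = (val_report.balanced_accuracy
                     if cfg.selection_metric == "balanced_accuracy"
                     else val_report.accuracy)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)) if losses else float("nan"),
            "validation_score": score,
            "mu": model.bank.mu.data.tolist(),
            "sigma": model.bank.sigma.data.tolist(),
        })
        # save on strict improvement only: ties keep the earliest best epoch
        if val_report is None or score > best_score:
            best_score = score
            best_state = copy.deepcopy(model.state_arrays())
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return Checkpoint(model=model, config=cfg, n_classes=n_classes,
                      history=history,
                      best_validation_accuracy=float(max(best_score, 0.0)))


def evaluate(model_or_ckpt, samples: Sequence[TFRSample]) -> EvalReport:
    """Nearest-proxy classification of *samples* plus the standard metrics."""
    model = model_or_ckpt.model if isinstance(model_or_ckpt, Checkpoint) else model_or_ckpt
    if not samples:
        raise ValueError("no samples to evaluate")
    y_true = np.array([s.label for s in samples])
    y_pred = model.predict_samples(samples)
    n_classes = model.proxies.n_classes
    return EvalReport.from_predictions(y_true, y_pred, n_classes)


def select_filter_count(dataset: DatasetSplit, candidates: Iterable[int],
                        cfg: TrainConfig) -> tuple[int, list[dict]]:
    """Train one model per candidate M and pick the best validation score.

    Returns (best M, report rows) where each row carries the candidate M,
    its validation and test accuracy, and the learned (mu, sigma) pairs —
    the usual shape of a filter-count sweep report.
    """
    from dataclasses import replace as dc_replace

    rows = []
    best_m, best_score = None, -np.inf
    for m in candidates:
        ckpt = train(dataset, dc_replace(cfg, filter_count=m))
        test_acc = (evaluate(ckpt, dataset.test).accuracy
                    if dataset.test else float("nan"))
        rows.append({
            "filter_count": m,
            "validation_accuracy": ckpt.best_validation_accuracy,
            "test_accuracy": test_acc,
            "learned_parameters": [(float(mu), float(sg)) for mu, sg in
                                   zip(ckpt.model.bank.mu.data,
                                       ckpt.model.bank.sigma.data)],
        })
        if ckpt.best_validation_accuracy > best_score:
            best_score = ckpt.best_validation_accuracy
            best_m = m
    return best_m, rows


def loo_split(samples: Sequence[TFRSample], validation_fraction: float = 0.2,
              seed: int = 1024) -> list[DatasetSplit]:
    """Leave-one-subject-out splits: one split per subject, that subject's
    samples as the test set and a seeded 20% of the rest as validation."""
    subjects = sorted({s.subject_id for s in samples})
    if len(subjects) < 2:
        raise ValueError("leave-one-out needs at least two subjects")
    splits = []
    for k, subject in enumerate(subjects):
        test = [s for s in samples if s.subject_id == subject]
        rest = [s for s in samples if s.subject_id != subject]
        rng = np.random.default_rng(seed + k)
        order = rng.permutation(len(rest))
        n_val = int(round(validation_fraction * len(rest)))
        val = [rest[i] for i in order[:n_val]]
        tr = [rest[i] for i in order[n_val:]]
        splits.append(DatasetSplit(train=tr, validation=val, test=test,
                                   ratios=(1 - validation_fraction,
                                           validation_fraction, 0.0)))
    return splits


# ---------------------------------------------------------------------------
# cross-entropy reference model (identical encoder, no filtering)
# ---------------------------------------------------------------------------

class CrossEntropyModel(Module):
    """The same encoder applied to the unfiltered TFR with a softmax head."""

    def __init__(self, encoder, n_classes: int, rng: np.random.Generator):
        super().__init__()
        from .nn import Linear

        self.encoder = encoder
        self.head = Linear(encoder.embed_dim, n_classes, rng)

    def logits(self, values: np.ndarray) -> Tensor:
        b, t, f = values.shape
        z = self.encoder(Tensor(values.reshape(b, 1, t, f)))
        return self.head(z)

    def predict_samples(self, samples: Sequence[TFRSample],
                        batch_size: int = 64) -> np.ndarray:
        self.eval()
        preds = []
        for start in range(0, len(samples), batch_size):
            chunk = samples[start:start + batch_size]
            values = np.stack([s.values for s in chunk])
            preds.append(self.logits(values).data.argmax(axis=1))
        self.train()
        return np.concatenate(preds)


def _softmax_ce(logits: Tensor, labels: np.ndarray) -> Tensor:
    shift = logits.data.max(axis=1, keepdims=True)  # constant for stability
    shifted = logits - shift
    lse = shifted.exp().sum(axis=1, keepdims=True).log()
    picked = shifted[np.arange(len(labels)), labels].reshape(-1, 1)
    return (lse - picked).mean()


def train_crossentropy_baseline(dataset: DatasetSplit, cfg: TrainConfig
                                ) -> CrossEntropyModel:
    """Train the identical encoder with plain cross-entropy on raw TFRs."""
    labels = sorted({s.label for s in dataset.train})
    n_classes = max(labels) + 1
    rng = np.random.default_rng(cfg.seed)
    encoder = build_encoder(cfg.encoder, rng)
    model = CrossEntropyModel(encoder, n_classes, rng)
    opt = Adam([{"params": list(model.parameters()), "lr": cfg.lr_encoder}])
    data_rng = np.random.default_rng(cfg.seed)
    best_state, best_score = None, -np.inf
    for epoch in range(cfg.epochs):
        model.train()
        order = data_rng.permutation(len(dataset.train))
        for bstart in range(0, len(order), cfg.batch_size):
            idx = order[bstart:bstart + cfg.batch_size]
            if len(idx) < 2:
                continue
            batch = [dataset.train[i] for i in idx]
            values = np.stack([s.values for s in batch])
            y = np.array([s.label for s in batch])
            loss = _softmax_ce(model.logits(values), y)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"baseline diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
        if dataset.validation:
            y_true = np.array([s.label for s in dataset.validation])
            acc = float((model.predict_samples(dataset.validation) == y_true).mean())
            if acc >= best_score:
                best_score = acc
                best_state = copy.deepcopy(model.state_arrays())
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model
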