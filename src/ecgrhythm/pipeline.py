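"""Orchestration: dataset assembly, training, prediction and evaluation.

Training operates at window level (each window inherits its recording's
rhythm label) with categorical cross-entropy, Adam and early stopping on
window-level validation loss; evaluation is recording level: z-score ->
sliding windows -> per-window softmax -> majority vote -> confusion matrix
and the full metric battery, with one-vs-rest AUC computed from the mean
window probabilities per recording.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .decision import RecordingPrediction, majority_vote
from .labels import CLASS_INDEX, CLASS_ORDER, RhythmLabel
from .metrics import ConfusionMatrix, MetricsReport, confusion, per_class_metrics, roc_auc
from .net import Adam, ModelConfig, RhythmTransformer
from .signal_io import ECGRecord, standardize
from .synth import SynthDataset, SynthDatasetConfig, generate_dataset
from .windowing import slide_windows


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0
    #: stride (samples) for cutting training windows
    stride: int = 5
    #: stride for validation windows (None = same as stride); a coarser
    #: validation stride is cheap and barely changes the vote
    val_stride: int | None = None
    #: windows drawn per recording per epoch (None = all); subsampling keeps
    #: epochs cheap since adjacent 5-point-stride windows are near-duplicates
    windows_per_record: int | None = None


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    data: SynthDatasetConfig = field(default_factory=SynthDatasetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: tuple = (0.6, 0.2, 0.2)
    output_dir: str = "run"


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_recording_acc: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _windows_and_labels(records: list[ECGRecord], W: int, S: int):
    """Stack windows of standardized records; labels are inherited indices."""
    mats, labs, owners = [], [], []
    for ri, rec in enumerate(records):
        wb = slide_windows(standardize(rec), W=W, S=S)
        mats.append(wb.windows)
        labs.append(np.full(wb.m, CLASS_INDEX[rec.label]))
        owners.append(np.full(wb.m, ri))
    return np.concatenate(mats), np.concatenate(labs), np.concatenate(owners)


def _epoch_subset(rng, owners, per_record):
    if per_record is None:
        return np.arange(owners.size)
    picks = []
    for ri in np.unique(owners):
        idx = np.flatnonzero(owners == ri)
        picks.append(rng.choice(idx, size=min(per_record, idx.size), replace=False))
    return np.concatenate(picks)


def train(cfg: RunConfig, dataset: SynthDataset | None = None,
          verbose: bool = False) -> tuple[RhythmTransformer, TrainHistory]:
    """Train on the dataset's train partition with early stopping on the
    validation partition; writes a checkpoint + model card + history +
    run manifest to cfg.output_dir."""
    t0 = time.time()
    if dataset is None:
        dataset = generate_dataset(cfg.data, split=cfg.split)
    train_recs = dataset.partitions["train"]
    val_recs = dataset.partitions["validation"]
    if not train_recs or not val_recs:
        raise ValueError("train and validation partitions must be non-empty")

    tc = cfg.train
    Xtr, ytr, own_tr = _windows_and_labels(train_recs, cfg.model.window_len, tc.stride)
    Xva, yva, own_va = _windows_and_labels(
        val_recs, cfg.model.window_len, tc.val_stride or tc.stride
    )

    rng = np.random.default_rng(tc.seed & 0x7FFFFFFF)
    model = RhythmTransformer(cfg.model, seed=tc.seed & 0x7FFFFFFF)
    if tc.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {tc.optimizer!r}")
    opt = Adam(model.params, lr=tc.learning_rate, weight_decay=cfg.model.l2)

    hist = TrainHistory()
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    stale = 0
    for epoch in range(tc.max_epochs):
        sel = _epoch_subset(rng, own_tr, tc.windows_per_record)
        order = rng.permutation(sel.size)
        sel = sel[order]
        losses = []
        for a in range(0, sel.size, tc.batch_size):
            idx = sel[a : a + tc.batch_size]
            loss, grads = model.loss_and_grads(Xtr[idx], ytr[idx], rng=rng)
            opt.step(model.params, grads)
            losses.append(loss)
        val_loss, rec_acc = _validate(model, Xva, yva, own_va)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(val_loss)
        hist.val_recording_acc.append(rec_acc)
        if verbose:
            print(f"epoch {epoch}: train {hist.train_loss[-1]:.4f} "
                  f"val {val_loss:.4f} rec-acc {rec_acc:.3f}", flush=True)
        if val_loss < best_val - 1e-5:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience:
                break
    model.params = best_params

    os.makedirs(cfg.output_dir, exist_ok=True)
    model.save(cfg.output_dir, extra_card={
        "train_seed": tc.seed,
        "epochs_run": hist.n_epochs,
        "best_val_loss": best_val,
        "wall_time_s": round(time.time() - t0, 2),
    })
    with open(os.path.join(cfg.output_dir, "history.json"), "w") as fh:
        json.dump(asdict(hist), fh, indent=2)
    with open(os.path.join(cfg.output_dir, "run_manifest.json"), "w") as fh:
        json.dump({
            "model": asdict(cfg.model),
            "data": {**asdict(cfg.data), "noise": asdict(cfg.data.noise)},
            "train": asdict(tc),
            "split": list(cfg.split),
            "parameter_count": model.count_parameters(),
        }, fh, indent=2, default=str)
    return model, hist


def _validate(model: RhythmTransformer, X: np.ndarray, y: np.ndarray,
              owners: np.ndarray) -> tuple[float, float]:
    """One forward pass over the validation windows gives both the
    window-level loss and the recording-level (majority-vote) accuracy."""
    probs = model.predict_proba(X)
    loss = float(-np.log(np.maximum(probs[np.arange(X.shape[0]), y], 1e-12)).mean())
    hits, n_rec = 0, 0
    for ri in np.unique(owners):
        idx = np.flatnonzero(owners == ri)
        vote = majority_vote(probs[idx])
        hits += CLASS_INDEX[vote.label] == y[idx[0]]
        n_rec += 1
    return loss, hits / n_rec


def predict_recording(model: RhythmTransformer, rec: ECGRecord,
                      W: int | None = None, S: int = 5,
                      crop_long: bool = False) -> RecordingPrediction:
    """Standardize -> windows -> per-window softmax -> majority vote."""
    W = W if W is not None else model.cfg.window_len
    std = standardize(rec, crop_long=crop_long)
    wb = slide_windows(std, W=W, S=S)
    probs = model.predict_proba(wb.windows)
    return majority_vote(probs, record_id=rec.source_id)


def _recording_accuracy(model, records, stride) -> float:
    preds = [predict_recording(model, r, S=stride) for r in records]
    hits = sum(p.label == r.label for p, r in zip(preds, records))
    return hits / len(records)


def evaluate(model: RhythmTransformer, records: list[ECGRecord], S: int = 5
             ) -> tuple[MetricsReport, ConfusionMatrix, list[RecordingPrediction]]:
    """Recording-level evaluation: confusion matrix + full metric battery,
    with per-class one-vs-rest AUC from the mean window probabilities."""
    if any(r.label is None for r in records):
        raise ValueError("all records must carry a ground-truth label")
    preds = [predict_recording(model, r, S=S) for r in records]
    y_true = [r.label for r in records]
    y_pred = [p.label for p in preds]
    cm = confusion(y_true, y_pred)
    scores = np.vstack([p.mean_probs for p in preds])
    aucs = {}
    for i, lab in enumerate(CLASS_ORDER):
        y_bin = np.array([1 if t == lab else 0 for t in y_true])
        if 0 < y_bin.sum() < y_bin.size:
            aucs[lab] = roc_auc(scores[:, i], y_bin)
    report = per_class_metrics(cm, aucs=aucs)
    return report, cm, preds


def evaluate_predictions(y_true, y_pred, scores: np.ndarray | None = None
                         ) -> tuple[MetricsReport, ConfusionMatrix]:
    """Metric battery from already-computed labels (and optional class scores)."""
    cm = confusion(y_true, y_pred)
    aucs = None
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        aucs = {}
        for i, lab in enumerate(CLASS_ORDER):
            y_bin = np.array([1 if RhythmLabel(str(t)) == lab else 0 for t in y_true])
            if 0 < y_bin.sum() < y_bin.size:
                aucs[lab] = roc_auc(scores[:, i], y_bin)
    return per_class_metrics(cm, aucs=aucs), cm
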