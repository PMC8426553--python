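"""Segment filtering, dataset assembly, training loop and reporting.

The experimental protocol mirrors a segment-level speech study: recordings
are cut into segments, segments shorter than 3 s (too little information)
or longer than 20 s are discarded, the survivors are split into train and
test sets, per-feature z-normalization statistics are fitted on the train
set only, and the attention LSTM is trained with cross-entropy, early
stopping on validation UAR.  Every stochastic step (split, shuffling,
initialization) is driven by explicit seeds so a run is exactly
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import ConfusionMatrix, confusion_from_predictions, precision_recall_f1, uar
from .model import AttentionLSTMClassifier, ModelConfig, pad_sequences

__all__ = [
    "SegmentRecord",
    "PipelineConfig",
    "filter_segments",
    "split_dataset",
    "NormStats",
    "normalize_features",
    "TrainResult",
    "train",
    "EvalReport",
    "evaluate",
    "AttentionTrace",
    "visualize_attention",
]


@dataclass(frozen=True)
class SegmentRecord:
    """One speech segment: identity, duration, label, optional speaker."""

    source_id: str
    duration: float
    label: int  # 0 = healthy control, 1 = depression
    path: str = ""
    speaker: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"{self.source_id}: duration must be positive")
        if self.label not in (0, 1):
            raise ValueError(f"{self.source_id}: label must be 0 or 1")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end experiment settings.

    Duration bounds are inclusive: segments with 3 s <= duration <= 20 s
    are kept.  ``val_fraction`` is carved out of the train split for early
    stopping; set it to 0 to train for the full epoch budget.
    """

    min_dur: float = 3.0
    max_dur: float = 20.0
    test_fraction: float = 0.2
    val_fraction: float = 0.1
    normalize: bool = True
    segment_level_split: bool = False
    epochs: int = 100
    patience: int = 10
    seed: int = 0
    model: ModelConfig | None = None

    def __post_init__(self) -> None:
        if not (0 < self.min_dur < self.max_dur):
            raise ValueError("need 0 < min_dur < max_dur")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if not (0 <= self.val_fraction < 1):
            raise ValueError("val_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# segment filtering and splitting


def filter_segments(
    records: Sequence[SegmentRecord], cfg: PipelineConfig
) -> tuple[list[SegmentRecord], list[tuple[SegmentRecord, str]]]:
    """Keep segments with min_dur <= duration <= max_dur; log rejections.

    Raises when nothing survives — an empty dataset is never a valid
    outcome of filtering.
    """
    kept: list[SegmentRecord] = []
    rejected: list[tuple[SegmentRecord, str]] = []
    for rec in records:
        if rec.duration < cfg.min_dur:
            rejected.append((rec, f"duration {rec.duration:.2f} s < {cfg.min_dur} s"))
        elif rec.duration > cfg.max_dur:
            rejected.append((rec, f"duration {rec.duration:.2f} s > {cfg.max_dur} s"))
        else:
            kept.append(rec)
    if not kept:
        raise ValueError(
            f"no segments survive the [{cfg.min_dur}, {cfg.max_dur}] s duration filter"
        )
    return kept, rejected


def split_dataset(
    records: Sequence[SegmentRecord],
    test_fraction: float,
    seed: int,
    segment_level: bool = False,
    max_retries: int = 50,
) -> dict[str, list[SegmentRecord]]:
    """Reproducible train/test split with both classes in both sets.

    When speaker ids are present (and ``segment_level`` is False) the split
    is grouped by speaker, so no speaker contributes to both sets; the draw
    is retried until both classes appear on both sides.  Without speaker
    ids the split is stratified by class at segment level.
    """
    if not (0 < test_fraction < 1):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    labels = np.array([r.label for r in records])
    for cls in (0, 1):
        if (labels == cls).sum() < 2:
            raise ValueError(f"need at least 2 records of class {cls} to split")
    rng = np.random.default_rng(seed)
    grouped = (not segment_level) and all(r.speaker is not None for r in records)

    for _ in range(max_retries):
        test_idx: set[int]
        if grouped:
            speakers = sorted({r.speaker for r in records})
            order = rng.permutation(len(speakers))
            n_test = max(int(round(test_fraction * len(speakers))), 1)
            test_speakers = {speakers[i] for i in order[:n_test]}
            test_idx = {i for i, r in enumerate(records) if r.speaker in test_speakers}
        else:
            test_idx = set()
            for cls in (0, 1):
                cls_idx = np.flatnonzero(labels == cls)
                order = rng.permutation(cls_idx)
                n_test = max(int(round(test_fraction * cls_idx.size)), 1)
                if n_test >= cls_idx.size:
                    n_test = cls_idx.size - 1
                test_idx.update(order[:n_test].tolist())
        train = [r for i, r in enumerate(records) if i not in test_idx]
        test = [r for i, r in enumerate(records) if i in test_idx]
        train_classes = {r.label for r in train}
        test_classes = {r.label for r in test}
        if train_classes == {0, 1} and test_classes == {0, 1}:
            return {"train": train, "test": test}
    raise ValueError(
        "could not produce a split with both classes in both sets; "
        "check class/speaker composition"
    )


# ---------------------------------------------------------------------------
# normalization


@dataclass(frozen=True)
class NormStats:
    """Per-feature z-score statistics, fitted on training data only."""

    mean: np.ndarray
    std: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


def normalize_features(
    train_feats: Sequence[np.ndarray], all_feats: Sequence[np.ndarray]
) -> tuple[list[np.ndarray], NormStats]:
    """z-normalize every feature column using train-set statistics.

    The statistics are computed across all frames of the training
    sequences; a standard-deviation floor of 1e-8 maps constant columns to
    zero.  ``all_feats`` (which may include validation and test sequences)
    is normalized with those same statistics — never its own.
    """
    stacked = np.concatenate([np.asarray(x) for x in train_feats], axis=0)
    mean = stacked.mean(axis=0)
    std = np.maximum(stacked.std(axis=0), 1e-8)
    stats = NormStats(mean, std)
    return [stats.apply(np.asarray(x)) for x in all_feats], stats


# ---------------------------------------------------------------------------
# batching and evaluation


def _length_bucketed_batches(
    n: int, lengths: np.ndarray, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Bucket indices by length then shuffle batch order (less padding waste)."""
    jitter = rng.uniform(0, 0.5, size=n)  # break ties randomly but reproducibly
    order = np.argsort(lengths + jitter, kind="stable")
    batches = [order[i: i + batch_size] for i in range(0, n, batch_size)]
    rng.shuffle(batches)
    return batches


def _predict_all(
    model: AttentionLSTMClassifier, sequences: Sequence[np.ndarray], batch_size: int
) -> np.ndarray:
    preds = np.empty(len(sequences), dtype=np.int64)
    for i in range(0, len(sequences), batch_size):
        chunk = sequences[i: i + batch_size]
        preds[i: i + len(chunk)] = model.predict(pad_sequences(chunk))
    return preds


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix, UAR and per-class precision/recall/F1."""

    confusion: ConfusionMatrix
    uar: float
    per_class: dict[str, dict[str, float]]


def evaluate(
    model: AttentionLSTMClassifier,
    sequences: Sequence[np.ndarray],
    labels: Sequence[int],
    batch_size: int | None = None,
) -> EvalReport:
    batch_size = batch_size or model.cfg.batch
    preds = _predict_all(model, sequences, batch_size)
    cm = confusion_from_predictions(np.asarray(labels), preds)
    per_class = {}
    for cls, name in enumerate(cm.class_names):
        try:
            p, r, f1 = precision_recall_f1(cm, positive_class=cls)
            per_class[name] = {"precision": p, "recall": r, "f1": f1}
        except ValueError:
            per_class[name] = {"precision": math.nan, "recall": math.nan, "f1": math.nan}
    return EvalReport(confusion=cm, uar=uar(cm), per_class=per_class)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    model: AttentionLSTMClassifier
    history: list[dict[str, float]]
    best_epoch: int
    best_val_uar: float
    norm_stats: NormStats | None = None


def _stratified_carve(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask selecting a stratified ``fraction`` of each class."""
    mask = np.zeros(labels.size, dtype=bool)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_sel = max(int(round(fraction * idx.size)), 1)
        mask[rng.permutation(idx)[:n_sel]] = True
    return mask


def train(
    sequences: Sequence[np.ndarray],
    labels: Sequence[int],
    cfg: PipelineConfig,
    val_sequences: Sequence[np.ndarray] | None = None,
    val_labels: Sequence[int] | None = None,
) -> TrainResult:
    """Train the attention LSTM with early stopping on validation UAR.

    If no validation set is supplied and ``cfg.val_fraction`` > 0, a
    stratified validation split is carved from the training data.  The
    best-validation-UAR parameters are checkpointed and restored at the
    end.  A non-finite loss aborts with a diagnostic.  Identical inputs,
    config and seeds give identical loss curves and parameters.
    """
    labels = np.asarray(labels, dtype=np.int64)
    sequences = [np.asarray(s) for s in sequences]
    if cfg.model is None:
        raise ValueError("PipelineConfig.model must be set before training")
    if cfg.model.input_size != sequences[0].shape[1]:
        raise ValueError(
            f"model expects {cfg.model.input_size} features, data has {sequences[0].shape[1]}"
        )
    rng = np.random.default_rng(cfg.seed)
    if val_sequences is None and cfg.val_fraction > 0:
        val_mask = _stratified_carve(labels, cfg.val_fraction, rng)
        val_sequences = [s for s, m in zip(sequences, val_mask) if m]
        val_labels = labels[val_mask]
        sequences = [s for s, m in zip(sequences, val_mask) if not m]
        labels = labels[~val_mask]

    model = AttentionLSTMClassifier(cfg.model)
    lengths = np.array([s.shape[0] for s in sequences])
    history: list[dict[str, float]] = []
    best_state = model.state_copy()
    best_val = -np.inf
    best_epoch = 0
    stale = 0
    have_val = val_sequences is not None and len(val_sequences) > 0

    for epoch in range(cfg.epochs):
        epoch_rng = np.random.default_rng(rng.integers(2**31))
        losses = []
        for batch_idx in _length_bucketed_batches(
            len(sequences), lengths, cfg.model.batch, epoch_rng
        ):
            batch = pad_sequences(
                [sequences[i] for i in batch_idx], labels[batch_idx]
            )
            losses.append(model.train_step(batch))
        train_preds = _predict_all(model, sequences, cfg.model.batch)
        train_uar = uar(confusion_from_predictions(labels, train_preds))
        entry = {"epoch": float(epoch), "loss": float(np.mean(losses)), "train_uar": train_uar}
        if have_val:
            val_preds = _predict_all(model, val_sequences, cfg.model.batch)
            val_uar = uar(confusion_from_predictions(np.asarray(val_labels), val_preds))
            entry["val_uar"] = val_uar
            # checkpoint ties go to the later epoch (among equal-validation
            # models prefer the one trained longer); patience still counts
            # epochs without a strict improvement
            if val_uar >= best_val:
                if val_uar > best_val:
                    stale = 0
                else:
                    stale += 1
                best_val, best_epoch = val_uar, epoch
                best_state = model.state_copy()
            else:
                stale += 1
        history.append(entry)
        if have_val and stale >= cfg.patience:
            break

    if have_val:
        model.load_state(best_state)
    else:
        best_epoch = cfg.epochs - 1
        best_val = history[-1]["train_uar"] if history else math.nan
    return TrainResult(model=model, history=history, best_epoch=best_epoch, best_val_uar=float(best_val))


# ---------------------------------------------------------------------------
# attention visualization


@dataclass(frozen=True)
class AttentionTrace:
    """Time-aligned attention scores for one segment: times in seconds
    (frame centres) and per-head scores (n_heads, T)."""

    times: np.ndarray
    scores: np.ndarray

    def plot(self, ax=None, waveform=None):
        """Plot the trace (and optionally the waveform above it)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, head in enumerate(self.scores):
            ax.plot(self.times, head, label=f"head {i}")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("attention score")
        ax.legend()
        return ax


def visualize_attention(
    model: AttentionLSTMClassifier,
    segment: np.ndarray,
    hop: float = 0.010,
    frame_len: float = 0.025,
) -> AttentionTrace:
    """Attention scores of one segment against time, for plotting over the
    waveform.  Times are frame centres derived from the analysis hop."""
    segment = np.asarray(segment)
    batch = pad_sequences([segment])
    _, att = model.forward(batch)
    if att is None:
        raise ValueError("the plain LSTM variant has no attention scores to visualize")
    t = segment.shape[0]
    times = np.arange(t) * hop + frame_len / 2.0
    return AttentionTrace(times=times, scores=att.scores[:, 0, 0, :t].copy())
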