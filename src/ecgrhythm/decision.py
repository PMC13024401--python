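"""Recording-level decision: majority voting over window predictions.

Each 1 s window casts one hard vote (argmax of its softmax probabilities);
the recording label is the most frequent vote.  This makes the 10 s
prediction robust to sporadic noisy windows: fewer than half the windows
being corrupted can never flip a unanimous vote.  Ties are broken by the
higher mean softmax probability among the tied classes, with the fixed
class order (NSR, ST, SB, SVT, VT) as the final deterministic fallback.

A recording-level probability vector (mean of the window softmax rows) is
also produced for one-vs-rest ROC/AUC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import CLASS_ORDER, RhythmLabel
from .net import WindowPrediction


@dataclass
class RecordingPrediction:
    record_id: str
    vote_counts: dict[RhythmLabel, int]
    label: RhythmLabel
    mean_probs: np.ndarray  # (n_classes,) in CLASS_ORDER
    m: int


def _prob_matrix(window_preds) -> np.ndarray:
    if len(window_preds) == 0:
        raise ValueError("window prediction list must be non-empty")
    rows = [
        wp.probs if isinstance(wp, WindowPrediction) else np.asarray(wp, dtype=np.float64)
        for wp in window_preds
    ]
    P = np.vstack(rows)
    if P.shape[1] != len(CLASS_ORDER):
        raise ValueError(f"expected {len(CLASS_ORDER)} classes, got {P.shape[1]}")
    return P


def recording_probability(window_preds) -> np.ndarray:
    """Arithmetic mean of the window probability vectors (stays on the simplex)."""
    return _prob_matrix(window_preds).mean(axis=0)


def majority_vote(window_preds, record_id: str = "") -> RecordingPrediction:
    """Fuse window predictions into one recording label.

    y_hat = argmax_c sum_j 1[C_j = c], where C_j is window j's argmax class.
    Invariant to the order of the windows.
    """
    P = _prob_matrix(window_preds)
    hard = P.argmax(axis=1)
    counts = np.bincount(hard, minlength=len(CLASS_ORDER))
    mean_probs = P.mean(axis=0)
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if tied.size == 1:
        winner = int(tied[0])
    else:
        # highest mean softmax probability among tied classes; np.argmax's
        # first-hit rule then realizes the fixed class-order fallback
        winner = int(tied[np.argmax(mean_probs[tied])])
    return RecordingPrediction(
        record_id=record_id,
        vote_counts={lab: int(counts[i]) for i, lab in enumerate(CLASS_ORDER)},
        label=CLASS_ORDER[winner],
        mean_probs=mean_probs,
        m=int(P.shape[0]),
    )


def export_predictions_tsv(preds: list[RecordingPrediction], true_labels, path: str) -> None:
    """record_id, true_label, pred_label, m, votes per class, mean probs per class."""
    cols = [f"votes_{lab}" for lab in CLASS_ORDER] + [f"prob_{lab}" for lab in CLASS_ORDER]
    with open(path, "w") as fh:
        fh.write("record_id\ttrue_label\tpred_label\tm\t" + "\t".join(cols) + "\n")
        for rp, yt in zip(preds, true_labels):
            votes = "\t".join(str(rp.vote_counts[lab]) for lab in CLASS_ORDER)
            probs = "\t".join(f"{p:.6f}" for p in rp.mean_probs)
            fh.write(f"{rp.record_id}\t{yt}\t{rp.label}\t{rp.m}\t{votes}\t{probs}\n")
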