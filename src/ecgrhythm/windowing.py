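"""Sliding-window decomposition of a standardized recording.

A 2500-sample (10 s at 250 Hz) strip cut into 1 s windows (W=250) with a
5-point stride yields floor((2500-250)/5)+1 = 451 sub-segments; this is the
data-augmentation step that turns 300 recordings per class into 135,300
training windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InputTooShortError
from .labels import RhythmLabel
from .signal_io import ECGRecord

DEFAULT_WINDOW = 250
DEFAULT_STRIDE = 5


@dataclass
class WindowBatch:
    """Ordered windows cut from one recording; window j starts at j*S (0-based, half-open)."""

    windows: np.ndarray  # (m, W)
    parent_id: str
    W: int
    S: int
    label: RhythmLabel | None = None

    @property
    def m(self) -> int:
        return self.windows.shape[0]

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.m) * self.S


def window_count(L: int, W: int, S: int) -> int:
    """Number of full windows: floor((L - W)/S) + 1 (trailing remainder dropped)."""
    if W < 1 or S < 1:
        raise ValueError("W and S must be >= 1")
    if L < W:
        raise InputTooShortError(f"record length {L} < window {W}")
    return (L - W) // S + 1


def slide_windows(rec: ECGRecord, W: int = DEFAULT_WINDOW, S: int = DEFAULT_STRIDE) -> WindowBatch:
    """Cut ``rec`` into windows of length W at stride S.

    Each window inherits the parent's label.  Raises InputTooShortError if
    the record is shorter than one window.
    """
    x = rec.samples
    m = window_count(x.size, W, S)
    view = np.lib.stride_tricks.sliding_window_view(x, W)[:: S]
    windows = np.ascontiguousarray(view[:m])
    return WindowBatch(windows=windows, parent_id=rec.source_id, W=W, S=S, label=rec.label)


def augmentation_count(n_records: int, L: int, W: int = DEFAULT_WINDOW, S: int = DEFAULT_STRIDE) -> int:
    """Total window count for ``n_records`` strips of length L (pure arithmetic)."""
    if n_records < 1:
        raise ValueError("n_records must be positive")
    return n_records * window_count(L, W, S)


def export_batch(batch: WindowBatch, matrix_path: str, sidecar_path: str) -> None:
    """Cache windows as a binary matrix plus a JSON sidecar with the geometry."""
    np.save(matrix_path, batch.windows.astype(np.float32))
    with open(sidecar_path, "w") as fh:
        json.dump(
            {
                "parent_id": batch.parent_id,
                "W": batch.W,
                "S": batch.S,
                "m": batch.m,
                "label": str(batch.label) if batch.label is not None else None,
            },
            fh,
            indent=2,
        )
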