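"""The five rhythm classes and their canonical order."""

from __future__ import annotations

from enum import Enum


class RhythmLabel(str, Enum):
    """Admissible rhythm categories for a 10 s strip.

    NSR: normal sinus rhythm (60-100 bpm, full P-QRS-T).
    ST:  sinus tachycardia (>100 bpm, sinus morphology).
    SB:  sinus bradycardia (<60 bpm, sinus morphology).
    SVT: supraventricular tachycardia (rapid, narrow QRS, P obscured/absent).
    VT:  ventricular tachycardia (rapid, wide distorted QRS).
    """

    NSR = "NSR"
    ST = "ST"
    SB = "SB"
    SVT = "SVT"
    VT = "VT"

    def __str__(self) -> str:  # serialize as the bare literal
        return self.value


#: Fixed class order used for probability vectors, confusion matrices and
#: deterministic tie-breaking.
CLASS_ORDER: tuple[RhythmLabel, ...] = (
    RhythmLabel.NSR,
    RhythmLabel.ST,
    RhythmLabel.SB,
    RhythmLabel.SVT,
    RhythmLabel.VT,
)

#: label -> index into CLASS_ORDER
CLASS_INDEX: dict[RhythmLabel, int] = {lab: i for i, lab in enumerate(CLASS_ORDER)}


def as_label(value) -> RhythmLabel:
    """Coerce a string or RhythmLabel to RhythmLabel, raising ValueError otherwise."""
    if isinstance(value, RhythmLabel):
        return value
    try:
        return RhythmLabel(str(value))
    except ValueError as exc:
        raise ValueError(f"unknown rhythm label: {value!r}") from exc
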