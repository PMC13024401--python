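"""Record container, file I/O, rate unification and z-score normalization.

Every strip entering the classifier is standardized to a single-channel
10 s signal at 250 Hz (2500 samples) and z-scored over the *full* 10 s
interval, so relative morphology (e.g. R height vs T height) is preserved
while device- and lead-dependent amplitude scales are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from . import wfdb_min
from .errors import DegenerateSignalError, FormatError, MissingChannelError
from .labels import RhythmLabel, as_label

TARGET_FS = 250.0

#: default lead preference: home patch monitors record lead I; lead II is the
#: compatible fallback (e.g. VFDB continuous recordings).
DEFAULT_LEAD_PREFERENCE = ("I", "II")


@dataclass
class ECGRecord:
    """One single-lead ECG strip.

    samples are amplitudes in arbitrary (or z-score) units; ``fs_hz`` is the
    sampling rate; ``lead`` is "I", "II" or "other"; ``label`` the optional
    ground-truth rhythm; ``subject_id`` supports patient-wise partitioning.
    """

    samples: np.ndarray
    fs_hz: float
    lead: str = "other"
    label: RhythmLabel | None = None
    source_id: str = ""
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D vector")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if self.label is not None:
            self.label = as_label(self.label)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    def copy_with(self, **kw) -> "ECGRecord":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# reading / writing


def _read_csv(path: str, fs_hz: float) -> ECGRecord:
    values = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if i == 0 and parts[0].strip().lower() == "sample_index":
                continue
            if len(parts) != 2:
                raise FormatError(f"{path}: line {i}: expected 'sample_index,value', got {line!r}")
            try:
                int(parts[0])
                values.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-numeric row {line!r}") from exc
    if not values:
        raise FormatError(f"{path}: no data rows")
    return ECGRecord(samples=np.array(values), fs_hz=fs_hz, source_id=path)


def read_record(
    path: str,
    dialect: str = "csv",
    fs_hz: float = TARGET_FS,
    lead_preference: tuple[str, ...] = DEFAULT_LEAD_PREFERENCE,
) -> ECGRecord:
    """Read one record.

    ``dialect`` is "csv" (two columns ``sample_index,value``; the rate is not
    stored in the file, pass ``fs_hz``) or "wfdb" (``path`` is the ``.hea``
    header; the first lead in ``lead_preference`` present among the channel
    descriptions is extracted).
    """
    if dialect == "csv":
        return _read_csv(path, fs_hz)
    if dialect == "wfdb":
        rec = wfdb_min.read_record(path)
        descs = [s.description for s in rec.signals]
        chan = None
        for want in lead_preference:
            if want in descs:
                chan = descs.index(want)
                break
        if chan is None:
            if rec.n_sig == 1:
                chan = 0
            else:
                raise MissingChannelError(
                    f"{path}: none of leads {lead_preference} in channels {descs}"
                )
        lead = descs[chan] if descs[chan] in ("I", "II") else "other"
        return ECGRecord(
            samples=rec.p_signal[:, chan], fs_hz=rec.fs, lead=lead, source_id=rec.name
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_csv(rec: ECGRecord, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_index,value\n")
        for i, v in enumerate(rec.samples.tolist()):  # repr of float round-trips exactly
            fh.write(f"{i},{v!r}\n")


def write_wfdb(rec: ECGRecord, out_dir: str, name: str) -> str:
    """Write the record as a WFDB header/signal pair; returns the .hea path."""
    return wfdb_min.write_record(
        out_dir, name, rec.samples[:, None], rec.fs_hz, [rec.lead]
    )


# ---------------------------------------------------------------------------
# standardization


def resample_to_250(rec: ECGRecord) -> ECGRecord:
    """Resample to 250 Hz, preserving duration (length = round(duration x 250)).

    Rational rate ratios use polyphase FIR resampling; non-rational rates fall
    back to linear interpolation.  Content below ~50 Hz (all rhythm-relevant
    ECG energy) passes with <1% amplitude error.
    """
    if rec.fs_hz == TARGET_FS:
        return rec
    n_out = int(round(rec.samples.size * TARGET_FS / rec.fs_hz))
    frac = Fraction(TARGET_FS / rec.fs_hz).limit_denominator(10000)
    if abs(float(frac) - TARGET_FS / rec.fs_hz) < 1e-12:
        y = resample_poly(rec.samples, frac.numerator, frac.denominator)
        if y.size > n_out:
            y = y[:n_out]
        elif y.size < n_out:
            y = np.pad(y, (0, n_out - y.size), mode="edge")
    else:
        t_old = np.arange(rec.samples.size) / rec.fs_hz
        t_new = np.arange(n_out) / TARGET_FS
        y = np.interp(t_new, t_old, rec.samples)
    return rec.copy_with(samples=y, fs_hz=TARGET_FS)


def zscore_normalize(rec: ECGRecord) -> ECGRecord:
    """Z-score over the full record: (x - mean) / population std.

    Raises DegenerateSignalError for a constant signal (a flat line carries
    no rhythm, and the transform is undefined).
    """
    x = rec.samples
    if x.size < 2:
        raise ValueError("z-score needs at least 2 samples")
    mu = x.mean()
    sigma = x.std()  # population convention (divide by N)
    if sigma < 1e-12 * max(1.0, abs(mu)):
        raise DegenerateSignalError("constant signal: zero variance")
    return rec.copy_with(samples=(x - mu) / sigma)


def standardize(rec: ECGRecord, crop_long: bool = False) -> ECGRecord:
    """Resample to 250 Hz, enforce 10 s length, and z-score.

    Records shorter than 10 s are rejected; with ``crop_long`` the first 10 s
    of a longer record is used (continuous-monitor input), otherwise longer
    records are rejected too.
    """
    rec = resample_to_250(rec)
    n_target = int(round(10 * TARGET_FS))
    if rec.samples.size < n_target:
        raise ValueError(f"record is {rec.duration_s:.2f} s; 10 s required")
    if rec.samples.size > n_target:
        if not crop_long:
            raise ValueError(f"record is {rec.duration_s:.2f} s; pass crop_long=True to take the first 10 s")
        rec = rec.copy_with(samples=rec.samples[:n_target])
    return zscore_normalize(rec)
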