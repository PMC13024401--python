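"""Minimal WFDB header/signal reader and writer.

Supports the subset of the PhysioNet WFDB format this package needs:
single-segment records, one shared ``.dat`` file, sample-interleaved
formats 16 (int16) and 32 (int32, little-endian), with per-channel
gain/baseline decoding and channel descriptions.

The physical value of sample ``v`` on channel ``c`` is
``(v - baseline_c) / gain_c``.  The writer picks an adaptive gain so that
the integer quantization error is negligible (format 32: relative error
on the order of 1e-9).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

_FMT_DTYPE = {16: np.int16, 32: np.int32}
_FMT_MAX = {16: 2**15 - 2, 32: 2**31 - 2}


@dataclass
class WfdbSignalInfo:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


@dataclass
class WfdbRecord:
    name: str
    fs: float
    n_sig: int
    n_samp: int
    signals: list[WfdbSignalInfo]
    #: physical samples, shape (n_samp, n_sig)
    p_signal: np.ndarray = field(default=None)


# header signal line:  file fmt gain(baseline)/units adcres adczero initval cksum bsize description
_SIG_RE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)"
    r"(?:\s+(?P<gain>[0-9.eE+-]+)(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?)?"
    r"(?:\s+(?P<adcres>\d+))?(?:\s+(?P<adczero>-?\d+))?(?:\s+(?P<initval>-?\d+))?"
    r"(?:\s+(?P<cksum>-?\d+))?(?:\s+(?P<bsize>\d+))?"
    r"(?:\s+(?P<desc>.*\S))?\s*$"
)


def read_header(hea_path: str) -> WfdbRecord:
    with open(hea_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea_path}: record line needs 'name n_sig fs n_samp', got {lines[0]!r}")
    name, n_sig = head[0], int(head[1])
    fs = float(head[2])
    n_samp = int(head[3])
    signals: list[WfdbSignalInfo] = []
    for i, ln in enumerate(lines[1 : 1 + n_sig]):
        m = _SIG_RE.match(ln)
        if not m:
            raise FormatError(f"{hea_path}: cannot parse signal line {i + 1}: {ln!r}")
        fmt = int(m.group("fmt"))
        if fmt not in _FMT_DTYPE:
            raise FormatError(f"{hea_path}: unsupported WFDB format {fmt}")
        gain = float(m.group("gain") or 200.0) or 200.0
        baseline = int(m.group("baseline") or m.group("adczero") or 0)
        signals.append(
            WfdbSignalInfo(
                file_name=m.group("file"),
                fmt=fmt,
                gain=gain,
                baseline=baseline,
                units=m.group("units") or "mV",
                description=m.group("desc") or f"ch{i}",
            )
        )
    if len(signals) != n_sig:
        raise FormatError(f"{hea_path}: header declares {n_sig} signals, found {len(signals)}")
    return WfdbRecord(name=name, fs=fs, n_sig=n_sig, n_samp=n_samp, signals=signals)


def read_record(hea_path: str) -> WfdbRecord:
    """Read header and signal data; fills ``p_signal`` with physical values."""
    rec = read_header(hea_path)
    dat_names = {s.file_name for s in rec.signals}
    if len(dat_names) != 1:
        raise FormatError(f"{hea_path}: multi-file records are not supported")
    fmts = {s.fmt for s in rec.signals}
    if len(fmts) != 1:
        raise FormatError(f"{hea_path}: mixed sample formats are not supported")
    dat_path = os.path.join(os.path.dirname(hea_path), dat_names.pop())
    raw = np.fromfile(dat_path, dtype=np.dtype(_FMT_DTYPE[fmts.pop()]).newbyteorder("<"))
    if raw.size != rec.n_samp * rec.n_sig:
        raise FormatError(
            f"{dat_path}: expected {rec.n_samp * rec.n_sig} samples, found {raw.size}"
        )
    adc = raw.reshape(rec.n_samp, rec.n_sig).astype(np.float64)
    gains = np.array([s.gain for s in rec.signals])
    bases = np.array([s.baseline for s in rec.signals])
    rec.p_signal = (adc - bases) / gains
    return rec


def write_record(
    out_dir: str,
    name: str,
    p_signal: np.ndarray,
    fs: float,
    descriptions: list[str],
    fmt: int = 32,
    units: str = "mV",
) -> str:
    """Write ``p_signal`` (n_samp, n_sig) as ``name.hea`` + ``name.dat``.

    Returns the header path.  Gain is chosen per channel so the integer
    range is fully used; baseline 0.
    """
    p_signal = np.asarray(p_signal, dtype=np.float64)
    if p_signal.ndim == 1:
        p_signal = p_signal[:, None]
    n_samp, n_sig = p_signal.shape
    if len(descriptions) != n_sig:
        raise ValueError("one description per channel required")
    if fmt not in _FMT_DTYPE:
        raise ValueError(f"unsupported WFDB format {fmt}")
    maxabs = np.max(np.abs(p_signal), axis=0)
    gains = np.where(maxabs > 0, _FMT_MAX[fmt] / np.maximum(maxabs, 1e-30), 200.0)
    adc = np.rint(p_signal * gains).astype(_FMT_DTYPE[fmt])
    os.makedirs(out_dir, exist_ok=True)
    dat_name = f"{name}.dat"
    adc.astype(np.dtype(_FMT_DTYPE[fmt]).newbyteorder("<")).tofile(
        os.path.join(out_dir, dat_name)
    )
    lines = [f"{name} {n_sig} {fs:g} {n_samp}"]
    for c in range(n_sig):
        lines.append(
            f"{dat_name} {fmt} {gains[c]:.6f}(0)/{units} {np.dtype(_FMT_DTYPE[fmt]).itemsize * 8}"
            f" 0 {adc[0, c]} 0 0 {descriptions[c]}"
        )
    hea_path = os.path.join(out_dir, f"{name}.hea")
    with open(hea_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return hea_path
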