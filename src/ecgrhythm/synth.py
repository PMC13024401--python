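"""Deterministic synthetic five-rhythm single-lead ECG generator.

Each recording is a sum of Gaussian deflections (P, Q, R, S, T) placed on a
beat grid whose R-R intervals are drawn from the class's heart-rate range
with mild beat-to-beat jitter.  The five classes reproduce the clinically
defining regime:

* NSR / ST / SB share full P-QRS-T morphology and differ only in rate
  (60-100 / 100-150 / 40-59 bpm);
* SVT is fast (150-220 bpm) with narrow QRS and no discernible P wave;
* VT is fast (120-250 bpm) with a wide (>120 ms), distorted QRS, absent P
  and discordant (inverted) T.

Optional noise adds baseline wander, high-frequency noise and sporadic
motion artifacts.  Generation is a pure function of the configuration and
seeds: identical inputs reproduce the sample vector bit-exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .labels import CLASS_INDEX, CLASS_ORDER, RhythmLabel, as_label
from .signal_io import ECGRecord, write_csv, write_wfdb


@dataclass(frozen=True)
class RhythmSpec:
    """Generative parameters of one rhythm class."""

    label: RhythmLabel
    hr_range_bpm: tuple[float, float]
    p_wave_present: bool
    p_amplitude_scale: float
    qrs_width_ms: float
    qrs_shape: str  # "narrow" | "wide_distorted"
    rr_jitter_frac: float

    def __post_init__(self):
        lo, hi = self.hr_range_bpm
        if not (lo > 0 and hi >= lo):
            raise ValueError("hr_range_bpm must satisfy 0 < lo <= hi")
        if self.qrs_width_ms <= 0:
            raise ValueError("qrs_width_ms must be positive")
        if self.qrs_shape == "wide_distorted" and self.qrs_width_ms <= 120:
            raise ValueError("wide_distorted QRS must be wider than 120 ms")
        if self.qrs_shape not in ("narrow", "wide_distorted"):
            raise ValueError(f"unknown qrs_shape {self.qrs_shape!r}")
        if self.p_amplitude_scale < 0 or self.rr_jitter_frac < 0:
            raise ValueError("p_amplitude_scale and rr_jitter_frac must be >= 0")


DEFAULT_SPECS: dict[RhythmLabel, RhythmSpec] = {
    RhythmLabel.NSR: RhythmSpec(RhythmLabel.NSR, (60, 100), True, 1.0, 80, "narrow", 0.03),
    RhythmLabel.ST: RhythmSpec(RhythmLabel.ST, (100, 150), True, 1.0, 80, "narrow", 0.02),
    RhythmLabel.SB: RhythmSpec(RhythmLabel.SB, (40, 59), True, 1.0, 80, "narrow", 0.03),
    RhythmLabel.SVT: RhythmSpec(RhythmLabel.SVT, (150, 220), False, 0.0, 80, "narrow", 0.01),
    RhythmLabel.VT: RhythmSpec(RhythmLabel.VT, (120, 250), False, 0.0, 160, "wide_distorted", 0.04),
}


@dataclass(frozen=True)
class NoiseConfig:
    """Additive disturbances, amplitudes relative to the (unit) R wave."""

    baseline_wander_amp: float = 0.15
    baseline_wander_freq_hz: float = 0.3
    hf_noise_sd: float = 0.05
    artifact_prob: float = 0.05

    def __post_init__(self):
        if min(self.baseline_wander_amp, self.baseline_wander_freq_hz, self.hf_noise_sd) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not 0 <= self.artifact_prob <= 1:
            raise ValueError("artifact_prob must lie in [0, 1]")

    @classmethod
    def clean(cls) -> "NoiseConfig":
        return cls(0.0, 0.3, 0.0, 0.0)


@dataclass(frozen=True)
class SynthDatasetConfig:
    per_class_count: int = 300
    duration_s: float = 10.0
    fs_hz: float = 250.0
    seed: int = 0
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self):
        if self.per_class_count < 1:
            raise ValueError("per_class_count must be positive")
        n = self.duration_s * self.fs_hz
        if not (n > 0 and abs(n - round(n)) < 1e-9):
            raise ValueError("duration_s x fs_hz must be a positive integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


# ---------------------------------------------------------------------------
# waveform synthesis


def _beat_components(spec: RhythmSpec, rr_s: float) -> list[tuple[float, float, float]]:
    """(offset_s from R, amplitude, Gaussian sigma_s) for one cardiac cycle.

    P and T offsets compress with rate (shorter diastole at high HR); QRS
    width does not.  Amplitudes are relative to a unit R wave.
    """
    scale = float(np.clip(rr_s / 0.8, 0.55, 1.15))
    sigma_r = spec.qrs_width_ms / 1000.0 / 2.355  # FWHM = qrs_width
    comps = []
    if spec.qrs_shape == "narrow":
        comps += [
            (-0.050, -0.10, 0.010),  # Q
            (0.0, 1.0, sigma_r),  # R
            (0.050, -0.15, 0.010),  # S
            (0.30 * scale, 0.35, 0.06 * scale),  # T
        ]
        if spec.p_wave_present and spec.p_amplitude_scale > 0:
            comps.append((-0.16 * scale, 0.15 * spec.p_amplitude_scale, 0.02))
    else:  # wide_distorted (VT-like): broad R, trailing opposite lobe, discordant T
        comps += [
            (0.0, 1.0, sigma_r),
            (0.13, -0.50, 0.030),
            (0.35 * scale, -0.30, 0.07 * scale),
        ]
        if spec.p_wave_present and spec.p_amplitude_scale > 0:
            comps.append((-0.16 * scale, 0.15 * spec.p_amplitude_scale, 0.02))
    return comps


def make_beat_template(spec: RhythmSpec, fs_hz: float) -> np.ndarray:
    """One noise-free cardiac cycle at the class's mid-range rate, R at the center."""
    if not fs_hz >= 100:
        raise ValueError("fs_hz must be >= 100")
    hr = 0.5 * (spec.hr_range_bpm[0] + spec.hr_range_bpm[1])
    rr = 60.0 / hr
    n = int(round(rr * fs_hz))
    t = np.arange(n) / fs_hz - rr / 2.0  # R at t = 0
    y = np.zeros(n)
    for off, amp, sig in _beat_components(spec, rr):
        y += amp * np.exp(-0.5 * ((t - off) / sig) ** 2)
    return y


def _render(beat_times: np.ndarray, spec: RhythmSpec, rr_mean: float, t: np.ndarray) -> np.ndarray:
    y = np.zeros_like(t)
    comps = _beat_components(spec, rr_mean)
    fs = 1.0 / (t[1] - t[0])
    for tb in beat_times:
        for off, amp, sig in comps:
            center = tb + off
            lo = max(0, int((center - 5 * sig) * fs))
            hi = min(t.size, int((center + 5 * sig) * fs) + 2)
            if hi > lo:
                y[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / sig) ** 2)
    return y


def generate_recording(
    label: RhythmLabel | str,
    cfg: SynthDatasetConfig,
    record_seed: int,
    spec: RhythmSpec | None = None,
) -> ECGRecord:
    """Generate one labeled strip; pure function of (label, cfg, record_seed).

    The record's ``meta`` carries the drawn heart rate and beat onset times
    for downstream oracles (peak counting, rate estimation).
    """
    label = as_label(label)
    spec = spec if spec is not None else DEFAULT_SPECS[label]
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, record_seed & 0x7FFFFFFF, CLASS_INDEX[label]])

    lo, hi = spec.hr_range_bpm
    margin = 0.05 * (hi - lo)
    hr = rng.uniform(lo + margin, hi - margin)  # keep mean instantaneous HR inside the range
    rr_mean = 60.0 / hr

    # beat grid: start before 0 so the first window is covered
    times = [-rr_mean + rng.uniform(0, rr_mean)]
    while times[-1] < cfg.duration_s + 1.0:
        rr = rr_mean * (1.0 + spec.rr_jitter_frac * rng.standard_normal())
        times.append(times[-1] + max(rr, 0.2))
    beat_times = np.array(times)

    t = np.arange(cfg.n_samples) / cfg.fs_hz
    y = _render(beat_times, spec, rr_mean, t)
    peak = np.max(y)
    if peak > 0:
        y = y / peak  # R amplitude -> 1.0 before noise

    nz = cfg.noise
    if nz.baseline_wander_amp > 0:
        y = y + nz.baseline_wander_amp * np.sin(
            2 * np.pi * nz.baseline_wander_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if nz.hf_noise_sd > 0:
        y = y + nz.hf_noise_sd * rng.standard_normal(t.size)
    if nz.artifact_prob > 0 and rng.uniform() < nz.artifact_prob:
        c = rng.uniform(0.5, cfg.duration_s - 0.5)
        width = rng.uniform(0.1, 0.4)
        env = np.exp(-0.5 * ((t - c) / width) ** 2)
        y = y + 0.5 * env * rng.standard_normal(t.size)

    onsets = beat_times[(beat_times >= 0) & (beat_times < cfg.duration_s)]
    return ECGRecord(
        samples=y,
        fs_hz=cfg.fs_hz,
        lead="I",
        label=label,
        source_id=f"synth-{label}-{record_seed:05d}",
        subject_id=f"subj-{label}-{record_seed:05d}",
        meta={"hr_bpm": hr, "beat_times_s": onsets},
    )


# ---------------------------------------------------------------------------
# dataset assembly

PARTITIONS = ("train", "validation", "test")


@dataclass
class SynthDataset:
    records: list[ECGRecord]
    partitions: dict[str, list[ECGRecord]]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for part in PARTITIONS:
            for rec in self.partitions[part]:
                rows.append(
                    {
                        "record_id": rec.source_id,
                        "subject_id": rec.subject_id,
                        "label": str(rec.label),
                        "partition": part,
                        "fs": rec.fs_hz,
                    }
                )
        return pd.DataFrame(rows, columns=["record_id", "subject_id", "label", "partition", "fs"])


def _split_counts(per_class: int, split) -> tuple[int, int, int]:
    split = tuple(split)
    if len(split) != 3:
        raise ValueError("split must have three entries (train, validation, test)")
    if all(isinstance(s, (int, np.integer)) for s in split):
        if sum(split) != per_class:
            raise ValueError(f"split counts {split} must sum to per_class_count={per_class}")
        return tuple(int(s) for s in split)
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("fractional split must sum to 1")
    n_val = int(round(split[1] * per_class))
    n_test = int(round(split[2] * per_class))
    n_train = per_class - n_val - n_test
    counts = (n_train, n_val, n_test)
    if any(c < 1 for c in counts):
        raise ValueError(
            f"per_class_count={per_class} too small to fill three partitions at split {split}"
        )
    return counts


def generate_dataset(
    cfg: SynthDatasetConfig,
    split=(0.6, 0.2, 0.2),
    specs: dict[RhythmLabel, RhythmSpec] | None = None,
) -> SynthDataset:
    """Balanced five-class dataset with a patient-wise partition.

    ``split`` is either three fractions summing to 1 or three integer counts
    per class summing to ``per_class_count``.  Each synthetic subject owns
    exactly one recording, so subject-wise and record-wise splitting
    coincide; subjects never straddle partitions.
    """
    if cfg.per_class_count < 3 and not all(isinstance(s, (int, np.integer)) for s in split):
        raise ValueError("per_class_count must be >= 3 to fill three partitions")
    counts = _split_counts(cfg.per_class_count, split)
    specs = specs or DEFAULT_SPECS
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0xD5])
    records: list[ECGRecord] = []
    partitions: dict[str, list[ECGRecord]] = {p: [] for p in PARTITIONS}
    for label in CLASS_ORDER:
        recs = [
            generate_recording(label, cfg, record_seed=i, spec=specs[label])
            for i in range(cfg.per_class_count)
        ]
        order = rng.permutation(cfg.per_class_count)
        edges = np.cumsum((0,) + counts)
        for part, a, b in zip(PARTITIONS, edges[:-1], edges[1:]):
            partitions[part].extend(recs[j] for j in order[a:b])
        records.extend(recs)
    return SynthDataset(records=records, partitions=partitions)


def write_dataset(ds: SynthDataset, out_dir: str, fmt: str = "csv") -> str:
    """Write fixtures plus a manifest TSV; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    for rec in ds.records:
        if fmt == "csv":
            write_csv(rec, os.path.join(out_dir, f"{rec.source_id}.csv"))
        elif fmt == "wfdb":
            write_wfdb(rec, out_dir, rec.source_id)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    ds.manifest().to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


# ---------------------------------------------------------------------------
# oracles used by tests and sanity checks


def detect_r_peaks(samples: np.ndarray, fs_hz: float, threshold: float = 0.5) -> np.ndarray:
    """Threshold-based R peak indices on a clean (noise-off) signal.

    A sample is a peak if it exceeds ``threshold`` x max and is the maximum
    within a 120 ms refractory neighbourhood.
    """
    x = np.asarray(samples, dtype=np.float64)
    thr = threshold * np.max(x)
    half = max(1, int(0.06 * fs_hz))
    peaks = []
    for i in range(1, x.size - 1):
        if x[i] >= thr and x[i] >= x[i - 1] and x[i] > x[i + 1]:
            lo, hi = max(0, i - half), min(x.size, i + half + 1)
            if x[i] >= np.max(x[lo:hi]):
                peaks.append(i)
    return np.array(peaks, dtype=int)


def mean_hr_bpm(samples: np.ndarray, fs_hz: float) -> float:
    """Mean heart rate from detected R-R intervals (clean signals)."""
    peaks = detect_r_peaks(samples, fs_hz)
    if peaks.size < 2:
        raise ValueError("need at least two R peaks to estimate rate")
    rr = np.diff(peaks) / fs_hz
    return float(np.mean(60.0 / rr))


def half_height_width_ms(template: np.ndarray, fs_hz: float) -> float:
    """Half-height width of the dominant positive deflection, in ms."""
    i = int(np.argmax(template))
    half = template[i] / 2.0
    lo = i
    while lo > 0 and template[lo - 1] >= half:
        lo -= 1
    hi = i
    while hi < template.size - 1 and template[hi + 1] >= half:
        hi += 1
    return (hi - lo + 1) / fs_hz * 1000.0
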