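"""Recording IO and the preprocessing chain.

The chain mirrors the acquisition pipeline: a sixth-order Butterworth
band-pass (1-40 Hz) with a 60 Hz notch applied at the native 500 Hz rate,
down-sampling to 125 Hz, then segmentation into 60-s epochs
(2 x 7500 samples for the ear channels, 6 x 7500 for the scalp channels).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    FilterDesignError,
    InvalidConfigError,
    MissingChannelError,
    RecordingReadError,
    TooShortError,
)
from .simulate import CHANNELS, Recording

EAR_CHANNELS = ("earL", "earR")
SCALP_CHANNELS = ("AF7", "Fpz", "AF8", "C3", "Cz", "C4")
TARGET_FS = 125.0
EPOCH_SECONDS = 60.0


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path) -> None:
    """Delimited text: one metadata comment line, a header row of channel
    labels, then samples x channels."""
    header = (
        f"# fs={recording.fs!r} subject_id={recording.subject_id} "
        f"condition={recording.condition}\n" + "\t".join(recording.channel_labels)
    )
    np.savetxt(path, recording.data.T, fmt="%.6f", delimiter="\t",
               header=header, comments="")


def _read_delimited(path) -> Recording:
    with open(path) as fh:
        meta_line = fh.readline().strip()
        label_line = fh.readline().strip()
    if not meta_line.startswith("#"):
        raise RecordingReadError(f"{path}: missing metadata comment line")
    meta = {}
    for tok in meta_line.lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    if "fs" not in meta:
        raise RecordingReadError(f"{path}: metadata does not declare fs")
    labels = tuple(label_line.split("\t"))
    if not labels or labels == ("",):
        raise RecordingReadError(f"{path}: missing channel-label header row")
    try:
        data = np.loadtxt(path, skiprows=2, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise RecordingReadError(f"{path}: inconsistent row lengths ({exc})") from exc
    if data.shape[1] != len(labels):
        raise RecordingReadError(
            f"{path}: {data.shape[1]} columns for {len(labels)} labels"
        )
    return Recording(
        data=data.T,
        fs=float(meta["fs"]),
        channel_labels=labels,
        subject_id=meta.get("subject_id", "unknown"),
        condition=meta.get("condition", "relax"),
    )


def _read_edf(path, subject_id=None, condition=None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,  # mne returns volts
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject_id=subject_id or "unknown",
        condition=condition or "relax",
    )


def read_recording(path, format="delimited", subject_id=None, condition=None) -> Recording:
    """Read a recording from delimited text or EDF."""
    if not os.path.exists(path):
        raise RecordingReadError(f"no such file: {path}")
    if format == "delimited":
        rec = _read_delimited(path)
        if subject_id is not None:
            rec.subject_id = subject_id
        if condition is not None:
            rec.condition = condition
        return rec
    if format == "edf":
        return _read_edf(path, subject_id, condition)
    raise RecordingReadError(f"unknown format {format!r}")


def require_channels(recording: Recording, labels) -> None:
    missing = [c for c in labels if c not in recording.channel_labels]
    if missing:
        raise MissingChannelError(
            f"recording {recording.subject_id}/{recording.condition} is missing "
            f"channel(s) {missing}"
        )


def write_dataset(recordings, out_dir, manifest_name="manifest.tsv") -> str:
    """Write recordings as delimited text plus a TSV manifest; returns the
    manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}_{rec.condition}.tsv"
        write_recording(rec, os.path.join(out_dir, fname))
        rows.append(
            {"subject_id": rec.subject_id, "condition": rec.condition,
             "path": fname, "fs": rec.fs}
        )
    manifest = os.path.join(out_dir, manifest_name)
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_manifest(manifest_path) -> list:
    """Load every recording listed in a TSV manifest (paths relative to it)."""
    base = os.path.dirname(os.path.abspath(manifest_path))
    table = pd.read_csv(manifest_path, sep="\t")
    recordings = []
    for row in table.itertuples():
        path = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        fmt = "edf" if str(path).lower().endswith(".edf") else "delimited"
        recordings.append(
            read_recording(path, fmt, subject_id=str(row.subject_id),
                           condition=str(row.condition))
        )
    return recordings


# ---------------------------------------------------------------------------
# Filtering and resampling
# ---------------------------------------------------------------------------

def bandpass_notch(
    recording: Recording,
    low: float = 1.0,
    high: float = 40.0,
    order: int = 6,
    notch: float = 60.0,
    notch_q: float = 30.0,
    zero_phase: bool = True,
) -> Recording:
    """Sixth-order Butterworth band-pass plus an IIR notch.

    Applied forward-backward by default (zero phase; effective magnitude
    order doubles); set zero_phase=False for causal filtering.
    """
    if recording.fs <= 2 * high:
        raise FilterDesignError(
            f"fs={recording.fs} too low for a {high} Hz band edge"
        )
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=recording.fs, output="sos")
    b_n, a_n = signal.iirnotch(notch, notch_q, fs=recording.fs)
    if zero_phase:
        data = signal.sosfiltfilt(sos, recording.data, axis=1)
        data = signal.filtfilt(b_n, a_n, data, axis=1)
    else:
        data = signal.sosfilt(sos, recording.data, axis=1)
        data = signal.lfilter(b_n, a_n, data, axis=1)
    return Recording(
        data=data, fs=recording.fs, channel_labels=recording.channel_labels,
        subject_id=recording.subject_id, condition=recording.condition,
    )


def resample_to_target(recording: Recording, target_fs: float = TARGET_FS) -> Recording:
    """Down-sample to target_fs.

    With an integer ratio (500 -> 125) this keeps every 4th sample — the
    preceding 40 Hz low-pass already prevents aliasing at 125 Hz.  Non-integer
    ratios fall back to polyphase resampling.
    """
    if target_fs > recording.fs:
        raise FilterDesignError(
            f"target_fs={target_fs} exceeds recording fs={recording.fs}"
        )
    ratio = recording.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        data = recording.data[:, :: int(round(ratio))]
    else:
        from fractions import Fraction

        frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
        data = signal.resample_poly(recording.data, frac.numerator,
                                    frac.denominator, axis=1)
    return Recording(
        data=data, fs=target_fs, channel_labels=recording.channel_labels,
        subject_id=recording.subject_id, condition=recording.condition,
    )


def preprocess_recording(recording: Recording, target_fs: float = TARGET_FS,
                         **filter_kwargs) -> Recording:
    """Filter at the native rate, then down-sample (in that order)."""
    return resample_to_target(bandpass_notch(recording, **filter_kwargs), target_fs)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Fixed-length epochs ready for the classifier and the marker pipeline.

    ear: (n, 2, samples) arrays ordered (earL, earR); scalp: optional
    (n, 6, samples) parallel arrays ordered as SCALP_CHANNELS; labels use
    stress=1, relax=0.
    """

    ear: np.ndarray
    labels: np.ndarray
    subject_ids: list
    fs: float
    scalp: np.ndarray = None
    scalp_labels: tuple = field(default=SCALP_CHANNELS)

    def __post_init__(self):
        self.ear = np.asarray(self.ear)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.ear.ndim != 3 or self.ear.shape[0] != len(self.labels):
            raise InvalidConfigError("epoch array / label count mismatch")
        if not np.isin(self.labels, [0, 1]).all():
            raise InvalidConfigError("labels must be 0 (relax) or 1 (stress)")

    def __len__(self) -> int:
        return self.ear.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.ear.shape[2]

    def subset(self, indices) -> "EpochSet":
        indices = np.asarray(indices)
        return EpochSet(
            ear=self.ear[indices],
            labels=self.labels[indices],
            subject_ids=[self.subject_ids[i] for i in indices],
            fs=self.fs,
            scalp=None if self.scalp is None else self.scalp[indices],
        )

    def indices_for_subjects(self, subjects) -> np.ndarray:
        wanted = set(subjects)
        return np.array(
            [i for i, s in enumerate(self.subject_ids) if s in wanted], dtype=int
        )


def extract_epochs(recordings, epoch_s: float = EPOCH_SECONDS,
                   multi_epoch: bool = False) -> EpochSet:
    """Cut each preprocessed recording into epoch_s-long epochs.

    By default only the first epoch of each recording is used (whole-segment
    epochs); multi_epoch=True slices every full non-overlapping window as a
    data-augmentation mode.  Windows are half-open [start, end) in 0-based
    sample indices.
    """
    ear, scalp, labels, subjects = [], [], [], []
    fs = recordings[0].fs
    n_epoch = int(round(epoch_s * fs))
    for rec in recordings:
        if abs(rec.fs - fs) > 1e-9:
            raise InvalidConfigError("recordings have inconsistent sampling rates")
        if rec.n_samples < n_epoch:
            raise TooShortError(
                f"{rec.subject_id}/{rec.condition}: {rec.n_samples} samples "
                f"< {n_epoch} required for a {epoch_s}-s epoch"
            )
        require_channels(rec, EAR_CHANNELS)
        has_scalp = all(c in rec.channel_labels for c in SCALP_CHANNELS)
        n_slices = rec.n_samples // n_epoch if multi_epoch else 1
        for j in range(n_slices):
            sl = slice(j * n_epoch, (j + 1) * n_epoch)
            ear.append(np.stack([rec.channel(c)[sl] for c in EAR_CHANNELS]))
            if has_scalp:
                scalp.append(np.stack([rec.channel(c)[sl] for c in SCALP_CHANNELS]))
            labels.append(1 if rec.condition == "stress" else 0)
            subjects.append(rec.subject_id)
    scalp_arr = np.stack(scalp) if len(scalp) == len(ear) and scalp else None
    return EpochSet(
        ear=np.stack(ear), labels=np.array(labels), subject_ids=subjects,
        fs=fs, scalp=scalp_arr,
    )


def preprocess_dataset(recordings, target_fs: float = TARGET_FS,
                       epoch_s: float = EPOCH_SECONDS,
                       multi_epoch: bool = False, **filter_kwargs) -> EpochSet:
    """Full chain: band-pass+notch at the native rate, down-sample, epoch."""
    processed = [preprocess_recording(r, target_fs, **filter_kwargs)
                 for r in recordings]
    return extract_epochs(processed, epoch_s=epoch_s, multi_epoch=multi_epoch)
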