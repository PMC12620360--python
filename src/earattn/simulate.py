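"""Synthetic bilateral ear-EEG / scalp-EEG generator.

Emulates paired 60-s eyes-open resting recordings from two conditions
(post-stressor rest vs. post-relaxation rest) on the eight-channel montage
{earL, earR, AF7, Fpz, AF8, C3, Cz, C4}.  Each recording is 1/f background
noise plus narrowband oscillatory sources:

* theta (4-7 Hz), strongest at Fpz (frontal-midline theta),
* left/right alpha (8-13 Hz) at AF7/AF8,
* beta (14-30 Hz) at Cz,
* a single high-beta (23-36 Hz) source shared across the frontal-central
  pairs (AF7-C3, AF8-C4, Fpz-Cz), driving their band coherence,
* hemispheric "temporal" mixtures feeding the two preauricular ear channels
  with a small interaural lag.

The stress condition rescales oscillator amplitudes (theta up, alpha down,
Cz beta up, shared high-beta up, an AF8-vs-AF7 alpha asymmetry shift) and
shifts the ear lag; it never changes which random substream is consumed, so
under a null configuration (all gains 1, shifts 0) the two conditions are
i.i.d. draws from the same distribution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import InvalidConfigError, UnknownConditionError

CHANNELS = ("earL", "earR", "AF7", "Fpz", "AF8", "C3", "Cz", "C4")
CONDITIONS = ("stress", "relax")

#: Band-limited unit-variance oscillators are scaled by these RMS amplitudes
#: (microvolts) before mixing; background 1/f noise is ~1 uV RMS per channel.
SOURCE_AMPLITUDE_UV = {
    "theta": 3.0,
    "alphaL": 4.0,
    "alphaR": 4.0,
    "beta": 2.0,
    "shared": 1.5,
    "ear_broadband": 0.8,
}

SOURCE_BANDS_HZ = {
    "theta": (4.0, 7.0),
    "alphaL": (8.0, 13.0),
    "alphaR": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "shared": (23.0, 36.0),
    "ear_broadband": (4.0, 36.0),
}

#: Scalp mixing weights per source (channel -> weight).
SCALP_MIX = {
    "theta": {"Fpz": 1.0, "Cz": 0.25, "AF7": 0.15, "AF8": 0.15},
    "alphaL": {"AF7": 1.0, "C3": 0.3},
    "alphaR": {"AF8": 1.0, "C4": 0.3},
    "beta": {"Cz": 1.0, "C3": 0.3, "C4": 0.3},
    "shared": {"AF7": 0.7, "C3": 0.7, "AF8": 0.7, "C4": 0.7, "Fpz": 0.7, "Cz": 0.7},
}

#: Hemispheric temporal-source weights feeding each ear channel.
EAR_MIX = {"theta": 0.4, "alpha": 0.7, "beta": 0.6, "shared": 0.5, "ear_broadband": 1.0}

NOISE_RMS_UV = 1.0

DEFAULT_EFFECT_SIZES = {
    "fm_theta_gain": 2.5,
    "alpha_gain": 0.6,
    "cz_beta_gain": 2.2,
    "coherence_gain": 2.0,
    "faa_shift": 0.5,
    "ear_lag_ms": 4.0,
    "ear_lag_shift_ms": 6.0,
}

_GAIN_KEYS = ("fm_theta_gain", "alpha_gain", "cz_beta_gain", "coherence_gain")


def null_effect_sizes() -> dict:
    """Effect map under which stress and relax are identically distributed."""
    return {
        "fm_theta_gain": 1.0,
        "alpha_gain": 1.0,
        "cz_beta_gain": 1.0,
        "coherence_gain": 1.0,
        "faa_shift": 0.0,
        "ear_lag_ms": DEFAULT_EFFECT_SIZES["ear_lag_ms"],
        "ear_lag_shift_ms": 0.0,
    }


@dataclass
class Recording:
    """A labeled multichannel time series.

    data is (channels x samples) in microvolts; channel_labels is an ordered
    subset of CHANNELS; condition is 'stress' or 'relax'.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple
    subject_id: str
    condition: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_labels = tuple(self.channel_labels)
        self.validate()

    def validate(self):
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise InvalidConfigError(
                f"data has {self.data.shape[0]} rows for "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidConfigError("channel labels are not unique")
        if self.fs <= 0:
            raise InvalidConfigError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidConfigError("recording contains non-finite samples")
        if self.condition not in CONDITIONS:
            raise UnknownConditionError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            from .errors import MissingChannelError

            raise MissingChannelError(label) from None


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the paired-recording simulator."""

    n_subjects: int = 32
    fs_raw: float = 500.0
    duration: float = 60.0
    noise_exponent: float = 1.0
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    subject_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise InvalidConfigError("n_subjects must be >= 2")
        if self.fs_raw <= 2 * 40.0:
            raise InvalidConfigError("fs_raw must exceed twice the 40 Hz band edge")
        if self.duration <= 0:
            raise InvalidConfigError("duration must be positive")
        if self.subject_sd < 0:
            raise InvalidConfigError("subject_sd must be >= 0")
        merged = dict(DEFAULT_EFFECT_SIZES)
        merged.update(self.effect_sizes)
        unknown = set(merged) - set(DEFAULT_EFFECT_SIZES)
        if unknown:
            raise InvalidConfigError(f"unknown effect keys: {sorted(unknown)}")
        for key in _GAIN_KEYS:
            if merged[key] <= 0:
                raise InvalidConfigError(f"effect gain {key} must be > 0")
        if merged["ear_lag_ms"] < 0:
            raise InvalidConfigError("ear_lag_ms must be >= 0")
        self.effect_sizes = merged

    def subject_ids(self) -> list:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


def _substream(seed: int, *keys: str) -> np.random.Generator:
    """Independent RNG substream keyed by strings; stable across processes."""
    entropy = [int(seed) & 0xFFFFFFFF] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Frequency-domain 1/f^exponent noise, unit RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.ones_like(freqs)
    nz = freqs >= 1.0  # flatten below 1 Hz: the band-pass removes it anyway
    amp[nz] = freqs[nz] ** (-exponent / 2.0)
    amp[~nz] = 1.0
    amp[0] = 0.0
    phases = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    x = np.fft.irfft(amp * phases, n=n)
    return x / x.std()


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple) -> np.ndarray:
    """Narrowband-filtered white noise, unit variance (not a pure sine, so
    spectral estimates on it have realistic variance)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _delay(x: np.ndarray, lag_samples: int) -> np.ndarray:
    if lag_samples <= 0:
        return x
    out = np.empty_like(x)
    out[:lag_samples] = x[0]
    out[lag_samples:] = x[:-lag_samples]
    return out


def _subject_gains(config: GeneratorConfig, subject_id: str) -> dict:
    """Log-normal per-subject amplitude factors, shared across conditions, so
    subject identity is a confound that subject-level CV must overcome."""
    rng = _substream(config.seed, subject_id, "subject_gains")
    names = list(SOURCE_AMPLITUDE_UV) + ["noise"]
    draws = rng.standard_normal(len(names))
    return {k: float(np.exp(config.subject_sd * d)) for k, d in zip(names, draws)}


def generate_subject_recording(
    config: GeneratorConfig, subject_id: str, condition: str
) -> Recording:
    """Generate one 8-channel recording for (subject, condition).

    Deterministic in (config.seed, subject_id, condition); the stress/relax
    pair for a subject differs by the configured effects plus independent
    noise draws.
    """
    if condition not in CONDITIONS:
        raise UnknownConditionError(f"condition {condition!r} not in {CONDITIONS}")
    eff = config.effect_sizes
    n = int(round(config.duration * config.fs_raw))
    fs = config.fs_raw
    sgain = _subject_gains(config, subject_id)
    stress = condition == "stress"

    # condition-dependent amplitude gains (multiplicative; draws untouched)
    gain = {k: 1.0 for k in SOURCE_AMPLITUDE_UV}
    if stress:
        gain["theta"] = eff["fm_theta_gain"]
        gain["alphaL"] = eff["alpha_gain"] * np.exp(-eff["faa_shift"] / 4.0)
        gain["alphaR"] = eff["alpha_gain"] * np.exp(+eff["faa_shift"] / 4.0)
        gain["beta"] = eff["cz_beta_gain"]
        gain["shared"] = eff["coherence_gain"]

    sources = {}
    for name, band in SOURCE_BANDS_HZ.items():
        if name == "ear_broadband":
            continue
        rng = _substream(config.seed, subject_id, condition, f"src:{name}")
        sources[name] = (
            _band_noise(rng, n, fs, band)
            * SOURCE_AMPLITUDE_UV[name]
            * sgain[name]
            * gain[name]
        )
    ear_bb = {}
    for side in ("L", "R"):
        rng = _substream(config.seed, subject_id, condition, f"src:ear_bb{side}")
        ear_bb[side] = (
            _band_noise(rng, n, fs, SOURCE_BANDS_HZ["ear_broadband"])
            * SOURCE_AMPLITUDE_UV["ear_broadband"]
            * sgain["ear_broadband"]
        )

    data = np.zeros((len(CHANNELS), n))
    for name, mix in SCALP_MIX.items():
        for ch, w in mix.items():
            data[CHANNELS.index(ch)] += w * sources[name]

    # hemispheric temporal mixtures, lagged into the preauricular channels
    lag_ms = eff["ear_lag_ms"] + (eff["ear_lag_shift_ms"] if stress else 0.0)
    lag = int(round(lag_ms * fs / 1000.0))
    for side, alpha_name in (("L", "alphaL"), ("R", "alphaR")):
        s = (
            EAR_MIX["theta"] * sources["theta"]
            + EAR_MIX["alpha"] * sources[alpha_name]
            + EAR_MIX["beta"] * sources["beta"]
            + EAR_MIX["shared"] * sources["shared"]
            + EAR_MIX["ear_broadband"] * ear_bb[side]
        )
        data[CHANNELS.index("ear" + side)] += _delay(s, lag)

    for i, ch in enumerate(CHANNELS):
        rng = _substream(config.seed, subject_id, condition, f"noise:{ch}")
        data[i] += NOISE_RMS_UV * sgain["noise"] * _pink_noise(
            rng, n, fs, config.noise_exponent
        )

    return Recording(
        data=data,
        fs=fs,
        channel_labels=CHANNELS,
        subject_id=subject_id,
        condition=condition,
    )


def generate_paired_dataset(config: GeneratorConfig, out_dir=None) -> list:
    """One stress and one relax recording per subject (2 x n_subjects total).

    If out_dir is given, recordings are written as delimited text with a
    tab-separated manifest (subject_id, condition, path, fs).
    """
    recordings = [
        generate_subject_recording(config, sid, cond)
        for sid in config.subject_ids()
        for cond in CONDITIONS
    ]
    if out_dir is not None:
        from .preprocess import write_dataset

        write_dataset(recordings, out_dir)
    return recordings
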