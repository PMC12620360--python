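"""Scalp-EEG stress markers and paradigm-validation statistics.

Seven canonical markers per 60-s resting segment: frontal alpha asymmetry
(FAA = ln alpha(AF8) - ln alpha(AF7)), alpha power at AF7 and AF8 (8-13 Hz),
beta power at Cz (14-30 Hz), the theta/beta ratio at Cz (4-7 / 14-30 Hz),
mean high-beta (23-36 Hz) magnitude-squared coherence over the AF7-C3,
AF8-C4 and Fpz-Cz pairs, and frontal-midline theta at Fpz (4-7 Hz).

The condition contrast (post-stressor vs. post-relaxation rest) is tested
per marker with a within-subject two-sided Wilcoxon signed-rank test plus
Rosenthal's r = |Z|/sqrt(n), and the seven p-values are corrected jointly
with the Benjamini-Hochberg step-up procedure at Q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, InvalidConfigError, MissingChannelError
from .preprocess import EpochSet, SCALP_CHANNELS

THETA_BAND = (4.0, 7.0)
ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (14.0, 30.0)
HIGH_BETA_BAND = (23.0, 36.0)
COHERENCE_PAIRS = (("AF7", "C3"), ("AF8", "C4"), ("Fpz", "Cz"))

MARKER_NAMES = (
    "FAA",
    "alpha_AF7",
    "alpha_AF8",
    "beta_Cz",
    "theta_beta_Cz",
    "high_beta_coh",
    "fm_theta_Fpz",
)

#: Welch segmentation: 2-s Hamming windows with 50% overlap (0.5 Hz
#: resolution, ~59 averaged segments on a 60-s epoch at 125 Hz).
WELCH_SEGMENT_SECONDS = 2.0


def _welch_kwargs(fs: float) -> dict:
    nperseg = int(round(WELCH_SEGMENT_SECONDS * fs))
    return dict(fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2)


def welch_band_power(x, band, fs: float = 125.0) -> float:
    """Band power in uV^2: trapezoidal integral of the Welch PSD over the
    closed interval [low, high]."""
    low, high = band
    if not 0 < low < high < fs / 2:
        raise InvalidConfigError(f"band {band} outside (0, fs/2) at fs={fs}")
    x = np.asarray(x, dtype=np.float64)
    kw = _welch_kwargs(fs)
    if len(x) < kw["nperseg"]:
        raise InvalidConfigError("signal shorter than one Welch segment")
    freqs, psd = signal.welch(x, **kw)
    mask = (freqs >= low) & (freqs <= high)
    return float(np.trapezoid(psd[mask], freqs[mask]))


def band_coherence(x, y, band, fs: float = 125.0) -> float:
    """Magnitude-squared coherence averaged over bins with center frequency
    in the closed band, using the same Welch segmentation as the powers."""
    low, high = band
    freqs, coh = signal.coherence(np.asarray(x, float), np.asarray(y, float),
                                  **_welch_kwargs(fs))
    mask = (freqs >= low) & (freqs <= high)
    return float(np.mean(coh[mask]))


def marker_row(scalp: np.ndarray, fs: float, channel_order=SCALP_CHANNELS) -> dict:
    """The seven markers from one (6 x samples) scalp array."""
    idx = {c: i for i, c in enumerate(channel_order)}
    for c in SCALP_CHANNELS:
        if c not in idx:
            raise MissingChannelError(c)

    def power(ch, band):
        return welch_band_power(scalp[idx[ch]], band, fs)

    a7 = power("AF7", ALPHA_BAND)
    a8 = power("AF8", ALPHA_BAND)
    if a7 <= 0 or a8 <= 0:
        raise DegenerateDataError("zero alpha power: FAA undefined")
    beta = power("Cz", BETA_BAND)
    theta_cz = power("Cz", THETA_BAND)
    coh = np.mean(
        [band_coherence(scalp[idx[a]], scalp[idx[b]], HIGH_BETA_BAND, fs)
         for a, b in COHERENCE_PAIRS]
    )
    return {
        "FAA": float(np.log(a8) - np.log(a7)),
        "alpha_AF7": a7,
        "alpha_AF8": a8,
        "beta_Cz": beta,
        "theta_beta_Cz": theta_cz / beta,
        "high_beta_coh": float(coh),
        "fm_theta_Fpz": power("Fpz", THETA_BAND),
    }


def compute_markers(epochs: EpochSet) -> pd.DataFrame:
    """Marker table: one row per epoch, indexed by (subject_id, condition)."""
    if epochs.scalp is None:
        raise MissingChannelError("epoch set carries no scalp channels")
    rows, index = [], []
    for i in range(len(epochs)):
        rows.append(marker_row(epochs.scalp[i], epochs.fs, epochs.scalp_labels))
        index.append(
            (epochs.subject_ids[i], "stress" if epochs.labels[i] == 1 else "relax")
        )
    table = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["subject_id", "condition"])
    )
    return table[list(MARKER_NAMES)]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class PairedTestResult:
    feature: str
    p: float
    q: float
    z: float
    r: float
    n: int
    significant: bool


def _exact_sf_counts(ranks: np.ndarray) -> np.ndarray:
    """Null distribution of W+ over all 2^n sign assignments (integer ranks),
    by dynamic programming; returns counts indexed by W+."""
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(stress, relax=None):
    """Two-sided Wilcoxon signed-rank test on paired values.

    Accepts either paired arrays or (when relax is None) precomputed
    differences.  Zero differences are dropped (Wilcoxon convention).  For
    n <= 25 without ties the exact permutation distribution of W+ is used;
    otherwise a normal approximation with continuity and tie correction.
    Returns (p, z, r) where z is the signed standardized statistic and
    r = |z|/sqrt(n) with n the original pair count (Rosenthal's r).
    """
    d = np.asarray(stress, dtype=np.float64)
    if relax is not None:
        d = d - np.asarray(relax, dtype=np.float64)
    n_pairs = len(d)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    ties = np.unique(ranks, return_counts=True)[1]
    has_ties = np.any(ties > 1)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((ties**3 - ties).sum()) / 48.0
    if var <= 0:
        raise DegenerateDataError("zero variance in signed ranks")
    cc = 0.5 * np.sign(w_plus - mu)  # continuity correction toward the mean
    z = 0.0 if w_plus == mu else (w_plus - mu - cc) / np.sqrt(var)

    if n <= 25 and not has_ties:
        counts = _exact_sf_counts(ranks)
        total = counts.sum()
        w = int(round(w_plus))
        p_low = counts[: w + 1].sum() / total
        p_high = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    r = abs(z) / np.sqrt(n_pairs)
    return float(p), float(z), float(r)


def bh_fdr_adjust(pvals, Q: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted q-values, rejection flags, and k
    (the number of rejected hypotheses)."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.ndim != 1 or len(p) == 0:
        raise InvalidConfigError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidConfigError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=Q, method="fdr_bh")
    return qvals, reject, int(reject.sum())


def validate_paradigm(markers: pd.DataFrame, Q: float = 0.05) -> list:
    """Per-marker paired Wilcoxon (stress vs. relax) with joint BH correction.

    markers is a compute_markers table; every subject must have both
    conditions.  Markers whose differences are all zero are reported as
    'no difference' (p = 1, z = 0) rather than erroring the whole report.
    """
    wide = markers.unstack("condition")
    results = []
    for name in MARKER_NAMES:
        sub = wide[name]
        if sub[["stress", "relax"]].isna().any().any():
            missing = sub.index[sub.isna().any(axis=1)].tolist()
            raise DegenerateDataError(
                f"unpaired subject(s) for marker {name}: {missing}"
            )
        n = len(sub)
        try:
            p, z, r = wilcoxon_signed_rank(sub["stress"].values, sub["relax"].values)
        except DegenerateDataError:
            p, z, r = 1.0, 0.0, 0.0
        results.append(PairedTestResult(name, p, 1.0, z, r, n, False))
    qvals, reject, _ = bh_fdr_adjust([t.p for t in results], Q=Q)
    for t, q, rej in zip(results, qvals, reject):
        t.q = float(q)
        t.significant = bool(rej)
    return results


def results_to_frame(results) -> pd.DataFrame:
    """TSV-ready report; q-values rounded to 4 decimals in the report only."""
    return pd.DataFrame(
        {
            "feature": [t.feature for t in results],
            "p": [round(t.p, 6) for t in results],
            "q": [round(t.q, 4) for t in results],
            "z": [round(t.z, 3) for t in results],
            "r": [round(t.r, 3) for t in results],
            "n": [t.n for t in results],
            "significant": [t.significant for t in results],
        }
    )


def write_validation_report(results, path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
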