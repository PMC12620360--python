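"""Explainability analyses for the cross-attention classifier.

Two attention summaries per direction (left->right, right->left):

* row-wise entropy: rows of a T' x T' attention map are renormalized to
  P_ij = A_ij / sum_j A_ij and scored by H_i = -sum_j P_ij log P_ij (natural
  log; 0 log 0 := 0).  Low values mean concentrated attention, high values
  uniform spread, with max ln T'.
* directional asymmetry: ||A - A^T||_F / ||A||_F, zero for a symmetric map
  and bounded by 2.

Temporal occlusion slides a zero-baseline window (default 0.5 s, step 0.1 s)
over both input channels and records the class-logit drop
delta_logit_c(t) = logit_c(x) - logit_c(x_occ(t)); positive values mark
segments supporting class c.  Deltas are summarized per fold as label-wise
means and stress-minus-relax differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidConfigError, UnsupportedVariantError
from .model import DIRECTIONS, DeepAttNet


def capture_attention(model: DeepAttNet, epochs: np.ndarray) -> dict:
    """Evaluation-mode attention maps for a (batch, 2, samples) array.

    Returns {direction: (batch, T', T') row-stochastic maps}."""
    if not getattr(model, "has_cross_attention", False):
        raise UnsupportedVariantError(
            f"variant {model.config.variant!r} has no cross-attention maps"
        )
    epochs = np.asarray(epochs)
    if epochs.ndim == 2:
        epochs = epochs[None]
    maps = {d: [] for d in DIRECTIONS}
    for i in range(0, len(epochs), 64):
        model.forward(epochs[i:i + 64], training=False)
        for d in DIRECTIONS:
            maps[d].append(model.last_attention[d].astype(np.float64))
    return {d: np.concatenate(v, axis=0) for d, v in maps.items()}


def row_entropy(attention_map, normalized: bool = False):
    """Per-row natural-log entropy of a nonnegative map after row
    renormalization, and the mean over rows.

    normalized=True divides by ln T' to give values in [0, 1]."""
    A = np.asarray(attention_map, dtype=np.float64)
    if A.ndim != 2:
        raise InvalidConfigError("attention map must be 2-D")
    if np.any(A < 0):
        raise InvalidConfigError("attention map must be nonnegative")
    sums = A.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise DegenerateDataError("attention map has an all-zero row")
    P = A / sums
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    H = -terms.sum(axis=1)
    if normalized:
        H = H / np.log(A.shape[1])
    return H, float(H.mean())


def directional_asymmetry(attention_map) -> float:
    """||A - A^T||_F / ||A||_F: 0 for symmetric maps, at most 2."""
    A = np.asarray(attention_map, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidConfigError("attention map must be square")
    denom = np.linalg.norm(A)
    if denom == 0:
        raise DegenerateDataError("all-zero attention map")
    return float(np.linalg.norm(A - A.T) / denom)


def attention_summaries(model: DeepAttNet, epochs, labels, fold_id: int = 0
                        ) -> pd.DataFrame:
    """Per-sample entropy/asymmetry rows for both directions."""
    maps = capture_attention(model, epochs)
    labels = np.asarray(labels)
    rows = []
    for d in DIRECTIONS:
        for i, amap in enumerate(maps[d]):
            _, mean_h = row_entropy(amap)
            rows.append({
                "fold_id": fold_id,
                "direction": d,
                "label": "stress" if labels[i] == 1 else "relax",
                "mean_row_entropy": mean_h,
                "asymmetry": directional_asymmetry(amap),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Temporal occlusion
# ---------------------------------------------------------------------------

@dataclass
class OcclusionProfile:
    """Delta-logit curve of a sliding zero-baseline occlusion."""

    window_s: float
    step_s: float
    times_s: np.ndarray  # window-center times
    delta_logit: np.ndarray
    class_index: int
    peak_time_s: float = field(default=0.0)
    positive_area: float = field(default=0.0)
    negative_area: float = field(default=0.0)
    label: str = ""
    fold_id: int = 0

    def __post_init__(self):
        self.delta_logit = np.asarray(self.delta_logit, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.peak_time_s = float(self.times_s[int(np.argmax(self.delta_logit))])
        self.positive_area = float(self.delta_logit[self.delta_logit > 0].sum())
        self.negative_area = float(self.delta_logit[self.delta_logit < 0].sum())


def _logit_fn(model):
    if callable(model):
        return model
    return model.predict_logits


def temporal_occlusion(model, epoch, class_index: int = 1,
                       window_s: float = 0.5, step_s: float = 0.1,
                       fs: float = 125.0, label: str = "", fold_id: int = 0,
                       batch_size: int = 64) -> OcclusionProfile:
    """Zero-baseline sliding-window occlusion of one (2 x samples) epoch.

    Both channels are zeroed within each window; windows that would overlap
    the epoch edge are dropped.  model may be a DeepAttNet or any callable
    mapping (batch, 2, samples) -> (batch, n_classes) logits."""
    if window_s <= 0 or step_s <= 0:
        raise InvalidConfigError("window_s and step_s must be positive")
    epoch = np.asarray(epoch, dtype=np.float32)
    if epoch.ndim != 2:
        raise InvalidConfigError("epoch must be (channels x samples)")
    n = epoch.shape[1]
    w = int(np.floor(window_s * fs))
    step = int(np.floor(step_s * fs))
    if w >= n:
        raise InvalidConfigError("occlusion window longer than the epoch")
    starts = np.arange(0, n - w + 1, step)
    logit_fn = _logit_fn(model)
    base = float(np.asarray(logit_fn(epoch[None]))[0, class_index])
    deltas = np.empty(len(starts))
    for i0 in range(0, len(starts), batch_size):
        chunk = starts[i0:i0 + batch_size]
        occluded = np.repeat(epoch[None], len(chunk), axis=0)
        for j, s in enumerate(chunk):
            occluded[j, :, s:s + w] = 0.0
        deltas[i0:i0 + len(chunk)] = base - np.asarray(
            logit_fn(occluded)
        )[:, class_index]
    return OcclusionProfile(
        window_s=window_s, step_s=step_s,
        times_s=(starts + w / 2.0) / fs, delta_logit=deltas,
        class_index=class_index, label=label, fold_id=fold_id,
    )


def occlusion_summaries(model, epochs, labels, fold_id: int = 0,
                        class_index: int = 1, **kwargs) -> pd.DataFrame:
    labels = np.asarray(labels)
    rows = []
    for i in range(len(epochs)):
        prof = temporal_occlusion(model, epochs[i], class_index=class_index,
                                  fold_id=fold_id, **kwargs)
        rows.append({
            "fold_id": fold_id,
            "label": "stress" if labels[i] == 1 else "relax",
            "mean_delta_logit": float(prof.delta_logit.mean()),
            "peak_time_s": prof.peak_time_s,
            "positive_area": prof.positive_area,
            "negative_area": prof.negative_area,
        })
    return pd.DataFrame(rows)


def delta_summaries(sample_table: pd.DataFrame, value_columns=None,
                    group_columns=("fold_id",)) -> pd.DataFrame:
    """Per-fold stress-minus-relax deltas of per-sample summary statistics.

    Samples are averaged within label per group first, then differenced
    (stress - relax), then a final row averages the deltas across folds.
    Negative entropy deltas mean more concentrated attention under stress.
    """
    df = sample_table.copy()
    if "direction" in df.columns and "direction" not in group_columns:
        group_columns = tuple(group_columns) + ("direction",)
    if value_columns is None:
        value_columns = [c for c in df.columns
                         if c not in group_columns and c != "label"
                         and np.issubdtype(df[c].dtype, np.number)]
    for gcols, sub in [(list(group_columns), df)]:
        counts = sub.groupby(gcols)["label"].nunique()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise DegenerateDataError(
                f"group(s) {bad} contain a single label; deltas undefined"
            )
    means = df.groupby(list(group_columns) + ["label"])[list(value_columns)].mean()
    stress = means.xs("stress", level="label")
    relax = means.xs("relax", level="label")
    deltas = (stress - relax).reset_index()
    deltas.columns = list(deltas.columns[: len(group_columns)]) + [
        f"delta_{c}" for c in value_columns
    ]
    mean_row = deltas.drop(columns=list(group_columns)).mean()
    summary_cols = [c for c in deltas.columns if c.startswith("delta_")]
    out = deltas.copy()
    if "direction" in out.columns:
        across = out.groupby("direction")[summary_cols].mean().reset_index()
        across.insert(0, "fold_id", "mean")
        out = pd.concat([out, across], ignore_index=True)
    else:
        out.loc[len(out)] = {"fold_id": "mean", **mean_row.to_dict()}
    return out
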