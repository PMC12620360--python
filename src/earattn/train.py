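"""Subject-independent training and evaluation protocol.

Eight-fold subject-level cross-validation: in each fold the epochs of four
held-out subjects form the test set and the remaining subjects are split
6:1 (by subject, preserving subject independence of early stopping) into
training and validation sets.  Training uses AdamW (lr 1e-3 constant,
betas (0.9, 0.999), eps 1e-8), cross-entropy on logits, mini-batches of 16
(validation 8, test full), up to 200 epochs with early stopping after 30
epochs without strict validation-loss improvement; the best-validation
parameters are restored.  Fold performance is accuracy and macro F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from . import nn
from .errors import DegenerateDataError, InvalidConfigError
from .markers import PairedTestResult, bh_fdr_adjust, wilcoxon_signed_rank
from .model import ModelConfig, build_variant
from .preprocess import EpochSet


@dataclass
class FoldSpec:
    fold_id: int
    test_subjects: list
    train_subjects: list
    val_subjects: list

    def __post_init__(self):
        roles = self.test_subjects + self.train_subjects + self.val_subjects
        if len(set(roles)) != len(roles):
            raise InvalidConfigError(
                f"fold {self.fold_id}: a subject appears in two roles"
            )


@dataclass
class TrainConfig:
    lr: float = 1e-3
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.01
    batch_size: int = 16
    val_batch_size: int = 8
    max_epochs: int = 200
    patience: int = 30
    seed: int = 42

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise InvalidConfigError("patience must be < max_epochs")
        if self.batch_size < 1 or self.val_batch_size < 1:
            raise InvalidConfigError("batch sizes must be >= 1")


@dataclass
class FoldMetrics:
    fold_id: int
    accuracy: float
    macro_f1: float
    precision: tuple  # per class (relax, stress)
    recall: tuple
    epochs_trained: int = 0


def make_subject_folds(subject_ids, k: int = 8, seed: int = 42) -> list:
    """Shuffle subjects once with the root seed, partition into k disjoint
    test groups, and split each fold's remainder 6:1 by subject into
    train/val."""
    subjects = sorted(set(subject_ids))
    if k > len(subjects):
        raise InvalidConfigError(f"k={k} exceeds {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    test_groups = [list(g) for g in np.array_split(np.array(order), k)]
    folds = []
    for fold_id, test in enumerate(test_groups):
        remaining = [s for s in order if s not in set(test)]
        fold_rng = np.random.default_rng(np.random.SeedSequence([seed, fold_id]))
        remaining = [remaining[i] for i in fold_rng.permutation(len(remaining))]
        n_val = max(1, int(round(len(remaining) / 7)))
        folds.append(FoldSpec(
            fold_id=fold_id,
            test_subjects=list(test),
            val_subjects=remaining[:n_val],
            train_subjects=remaining[n_val:],
        ))
    return folds


def _loss_on(model, X, y, batch_size: int) -> float:
    losses, weights = [], []
    for i in range(0, len(X), batch_size):
        logits = model.forward(X[i:i + batch_size], training=False)
        loss, _ = nn.cross_entropy(logits, y[i:i + batch_size])
        losses.append(loss)
        weights.append(len(logits))
    return float(np.average(losses, weights=weights))


def train_fold(model, fold: FoldSpec, epochs: EpochSet, cfg: TrainConfig):
    """Train one fold's model; returns (model, history).

    history carries per-epoch train/val losses, the stopping epoch, and an
    audit trail of the subject ids that contributed to each training batch.
    """
    tr_idx = epochs.indices_for_subjects(fold.train_subjects)
    va_idx = epochs.indices_for_subjects(fold.val_subjects)
    if len(tr_idx) == 0 or len(va_idx) == 0:
        raise InvalidConfigError(
            f"fold {fold.fold_id}: empty train or validation set"
        )
    X_tr = epochs.ear[tr_idx].astype(nn.DTYPE)
    y_tr = epochs.labels[tr_idx]
    tr_subjects = [epochs.subject_ids[i] for i in tr_idx]
    X_va = epochs.ear[va_idx].astype(nn.DTYPE)
    y_va = epochs.labels[va_idx]

    opt = nn.AdamW(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                   eps=cfg.eps, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, fold.fold_id, 2]))
    history = {"train_loss": [], "val_loss": [], "batch_subjects": []}
    best_val = np.inf
    best_state = model.get_state()
    best_epoch = 0
    since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X_tr))
        epoch_losses, epoch_weights = [], []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            logits = model.forward(X_tr[sel], training=True)
            loss, dlogits = nn.cross_entropy(logits, y_tr[sel])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)
            epoch_weights.append(len(sel))
            history["batch_subjects"].append(sorted({tr_subjects[i] for i in sel}))
        history["train_loss"].append(
            float(np.average(epoch_losses, weights=epoch_weights))
        )
        val_loss = _loss_on(model, X_va, y_va, cfg.val_batch_size)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:  # strict improvement by any margin
            best_val = val_loss
            best_state = model.get_state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.set_state(best_state)
    history["best_epoch"] = best_epoch
    history["epochs_trained"] = len(history["train_loss"])
    return model, history


def evaluate_fold(model, test_epochs: EpochSet, fold_id: int = 0,
                  epochs_trained: int = 0) -> FoldMetrics:
    """Single full-batch evaluation pass: accuracy and macro F1."""
    if len(test_epochs) == 0:
        raise InvalidConfigError("empty test set")
    logits = model.predict_logits(test_epochs.ear.astype(nn.DTYPE),
                                  batch_size=len(test_epochs))
    pred = logits.argmax(axis=1)
    return metrics_from_predictions(test_epochs.labels, pred, fold_id,
                                    epochs_trained)


def metrics_from_predictions(y_true, y_pred, fold_id: int = 0,
                             epochs_trained: int = 0) -> FoldMetrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0
    )
    return FoldMetrics(
        fold_id=fold_id,
        accuracy=float((y_true == y_pred).mean()),
        macro_f1=float(f1.mean()),
        precision=tuple(float(p) for p in prec),
        recall=tuple(float(r) for r in rec),
        epochs_trained=epochs_trained,
    )


def run_cross_validation(
    epochs: EpochSet,
    model_config: ModelConfig = None,
    train_config: TrainConfig = None,
    k: int = 8,
    variant: str = None,
    model_factory=None,
):
    """Train and evaluate one model per fold.

    model_factory(fold_seed) overrides the default builder (which constructs
    model_config's variant, or the named variant, per fold).  Returns
    (list of FoldMetrics, summary DataFrame with mean and sd per metric).
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    if variant is not None:
        model_config = ModelConfig(**{**model_config.__dict__, "variant": variant})
    folds = make_subject_folds(set(epochs.subject_ids), k=k,
                               seed=train_config.seed)
    per_fold = []
    for fold in folds:
        fold_seed = int(
            np.random.SeedSequence(
                [train_config.seed, fold.fold_id]
            ).generate_state(1)[0] % (2**31)
        )
        if model_factory is not None:
            model = model_factory(fold_seed)
        else:
            model = build_variant(model_config, model_config.variant, seed=fold_seed)
        model, history = train_fold(model, fold, epochs, train_config)
        test = epochs.subset(epochs.indices_for_subjects(fold.test_subjects))
        per_fold.append(
            evaluate_fold(model, test, fold.fold_id, history["epochs_trained"])
        )
    summary = summarize_metrics(per_fold)
    return per_fold, summary


def summarize_metrics(per_fold) -> pd.DataFrame:
    acc = np.array([m.accuracy for m in per_fold])
    f1 = np.array([m.macro_f1 for m in per_fold])
    return pd.DataFrame(
        {
            "metric": ["accuracy", "macro_f1"],
            "mean": [acc.mean(), f1.mean()],
            "sd": [acc.std(ddof=1), f1.std(ddof=1)],
            "n_folds": [len(per_fold)] * 2,
        }
    )


def compare_models(fold_metrics: dict, reference: str, Q: float = 0.05) -> list:
    """Paired Wilcoxon of each model's per-fold metric against a reference,
    BH-corrected across the comparisons.

    fold_metrics maps model name -> per-fold metric values on identical
    folds.  Identical metric vectors (degenerate Wilcoxon input) are
    surfaced as 'no difference' (p = 1, z = 0)."""
    ref = np.asarray(fold_metrics[reference], dtype=float)
    results = []
    for name, values in fold_metrics.items():
        if name == reference:
            continue
        values = np.asarray(values, dtype=float)
        if len(values) != len(ref):
            raise InvalidConfigError(
                f"{name}: fold count {len(values)} != reference {len(ref)}"
            )
        try:
            p, z, r = wilcoxon_signed_rank(ref, values)
        except DegenerateDataError:
            p, z, r = 1.0, 0.0, 0.0
        results.append(PairedTestResult(
            feature=f"{reference}_vs_{name}", p=p, q=1.0, z=z, r=r,
            n=len(ref), significant=False,
        ))
    if results:
        qvals, reject, _ = bh_fdr_adjust([t.p for t in results], Q=Q)
        for t, q, rej in zip(results, qvals, reject):
            t.q = float(q)
            t.significant = bool(rej)
    return results
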