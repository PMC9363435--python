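"""Two-stage random-forest ensemble for maternal deletion genotype calling.

Stage 1 is a binary forest separating normal (aa/aa) from abnormal coverage
profiles; it is trained on a class-balanced set obtained by down-sampling
the normal majority to the abnormal count, so that rare deletion signatures
are not swamped.  Stage 2 is a four-class forest (aa_SEA, aa_3.7, aa_4.2,
Others) trained on the truth-labelled abnormal subset of the original
(un-rebalanced) training data.  At prediction time a sample called normal by
stage 1 is labelled aa_aa and never reaches stage 2; otherwise its label is
the stage-2 argmax.  Features are the per-bin TPM values; the validation
split is held out for logged model selection only and the test split is
never touched during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score

from .counts import CountProfile
from .regions import CLASS_LABELS

__all__ = [
    "SplitSpec",
    "Hyperparameters",
    "EnsembleModel",
    "split_dataset",
    "rebalance_training",
    "train_ensemble",
    "predict",
    "save_model",
    "load_model",
]

NORMAL_LABEL = "aa_aa"
ABNORMAL_LABELS = tuple(l for l in CLASS_LABELS if l != NORMAL_LABEL)

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validate/test proportions."""

    train: float = 0.6
    validate: float = 0.2
    test: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        props = (self.train, self.validate, self.test)
        if any(p <= 0 for p in props):
            raise ValueError("split proportions must be positive")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"split proportions sum to {sum(props)}, not 1")


@dataclass(frozen=True)
class Hyperparameters:
    n_trees: int = 500
    max_features: str | float = "sqrt"
    min_samples_leaf: int = 1
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_trees <= 10_000:
            raise ValueError("n_trees must be in [1, 10000]")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")


@dataclass
class EnsembleModel:
    stage1: RandomForestClassifier
    stage2: RandomForestClassifier
    n_features: int
    normalization: str  # feature schema flag; "tpm" in the standard pipeline
    hyperparameters: Hyperparameters
    seed: int
    training_meta: dict = field(default_factory=dict)


def split_dataset(
    X: np.ndarray,
    labels: Sequence[str],
    spec: SplitSpec,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Stratified, seed-reproducible train/validate/test partition.

    Stratification is per class label so validation and test sets keep the
    population prevalence of each class.  Returns ((X, y) for each split).
    Every class must have at least 3 members (one per split).
    """
    X = np.asarray(X)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("labels not aligned to matrix rows")
    rng = np.random.default_rng(spec.seed)
    idx_train, idx_val, idx_test = [], [], []
    for cls in sorted(set(labels.tolist())):
        cls_idx = np.flatnonzero(labels == cls)
        if cls_idx.size < 3:
            raise ValueError(
                f"class {cls!r} has only {cls_idx.size} samples; need >= 3"
            )
        cls_idx = rng.permutation(cls_idx)
        n = cls_idx.size
        n_val = max(1, round(spec.validate * n))
        n_test = max(1, round(spec.test * n))
        if n_val + n_test >= n:  # keep at least one training sample
            n_val = n_test = max(1, (n - 1) // 2)
        idx_test.append(cls_idx[:n_test])
        idx_val.append(cls_idx[n_test : n_test + n_val])
        idx_train.append(cls_idx[n_test + n_val :])
    parts = []
    for chunks in (idx_train, idx_val, idx_test):
        idx = np.sort(np.concatenate(chunks))
        parts.append((X[idx], labels[idx]))
    return tuple(parts)  # type: ignore[return-value]


def rebalance_training(
    X: np.ndarray, labels: Sequence[str], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Down-sample the normal majority class to the abnormal count.

    Abnormal samples are all retained with their subclass labels intact;
    normal samples are drawn without replacement.  Returns the balanced
    (X, labels) with five-class labels preserved.
    """
    X = np.asarray(X)
    labels = np.asarray(labels)
    normal_idx = np.flatnonzero(labels == NORMAL_LABEL)
    abnormal_idx = np.flatnonzero(labels != NORMAL_LABEL)
    if abnormal_idx.size == 0:
        raise ValueError("no abnormal samples to balance against")
    rng = np.random.default_rng(seed)
    n_keep = min(normal_idx.size, abnormal_idx.size)
    kept_normal = rng.choice(normal_idx, size=n_keep, replace=False)
    idx = np.sort(np.concatenate([kept_normal, abnormal_idx]))
    return X[idx], labels[idx]


def _forest(hp: Hyperparameters, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=hp.n_trees,
        max_features=hp.max_features,
        min_samples_leaf=hp.min_samples_leaf,
        max_depth=hp.max_depth,
        random_state=seed,
        n_jobs=1,
    )


def train_ensemble(
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_val: np.ndarray,
    y_val: Sequence[str],
    hyperparameters: Hyperparameters | None = None,
    seed: int = 0,
    normalization: str = "tpm",
) -> EnsembleModel:
    """Fit both stages; all randomness is governed by ``seed``.

    Stage 1 is fit on the rebalanced binary-relabelled training set; stage 2
    on the truth-labelled abnormal subset of the *original* training set.
    Validation macro-F1 of both stages is recorded in ``training_meta``.
    """
    hp = hyperparameters or Hyperparameters()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    missing = set(CLASS_LABELS) - set(y_train.tolist())
    if missing:
        raise ValueError(f"training set lacks classes: {sorted(missing)}")

    Xb, yb = rebalance_training(X_train, y_train, seed=seed)
    y_binary = np.where(yb == NORMAL_LABEL, "normal", "abnormal")
    stage1 = _forest(hp, seed).fit(Xb, y_binary)

    abn = y_train != NORMAL_LABEL
    stage2 = _forest(hp, seed + 1).fit(X_train[abn], y_train[abn])

    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val)
    val_binary_true = np.where(y_val == NORMAL_LABEL, "normal", "abnormal")
    val_binary_pred = stage1.predict(X_val)
    val_abn = y_val != NORMAL_LABEL
    meta = {
        "class_counts_before": {c: int((y_train == c).sum()) for c in CLASS_LABELS},
        "class_counts_rebalanced": {c: int((yb == c).sum()) for c in CLASS_LABELS},
        "val_stage1_macro_f1": float(
            f1_score(val_binary_true, val_binary_pred, average="macro")
        ),
        "val_stage2_macro_f1": float(
            f1_score(
                y_val[val_abn], stage2.predict(X_val[val_abn]), average="macro"
            )
        )
        if val_abn.any()
        else float("nan"),
        "seed": seed,
    }
    return EnsembleModel(
        stage1=stage1,
        stage2=stage2,
        n_features=X_train.shape[1],
        normalization=normalization,
        hyperparameters=hp,
        seed=seed,
        training_meta=meta,
    )


def _as_matrix(model: EnsembleModel, profiles) -> tuple[np.ndarray, list[str]]:
    if isinstance(profiles, np.ndarray):
        X = profiles
        ids = [str(i) for i in range(X.shape[0])]
    else:
        profs = list(profiles)
        if profs and isinstance(profs[0], CountProfile):
            X = np.stack([p.tpm for p in profs])
            ids = [p.sample_id for p in profs]
        else:
            X = np.asarray(profs, dtype=float)
            ids = [str(i) for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature schema mismatch: model expects {model.n_features} "
            f"features, got {X.shape[-1] if X.ndim else 0}"
        )
    return X, ids


def predict(model: EnsembleModel, profiles) -> pd.DataFrame:
    """Predict class labels with per-stage scores for audit.

    A sample whose stage-1 abnormal probability is <= 0.5 is labelled
    aa_aa and never reaches stage 2.  Returns a DataFrame with sample_id,
    predicted_label, stage1_score (P(abnormal)) and one stage2_p_<class>
    column per abnormal class.
    """
    X, ids = _as_matrix(model, profiles)
    abn_col = list(model.stage1.classes_).index("abnormal")
    p_abnormal = model.stage1.predict_proba(X)[:, abn_col]
    is_abnormal = p_abnormal > 0.5

    labels = np.full(X.shape[0], NORMAL_LABEL, dtype=object)
    stage2_proba = np.full((X.shape[0], len(model.stage2.classes_)), np.nan)
    if is_abnormal.any():
        proba = model.stage2.predict_proba(X[is_abnormal])
        stage2_proba[is_abnormal] = proba
        labels[is_abnormal] = model.stage2.classes_[np.argmax(proba, axis=1)]

    out = pd.DataFrame({"sample_id": ids, "predicted_label": labels})
    out["stage1_score"] = p_abnormal
    for j, cls in enumerate(model.stage2.classes_):
        out[f"stage2_p_{cls}"] = stage2_proba[:, j]
    return out


def save_model(model: EnsembleModel, path) -> None:
    """Persist the ensemble with its feature schema and metadata."""
    joblib.dump(
        {
            "format_version": _FORMAT_VERSION,
            "stage1": model.stage1,
            "stage2": model.stage2,
            "n_features": model.n_features,
            "normalization": model.normalization,
            "hyperparameters": asdict(model.hyperparameters),
            "seed": model.seed,
            "training_meta": model.training_meta,
        },
        path,
    )


def load_model(path) -> EnsembleModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path}: not a thalascreen model file")
    if payload["format_version"] != _FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {payload['format_version']} "
            f"!= supported {_FORMAT_VERSION}"
        )
    return EnsembleModel(
        stage1=payload["stage1"],
        stage2=payload["stage2"],
        n_features=payload["n_features"],
        normalization=payload["normalization"],
        hyperparameters=Hyperparameters(**payload["hyperparameters"]),
        seed=payload["seed"],
        training_meta=payload["training_meta"],
    )
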