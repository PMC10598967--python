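"""Two-layer stacking: out-of-fold base probabilities, concatenated with the
flattened one-hot features, train a logistic-regression meta-learner.

The out-of-fold (OOF) matrix is built with stratified K-fold splitting so no
base model ever scores a sample it trained on; the per-sample fold ids and
per-fold training indices are kept for the leakage audit.  For deployment
the three base models are refit on the full training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from . import base_models as bm
from .base_models import BaseModelSpec, TrainConfig, TrainedBaseModel

__all__ = [
    "OofMatrix", "StackedEnsemble",
    "oof_predictions", "assemble_meta_features", "fit_meta",
    "fit_stacked_ensemble", "predict_ensemble",
    "save_ensemble", "load_ensemble", "default_specs",
]


def default_specs(input_shape=(41, 4),
                  architectures: Sequence[str] = ("densenet_senet",
                                                  "dcnn_bilstm",
                                                  "msrn_bigru"),
                  hyperparameters: dict | None = None) -> list[BaseModelSpec]:
    hp = hyperparameters or {}
    return [BaseModelSpec(a, hyperparameters=hp.get(a, {}),
                          input_shape=input_shape)
            for a in architectures]


@dataclass
class OofMatrix:
    values: np.ndarray                  # (n, n_architectures)
    fold_assignment: np.ndarray         # (n,) fold id per sample
    train_indices: list[np.ndarray]     # per-fold training index sets (audit)

    def leakage_audit(self) -> bool:
        """True iff no sample's fold intersects its own OOF training set."""
        for fold, idx in enumerate(self.train_indices):
            members = np.flatnonzero(self.fold_assignment == fold)
            if np.intersect1d(members, idx).size:
                return False
        return True


def _default_trainer(spec: BaseModelSpec, X: np.ndarray, y: np.ndarray,
                     config: TrainConfig, seed: int):
    model = bm.build_model(spec, seed=seed, dropout_rate=config.dropout_rate)
    cfg = TrainConfig(**{**vars(config), "seed": seed})
    return bm.train_base_model(model, X, y, cfg)


def oof_predictions(specs: Sequence[BaseModelSpec], X: np.ndarray,
                    y: np.ndarray, k_folds: int = 5,
                    config: TrainConfig | None = None, seed: int = 0,
                    trainer: Callable | None = None) -> OofMatrix:
    """Out-of-fold probability matrix, one column per architecture.

    ``trainer(spec, X_train, y_train, config, seed)`` must return an object
    accepted by :func:`m6amstack.base_models.predict_proba`; the default
    trains the real model.  Injectable so the plumbing can be validated with
    label-oracle stubs.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    config = config or TrainConfig()
    trainer = trainer or _default_trainer
    y = np.asarray(y)
    n = len(y)
    values = np.full((n, len(specs)), np.nan)
    fold_assignment = np.full(n, -1, dtype=int)
    train_indices: list[np.ndarray] = []

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_assignment[te] = fold
        train_indices.append(tr.copy())
        for j, spec in enumerate(specs):
            fitted = trainer(spec, X[tr], y[tr], config,
                             seed + 1000 * fold + j)
            values[te, j] = bm.predict_proba(fitted, X[te])
    assert not np.isnan(values).any(), "OOF matrix has uncovered samples"
    return OofMatrix(values=values, fold_assignment=fold_assignment,
                     train_indices=train_indices)


def assemble_meta_features(oof_values: np.ndarray | OofMatrix,
                           X_flat: np.ndarray) -> np.ndarray:
    """[base probabilities | flattened original features], row-aligned."""
    values = oof_values.values if isinstance(oof_values, OofMatrix) else oof_values
    X_flat = np.asarray(X_flat)
    if X_flat.ndim == 1:
        X_flat = X_flat.reshape(len(values), -1)
    if len(values) != len(X_flat):
        raise ValueError(
            f"row mismatch: {len(values)} probabilities vs {len(X_flat)} feature rows")
    return np.concatenate([values, X_flat], axis=1)


def fit_meta(meta_features: np.ndarray, y: np.ndarray,
             regularization: float = 1.0) -> LogisticRegression:
    """L2-penalized logistic regression (C = `regularization`)."""
    if len(np.unique(y)) < 2:
        raise ValueError("meta training requires both classes")
    clf = LogisticRegression(C=regularization, max_iter=2000, solver="lbfgs")
    clf.fit(meta_features, y)
    return clf


@dataclass
class StackedEnsemble:
    base_models: list[TrainedBaseModel]
    meta_model: LogisticRegression
    feature_recipe: dict = field(default_factory=dict)

    @property
    def meta_input_dim(self) -> int:
        L, C = self.feature_recipe["input_shape"]
        return len(self.base_models) + L * C


def fit_stacked_ensemble(specs: Sequence[BaseModelSpec], X: np.ndarray,
                         y: np.ndarray, k_folds: int = 5,
                         config: TrainConfig | None = None, seed: int = 0,
                         regularization: float = 1.0,
                         trainer: Callable | None = None) -> StackedEnsemble:
    """Fit the whole stack: OOF meta-features -> meta model -> full refit."""
    config = config or TrainConfig()
    trainer = trainer or _default_trainer
    y = np.asarray(y)
    oof = oof_predictions(specs, X, y, k_folds=k_folds, config=config,
                          seed=seed, trainer=trainer)
    X_flat = X.reshape(len(X), -1)
    meta_features = assemble_meta_features(oof, X_flat)
    meta = fit_meta(meta_features, y, regularization)
    base = [trainer(spec, X, y, config, seed + 7919 * (j + 1))
            for j, spec in enumerate(specs)]
    recipe = {"input_shape": list(X.shape[1:]),
              "architectures": [s.architecture for s in specs]}
    return StackedEnsemble(base_models=base, meta_model=meta,
                           feature_recipe=recipe)


def base_probabilities(ensemble: StackedEnsemble, X: np.ndarray) -> np.ndarray:
    return np.column_stack([bm.predict_proba(m, X)
                            for m in ensemble.base_models])


def predict_ensemble(ensemble: StackedEnsemble, X: np.ndarray) -> np.ndarray:
    """Meta probability for each encoded window (n, L, C) -> (n,)."""
    expected = tuple(ensemble.feature_recipe["input_shape"])
    if tuple(X.shape[1:]) != expected:
        raise ValueError(f"input shape {X.shape[1:]} != recipe {expected}")
    if len(X) == 0:
        return np.zeros(0)
    probs = base_probabilities(ensemble, X)
    meta_features = assemble_meta_features(probs, X.reshape(len(X), -1))
    return ensemble.meta_model.predict_proba(meta_features)[:, 1]


# ---------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------

def save_ensemble(ensemble: StackedEnsemble, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for j, trained in enumerate(ensemble.base_models):
        bm.save_trained_model(trained, directory / f"base_{j}")
    meta = ensemble.meta_model
    np.savez(directory / "meta.npz", coef=meta.coef_, intercept=meta.intercept_,
             classes=meta.classes_)
    manifest = {"feature_recipe": ensemble.feature_recipe,
                "n_base_models": len(ensemble.base_models),
                "meta_C": float(meta.C)}
    (directory / "ensemble.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(directory: str | Path) -> StackedEnsemble:
    directory = Path(directory)
    manifest = json.loads((directory / "ensemble.json").read_text())
    base = [bm.load_trained_model(directory / f"base_{j}")
            for j in range(manifest["n_base_models"])]
    with np.load(directory / "meta.npz") as data:
        meta = LogisticRegression(C=manifest["meta_C"])
        meta.coef_ = data["coef"]
        meta.intercept_ = data["intercept"]
        meta.classes_ = data["classes"]
    return StackedEnsemble(base_models=base, meta_model=meta,
                           feature_recipe=manifest["feature_recipe"])
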