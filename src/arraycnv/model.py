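"""Model/Results interface for the stacked-LSTM CNV scorer.

Usage follows the fit/results convention of statistical modelling
packages::

    model = CnvLstmModel(train_features, labels)       # FeatureArray + 0/1 labels
    res = model.fit()                                  # -> CnvLstmResults
    print(res.summary())
    scores = res.predict(new_features)                 # values in [0, 1]

The scorer consumes the per-window feature sequence of a sample and
emits one value in [0, 1], interpreted as the likelihood that the sample
carries a CNV of the model's type in the region of interest.  Training
is deterministic for a fixed config seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import FeatureArray, ScalingStats
from .metrics import brier_score, compute_auc
from .nn import AdamOptimizer, StackedLstmClassifier

__all__ = ["ModelConfig", "CnvLstmModel", "CnvLstmResults", "EvalReport",
           "cross_validate", "load_results"]

_ARTIFACT_VERSION = 1


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the stacked-LSTM scorer.

    The architecture is fixed at three recurrent layers; sizes, batch and
    schedule are modest defaults suitable for training sets of a few
    hundred samples.
    """

    hidden_units: tuple[int, int, int] = (64, 32, 16)
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 10
    validation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_units) != 3:
            raise ValueError("the scorer stacks exactly 3 recurrent layers")
        if any(u < 1 for u in self.hidden_units):
            raise ValueError("hidden layer sizes must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


class CnvLstmModel:
    """Binary CNV scorer built from a model-ready feature array."""

    def __init__(self, features: FeatureArray, labels):
        labels = np.asarray(labels)
        if labels.ndim != 1 or len(labels) != features.values.shape[0]:
            raise ValueError(
                f"labels length {labels.shape} does not match "
                f"{features.values.shape[0]} samples"
            )
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(labels)) < 2:
            raise ValueError("training requires both classes present")
        if features.scaling is None:
            raise ValueError("features must be scaled before training "
                             "(build_feature_array default)")
        self.features = features
        self.labels = labels.astype(float)

    def fit(self, config: ModelConfig | None = None) -> "CnvLstmResults":
        """Train with Adam + BPTT; early stopping with best-weight restore."""
        config = ModelConfig() if config is None else config
        X = self.features.values
        y = self.labels
        n, n_windows, n_features = X.shape

        rng = np.random.default_rng(config.seed)
        net = StackedLstmClassifier(n_features, config.hidden_units, seed=config.seed)
        opt = AdamOptimizer(net.params, lr=config.learning_rate)

        # optional stratified validation split for the early-stop monitor
        if config.validation_fraction > 0.0:
            order = rng.permutation(n)
            n_val = max(1, int(round(config.validation_fraction * n)))
            val_idx, train_idx = order[:n_val], order[n_val:]
            if len(np.unique(y[train_idx])) < 2:
                raise ValueError("validation split left a single-class training set")
        else:
            train_idx = np.arange(n)
            val_idx = None

        best_loss = np.inf
        best_weights = net.get_weights()
        best_epoch = 0
        history: list[dict] = []
        wait = 0
        for epoch in range(config.epochs):
            perm = rng.permutation(len(train_idx))
            idx = train_idx[perm]
            epoch_loss = 0.0
            for start in range(0, len(idx), config.batch_size):
                batch = idx[start : start + config.batch_size]
                loss, grads = net.loss_and_grads(X[batch], y[batch])
                opt.step(net.params, grads)
                epoch_loss += loss * len(batch)
            epoch_loss /= len(idx)
            monitor = (
                net.bce_loss(X[val_idx], y[val_idx]) if val_idx is not None else epoch_loss
            )
            history.append(
                {"epoch": epoch, "loss": epoch_loss, "monitor": monitor}
            )
            if monitor < best_loss - 1e-12:
                best_loss = monitor
                best_weights = net.get_weights()
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= config.patience:
                    break
        net.set_weights(best_weights)
        return CnvLstmResults(
            net=net,
            config=config,
            cnv_type=self.features.cnv_type,
            feature_names=tuple(self.features.feature_names),
            n_windows=n_windows,
            scaling=self.features.scaling,
            history=history,
            best_epoch=best_epoch,
            model=self,
        )


class CnvLstmResults:
    """Trained scorer plus its training history and scaling statistics."""

    def __init__(self, net, config, cnv_type, feature_names, n_windows, scaling,
                 history, best_epoch, model=None):
        self.net = net
        self.config = config
        self.cnv_type = cnv_type
        self.feature_names = tuple(feature_names)
        self.n_windows = int(n_windows)
        self.n_features = len(self.feature_names)
        self.scaling = scaling
        self.history = history
        self.best_epoch = best_epoch
        self.model = model

    # ---- inference ---------------------------------------------------

    def _check_features(self, features: FeatureArray) -> None:
        shape = features.values.shape[1:]
        if shape != (self.n_windows, self.n_features):
            raise ValueError(
                f"feature shape {shape} does not match the trained model "
                f"({self.n_windows}, {self.n_features})"
            )
        if features.cnv_type != self.cnv_type:
            raise ValueError(
                f"features built for {features.cnv_type!r} fed to a "
                f"{self.cnv_type!r} model"
            )
        if features.scaling is None:
            raise ValueError(
                "features are unscaled; build them with scaling=results.scaling"
            )
        if features.scaling != self.scaling:
            raise ValueError(
                "feature scaling statistics differ from the model's training "
                "statistics; rebuild features with scaling=results.scaling"
            )

    def predict(self, features: FeatureArray) -> np.ndarray:
        """Score samples; one value in [0, 1] per sample."""
        self._check_features(features)
        return self.net.forward(features.values)

    def evaluate(self, features: FeatureArray, labels, threshold: float = 0.5) -> dict:
        """AUC, Brier score and confusion counts at a reporting threshold."""
        scores = self.predict(features)
        labels = np.asarray(labels)
        calls = scores >= threshold
        tp = int(np.sum(calls & (labels == 1)))
        tn = int(np.sum(~calls & (labels == 0)))
        fp = int(np.sum(calls & (labels == 0)))
        fn = int(np.sum(~calls & (labels == 1)))
        return {
            "auc": compute_auc(labels, scores),
            "brier": brier_score(labels, scores),
            "threshold": threshold,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        }

    def summary(self) -> str:
        lines = [
            "Stacked-LSTM CNV scorer",
            "=" * 47,
            f"CNV type:          {self.cnv_type}",
            f"input shape:       ({self.n_windows} windows, {self.n_features} features)",
            f"hidden units:      {self.config.hidden_units}",
            f"epochs run:        {len(self.history)} (best at {self.best_epoch})",
            f"final train loss:  {self.history[-1]['loss']:.4f}" if self.history else "",
            f"seed:              {self.config.seed}",
            "features:          " + ", ".join(self.feature_names),
        ]
        return "\n".join(l for l in lines if l)

    # ---- persistence -------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Bundle architecture metadata, weights and scaling stats in one file."""
        meta = {
            "version": _ARTIFACT_VERSION,
            "cnv_type": self.cnv_type,
            "feature_names": list(self.feature_names),
            "n_windows": self.n_windows,
            "config": dataclasses.asdict(self.config),
            "best_epoch": self.best_epoch,
            "history": self.history,
        }
        weights = self.net.get_weights()
        arrays = {f"w{i}": w for i, w in enumerate(weights)}
        np.savez(
            path,
            meta=np.array(json.dumps(meta)),
            scaling_center=self.scaling.center,
            scaling_scale=self.scaling.scale,
            **arrays,
        )


def load_results(path: str | Path, expected_cnv_type: str | None = None) -> CnvLstmResults:
    """Load a saved scorer; round-trips predictions bit-for-bit."""
    try:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("version") != _ARTIFACT_VERSION:
                raise ValueError(f"unsupported model artifact version: {meta.get('version')}")
            scaling = ScalingStats(
                center=data["scaling_center"], scale=data["scaling_scale"]
            )
            weights = [data[f"w{i}"] for i in range(len(data.files) - 3)]
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot load model artifact {path}: {exc}") from exc
    if expected_cnv_type is not None and meta["cnv_type"] != expected_cnv_type:
        raise ValueError(
            f"model artifact is for {meta['cnv_type']!r}, expected {expected_cnv_type!r}"
        )
    cfg_dict = dict(meta["config"])
    cfg_dict["hidden_units"] = tuple(cfg_dict["hidden_units"])
    config = ModelConfig(**cfg_dict)
    net = StackedLstmClassifier(
        len(meta["feature_names"]), config.hidden_units, seed=config.seed
    )
    net.set_weights(weights)
    return CnvLstmResults(
        net=net,
        config=config,
        cnv_type=meta["cnv_type"],
        feature_names=tuple(meta["feature_names"]),
        n_windows=meta["n_windows"],
        scaling=scaling,
        history=meta["history"],
        best_epoch=meta["best_epoch"],
    )


@dataclasses.dataclass(frozen=True)
class EvalReport:
    """Cross-validation report: per-fold AUC, their mean, Brier score."""

    fold_aucs: tuple[float, ...]
    mean_auc: float
    brier: float
    k: int
    seed: int


def cross_validate(features: FeatureArray, labels, k: int = 5,
                   config: ModelConfig | None = None) -> EvalReport:
    """Stratified k-fold cross-validation of the scorer.

    Each fold trains a fresh model on the other k−1 folds and scores the
    held-out fold; the report carries per-fold AUCs, their arithmetic
    mean, and the pooled out-of-fold Brier score.
    """
    config = ModelConfig() if config is None else config
    labels = np.asarray(labels).astype(int)
    X = features.values
    if len(labels) < k:
        raise ValueError(f"need at least k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    fold_aucs = []
    oof = np.zeros(len(labels))
    for train_idx, test_idx in skf.split(X, labels):
        if len(np.unique(labels[test_idx])) < 2 or len(np.unique(labels[train_idx])) < 2:
            raise ValueError("a fold contains a single class; use fewer folds")
        sub = FeatureArray(
            values=X[train_idx],
            sample_ids=[features.sample_ids[i] for i in train_idx],
            feature_names=features.feature_names,
            cnv_type=features.cnv_type,
            scheme=features.scheme,
            scaling=features.scaling,
        )
        res = CnvLstmModel(sub, labels[train_idx]).fit(config)
        scores = res.net.forward(X[test_idx])
        fold_aucs.append(compute_auc(labels[test_idx], scores))
        oof[test_idx] = scores
    return EvalReport(
        fold_aucs=tuple(fold_aucs),
        mean_auc=float(np.mean(fold_aucs)),
        brier=brier_score(labels, oof),
        k=k,
        seed=config.seed,
    )
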