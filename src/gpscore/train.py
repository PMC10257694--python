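"""Generalizable precursor classifiers.

Two model families are supported, both trained on pooled (usually
denoised) target/decoy tables with class-imbalance weighting:

* ``svm`` — a linear maximum-margin classifier fitted by stochastic
  gradient descent (hinge loss, L2 penalty, alpha 1e-5, adaptive learning
  rate, early stopping on a held-out validation fraction);
* ``gbt`` — gradient-boosted trees with a raw-logit margin objective and
  log-loss evaluation, early-stopped on the same kind of validation
  split.

The discriminant score ("DScore") is the *untransformed* decision margin
(linear margin or raw tree logit): margins preserve the bimodal
target/decoy score geometry that downstream density-based q-value
estimation needs, where a squashed probability would saturate both modes.
For thresholded prediction the margin is mapped through a logistic link.

A fitted :class:`PrecursorModel` bundles the parameters with the feature
scaler and provenance and serializes to a single JSON document that
round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import train_test_split

from .errors import (
    ConfigurationError,
    DegenerateLabels,
    SchemaMismatch,
    TooFewRecords,
)
from .io_model import SUBSCORE_COLUMNS, SampleTable, concat_tables


@dataclass
class TrainingConfig:
    """Training recipe; defaults mirror the published settings."""

    model_kind: str = "gbt"
    l2_alpha: float = 1e-5
    learning_rate_schedule: str = "adaptive"
    early_stopping: bool = True
    validation_fraction: float = 0.1
    gbt_objective: str = "binary:logitraw"
    gbt_eval_metric: str = "logloss"
    gbt_max_depth: int = 6
    gbt_n_rounds: int = 200
    gbt_learning_rate: float = 0.1
    gbt_early_stopping_rounds: int = 20
    class_weighting: str = "balanced_by_ratio"
    seed: int = 0

    def validate(self) -> None:
        if self.model_kind not in ("svm", "gbt"):
            raise ConfigurationError(f"unknown model_kind {self.model_kind!r}")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ConfigurationError("validation_fraction must be in (0, 1)")
        if self.l2_alpha <= 0:
            raise ConfigurationError("l2_alpha must be positive")


@dataclass
class PrecursorModel:
    """A trained classifier plus its feature scaler and provenance.

    ``decision_margin`` is the DScore; ``predict_probability`` maps it
    through the logistic link for thresholding at
    ``probability_threshold``.
    """

    model_kind: str
    feature_names: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    probability_threshold: float = 0.5
    weights: np.ndarray | None = None  # svm
    bias: float | None = None  # svm
    booster: xgb.Booster | None = None  # gbt
    provenance: dict = field(default_factory=dict)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def decision_margin(self, X: np.ndarray) -> np.ndarray:
        Xs = self._scale(np.asarray(X, dtype=np.float64))
        if self.model_kind == "svm":
            return Xs @ self.weights + self.bias
        dm = xgb.DMatrix(Xs, feature_names=list(self.feature_names))
        return self.booster.predict(dm)  # logitraw objective => raw margin

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        margin = self.decision_margin(X)
        return 1.0 / (1.0 + np.exp(-margin))

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        doc = {
            "format": "gpscore-model-v1",
            "model_kind": self.model_kind,
            "feature_names": list(self.feature_names),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "probability_threshold": self.probability_threshold,
            "provenance": self.provenance,
        }
        if self.model_kind == "svm":
            doc["weights"] = self.weights.tolist()
            doc["bias"] = self.bias
        else:
            doc["booster_json"] = self.booster.save_raw(raw_format="json").decode()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PrecursorModel":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        kwargs = dict(
            model_kind=doc["model_kind"],
            feature_names=tuple(doc["feature_names"]),
            scaler_mean=np.asarray(doc["scaler_mean"], dtype=np.float64),
            scaler_scale=np.asarray(doc["scaler_scale"], dtype=np.float64),
            probability_threshold=doc["probability_threshold"],
            provenance=doc.get("provenance", {}),
        )
        if doc["model_kind"] == "svm":
            kwargs["weights"] = np.asarray(doc["weights"], dtype=np.float64)
            kwargs["bias"] = float(doc["bias"])
        else:
            booster = xgb.Booster()
            booster.load_model(bytearray(doc["booster_json"].encode()))
            kwargs["booster"] = booster
        return cls(**kwargs)


@dataclass
class PrecisionReport:
    """Confusion counts for 'is this a true target' prediction."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float | None:
        """tp/(tp+fp); None when no positive predictions were made."""
        if self.tp + self.fp == 0:
            return None
        return self.tp / (self.tp + self.fp)


def assemble_training_set(tables: Iterable[SampleTable]) -> pd.DataFrame:
    """Pool per-sample tables into one labeled frame (targets 1, decoys 0).

    All tables must share the canonical feature names; subscore columns
    are re-ordered canonically so permuted inputs pool cleanly.
    """
    tables = list(tables)
    names = {t.feature_names for t in tables}
    if len(names) > 1:
        raise SchemaMismatch(f"tables disagree on feature names: {names}")
    if names and set(names.pop()) != set(SUBSCORE_COLUMNS):
        raise SchemaMismatch("tables do not carry the canonical 22 subscores")
    pool = concat_tables(tables)
    pool["label"] = (pool["decoy"] == 0).astype(np.int64)
    return pool


def _positive_class_weight(y: np.ndarray) -> float:
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    return n_neg / n_pos


def train_classifier(pool: pd.DataFrame, config: TrainingConfig) -> PrecursorModel:
    """Fit a :class:`PrecursorModel` on a pooled labeled set.

    The scaler is fitted on the full pool; the positive class gets weight
    #negatives/#positives; early stopping uses a stratified
    ``validation_fraction`` split.  The same pool, config and seed always
    produce an identical serialized model.
    """
    config.validate()
    y = pool["label"].to_numpy(dtype=np.int64)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateLabels("training pool holds a single class")
    if min((y == c).sum() for c in classes) < 100:
        raise TooFewRecords("need at least 100 records per class")
    X = pool.loc[:, list(SUBSCORE_COLUMNS)].to_numpy(dtype=np.float64)

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    Xs = (X - mean) / scale
    w_pos = _positive_class_weight(y)

    provenance = {
        "n_records": int(len(y)),
        "n_targets": int((y == 1).sum()),
        "n_decoys": int((y == 0).sum()),
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
    }

    if config.model_kind == "svm":
        clf = SGDClassifier(
            loss="hinge",
            penalty="l2",
            alpha=config.l2_alpha,
            learning_rate=config.learning_rate_schedule,
            eta0=0.01,
            early_stopping=config.early_stopping,
            validation_fraction=config.validation_fraction,
            class_weight={1: w_pos, 0: 1.0},
            random_state=config.seed,
        )
        clf.fit(Xs, y)
        return PrecursorModel(
            model_kind="svm",
            feature_names=SUBSCORE_COLUMNS,
            scaler_mean=mean,
            scaler_scale=scale,
            weights=clf.coef_.ravel().copy(),
            bias=float(clf.intercept_[0]),
            provenance=provenance,
        )

    X_tr, X_va, y_tr, y_va = train_test_split(
        Xs,
        y,
        test_size=config.validation_fraction,
        stratify=y,
        random_state=config.seed,
    )
    sw_tr = np.where(y_tr == 1, w_pos, 1.0)
    sw_va = np.where(y_va == 1, w_pos, 1.0)
    dtrain = xgb.DMatrix(
        X_tr, label=y_tr, weight=sw_tr, feature_names=list(SUBSCORE_COLUMNS)
    )
    dvalid = xgb.DMatrix(
        X_va, label=y_va, weight=sw_va, feature_names=list(SUBSCORE_COLUMNS)
    )
    params = {
        "objective": config.gbt_objective,
        "eval_metric": config.gbt_eval_metric,
        "max_depth": config.gbt_max_depth,
        "eta": config.gbt_learning_rate,
        "tree_method": "hist",
        "nthread": 1,
        "seed": config.seed,
    }
    booster = xgb.train(
        params,
        dtrain,
        num_boost_round=config.gbt_n_rounds,
        evals=[(dvalid, "validation")],
        early_stopping_rounds=(
            config.gbt_early_stopping_rounds if config.early_stopping else None
        ),
        verbose_eval=False,
    )
    return PrecursorModel(
        model_kind="gbt",
        feature_names=SUBSCORE_COLUMNS,
        scaler_mean=mean,
        scaler_scale=scale,
        booster=booster,
        provenance=provenance,
    )


def precision_report(model: PrecursorModel, table: SampleTable) -> PrecisionReport:
    """Confusion counts of the model's target predictions on labeled data.

    Ground truth is the ``truth_label`` column when present (synthetic
    data), otherwise the target/decoy flag.
    """
    df = table.data
    prob = model.predict_probability(table.features())
    predicted = prob >= model.probability_threshold
    if "truth_label" in df.columns and df["truth_label"].notna().all():
        actual = (df["truth_label"] == "true_target").to_numpy()
    else:
        actual = (df["decoy"] == 0).to_numpy()
    tp = int((predicted & actual).sum())
    fp = int((predicted & ~actual).sum())
    tn = int((~predicted & ~actual).sum())
    fn = int((~predicted & actual).sum())
    return PrecisionReport(tp=tp, fp=fp, tn=tn, fn=fn)
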