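"""Low-level gradient-boosted tree helpers shared across the pipeline.

All boosters are binary-logistic XGBoost models trained single-threaded with
an explicit seed and ``base_score = 0.5`` (zero base logit), which keeps
training deterministic and the log-odds decomposition arithmetic clean.
The feature-extraction / backward-elimination stages use a fixed
configuration of 50 boosting rounds with step-size shrinkage 0.2; everything
else stays at library defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xgboost as xgb

#: Booster settings used during feature extraction and backward elimination.
EXTRACTION_ROUNDS = 50
EXTRACTION_SHRINKAGE = 0.2

BASE_SCORE = 0.5


@dataclass
class BoosterParams:
    """Tunable hyperparameters of the final classifier, with their tuning boxes."""

    num_boost_round: int = EXTRACTION_ROUNDS
    eta: float = EXTRACTION_SHRINKAGE
    max_depth: int = 6
    min_child_weight: float = 1.0
    subsample: float = 1.0
    colsample_bytree: float = 1.0

    #: (low, high) tuning box per field, in declaration order.
    BOX = {
        "num_boost_round": (10, 300),
        "eta": (0.01, 0.5),
        "max_depth": (2, 10),
        "min_child_weight": (1.0, 10.0),
        "subsample": (0.5, 1.0),
        "colsample_bytree": (0.5, 1.0),
    }

    def __post_init__(self) -> None:
        if self.num_boost_round < 1:
            raise ValueError("num_boost_round must be >= 1")
        for name, (lo, hi) in self.BOX.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside its box [{lo}, {hi}]")

    def to_xgb(self) -> dict:
        return {
            "eta": self.eta,
            "max_depth": int(self.max_depth),
            "min_child_weight": self.min_child_weight,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
        }

    def to_dict(self) -> dict:
        return {
            "num_boost_round": int(self.num_boost_round),
            "eta": float(self.eta),
            "max_depth": int(self.max_depth),
            "min_child_weight": float(self.min_child_weight),
            "subsample": float(self.subsample),
            "colsample_bytree": float(self.colsample_bytree),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoosterParams":
        return cls(**d)


def make_dmatrix(X, label=None, feature_names=None) -> xgb.DMatrix:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    return xgb.DMatrix(X, label=label, feature_names=feature_names)


def fit_booster(
    X,
    y,
    num_boost_round: int = EXTRACTION_ROUNDS,
    eta: float = EXTRACTION_SHRINKAGE,
    seed: int = 0,
    feature_names=None,
    extra_params: dict | None = None,
) -> xgb.Booster:
    """Train a binary-logistic booster; deterministic for a fixed seed."""
    d = make_dmatrix(X, label=np.asarray(y, dtype=float), feature_names=feature_names)
    params = {
        "objective": "binary:logistic",
        "eta": eta,
        "base_score": BASE_SCORE,
        "seed": int(seed),
        "nthread": 1,
    }
    if extra_params:
        params.update(extra_params)
    return xgb.train(params, d, num_boost_round=int(num_boost_round))


def predict_proba(booster: xgb.Booster, X, feature_names=None) -> np.ndarray:
    return booster.predict(make_dmatrix(X, feature_names=feature_names))


def predict_margin(booster: xgb.Booster, X, feature_names=None) -> np.ndarray:
    return booster.predict(make_dmatrix(X, feature_names=feature_names),
                           output_margin=True)
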