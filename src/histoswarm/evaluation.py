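"""Final-classifier training, AUC evaluation, cross-sample transfer and method comparison."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import sklearn.metrics
import xgboost as xgb

from . import boosting
from .boosting import BoosterParams
from .patterns import Pattern, build_feature_matrix, feature_names
from .signal_io import ProfileSet


def auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the normalized Mann-Whitney concordance statistic
    P(score_pos > score_neg) + 0.5 * P(tie); ties across classes contribute
    one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present to compute an AUC")
    return float(sklearn.metrics.roc_auc_score(labels, scores))


@dataclass
class BoosterModel:
    """A trained classifier plus the patterns whose frequencies it expects as features."""

    booster: xgb.Booster
    params: BoosterParams
    patterns: list[Pattern]
    seed: int = 0
    sample_id: str | None = None

    @property
    def feature_names(self) -> list[str]:
        return feature_names(self.patterns)

    def predict_from_features(self, F) -> np.ndarray:
        """Predicted above-median probabilities from a precomputed feature matrix."""
        X = np.asarray(F, dtype=float)
        if X.shape[1] != len(self.patterns):
            raise ValueError(
                f"feature matrix has {X.shape[1]} columns, model expects {len(self.patterns)}"
            )
        return boosting.predict_proba(self.booster, X, self.feature_names)

    def predict_margin_from_features(self, F) -> np.ndarray:
        X = np.asarray(F, dtype=float)
        if X.shape[1] != len(self.patterns):
            raise ValueError("feature-matrix width does not match the model")
        return boosting.predict_margin(self.booster, X, self.feature_names)

    def predict(self, profiles: ProfileSet) -> pd.Series:
        """Recompute pattern frequencies on ``profiles`` and score them."""
        F = build_feature_matrix(profiles, self.patterns)
        return pd.Series(self.predict_from_features(F.to_numpy()), index=F.index)

    def base_logit(self) -> float:
        """The booster's intercept on the log-odds scale (logit of base_score)."""
        cfg = json.loads(self.booster.save_config())
        p = float(cfg["learner"]["learner_model_param"]["base_score"])
        return float(np.log(p / (1.0 - p)))

    def save(self, path) -> None:
        payload = {
            "format": "histoswarm-booster-model",
            "params": self.params.to_dict(),
            "patterns": [p.to_dict() for p in self.patterns],
            "seed": int(self.seed),
            "sample_id": self.sample_id,
            "booster_raw_json": self.booster.save_raw(raw_format="json").decode(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "BoosterModel":
        with open(path) as fh:
            payload = json.load(fh)
        booster = xgb.Booster()
        booster.load_model(bytearray(payload["booster_raw_json"].encode()))
        return cls(
            booster=booster,
            params=BoosterParams.from_dict(payload["params"]),
            patterns=[Pattern.from_dict(d) for d in payload["patterns"]],
            seed=payload.get("seed", 0),
            sample_id=payload.get("sample_id"),
        )


def train_final(
    patterns: list[Pattern],
    params: BoosterParams,
    F_train,
    y_train,
    seed: int = 0,
    sample_id: str | None = None,
) -> BoosterModel:
    """Train the final classifier on the full training set with tuned hyperparameters."""
    if not patterns:
        raise ValueError("need at least one pattern to train a model")
    y = np.asarray(y_train)
    if len(np.unique(y)) != 2:
        raise ValueError("training labels are single-class; cannot train a classifier")
    booster = boosting.fit_booster(
        np.asarray(F_train, dtype=float),
        y,
        num_boost_round=params.num_boost_round,
        eta=params.eta,
        seed=seed,
        feature_names=feature_names(patterns),
        extra_params=params.to_xgb(),
    )
    return BoosterModel(booster=booster, params=params, patterns=patterns,
                        seed=seed, sample_id=sample_id)


def evaluate(model: BoosterModel, profiles: ProfileSet, labels) -> float:
    """AUC of ``model`` on a profile set with known labels (features recomputed)."""
    scores = model.predict(profiles)
    return auc(scores.to_numpy(), np.asarray(labels))


def cross_sample_apply(model: BoosterModel, profiles: ProfileSet, labels) -> float:
    """Apply a model trained on sample A to another sample's profiles unchanged.

    The model's own patterns are re-counted on the target profiles; no
    re-tuning or re-selection happens.  Applying a model to its own test
    split reproduces the standard evaluation exactly.
    """
    if profiles.n_marks < max(p.mark for p in model.patterns) + 1:
        raise KeyError("target profiles miss a mark required by the model's patterns")
    return evaluate(model, profiles, labels)


def transfer_matrix(models: list[BoosterModel], test_sets: list[tuple[ProfileSet, np.ndarray]],
                    names: list[str] | None = None) -> pd.DataFrame:
    """All-pairs transfer AUCs: row = training sample's model, column = target test set."""
    names = names or [m.sample_id or f"sample_{i}" for i, m in enumerate(models)]
    out = np.zeros((len(models), len(test_sets)))
    for i, model in enumerate(models):
        for j, (profiles, labels) in enumerate(test_sets):
            out[i, j] = cross_sample_apply(model, profiles, labels)
    return pd.DataFrame(out, index=names, columns=names[: len(test_sets)])


def compare_paired_auc(auc_a, auc_b) -> float:
    """One-sided p-value that method B outperforms method A on paired per-sample AUCs.

    Wilcoxon signed-rank test, normal approximation with continuity
    correction, alternative "B > A"; zero differences are dropped before
    ranking.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired AUC vectors must be 1-D of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired samples")
    if np.all(a == b):
        raise ValueError("all paired differences are zero; test undefined")
    res = scipy.stats.wilcoxon(
        b, a, alternative="greater", zero_method="wilcox",
        correction=True, method="approx",
    )
    return float(res.pvalue)
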