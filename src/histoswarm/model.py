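"""High-level modelling interface: fit the full pipeline, inspect the results.

:class:`PatternExpressionModel` wraps the four pipeline stages — PSO pattern
extraction, backward elimination, hyperparameter tuning and final classifier
training — behind a statsmodels-style ``Model.fit() -> Results`` interface.
The Results object carries the accepted and surviving patterns, tuned
hyperparameters, AUCs on all three splits, stage traces, and hangs the
prediction, explanation and transfer utilities off the fitted state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, explain, selection
from .boosting import BoosterParams
from .evaluation import BoosterModel, auc, train_final
from .extraction import ExtractionConfig, extract_features
from .patterns import Pattern, build_feature_matrix
from .pso import PSOControl
from .signal_io import DatasetSplit, ProfileSet, binarize_expression, split_genes


@dataclass
class PipelineConfig:
    """End-to-end settings; extraction settings nest an :class:`ExtractionConfig`."""

    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    tune: bool = True
    tune_max_iter: int = 10
    tune_max_stagnant: int = 4
    n_train: int | None = None   # default: even-truncated half of the genes
    seed: int = 0


class PatternExpressionModel:
    """Binary expression classifier from binned histone-modification profiles.

    Parameters
    ----------
    profiles
        Binned signal for all genes (five marks x 200 bins each).
    expression
        Per-gene expression values (Series indexed by gene_id), binarized at
        the median; alternatively pass precomputed ``labels``.
    labels
        Optional per-gene binary labels (Series indexed by gene_id).
    split
        Optional train/validation/test partition; drawn from ``config.seed``
        when omitted.
    config
        Pipeline settings.
    """

    def __init__(self, profiles: ProfileSet, expression: pd.Series | None = None,
                 labels: pd.Series | None = None, split: DatasetSplit | None = None,
                 config: PipelineConfig | None = None, sample_id: str | None = None):
        if (expression is None) == (labels is None):
            raise ValueError("pass exactly one of expression or labels")
        self.profiles = profiles
        self.config = config or PipelineConfig()
        self.sample_id = sample_id
        if labels is None:
            lab = binarize_expression(expression.loc[profiles.gene_ids].to_numpy())
            labels = pd.Series(lab, index=profiles.gene_ids)
        self.labels = labels
        if split is None:
            n_train = self.config.n_train
            if n_train is None:
                n_train = (profiles.n_genes // 2) // 2 * 2
            split = split_genes(profiles.gene_ids, n_train=n_train,
                                seed=self.config.seed)
        self.split = split

    @classmethod
    def from_dataset(cls, dataset, config: PipelineConfig | None = None,
                     split: DatasetSplit | None = None) -> "PatternExpressionModel":
        """Build from a :class:`histoswarm.synthetic.Dataset`."""
        return cls(dataset.profiles, labels=dataset.labels, split=split,
                   config=config, sample_id=dataset.sample_id)

    def _subset(self, ids: list[str]) -> tuple[ProfileSet, np.ndarray]:
        return self.profiles.subset(ids), self.labels.loc[ids].to_numpy()

    def fit(self) -> "PatternExpressionResults":
        """Run extraction -> backward elimination -> tuning -> final training."""
        cfg = self.config
        train_profiles, y_train = self._subset(self.split.train_ids)
        valid_profiles, y_valid = self._subset(self.split.valid_ids)
        test_profiles, y_test = self._subset(self.split.test_ids)

        extraction = extract_features(train_profiles, y_train, cfg.extraction)
        patterns = extraction.patterns
        traces = {"extraction": extraction.trace}

        if not patterns:
            warnings.warn("extraction accepted no pattern; returning a trivial "
                          "featureless result", stacklevel=2)
            return PatternExpressionResults(
                model_spec=self, booster_model=None, patterns=[],
                surviving_patterns=[], params=BoosterParams(),
                auc_train=0.5, auc_valid=0.5, auc_test=0.5, traces=traces,
            )

        F_train = extraction.feature_matrix
        F_valid = build_feature_matrix(valid_profiles, patterns)
        be = selection.backward_eliminate(
            patterns, F_train.to_numpy(), y_train, F_valid.to_numpy(), y_valid,
            booster_rounds=cfg.extraction.booster_rounds,
            shrinkage=cfg.extraction.shrinkage, seed=cfg.seed,
        )
        traces["backward_elimination"] = be.trace
        survivors = be.patterns
        if not survivors:
            return PatternExpressionResults(
                model_spec=self, booster_model=None, patterns=patterns,
                surviving_patterns=[], params=BoosterParams(),
                auc_train=0.5, auc_valid=be.best_auc, auc_test=0.5, traces=traces,
            )
        Ft = F_train.iloc[:, be.kept_indices]
        Fv = F_valid.iloc[:, be.kept_indices]

        if cfg.tune:
            params, tuned_auc = selection.tune_hyperparameters(
                Ft.to_numpy(), y_train, Fv.to_numpy(), y_valid,
                control=PSOControl(max_iter=cfg.tune_max_iter,
                                   max_stagnant=cfg.tune_max_stagnant,
                                   seed=cfg.seed),
                seed=cfg.seed,
            )
        else:
            params = BoosterParams()

        booster_model = train_final(survivors, params, Ft.to_numpy(), y_train,
                                    seed=cfg.seed, sample_id=self.sample_id)
        auc_train = auc(booster_model.predict_from_features(Ft.to_numpy()), y_train)
        auc_valid = auc(booster_model.predict_from_features(Fv.to_numpy()), y_valid)
        auc_test = evaluation.evaluate(booster_model, test_profiles, y_test)
        return PatternExpressionResults(
            model_spec=self, booster_model=booster_model, patterns=patterns,
            surviving_patterns=survivors, params=params,
            auc_train=auc_train, auc_valid=auc_valid, auc_test=auc_test,
            traces=traces,
        )


@dataclass
class PatternExpressionResults:
    """Fitted pipeline state: patterns, classifier, split AUCs and diagnostics."""

    model_spec: PatternExpressionModel
    booster_model: BoosterModel | None
    patterns: list[Pattern]
    surviving_patterns: list[Pattern]
    params: BoosterParams
    auc_train: float
    auc_valid: float
    auc_test: float
    traces: dict[str, pd.DataFrame]

    def predict(self, profiles: ProfileSet) -> pd.Series:
        """Above-median expression probability per gene."""
        if self.booster_model is None:
            return pd.Series(0.5, index=profiles.gene_ids)
        return self.booster_model.predict(profiles)

    def score(self, profiles: ProfileSet, labels) -> float:
        """AUC on an external profile set (features recomputed with this model's patterns)."""
        if self.booster_model is None:
            return 0.5
        return evaluation.cross_sample_apply(self.booster_model, profiles,
                                             np.asarray(labels))

    def explain_gene(self, gene_id: str) -> explain.Explanation:
        """Log-odds decomposition of one gene's prediction."""
        if self.booster_model is None:
            raise ValueError("no fitted classifier to explain")
        profiles = self.model_spec.profiles.subset([gene_id])
        F = build_feature_matrix(profiles, self.surviving_patterns)
        return explain.decompose_prediction(self.booster_model,
                                            F.to_numpy()[0], gene_id=gene_id)

    def bin_importance(self, which: str = "test") -> np.ndarray:
        """Marks x bins relative importance over the chosen split's genes."""
        if self.booster_model is None:
            raise ValueError("no fitted classifier")
        ids = {"train": self.model_spec.split.train_ids,
               "valid": self.model_spec.split.valid_ids,
               "test": self.model_spec.split.test_ids,
               "all": self.model_spec.profiles.gene_ids}[which]
        profiles = self.model_spec.profiles.subset(ids)
        F = build_feature_matrix(profiles, self.surviving_patterns)
        contribs, _ = explain.explain_genes(self.booster_model, F)
        return explain.bin_importance([(self.booster_model, contribs, profiles)],
                                      n_marks=profiles.n_marks,
                                      n_bins=profiles.n_bins)

    def summary(self) -> str:
        """Human-readable fit report."""
        split = self.model_spec.split
        lines = [
            "Pattern-based expression classification results",
            "=" * 48,
            f"genes: {self.model_spec.profiles.n_genes} "
            f"(train {len(split.train_ids)} / valid {len(split.valid_ids)} "
            f"/ test {len(split.test_ids)})",
            f"patterns accepted: {len(self.patterns)}; "
            f"surviving backward elimination: {len(self.surviving_patterns)}",
            f"booster: {self.params.num_boost_round} rounds, eta {self.params.eta:.3f}, "
            f"depth {self.params.max_depth}, min_child_weight "
            f"{self.params.min_child_weight:.2f}, subsample {self.params.subsample:.2f}, "
            f"colsample {self.params.colsample_bytree:.2f}",
            f"AUC  train: {self.auc_train:.4f}   valid: {self.auc_valid:.4f}   "
            f"test: {self.auc_test:.4f}",
        ]
        for k, p in enumerate(self.surviving_patterns):
            shape = ", ".join(f"{v:.2f}" for v in p.shape)
            mark = self.model_spec.profiles.marks[p.mark]
            lines.append(f"  pattern {k}: {mark}, L={p.length}, "
                         f"tau={p.cutoff:.2f}, shape=[{shape}]")
        return "\n".join(lines)
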