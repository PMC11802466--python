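"""Backward elimination of redundant patterns and PSO hyperparameter tuning.

Backward elimination (BE) repeatedly removes the most recently added pattern
whose removal does not lower the validation AUC: starting from the full
feature set, patterns are transiently removed from last-added to first; a
removal is made permanent when the new validation AUC is equal to or greater
than the memorized best, after which the walk restarts from the (new) last
pattern.  BE finishes on a complete pass without a removal.  The booster
inside BE uses the fixed feature-extraction settings (50 rounds, shrinkage
0.2).

Hyperparameter tuning then runs the same SPSO2007 optimizer over a box of
booster hyperparameters, maximizing validation AUC, with one particle seeded
at the box centre so the tuned result can never fall below that reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import boosting
from .boosting import BoosterParams
from .evaluation import auc
from .patterns import Pattern
from .pso import PSOControl, pso_minimize

logger = logging.getLogger(__name__)

__all__ = ["BoosterParams", "backward_eliminate", "tune_hyperparameters",
           "BackwardEliminationResult"]


@dataclass
class BackwardEliminationResult:
    patterns: list[Pattern]
    kept_indices: list[int]
    trace: pd.DataFrame
    best_auc: float
    n_evaluations: int


def _valid_auc(F_train, y_train, F_valid, y_valid, cols, rounds, eta, seed) -> float:
    if not cols:
        return 0.5  # featureless model scores every gene identically
    booster = boosting.fit_booster(F_train[:, cols], y_train,
                                   num_boost_round=rounds, eta=eta, seed=seed)
    scores = boosting.predict_proba(booster, F_valid[:, cols])
    if np.ptp(scores) == 0:
        return 0.5
    return auc(scores, y_valid)


def backward_eliminate(
    patterns: list[Pattern],
    F_train,
    y_train,
    F_valid,
    y_valid,
    booster_rounds: int = boosting.EXTRACTION_ROUNDS,
    shrinkage: float = boosting.EXTRACTION_SHRINKAGE,
    seed: int = 0,
) -> BackwardEliminationResult:
    """Prune patterns whose removal does not hurt validation AUC.

    Survivors keep their original relative order; equal-AUC removals are
    taken (removal on ties), so duplicated feature columns cannot jointly
    survive.  The memorized best validation AUC never decreases.
    """
    if not patterns:
        raise ValueError("backward elimination needs at least one pattern")
    F_train = np.asarray(F_train, dtype=float)
    F_valid = np.asarray(F_valid, dtype=float)
    y_train = np.asarray(y_train)
    y_valid = np.asarray(y_valid)
    if F_train.shape[1] != len(patterns) or F_valid.shape[1] != len(patterns):
        raise ValueError("feature matrices must have one column per pattern")

    cache: dict[tuple[int, ...], float] = {}

    def evaluate(cols: list[int]) -> float:
        key = tuple(cols)
        if key not in cache:
            cache[key] = _valid_auc(F_train, y_train, F_valid, y_valid, cols,
                                    booster_rounds, shrinkage, seed)
        return cache[key]

    active = list(range(len(patterns)))
    best = evaluate(active)
    rows = [{"step": 0, "removed": None, "n_active": len(active), "valid_auc": best}]
    step = 0
    finished = False
    while not finished and active:
        finished = True
        for pos in range(len(active) - 1, -1, -1):
            trial = active[:pos] + active[pos + 1:]
            trial_auc = evaluate(trial)
            step += 1
            if trial_auc >= best:
                removed = active[pos]
                active = trial
                best = trial_auc
                rows.append({"step": step, "removed": removed,
                             "n_active": len(active), "valid_auc": best})
                logger.info("BE removed pattern %d (valid AUC %.4f, %d left)",
                            removed, best, len(active))
                finished = False
                break  # restart the walk from the (new) last pattern
    if not active:
        warnings.warn("backward elimination removed every pattern", stacklevel=2)
    return BackwardEliminationResult(
        patterns=[patterns[i] for i in active],
        kept_indices=active,
        trace=pd.DataFrame(rows),
        best_auc=best,
        n_evaluations=len(cache),
    )


def decode_hyperparameters(x: np.ndarray, box: dict[str, tuple[float, float]] | None = None) -> BoosterParams:
    """Map a unit-box vector onto BoosterParams; integer fields by interval partition."""
    box = box or BoosterParams.BOX
    names = list(box)
    x = np.asarray(x, dtype=float)
    if x.shape != (len(names),):
        raise ValueError(f"hyperparameter vector must have dimension {len(names)}")
    values = {}
    for xi, name in zip(x, names):
        lo, hi = box[name]
        if name in ("num_boost_round", "max_depth"):
            n_levels = int(hi) - int(lo) + 1
            values[name] = min(int(hi), int(lo) + int(xi * n_levels))
        else:
            values[name] = lo + xi * (hi - lo)
    return BoosterParams(**values)


def tune_hyperparameters(
    F_train,
    y_train,
    F_valid,
    y_valid,
    control: PSOControl | None = None,
    box: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> tuple[BoosterParams, float]:
    """PSO-tune booster hyperparameters against validation AUC.

    Returns the best parameters and their validation AUC.  One particle
    starts at the box centre, so the result is never worse than the
    centre-point reference configuration.
    """
    F_train = np.asarray(F_train, dtype=float)
    F_valid = np.asarray(F_valid, dtype=float)
    if F_train.shape[1] == 0:
        raise ValueError("cannot tune a model with zero features")
    y_train = np.asarray(y_train)
    y_valid = np.asarray(y_valid)
    box = box or BoosterParams.BOX
    D = len(box)

    def objective(x: np.ndarray) -> float:
        params = decode_hyperparameters(x, box)
        booster = boosting.fit_booster(
            F_train, y_train, num_boost_round=params.num_boost_round,
            eta=params.eta, seed=seed, extra_params=params.to_xgb(),
        )
        scores = boosting.predict_proba(booster, F_valid)
        if np.ptp(scores) == 0:
            return -0.5
        return -auc(scores, y_valid)

    control = control or PSOControl(max_iter=15, max_stagnant=5, seed=seed)
    result = pso_minimize(objective, np.zeros(D), np.ones(D), control,
                          x0=np.full(D, 0.5))
    return decode_hyperparameters(result.x, box), -result.fun
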