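"""Pattern discovery: PSO over pattern parameters scored by booster training AUC.

Each round a fresh, class-stratified subset of (up to) 3000 training genes is
drawn and the swarm searches an 11-dimensional box encoding one candidate
pattern: histone mark, template length (2-8), correlation cutoff and up to 8
shape values.  Every candidate is scored by the training-subset AUC of a
50-round shrinkage-0.2 booster fitted to the already-accepted pattern
frequencies plus the candidate's.  The round's best pattern is accepted only
if it strictly improves the best AUC seen so far; its frequency column is
then computed on the full training set and appended.  Extraction stops when
the training AUC reaches the target (default 0.999) or after a run of
non-improving rounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import boosting
from .evaluation import auc
from .patterns import (MAX_CUTOFF, MAX_LENGTH, MIN_CUTOFF, MIN_LENGTH,
                       Pattern, build_feature_matrix, match_counts)
from .pso import PSOControl, pso_minimize
from .signal_io import ProfileSet

logger = logging.getLogger(__name__)

#: Dimension of the particle encoding: mark, length, cutoff, 8 shape values.
PARTICLE_DIM = 3 + MAX_LENGTH
N_MARKS = 5

LOWER = np.zeros(PARTICLE_DIM)
UPPER = np.ones(PARTICLE_DIM)


def decode_particle(x: np.ndarray) -> Pattern:
    """Decode an 11-vector in the unit box into a valid Pattern.

    Discrete coordinates use interval partitioning (floor of the scaled
    coordinate) so both endpoints of each discrete range stay reachable.
    The decode is total: in the measure-zero case of a constant decoded
    shape, one endpoint value is nudged to restore a defined correlation.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (PARTICLE_DIM,):
        raise ValueError(f"particle must have dimension {PARTICLE_DIM}")
    if ((x < 0) | (x > 1)).any():
        raise ValueError("particle outside the unit box")
    mark = min(N_MARKS - 1, int(x[0] * N_MARKS))
    length = min(MAX_LENGTH, MIN_LENGTH + int(x[1] * (MAX_LENGTH - MIN_LENGTH + 1)))
    cutoff = MIN_CUTOFF + x[2] * (MAX_CUTOFF - MIN_CUTOFF)
    shape = x[3:3 + length].copy()
    if np.ptp(shape) == 0:
        v = shape[0]
        shape[0] = v + 0.5 if v + 0.5 <= 1.0 else v - 0.5
    return Pattern(mark=mark, shape=shape, cutoff=float(cutoff))


def encode_pattern(p: Pattern) -> np.ndarray:
    """Inverse of :func:`decode_particle` (interval midpoints for discrete coords)."""
    x = np.zeros(PARTICLE_DIM)
    x[0] = (p.mark + 0.5) / N_MARKS
    x[1] = (p.length - MIN_LENGTH + 0.5) / (MAX_LENGTH - MIN_LENGTH + 1)
    x[2] = (p.cutoff - MIN_CUTOFF) / (MAX_CUTOFF - MIN_CUTOFF)
    x[3:3 + p.length] = p.shape
    return x


@dataclass
class ExtractionConfig:
    """Pattern-search schedule: AUC target, subset size, PSO budget, booster settings."""

    auc_target: float = 0.999
    subset_size: int = 3000
    max_rounds: int = 60
    max_stagnant_rounds: int = 5
    booster_rounds: int = boosting.EXTRACTION_ROUNDS
    shrinkage: float = boosting.EXTRACTION_SHRINKAGE
    pso_swarm_size: int | None = None
    pso_max_iter: int = 20
    pso_max_stagnant: int = 7
    pso_restarts: int = 1
    seed: int = 0


@dataclass
class ExtractionResult:
    patterns: list[Pattern]
    feature_matrix: pd.DataFrame
    trace: pd.DataFrame
    best_auc: float


def score_candidate(
    pattern: Pattern,
    existing: np.ndarray,
    subset_profiles: ProfileSet,
    subset_labels: np.ndarray,
    booster_rounds: int = boosting.EXTRACTION_ROUNDS,
    shrinkage: float = boosting.EXTRACTION_SHRINKAGE,
    seed: int = 0,
) -> float:
    """Training-subset AUC of a booster on existing features plus one candidate column.

    ``existing`` is (n_subset, k) match counts for already-accepted patterns
    (k may be 0).  The candidate column is computed fresh; nothing is mutated.
    A candidate whose column is constant with no existing features yields an
    uninformative model and an AUC of 0.5.
    """
    cand = match_counts(subset_profiles.values[:, pattern.mark, :], pattern)
    X = np.column_stack([existing, cand]) if existing.size else cand[:, None].astype(float)
    if np.all(np.ptp(X, axis=0) == 0):
        return 0.5
    booster = boosting.fit_booster(X, subset_labels, num_boost_round=booster_rounds,
                                   eta=shrinkage, seed=seed)
    scores = boosting.predict_proba(booster, X)
    if np.ptp(scores) == 0:
        return 0.5
    return auc(scores, subset_labels)


def _stratified_subset(rng: np.random.Generator, labels: np.ndarray, size: int) -> np.ndarray:
    """Indices of a class-balanced random subset of at most ``size`` genes."""
    size = min(size, labels.size)
    per_class = size // 2
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    take_pos = min(per_class, pos.size)
    take_neg = min(size - take_pos, neg.size)
    idx = np.concatenate([
        rng.choice(pos, size=take_pos, replace=False),
        rng.choice(neg, size=take_neg, replace=False),
    ])
    rng.shuffle(idx)
    return idx


def extract_features(
    profiles: ProfileSet,
    labels,
    config: ExtractionConfig | None = None,
) -> ExtractionResult:
    """Run the iterative PSO pattern search on the training set.

    Returns the accepted patterns in acceptance order, their full-training-set
    frequency matrix, and a per-round trace of the candidate and best AUCs.
    The best-AUC sequence over accepted rounds is non-decreasing by
    construction (acceptance requires strict improvement).
    """
    config = config or ExtractionConfig()
    labels = np.asarray(labels)
    if labels.size != profiles.n_genes:
        raise ValueError("labels length must match the number of profiles")
    if len(np.unique(labels)) != 2:
        raise ValueError("need both expression classes in the training set")

    master = np.random.SeedSequence(config.seed)
    accepted: list[Pattern] = []
    best_auc = 0.5
    stagnant = 0
    rows = []

    for rnd in range(1, config.max_rounds + 1):
        ss_subset, ss_pso, ss_boost = np.random.SeedSequence(
            entropy=master.entropy, spawn_key=(rnd,)
        ).spawn(3)
        rng = np.random.default_rng(ss_subset)
        idx = _stratified_subset(rng, labels, config.subset_size)
        sub_profiles = ProfileSet([profiles.gene_ids[i] for i in idx],
                                  profiles.values[idx], profiles.marks)
        sub_labels = labels[idx]
        existing = (
            build_feature_matrix(sub_profiles, accepted).to_numpy()
            if accepted else np.empty((idx.size, 0))
        )
        boost_seed = int(np.random.default_rng(ss_boost).integers(2**31))

        def objective(x: np.ndarray) -> float:
            pat = decode_particle(x)
            return -score_candidate(
                pat, existing, sub_profiles, sub_labels,
                config.booster_rounds, config.shrinkage, boost_seed,
            )

        # the candidate landscape is multimodal (a broad plateau of diffuse
        # low-cutoff patterns next to a narrow basin of crisp ones), so each
        # round may run several independent swarms and keep the best
        pso_rng = np.random.default_rng(ss_pso)
        result = None
        n_evals = 0
        for _ in range(max(1, config.pso_restarts)):
            control = PSOControl(
                swarm_size=config.pso_swarm_size,
                max_iter=config.pso_max_iter,
                max_stagnant=config.pso_max_stagnant,
                value_to_reach=-config.auc_target,
                seed=int(pso_rng.integers(2**31)),
            )
            candidate = pso_minimize(objective, LOWER, UPPER, control)
            n_evals += candidate.n_evals
            if result is None or candidate.fun < result.fun:
                result = candidate
            if (config.auc_target is not None
                    and -result.fun >= config.auc_target):
                break
        round_auc = -result.fun
        accepted_this = round_auc > best_auc
        if accepted_this:
            accepted.append(decode_particle(result.x))
            best_auc = round_auc
            stagnant = 0
        else:
            stagnant += 1
        rows.append({
            "round": rnd, "candidate_auc": round_auc, "accepted": accepted_this,
            "best_auc": best_auc, "n_evals": n_evals,
        })
        logger.info("round %d: candidate AUC %.4f (%s), best %.4f", rnd, round_auc,
                    "accepted" if accepted_this else "rejected", best_auc)
        if best_auc >= config.auc_target or stagnant >= config.max_stagnant_rounds:
            break

    if not accepted:
        warnings.warn("no pattern improved the training AUC; returning an empty "
                      "feature set", stacklevel=2)
    for k, p in enumerate(accepted):
        p.name = f"pattern_{k}"
    feature_matrix = build_feature_matrix(profiles, accepted)
    return ExtractionResult(
        patterns=accepted,
        feature_matrix=feature_matrix,
        trace=pd.DataFrame(rows),
        best_auc=best_auc,
    )
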