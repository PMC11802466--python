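"""Standard Particle Swarm Optimization, 2007 variant (SPSO2007).

A box-constrained global minimizer used both for pattern search and for
booster hyperparameter tuning.  Defaults follow the published SPSO2007
constants: swarm size S = 10 + floor(2*sqrt(D)), inertia w = 1/(2 ln 2),
acceleration c = 0.5 + ln 2 for the cognitive and social terms alike, and
K = 3 informants per particle with the informant links re-drawn after every
iteration that fails to improve the global best.  Positions violating the box
are clamped to the boundary with the offending velocity component zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

W_DEFAULT = 1.0 / (2.0 * math.log(2.0))
C_DEFAULT = 0.5 + math.log(2.0)


@dataclass
class PSOControl:
    """Swarm-behaviour knobs; ``swarm_size=None`` uses 10 + floor(2*sqrt(D))."""

    swarm_size: int | None = None
    w: float = W_DEFAULT
    c: float = C_DEFAULT
    k_informants: int = 3
    max_iter: int = 100
    max_stagnant: int = 20
    value_to_reach: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size is not None and self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if min(self.k_informants, self.max_iter, self.max_stagnant) < 1:
            raise ValueError("k_informants, max_iter, max_stagnant must be positive")


@dataclass
class PSOResult:
    x: np.ndarray
    fun: float
    n_evals: int
    n_iter: int
    trace: list[float] = field(default_factory=list)


class ObjectiveError(RuntimeError):
    """Objective raised inside the swarm loop; carries iteration/particle context."""


def pso_minimize(objective, lower, upper, control: PSOControl | None = None,
                 x0: np.ndarray | None = None) -> PSOResult:
    """Minimize ``objective`` over the box [lower, upper] with SPSO2007.

    Parameters
    ----------
    objective
        Callable mapping a D-vector to a finite float.
    lower, upper
        Box bounds, elementwise ``lower < upper``.
    control
        :class:`PSOControl`; defaults are the SPSO2007 constants.
    x0
        Optional start position for the first particle (e.g. a box-centre
        reference point); must lie inside the box.

    Returns
    -------
    PSOResult
        Best position, best value, number of objective evaluations, number of
        iterations, and the per-iteration best-value trace (monotone
        non-increasing).
    """
    control = control or PSOControl()
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or lower.ndim != 1:
        raise ValueError("lower/upper must be 1-D of equal length")
    if not (lower < upper).all():
        raise ValueError("need lower < upper elementwise")
    D = lower.size
    S = control.swarm_size or (10 + int(2.0 * math.sqrt(D)))
    rng = np.random.default_rng(control.seed)
    span = upper - lower

    X = lower + rng.uniform(size=(S, D)) * span
    if x0 is not None:
        x0 = np.asarray(x0, dtype=float)
        if ((x0 < lower) | (x0 > upper)).any():
            raise ValueError("x0 outside the box")
        X[0] = x0
    V = (lower + rng.uniform(size=(S, D)) * span - X) / 2.0

    def evaluate(x: np.ndarray, it: int, p: int) -> float:
        try:
            return float(objective(x))
        except Exception as err:  # add swarm context, keep the cause
            raise ObjectiveError(
                f"objective failed at iteration {it}, particle {p}, x={x!r}"
            ) from err

    n_evals = 0
    pval = np.empty(S)
    for p in range(S):
        pval[p] = evaluate(X[p], 0, p)
        n_evals += 1
    pbest = X.copy()
    gbest = int(np.argmin(pval))

    def draw_links() -> np.ndarray:
        # informs[i, j] True when particle i informs particle j; self-links always on
        informs = np.zeros((S, S), dtype=bool)
        np.fill_diagonal(informs, True)
        for i in range(S):
            informs[i, rng.integers(0, S, size=control.k_informants)] = True
        return informs

    informs = draw_links()
    trace = [float(pval[gbest])]
    stagnant = 0
    it = 0
    while it < control.max_iter:
        it += 1
        improved = False
        for p in range(S):
            informants = np.flatnonzero(informs[:, p])
            g = informants[np.argmin(pval[informants])]
            r1 = rng.uniform(0.0, control.c, size=D)
            V[p] = control.w * V[p] + r1 * (pbest[p] - X[p])
            if g != p:  # particle that is its own best informant keeps only the cognitive pull
                r2 = rng.uniform(0.0, control.c, size=D)
                V[p] += r2 * (pbest[g] - X[p])
            X[p] += V[p]
            low_mask = X[p] < lower
            high_mask = X[p] > upper
            X[p] = np.where(low_mask, lower, np.where(high_mask, upper, X[p]))
            V[p] = np.where(low_mask | high_mask, 0.0, V[p])

            f = evaluate(X[p], it, p)
            n_evals += 1
            if f < pval[p]:
                better_global = f < pval[gbest]
                pval[p] = f
                pbest[p] = X[p].copy()
                if better_global:
                    gbest = p
                    improved = True
        trace.append(float(pval[gbest]))
        if improved:
            stagnant = 0
        else:
            stagnant += 1
            informs = draw_links()
        if control.value_to_reach is not None and pval[gbest] <= control.value_to_reach:
            break
        if stagnant >= control.max_stagnant:
            break
    return PSOResult(x=pbest[gbest].copy(), fun=float(pval[gbest]),
                     n_evals=n_evals, n_iter=it, trace=trace)
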