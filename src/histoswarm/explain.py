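"""Per-prediction log-odds decomposition and promoter-bin importance maps.

The decomposition follows the classic cover-weighted tree walk: for each tree
every internal node is assigned the cover-weighted mean of the leaf values
beneath it (its "expected value"); walking a gene's decision path from root
to leaf, the change in expected value at each step is credited to the step's
split feature.  The intercept is the booster's base logit plus the sum of
root expected values, and intercept + contributions equals the prediction's
logit exactly, so the contributions are an additive log-odds account of one
prediction.

Aggregating |contribution| over genes and models, and spreading each
pattern's share uniformly over the bins its matches cover, yields a
marks x bins relative-importance map of the promoter region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .evaluation import BoosterModel
from .patterns import Pattern, match_positions

logger = logging.getLogger(__name__)


@dataclass
class Explanation:
    """Additive log-odds account of one gene's prediction."""

    gene_id: str | None
    intercept: float
    contributions: np.ndarray  # one log-odds value per feature
    probability: float

    @property
    def logit(self) -> float:
        return float(self.intercept + self.contributions.sum())


class _TreeEnsemble:
    """Parsed tree table of a booster with per-node expected leaf values."""

    def __init__(self, model: BoosterModel):
        self.feature_index = {n: i for i, n in enumerate(model.feature_names)}
        self.base_logit = model.base_logit()
        try:
            df = model.booster.trees_to_dataframe()
        except ValueError:
            df = pd.DataFrame(columns=["Tree"])
        self.trees = []
        for _, tdf in df.groupby("Tree"):
            nodes = {}
            for _, r in tdf.iterrows():
                nodes[r["ID"]] = {
                    "leaf": r["Feature"] == "Leaf",
                    "feature": r["Feature"],
                    "split": r["Split"],
                    "yes": r["Yes"],
                    "no": r["No"],
                    "value": r["Gain"],  # leaf output value for leaves
                    "cover": r["Cover"],
                }
            root = f"{int(tdf['Tree'].iloc[0])}-0"
            self._fill_expected(nodes, root)
            self.trees.append((root, nodes))

    def _fill_expected(self, nodes: dict, node_id: str) -> float:
        node = nodes[node_id]
        if node["leaf"]:
            node["expected"] = float(node["value"])
        else:
            ey = self._fill_expected(nodes, node["yes"])
            en = self._fill_expected(nodes, node["no"])
            cy = nodes[node["yes"]]["cover"]
            cn = nodes[node["no"]]["cover"]
            node["expected"] = float((cy * ey + cn * en) / (cy + cn))
        return node["expected"]

    def decompose(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """(intercept, per-feature contributions) for one feature vector."""
        contrib = np.zeros(len(self.feature_index))
        intercept = self.base_logit
        for root, nodes in self.trees:
            node_id = root
            intercept += nodes[root]["expected"]
            while not nodes[node_id]["leaf"]:
                node = nodes[node_id]
                fi = self.feature_index[node["feature"]]
                child = node["yes"] if x[fi] < node["split"] else node["no"]
                contrib[fi] += nodes[child]["expected"] - node["expected"]
                node_id = child
        return intercept, contrib


def decompose_prediction(model: BoosterModel, feature_vector,
                         gene_id: str | None = None,
                         _ensemble: _TreeEnsemble | None = None) -> Explanation:
    """Break one prediction into an intercept plus per-feature log-odds contributions.

    The identity sigmoid(intercept + sum(contributions)) == predicted
    probability holds to floating-point precision.
    """
    x = np.asarray(feature_vector, dtype=float)
    if x.shape != (len(model.patterns),):
        raise ValueError(
            f"feature vector has length {x.size}, model expects {len(model.patterns)}"
        )
    ens = _ensemble or _TreeEnsemble(model)
    intercept, contrib = ens.decompose(x)
    prob = float(scipy.special.expit(intercept + contrib.sum()))
    return Explanation(gene_id=gene_id, intercept=intercept,
                       contributions=contrib, probability=prob)


def explain_genes(model: BoosterModel, F: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Decompose every row of a feature matrix.

    Returns (contributions DataFrame aligned to F, shared intercept).
    """
    ens = _TreeEnsemble(model)
    out = np.zeros((len(F), len(model.patterns)))
    intercept = ens.base_logit + sum(nodes[root]["expected"] for root, nodes in ens.trees)
    X = F.to_numpy(dtype=float)
    for i in range(len(F)):
        _, out[i] = ens.decompose(X[i])
    return pd.DataFrame(out, index=F.index, columns=model.feature_names), intercept


def bin_importance(
    cases: list[tuple[BoosterModel, pd.DataFrame, "ProfileSet"]],
    n_marks: int = 5,
    n_bins: int = 200,
) -> np.ndarray:
    """Relative promoter-bin importance aggregated over models and genes.

    ``cases`` pairs each model with the per-gene contribution matrix from
    :func:`explain_genes` and the profiles those genes were scored on.  Each
    pattern's absolute contribution for a gene is spread uniformly over the
    bins covered by the pattern's matches in that gene's profile; patterns
    with zero matches in a gene contribute nothing there.  The aggregated
    map is normalized to sum to one.
    """
    heat = np.zeros((n_marks, n_bins))
    for model, contribs, profiles in cases:
        for k, pattern in enumerate(model.patterns):
            col = contribs.iloc[:, k].to_numpy()
            L = pattern.length
            for gi, gene_id in enumerate(contribs.index):
                c = abs(col[gi])
                if c == 0:
                    continue
                starts = match_positions(profiles.row(gene_id, pattern.mark), pattern)
                if starts.size == 0:
                    continue
                w = c / (starts.size * L)
                for s in starts:
                    heat[pattern.mark, s:s + L] += w
    total = heat.sum()
    if total == 0:
        raise ValueError("no non-zero contributions: importance map undefined")
    return heat / total


def region_importance(heat: np.ndarray, mark: int | None = None,
                      lo_label: int | None = None, hi_label: int | None = None) -> float:
    """Share of total importance in a bin-label range (inclusive), optionally one mark."""
    from .signal_io import bin_index
    n_bins = heat.shape[1]
    sel = heat if mark is None else heat[[mark]]
    lo = 0 if lo_label is None else bin_index(lo_label, n_bins)
    hi = n_bins - 1 if hi_label is None else bin_index(hi_label, n_bins)
    return float(sel[:, lo:hi + 1].sum() / heat.sum())


def contribution_frequency_correlation(
    contribs: pd.DataFrame,
    feature_matrix: pd.DataFrame,
    patterns: list[Pattern],
    mark_names: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation between pattern frequency and signed contribution, per pattern.

    Activating patterns (enriched in high-expression genes) correlate
    positively, repressive ones negatively.  Patterns with a constant
    frequency column are skipped (logged) since their correlation is
    undefined.  Returns (per-pattern table, per-mark mean/sd/count summary).
    """
    rows = []
    for k, pattern in enumerate(patterns):
        freq = feature_matrix.iloc[:, k].to_numpy(dtype=float)
        contrib = contribs.iloc[:, k].to_numpy(dtype=float)
        if np.ptp(freq) == 0 or np.ptp(contrib) == 0 or freq.size < 3:
            logger.info("skipping pattern %d: constant frequency or contribution", k)
            continue
        rho = scipy.stats.pearsonr(freq, contrib).statistic
        rows.append({"pattern": k, "mark": pattern.mark, "rho": float(rho)})
    per_pattern = pd.DataFrame(rows, columns=["pattern", "mark", "rho"])
    if len(per_pattern):
        per_mark = (per_pattern.groupby("mark")["rho"]
                    .agg(mean="mean", sd="std", n="count").reset_index())
    else:
        per_mark = pd.DataFrame(columns=["mark", "mean", "sd", "n"])
    if mark_names is not None and len(per_mark):
        per_mark.insert(1, "mark_name", [mark_names[m] for m in per_mark["mark"]])
    return per_pattern, per_mark


def plot_waterfall(explanation: Explanation, feature_names: list[str],
                   counts=None, ax=None):
    """Waterfall of cumulative log-odds contributions, ordered by |contribution|."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    order = np.argsort(-np.abs(explanation.contributions))
    labels = ["intercept"]
    for i in order:
        lab = feature_names[i]
        if counts is not None:
            lab += f" (n={int(counts[i])})"
        labels.append(lab)
    steps = np.concatenate([[explanation.intercept],
                            explanation.contributions[order]])
    cum = np.cumsum(steps)
    bottoms = np.concatenate([[0.0], cum[:-1]])
    colors = ["grey"] + ["tab:green" if s > 0 else "tab:red" for s in steps[1:]]
    ax.bar(range(len(steps)), steps, bottom=bottoms, color=colors)
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xticks(range(len(steps)))
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("cumulative log-odds")
    ax.set_title(f"{explanation.gene_id or 'gene'}: "
                 f"P(high) = {explanation.probability:.3f}")
    return ax
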