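"""Histone-modification patterns and sliding-window Pearson matching.

A pattern is a short shape template (2-8 values in [0, 1]) on one histone
mark plus a correlation cutoff tau in [0.5, 0.99].  Its frequency in a gene's
binned profile is the number of window start positions whose Pearson
correlation with the shape strictly exceeds tau.  Because Pearson r is
invariant under positive affine transforms of the window, the frequency is a
scale-invariant readout of local signal shape, not of signal amount.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .signal_io import ProfileSet

MIN_LENGTH = 2
MAX_LENGTH = 8
MIN_CUTOFF = 0.5
MAX_CUTOFF = 0.99


@dataclass
class Pattern:
    """A one-mark shape template with a per-pattern correlation cutoff."""

    mark: int
    shape: np.ndarray
    cutoff: float
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.shape = np.asarray(self.shape, dtype=float)
        if self.shape.ndim != 1 or not MIN_LENGTH <= self.shape.size <= MAX_LENGTH:
            raise ValueError(
                f"shape length must be {MIN_LENGTH}..{MAX_LENGTH}, got {self.shape.size}"
            )
        if ((self.shape < 0) | (self.shape > 1)).any():
            raise ValueError("shape values must lie in [0, 1]")
        if np.ptp(self.shape) == 0:
            raise ValueError("shape must not be constant (undefined correlation)")
        if not MIN_CUTOFF <= self.cutoff <= MAX_CUTOFF:
            raise ValueError(
                f"cutoff must lie in [{MIN_CUTOFF}, {MAX_CUTOFF}], got {self.cutoff}"
            )
        if self.mark < 0:
            raise ValueError("mark index must be non-negative")

    @property
    def length(self) -> int:
        return self.shape.size

    def to_dict(self) -> dict:
        return {"mark": int(self.mark), "shape": [float(v) for v in self.shape],
                "cutoff": float(self.cutoff), "name": self.name}

    @classmethod
    def from_dict(cls, d: dict) -> "Pattern":
        return cls(mark=int(d["mark"]), shape=np.asarray(d["shape"], float),
                   cutoff=float(d["cutoff"]), name=d.get("name"))


def save_patterns(patterns: list[Pattern], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in patterns], fh, indent=1)


def load_patterns(path) -> list[Pattern]:
    with open(path) as fh:
        return [Pattern.from_dict(d) for d in json.load(fh)]


def sliding_correlations(row: np.ndarray, shape: np.ndarray) -> np.ndarray:
    """Pearson r between every length-L window of ``row`` and ``shape``.

    Returns one value per window start (len(row)-L+1 values); windows with
    zero variance yield NaN.
    """
    return _batch_correlations(np.asarray(row, float)[None, :], shape)[0]


def _batch_correlations(rows: np.ndarray, shape: np.ndarray) -> np.ndarray:
    shape = np.asarray(shape, dtype=float)
    L = shape.size
    if rows.shape[1] < L:
        raise ValueError(f"profile of length {rows.shape[1]} shorter than pattern ({L})")
    sc = shape - shape.mean()
    ssc = float(sc @ sc)
    if ssc == 0:
        raise ValueError("constant shape has undefined correlation")
    W = sliding_window_view(rows, L, axis=1)            # (n, P, L)
    Wc = W - W.mean(axis=-1, keepdims=True)
    num = Wc @ sc
    den = np.sqrt((Wc * Wc).sum(axis=-1) * ssc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def match_positions(row: np.ndarray, pattern: Pattern) -> np.ndarray:
    """Window start indices where r > cutoff (strict); zero-variance windows never match."""
    r = sliding_correlations(row, pattern.shape)
    with np.errstate(invalid="ignore"):
        return np.flatnonzero(r > pattern.cutoff)


def match_count(row: np.ndarray, pattern: Pattern) -> int:
    """Pattern frequency in one profile row: the number of matching window positions.

    Overlapping matches each count; matching is strict (r > cutoff).
    """
    return int(match_positions(row, pattern).size)


def match_counts(rows: np.ndarray, pattern: Pattern) -> np.ndarray:
    """Vectorized :func:`match_count` over a (n_genes, n_bins) row matrix."""
    r = _batch_correlations(np.asarray(rows, float), pattern.shape)
    with np.errstate(invalid="ignore"):
        return (r > pattern.cutoff).sum(axis=1).astype(int)


def feature_names(patterns: list[Pattern]) -> list[str]:
    return [p.name or f"pattern_{k}" for k, p in enumerate(patterns)]


def build_feature_matrix(profiles: ProfileSet, patterns: list[Pattern]) -> pd.DataFrame:
    """Genes x patterns table of match counts, columns in pattern acceptance order."""
    cols = {}
    for k, pat in enumerate(patterns):
        if pat.mark >= profiles.n_marks:
            raise KeyError(
                f"pattern {k} needs mark index {pat.mark} but profiles carry "
                f"only {profiles.n_marks} marks ({', '.join(profiles.marks)})"
            )
        cols[feature_names(patterns)[k]] = match_counts(
            profiles.values[:, pat.mark, :], pat
        )
    return pd.DataFrame(cols, index=pd.Index(profiles.gene_ids, name="gene_id"),
                        dtype=float)
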