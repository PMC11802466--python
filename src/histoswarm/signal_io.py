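"""Signal input, TSS-centred binning, expression binarization and dataset splits.

Per-gene input is the mean ChIP-seq signal in 50-bp bins spanning 5000 bp up-
and downstream of the transcription start site (TSS): 200 bins for each of
five histone modifications.  Expression is binarized at the per-sample median
(label 1 = above-median, "high").  Genes are randomly partitioned into
train/validation/test with the larger remainder half going to validation.

Bin index convention: -100..-1 upstream, +1..+100 downstream of the TSS
(there is no bin 0).  Minus-strand profiles are orientation-normalized
(reversed) so that bin -100 is always 5' of the TSS in transcription
direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five histone modifications modelled, in canonical order.
DEFAULT_MARKS: tuple[str, ...] = (
    "H3K4me3",
    "H3K4me1",
    "H3K36me3",
    "H3K9me3",
    "H3K27me3",
)

DEFAULT_FLANK_BP = 5000
DEFAULT_BIN_BP = 50
DEFAULT_N_BINS = 2 * DEFAULT_FLANK_BP // DEFAULT_BIN_BP  # 200


def bin_label(index: int, n_bins: int = DEFAULT_N_BINS) -> int:
    """Map an array index 0..n_bins-1 to the signed bin label (-half..-1, +1..+half)."""
    half = n_bins // 2
    if not 0 <= index < n_bins:
        raise IndexError(f"bin index {index} outside 0..{n_bins - 1}")
    return index - half if index < half else index - half + 1


def bin_index(label: int, n_bins: int = DEFAULT_N_BINS) -> int:
    """Inverse of :func:`bin_label`."""
    half = n_bins // 2
    if label == 0 or not -half <= label <= half:
        raise IndexError(f"bin label {label} outside -{half}..-1, +1..+{half}")
    return label + half if label < 0 else label + half - 1


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's TSS anchor: id, chromosome, 0-based TSS coordinate, strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: TSS must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass
class ProfileSet:
    """Binned signal profiles for a set of genes.

    ``values`` has shape (n_genes, n_marks, n_bins); row order follows
    ``gene_ids``.  All values are finite and non-negative.
    """

    gene_ids: list[str]
    values: np.ndarray
    marks: tuple[str, ...] = DEFAULT_MARKS
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_genes, n_marks, n_bins)")
        n, m, _ = self.values.shape
        if n != len(self.gene_ids):
            raise ValueError("gene_ids length does not match values")
        if m != len(self.marks):
            raise ValueError("marks length does not match values")
        if not np.isfinite(self.values).all():
            raise ValueError("profile values must be finite")
        if (self.values < 0).any():
            raise ValueError("profile values must be non-negative")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids must be unique")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_marks(self) -> int:
        return len(self.marks)

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def mark_id(self, mark: int | str) -> int:
        if isinstance(mark, str):
            try:
                return self.marks.index(mark)
            except ValueError:
                raise KeyError(f"unknown mark {mark!r}; have {self.marks}") from None
        if not 0 <= mark < self.n_marks:
            raise KeyError(f"mark index {mark} outside 0..{self.n_marks - 1}")
        return mark

    def row(self, gene_id: str, mark: int | str) -> np.ndarray:
        """The 200-bin vector for one gene and one histone mark."""
        try:
            gi = self._index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None
        return self.values[gi, self.mark_id(mark)]

    def subset(self, gene_ids: list[str]) -> "ProfileSet":
        idx = [self._index[g] for g in gene_ids]
        return ProfileSet(list(gene_ids), self.values[idx].copy(), self.marks)

    def to_tsv(self, path) -> None:
        """Write a long-format table: gene_id, mark, bin_-100 .. bin_+100."""
        cols = [f"bin_{bin_label(i, self.n_bins):+d}" for i in range(self.n_bins)]
        frames = []
        for mi, mark in enumerate(self.marks):
            df = pd.DataFrame(self.values[:, mi, :], columns=cols)
            df.insert(0, "mark", mark)
            df.insert(0, "gene_id", self.gene_ids)
            frames.append(df)
        pd.concat(frames).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProfileSet":
        df = pd.read_csv(path, sep="\t")
        marks = tuple(dict.fromkeys(df["mark"]))
        gene_ids = list(dict.fromkeys(df["gene_id"]))
        bin_cols = [c for c in df.columns if c.startswith("bin_")]
        values = np.zeros((len(gene_ids), len(marks), len(bin_cols)))
        gidx = {g: i for i, g in enumerate(gene_ids)}
        for mi, mark in enumerate(marks):
            sub = df[df["mark"] == mark]
            rows = [gidx[g] for g in sub["gene_id"]]
            values[rows, mi, :] = sub[bin_cols].to_numpy(dtype=float)
        return cls(gene_ids, values, marks)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test gene-id partitions plus the seed used."""

    train_ids: list[str]
    valid_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.valid_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("train/valid/test sets must be pairwise disjoint")
        if not 0 <= len(self.valid_ids) - len(self.test_ids) <= 1:
            raise ValueError("|valid| - |test| must be 0 or 1")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#seed={self.seed}\n")
            fh.write("gene_id\tsubset\n")
            for name, ids in (("train", self.train_ids),
                              ("valid", self.valid_ids),
                              ("test", self.test_ids)):
                for g in ids:
                    fh.write(f"{g}\t{name}\n")

    @classmethod
    def from_tsv(cls, path) -> "DatasetSplit":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#seed="):
                raise ValueError("split file must start with a '#seed=' line")
            seed = int(header.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t")
        groups = {k: list(v) for k, v in df.groupby("subset")["gene_id"]}
        return cls(groups.get("train", []), groups.get("valid", []),
                   groups.get("test", []), seed)


def bin_signal(
    track,
    annotation: GeneAnnotation,
    flank_bp: int = DEFAULT_FLANK_BP,
    bin_bp: int = DEFAULT_BIN_BP,
) -> np.ndarray:
    """Bin one mark's signal around a TSS into fixed-width mean-signal bins.

    Parameters
    ----------
    track
        Interval signal for the gene's chromosome: an (n, 3) array-like of
        0-based half-open ``(start, end, value)`` rows (bedGraph convention).
        Bases not covered by any interval read as signal 0.
    annotation
        The gene whose TSS anchors the window.
    flank_bp, bin_bp
        Window half-width and bin width in bp; ``flank_bp`` must be divisible
        by ``bin_bp``.

    Returns
    -------
    numpy.ndarray
        ``2 * flank_bp / bin_bp`` per-bin mean signals, oriented so the first
        bin is the most 5' in transcription direction (reversed for minus
        strand).
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be divisible by bin_bp")
    arr = np.asarray(track, dtype=float)
    if arr.size == 0:
        arr = arr.reshape(0, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("track must be (n, 3): start, end, value")
    if (arr[:, 2] < 0).any():
        raise ValueError("negative signal values in track")

    win_start = annotation.tss - flank_bp
    win_len = 2 * flank_bp
    if win_start < 0:
        warnings.warn(
            f"{annotation.gene_id}: window extends {-win_start} bp past the "
            "chromosome start; missing bases read as 0",
            stacklevel=2,
        )
    base = np.zeros(win_len)
    s = np.clip(arr[:, 0] - win_start, 0, win_len).astype(int)
    e = np.clip(arr[:, 1] - win_start, 0, win_len).astype(int)
    for si, ei, v in zip(s, e, arr[:, 2]):
        if ei > si:
            base[si:ei] = v
    bins = base.reshape(-1, bin_bp).mean(axis=1)
    if annotation.strand == "-":
        bins = bins[::-1].copy()
    return bins


def bin_profiles(
    tracks: dict[str, dict[str, np.ndarray]],
    annotations: list[GeneAnnotation],
    marks: tuple[str, ...] = DEFAULT_MARKS,
    flank_bp: int = DEFAULT_FLANK_BP,
    bin_bp: int = DEFAULT_BIN_BP,
) -> ProfileSet:
    """Bin all marks for all genes: ``tracks[mark][chrom]`` -> interval array."""
    n_bins = 2 * flank_bp // bin_bp
    values = np.zeros((len(annotations), len(marks), n_bins))
    empty = np.zeros((0, 3))
    for gi, ann in enumerate(annotations):
        for mi, mark in enumerate(marks):
            if mark not in tracks:
                raise KeyError(f"no track for mark {mark!r}")
            chrom_track = tracks[mark].get(ann.chrom, empty)
            values[gi, mi] = bin_signal(chrom_track, ann, flank_bp, bin_bp)
    return ProfileSet([a.gene_id for a in annotations], values, marks)


def binarize_expression(values) -> np.ndarray:
    """Binary expression labels at the median: 1 = above median.

    Genes whose value equals the median are tie-broken by stable input order
    (promoted to the high class first-come-first-served) so that the two
    classes differ in size by at most one gene.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of at least 2 expression values")
    if not np.isfinite(v).all():
        raise ValueError("expression values must be finite")
    if (v < 0).any():
        raise ValueError("expression values must be non-negative")
    if np.ptp(v) == 0:
        raise ValueError("all expression values identical: no meaningful median split")
    med = np.median(v)
    labels = (v > med).astype(int)
    ties = np.flatnonzero(v == med)
    i = 0
    # lows can outnumber highs when values sit exactly at the median
    while (v.size - 2 * labels.sum()) > 1 and i < ties.size:
        labels[ties[i]] = 1
        i += 1
    assert abs(int(v.size) - 2 * int(labels.sum())) <= 1
    return labels


def split_genes(gene_ids, n_train: int = 6600, seed: int = 0) -> DatasetSplit:
    """Random train/validation/test split with the larger remainder half to validation.

    ``n_train`` must be even: with median-binarized labels an even training
    set is what keeps the two classes exactly balanced during training.
    """
    ids = list(gene_ids)
    if n_train % 2 != 0:
        raise ValueError(
            "n_train must be even: balanced high/low training labels require "
            "an even number of training genes"
        )
    if not 0 < n_train < len(ids):
        raise ValueError(f"n_train={n_train} must be in (0, {len(ids)})")
    perm = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    rest = shuffled[n_train:]
    n_valid = (len(rest) + 1) // 2
    return DatasetSplit(
        train_ids=shuffled[:n_train],
        valid_ids=rest[:n_valid],
        test_ids=rest[n_valid:],
        seed=seed,
    )


def read_gene_annotation(path, fmt: str = "auto", one_based: bool = False) -> list[GeneAnnotation]:
    """Read gene TSS annotations from BED6 or a (gene_id, chrom, tss, strand) TSV.

    For BED6 the TSS is chromStart for '+' genes and chromEnd-1 for '-' genes
    (0-based half-open).  Set ``one_based`` for 1-based TSV coordinates.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if fmt == "auto":
        fmt = "bed6" if df.shape[1] >= 6 and str(df.iloc[0, 5]) in "+-" else "tsv"
    anns = []
    if fmt == "bed6":
        for _, r in df.iterrows():
            strand = str(r[5])
            tss = int(r[1]) if strand == "+" else int(r[2]) - 1
            anns.append(GeneAnnotation(str(r[3]), str(r[0]), tss, strand))
    elif fmt == "tsv":
        for _, r in df.iterrows():
            tss = int(r[2]) - (1 if one_based else 0)
            anns.append(GeneAnnotation(str(r[0]), str(r[1]), tss, str(r[3])))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    ids = [a.gene_id for a in anns]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in annotation file")
    return anns


def read_expression(path) -> pd.Series:
    """Read a 2-column (gene_id, value) TSV into a Series indexed by gene_id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_id", "value"])
    return pd.Series(df["value"].to_numpy(float), index=df["gene_id"].astype(str))


def read_bedgraph(path) -> dict[str, np.ndarray]:
    """Read a 4-column bedGraph into per-chromosome (start, end, value) arrays."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return {
        chrom: sub[["start", "end", "value"]].to_numpy(float)
        for chrom, sub in df.groupby("chrom")
    }
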