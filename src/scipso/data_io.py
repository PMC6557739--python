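"""Reading, writing and splitting labelled expression matrices.

The canonical in-memory orientation is samples x genes.  Microarray
text files are frequently distributed genes x samples, so the loader
takes an explicit ``orientation`` argument instead of guessing —
silent transposition is the classic bug in this domain.

Gene indices are 0-based everywhere inside the library; user-facing
reports print 1-based serial numbers, the convention used in the
microarray gene-selection literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SplitSpec",
    "load_dataset",
    "write_dataset",
    "split_dataset",
    "write_ranked_genes",
]


@dataclass
class ExpressionDataset:
    """A labelled samples x genes expression matrix.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Real-valued expression levels; must be finite.
    gene_ids : list of str
        Unique gene identifiers, one per column.
    labels : ndarray of int
        Class label per sample, remapped to ``1..c`` on construction.
    label_names : dict, optional
        Mapping from the internal integer class back to the original
        label as it appeared in the source file.
    """

    values: np.ndarray
    gene_ids: list[str]
    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.validate()

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, g = self.values.shape
        if len(self.gene_ids) != g:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {g} expression columns"
            )
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if self.labels.shape != (n,):
            raise ValueError("one label per sample is required")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite expression value at sample {i + 1}, gene "
                f"{self.gene_ids[j]!r} (column {j + 1})"
            )
        classes = np.unique(self.labels)
        c = classes.max() if classes.size else 0
        if c < 2 or not np.array_equal(classes, np.arange(1, c + 1)):
            raise ValueError("labels must cover the contiguous range 1..c with c >= 2")
        counts = np.bincount(self.labels, minlength=c + 1)[1:]
        if counts.min() < 2:
            small = int(np.argmin(counts)) + 1
            raise ValueError(
                f"class {small} has {counts.min()} sample(s); every class needs "
                "at least 2 for per-class standard deviations"
            )


@dataclass(frozen=True)
class SplitSpec:
    """A train/test partition of sample indices, stratified by class."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_indices, dtype=int)
        te = np.asarray(self.test_indices, dtype=int)
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)
        if np.intersect1d(tr, te).size:
            raise ValueError("train and test indices overlap")


def _remap_labels(raw: pd.Series) -> tuple[np.ndarray, dict[int, str]]:
    """Map arbitrary label values onto 1..c, keeping the originals."""
    try:
        numeric = raw.astype(int)
        if not (numeric == raw.astype(float)).all():
            raise ValueError
        order = sorted(numeric.unique())
        mapping = {orig: i + 1 for i, orig in enumerate(order)}
        labels = numeric.map(mapping).to_numpy()
    except (ValueError, TypeError):
        order = sorted(raw.astype(str).unique())
        mapping = {orig: i + 1 for i, orig in enumerate(order)}
        labels = raw.astype(str).map(mapping).to_numpy()
    names = {v: str(k) for k, v in mapping.items()}
    return labels, names


def load_dataset(
    path,
    label_column: str,
    orientation: str = "samples-by-genes",
    sep: str | None = None,
) -> ExpressionDataset:
    """Load a delimited expression matrix with a header row.

    Parameters
    ----------
    path : path-like
        CSV/TSV file.  The delimiter is sniffed from the extension
        unless ``sep`` is given.
    label_column : str
        Name of the column (samples-by-genes) or row (genes-by-samples)
        holding the class labels.
    orientation : {"samples-by-genes", "genes-by-samples"}
        Layout of the file.  Genes-by-samples input is transposed to the
        canonical samples x genes orientation.
    """
    if orientation not in ("samples-by-genes", "genes-by-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes-by-samples":
        frame = frame.T
    if label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels_raw = frame[label_column]
    expr = frame.drop(columns=[label_column])
    values = expr.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric or missing expression value at sample "
            f"{expr.index[i]!r}, gene {expr.columns[j]!r}"
        )
    labels, names = _remap_labels(labels_raw)
    return ExpressionDataset(
        values=values,
        gene_ids=list(expr.columns),
        labels=labels,
        label_names=names,
    )


def write_dataset(ds: ExpressionDataset, path, sep: str | None = None) -> None:
    """Write a dataset in the samples-by-genes layout `load_dataset` reads."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.DataFrame(
        ds.values,
        columns=ds.gene_ids,
        index=[f"s{i + 1}" for i in range(ds.n_samples)],
    )
    frame.insert(0, "label", ds.labels)
    frame.to_csv(path, sep=sep, index=True, index_label="sample_id")


def split_dataset(
    ds: ExpressionDataset, train_fraction: float, seed: int
) -> SplitSpec:
    """Stratified train/test split, deterministic given ``seed``.

    Per-class training counts are apportioned by the largest-remainder
    rule so the overall training size equals ``round(train_fraction * n)``
    whenever the class structure permits it.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = ds.n_samples
    target = int(round(train_fraction * n))
    classes = np.arange(1, ds.n_classes + 1)
    counts = np.array([(ds.labels == c).sum() for c in classes])
    ideal = train_fraction * counts
    take = np.floor(ideal).astype(int)
    remainder = ideal - take
    short = target - take.sum()
    if short > 0:
        for c in np.argsort(-remainder)[:short]:
            take[c] += 1
    # a class absent from training makes per-class statistics undefined
    if (take < 1).any():
        absent = int(np.argmin(take)) + 1
        raise ValueError(
            f"train_fraction={train_fraction} leaves class {absent} without "
            "training samples"
        )
    take = np.minimum(take, counts)
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for c, k in zip(classes, take):
        idx = np.flatnonzero(ds.labels == c)
        idx = rng.permutation(idx)
        train.append(idx[:k])
        test.append(idx[k:])
    tr = np.sort(np.concatenate(train))
    te = np.sort(np.concatenate(test))
    if te.size == 0:
        raise ValueError("train_fraction leaves the test split empty")
    return SplitSpec(train_indices=tr, test_indices=te, seed=seed)


def write_ranked_genes(path, rows) -> None:
    """Write a ranked gene list as TSV.

    ``rows`` is an iterable of ``(gene_index, gene_id, score)`` with
    0-based indices; serial numbers in the file are printed 1-based.
    """
    frame = pd.DataFrame(
        [(r + 1, idx + 1, gid, score) for r, (idx, gid, score) in enumerate(rows)],
        columns=["rank", "serial", "gene_id", "score"],
    )
    frame.to_csv(path, sep="\t", index=False)
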