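"""The three-level gene-pool cascade.

Level 1 ranks every gene by a class-separability statistic d(g) — the
information index to classification — and keeps the top 200-400.
Level 2 draws many random gene subsets from that pool, scores each by
ELM 5-fold cross-validation accuracy, deletes subsets below a survival
threshold theta_ac, and ranks the survivors (rank 1 = most accurate).
Level 3 turns subset ranks into per-gene scores — a gene's raw score
is the sum of reversed ranks (l_se - R_j + 1) over surviving subsets
that contain it — min-max normalizes the scores to [0, 1], and keeps
a small pool (default 40 genes) of top scorers for the swarm search.

The statistic d(g) sums, over every ordered pair of classes (j, k),

    0.5 * |mu_j - mu_k| / (sigma_j + sigma_k)
      + 0.5 * ln((sigma_j^2 + sigma_k^2) / (2 sigma_j sigma_k)),

so each unordered pair is counted twice.  The first term rewards mean
separation, the second penalizes unequal spreads; both are invariant
under positive affine rescaling of the gene's values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from scipso.elm import kfold_cv_accuracy, stratified_folds

__all__ = [
    "GenePool",
    "GeneSubset",
    "iic_scores",
    "build_first_level_pool",
    "generate_candidate_subsets",
    "screen_and_rank_subsets",
    "score_genes",
    "build_third_level_pool",
]

#: relative and absolute floors applied to per-class standard deviations
#: so d(g) stays finite for genes constant within a class
SIGMA_FLOOR_REL = 1e-6
SIGMA_FLOOR_ABS = 1e-12


@dataclass
class GenePool:
    """One level of the filter cascade.

    ``gene_indices`` are 0-based indices into the originating dataset,
    ordered best-first.  ``scores`` aligns with ``gene_indices`` and
    holds IIC values for level 1 and normalized subset scores for
    level 3.
    """

    level: int
    gene_indices: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=int)
        if len(np.unique(self.gene_indices)) != len(self.gene_indices):
            raise ValueError("gene pool indices must be unique")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != self.gene_indices.shape:
                raise ValueError("scores must align with gene_indices")

    def __len__(self) -> int:
        return len(self.gene_indices)


@dataclass
class GeneSubset:
    """A candidate gene subset with its cross-validated accuracy and rank."""

    gene_indices: tuple[int, ...]
    cv_accuracy: float | None = None
    rank: int | None = None
    draw_order: int = 0


def iic_scores(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Information-index-to-classification d(g) for every gene (column).

    Parameters
    ----------
    X : ndarray (n_samples, n_genes)
        Training-split expression values only; per-class statistics
        must never see test samples.
    labels : ndarray of int in 1..c, every class with >= 2 samples.

    Returns
    -------
    ndarray (n_genes,) of non-negative separability scores.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("at least two classes are required")
    mus = np.empty((classes.size, X.shape[1]))
    sds = np.empty_like(mus)
    for ci, c in enumerate(classes):
        block = X[labels == c]
        if block.shape[0] < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        mus[ci] = block.mean(axis=0)
        sds[ci] = block.std(axis=0, ddof=1)
    if (sds <= 0).any():
        warnings.warn(
            "zero within-class standard deviation encountered; applying "
            "variance floor"
        )
    global_sd = X.std(axis=0, ddof=1)
    floor = np.maximum(SIGMA_FLOOR_REL * global_sd, SIGMA_FLOOR_ABS)
    sds = np.maximum(sds, floor)

    d = np.zeros(X.shape[1])
    for j in range(classes.size):
        for k in range(classes.size):
            if j == k:
                continue
            sep = 0.5 * np.abs(mus[j] - mus[k]) / (sds[j] + sds[k])
            disp = 0.5 * np.log(
                (sds[j] ** 2 + sds[k] ** 2) / (2.0 * sds[j] * sds[k])
            )
            d += sep + disp
    return d


def build_first_level_pool(
    X: np.ndarray, labels: np.ndarray, n_top: int = 300
) -> GenePool:
    """Top ``n_top`` genes by d(g), best first; IIC ties break to the
    lower gene index."""
    n_genes = X.shape[1]
    if not 1 <= n_top <= n_genes:
        raise ValueError(f"n_top must lie in [1, {n_genes}]")
    d = iic_scores(X, labels)
    # stable sort on -d keeps lower indices first among ties
    order = np.argsort(-d, kind="stable")[:n_top]
    return GenePool(level=1, gene_indices=order, scores=d[order])


def generate_candidate_subsets(
    pool: GenePool,
    n_subsets: int,
    size_range: tuple[int, int] = (5, 15),
    seed: int = 0,
) -> list[GeneSubset]:
    """Draw random gene subsets from the first-level pool.

    Subset sizes are uniform over ``size_range``; genes are sampled
    without replacement within a subset.  Distinctness across draws is
    not enforced — duplicate subsets are harmless to the downstream
    ranking and scoring.
    """
    if len(pool) == 0:
        raise ValueError("gene pool is empty")
    lo, hi = size_range
    if lo < 1 or hi > len(pool) or lo > hi:
        raise ValueError(
            f"size_range {size_range} incompatible with pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    subsets = []
    for i in range(n_subsets):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(pool.gene_indices, size=size, replace=False)
        subsets.append(GeneSubset(gene_indices=tuple(int(g) for g in genes), draw_order=i))
    return subsets


def screen_and_rank_subsets(
    subsets: list[GeneSubset],
    X: np.ndarray,
    labels: np.ndarray,
    theta_ac: float = 0.80,
    k: int = 5,
    n_hidden: int | None = None,
    activation: str = "sigmoid",
    seed: int = 0,
) -> list[GeneSubset]:
    """Score each subset by ELM k-fold CV accuracy, delete those below
    ``theta_ac``, and rank the survivors 1..l_se.

    Rank 1 is the most accurate surviving subset.  Accuracy ties break
    to the smaller subset, then to draw order.  The fold assignment is
    shared across subsets so accuracies are comparable.
    """
    if not subsets:
        raise ValueError("no candidate subsets supplied")
    if not 0.0 <= theta_ac <= 1.0:
        raise ValueError("theta_ac must lie in [0, 1]")
    folds = stratified_folds(labels, k, seed)
    survivors = []
    for s in subsets:
        res = kfold_cv_accuracy(
            X[:, list(s.gene_indices)],
            labels,
            k=k,
            n_hidden=n_hidden,
            activation=activation,
            seed=seed,
            folds=folds,
        )
        s.cv_accuracy = res.mean_accuracy
        if s.cv_accuracy >= theta_ac:
            survivors.append(s)
    if not survivors:
        raise ValueError(
            f"no subset reached theta_ac={theta_ac}; lower the threshold"
        )
    survivors.sort(
        key=lambda s: (-s.cv_accuracy, len(s.gene_indices), s.draw_order)
    )
    for r, s in enumerate(survivors, start=1):
        s.rank = r
    return survivors


def score_genes(
    ranked: list[GeneSubset], n_genes: int
) -> np.ndarray:
    """Per-gene scores in [0, 1] from ranked surviving subsets.

    A gene's raw score is the sum of ``l_se - R_j + 1`` over surviving
    subsets j that contain it, i.e. membership weighted by reversed
    rank; min-max normalization maps the scores of genes appearing in
    at least one survivor onto [0, 1].  Genes in no surviving subset
    score 0.  If all member genes tie (degenerate min-max) they all
    map to 1.0.

    Returns an array of length ``n_genes`` indexed by gene.
    """
    if not ranked:
        raise ValueError("ranked subset list is empty")
    l_se = len(ranked)
    ranks = sorted(s.rank for s in ranked)
    if ranks != list(range(1, l_se + 1)):
        raise ValueError("subset ranks must be exactly 1..l_se")
    raw = np.zeros(n_genes)
    member = np.zeros(n_genes, dtype=bool)
    for s in ranked:
        w = l_se - s.rank + 1
        idx = list(s.gene_indices)
        raw[idx] += w
        member[idx] = True
    scores = np.zeros(n_genes)
    vals = raw[member]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        scores[member] = (raw[member] - lo) / (hi - lo)
    else:
        scores[member] = 1.0
    return scores


def build_third_level_pool(
    scores: np.ndarray,
    pool_size: int = 40,
    iic: np.ndarray | None = None,
) -> GenePool:
    """Keep the ``pool_size`` genes with the highest normalized scores.

    Ties break by higher IIC d(g) (when supplied), then lower index.
    If fewer than ``pool_size`` genes scored above zero, all positive
    scorers are kept and a warning issued.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    scores = np.asarray(scores, dtype=float)
    positive = np.flatnonzero(scores > 0)
    if len(positive) < pool_size:
        warnings.warn(
            f"only {len(positive)} genes scored > 0; returning all of them"
        )
        pool_size = len(positive)
    tiebreak = iic if iic is not None else np.zeros_like(scores)
    # lexsort: last key is primary
    order = np.lexsort((np.arange(len(scores)), -tiebreak, -scores))
    chosen = order[:pool_size]
    return GenePool(level=3, gene_indices=chosen, scores=scores[chosen])
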