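"""Synthetic expression matrices with planted informative genes.

The generator emulates the shape of classic diagnostic microarray
studies — tens of samples, thousands of genes, 2-5 classes — with a
known ground truth: ``k`` informative genes whose class means are
spaced ``delta`` within-class standard deviations apart, buried among
independent Gaussian noise genes.  The truth indices are shuffled into
random positions so positional bugs (off-by-one pool indexing and the
like) surface in recovery tests.

A Gaussian noise model keeps the class-separability statistic
analyzable (both of its terms have closed-form expectations under
normality); a log-normal toggle gives the skewed, strictly positive
intensities closer to real microarray scans.  Probe effects, batch
structure and array artifacts are deliberately not modelled.

``deceptive_landscape`` additionally plants decoy gene sets that
explain only a fraction of the samples, creating near-optimal local
optima for subset search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipso.data_io import ExpressionDataset

__all__ = ["SynthSpec", "generate", "deceptive_landscape"]


@dataclass
class SynthSpec:
    """Parameters of the planted-gene generator.

    Parameters
    ----------
    n_per_class : int or sequence of int
        Samples per class; an int means balanced classes.
    n_genes : int
        Total gene count G.
    n_informative : int
        Number of planted class-informative genes k.
    effect_size : float
        delta — spacing of adjacent class means in units of the
        within-class standard deviation.
    sigma : float
        Within-class standard deviation.
    n_classes : int
    distribution : {"normal", "lognormal"}
        Log-normal exponentiates the Gaussian field (class shifts
        become multiplicative).
    """

    n_per_class: int | tuple[int, ...] = 30
    n_genes: int = 2000
    n_informative: int = 10
    effect_size: float = 2.0
    sigma: float = 1.0
    n_classes: int = 2
    distribution: str = "normal"
    seed: int = 0

    def class_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_class, int):
            return (self.n_per_class,) * self.n_classes
        sizes = tuple(int(x) for x in self.n_per_class)
        if len(sizes) != self.n_classes:
            raise ValueError("n_per_class length must equal n_classes")
        return sizes

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("at least two classes are required")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("n_informative must lie in [0, n_genes]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if min(self.class_sizes()) < 2:
            raise ValueError("every class needs >= 2 samples")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError("distribution must be 'normal' or 'lognormal'")


def _labels_for(sizes: tuple[int, ...]) -> np.ndarray:
    return np.concatenate(
        [np.full(sz, c + 1, dtype=int) for c, sz in enumerate(sizes)]
    )


def generate(spec: SynthSpec) -> tuple[ExpressionDataset, np.ndarray]:
    """Generate a dataset and the (sorted) truth gene indices.

    Noise genes are Normal(0, sigma^2) independent of class; planted
    gene g in class j has mean ``(j - 1) * effect_size * sigma``.
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = spec.class_sizes()
    labels = _labels_for(sizes)
    n = len(labels)
    X = rng.normal(0.0, spec.sigma, size=(n, spec.n_genes))
    truth = np.sort(rng.choice(spec.n_genes, size=spec.n_informative, replace=False))
    shift = spec.effect_size * spec.sigma
    for g in truth:
        X[:, g] += (labels - 1) * shift
    if spec.distribution == "lognormal":
        X = np.exp(X)
    gene_ids = [f"g{j + 1:05d}" for j in range(spec.n_genes)]
    ds = ExpressionDataset(values=X, gene_ids=gene_ids, labels=labels)
    return ds, truth


def deceptive_landscape(
    spec: SynthSpec,
    n_decoys: int = 4,
    decoy_coverage: float = 0.8,
    hard_fraction: float = 0.15,
) -> tuple[ExpressionDataset, np.ndarray]:
    """A landscape with one fully predictive gene set and decoy sets.

    The truth set is ``spec.n_informative`` genes that jointly separate
    the classes.  Each decoy set (same size) carries class signal only
    on its own "covered" samples; a fixed ``hard_fraction`` of samples
    is covered by no decoy at all, so any decoy-only subset plateaus
    strictly below the truth subset's fitness — a local optimum for
    subset search.  With ``n_decoys=0`` this reduces to ``generate``.

    Returns the dataset and the truth gene indices.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    if n_decoys == 0:
        return generate(spec)
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = spec.class_sizes()
    labels = _labels_for(sizes)
    n = len(labels)
    k = spec.n_informative
    total_planted = k * (1 + n_decoys)
    if total_planted > spec.n_genes:
        raise ValueError("n_genes too small for the requested decoy sets")
    X = rng.normal(0.0, spec.sigma, size=(n, spec.n_genes))
    planted = rng.choice(spec.n_genes, size=total_planted, replace=False)
    truth = np.sort(planted[:k])
    shift = spec.effect_size * spec.sigma
    for g in truth:
        X[:, g] += (labels - 1) * shift

    # samples no decoy explains: class signal absent there for decoys
    n_hard = max(1, int(round(hard_fraction * n)))
    hard = rng.choice(n, size=n_hard, replace=False)
    soft = np.setdiff1d(np.arange(n), hard)
    for d in range(n_decoys):
        genes = planted[k * (d + 1) : k * (d + 2)]
        n_cov = int(round(decoy_coverage * len(soft)))
        covered = rng.choice(soft, size=n_cov, replace=False)
        for g in genes:
            X[covered, g] += (labels[covered] - 1) * shift
    if spec.distribution == "lognormal":
        X = np.exp(X)
    gene_ids = [f"g{j + 1:05d}" for j in range(spec.n_genes)]
    ds = ExpressionDataset(values=X, gene_ids=gene_ids, labels=labels)
    return ds, truth
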