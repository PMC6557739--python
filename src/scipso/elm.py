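"""Extreme learning machine (ELM) classification and cross-validated accuracy.

An ELM is a single-hidden-layer feedforward network whose input
weights and hidden biases are drawn at random once and never trained.
Writing H for the hidden-layer activation matrix and T for the one-hot
target matrix, the output weights are the minimum-norm least-squares
solution of H @ wo = T, obtained through the Moore-Penrose
pseudoinverse: wo = pinv(H) @ T.  With as many hidden neurons as
training samples and a full-rank H the network interpolates the
training set exactly.

The hidden layer here is drawn uniformly from [-1, 1] and the default
activation is the logistic sigmoid; both are the standard ELM choices
and are configurable.  Targets are encoded 0/1 one-hot, which pairs
with argmax decoding of the output neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ELMModel",
    "CVResult",
    "ACTIVATIONS",
    "train_elm",
    "predict",
    "stratified_folds",
    "kfold_cv_accuracy",
]

# Numerically stable activations; names are part of the config surface.
def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


ACTIVATIONS = {
    "sigmoid": _sigmoid,
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}

#: singular values below RCOND * s_max are truncated in the pseudoinverse
RCOND = 1e-10


@dataclass
class ELMModel:
    """A trained ELM: frozen random hidden layer plus solved output weights."""

    input_weights: np.ndarray  # (n_features, n_hidden)
    biases: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden, n_classes)
    activation: str
    n_classes: int
    seed: int

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[1]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[0]

    def hidden(self, X: np.ndarray) -> np.ndarray:
        g = ACTIVATIONS[self.activation]
        return g(X @ self.input_weights + self.biases)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.n_features} features, got {X.shape[1]}"
            )
        return self.hidden(X) @ self.output_weights

    def to_dict(self) -> dict:
        return {
            "input_weights": self.input_weights.tolist(),
            "biases": self.biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "activation": self.activation,
            "n_classes": self.n_classes,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ELMModel":
        return cls(
            input_weights=np.asarray(d["input_weights"], dtype=float),
            biases=np.asarray(d["biases"], dtype=float),
            output_weights=np.asarray(d["output_weights"], dtype=float),
            activation=d["activation"],
            n_classes=int(d["n_classes"]),
            seed=int(d["seed"]),
        )


@dataclass
class CVResult:
    """Per-fold and mean accuracy of a k-fold cross-validation run."""

    fold_accuracies: list[float]
    degraded_folds: int = 0  # folds whose validation part misses a class

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_accuracies))


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """0/1 one-hot target matrix, +1 in the true-class column."""
    T = np.zeros((len(labels), n_classes))
    T[np.arange(len(labels)), np.asarray(labels) - 1] = 1.0
    return T


def train_elm(
    X: np.ndarray,
    labels: np.ndarray,
    n_hidden: int | None = None,
    activation: str = "sigmoid",
    seed: int = 0,
    n_classes: int | None = None,
) -> ELMModel:
    """Train an ELM classifier.

    Parameters
    ----------
    X : ndarray (n_samples, n_features)
    labels : ndarray of int in 1..c
    n_hidden : int, optional
        Hidden-neuron count N_H.  Defaults to ``min(n_samples, 20)``:
        enough for the few-gene subsets this package evaluates while
        keeping repeated cross-validation cheap.
    activation : str
        One of ``ACTIVATIONS``.
    seed : int
        Seeds the one-time draw of input weights and biases.
    n_classes : int, optional
        Number of output neurons; inferred from the labels if omitted.

    Returns
    -------
    ELMModel
        With ``output_weights`` the minimum-norm least-squares solution
        of ``H @ wo = T`` (rank-revealing pseudoinverse, singular values
        below ``1e-10 * s_max`` truncated).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("X must be a non-empty 2-D matrix")
    if activation not in ACTIVATIONS:
        raise ValueError(
            f"unknown activation {activation!r}; choose from {sorted(ACTIVATIONS)}"
        )
    n, d = X.shape
    if n_hidden is None:
        n_hidden = min(n, 20)
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if n_classes is None:
        n_classes = int(labels.max())
    if np.ptp(X) == 0.0:
        warnings.warn("training matrix is constant; ELM cannot discriminate")

    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(d, n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = ACTIVATIONS[activation](X @ W + b)
    T = one_hot(labels, n_classes)
    wo, *_ = np.linalg.lstsq(H, T, rcond=RCOND)
    return ELMModel(
        input_weights=W,
        biases=b,
        output_weights=wo,
        activation=activation,
        n_classes=n_classes,
        seed=seed,
    )


def predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Predicted class labels in 1..c; output-neuron ties break to the
    lowest class index (argmax keeps the first maximum)."""
    scores = model.decision_function(X)
    return np.argmax(scores, axis=1) + 1


def stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Assign samples to ``k`` validation folds, stratified by class.

    Each class's samples are shuffled and dealt round-robin, so fold
    class proportions track the dataset's.  A class with fewer than
    ``k`` samples is simply absent from some folds (graceful
    degradation; callers may flag it).
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    offset = 0
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        assignment[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)  # stagger classes so small classes spread out
    return [np.flatnonzero(assignment == f) for f in range(k)]


def kfold_cv_accuracy(
    X: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    n_hidden: int | None = None,
    activation: str = "sigmoid",
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation accuracy of an ELM.

    Every sample appears in exactly one validation fold.  The fold
    assignment and each fold's hidden layer are deterministic given
    ``seed``.  Precomputed ``folds`` may be passed to amortize the
    assignment across many subset evaluations.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_classes = int(labels.max())
    if folds is None:
        folds = stratified_folds(labels, k, seed)
    accs: list[float] = []
    degraded = 0
    mask = np.ones(len(labels), dtype=bool)
    for f, val_idx in enumerate(folds):
        mask[:] = True
        mask[val_idx] = False
        if len(np.unique(labels[val_idx])) < n_classes:
            degraded += 1
        model = train_elm(
            X[mask],
            labels[mask],
            n_hidden=n_hidden,
            activation=activation,
            seed=seed + 1000003 * (f + 1),
            n_classes=n_classes,
        )
        pred = predict(model, X[val_idx])
        accs.append(float(np.mean(pred == labels[val_idx])))
    return CVResult(fold_accuracies=accs, degraded_folds=degraded)
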