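"""Extreme learning machine: a single-hidden-layer network whose hidden
weights are random and whose output weights are solved in closed form.

Training solves the linear system ``H beta = T`` in the minimum-norm
least-squares sense via the Moore-Penrose pseudoinverse, where ``H`` is the
hidden-layer output matrix for the training inputs and ``T`` one-hot encodes
the class labels.  There is no iterative optimisation: given the random
hidden layer, training is a single pseudoinverse.

Labels are integers ``1..m``; prediction takes the arg-max over the ``m``
output columns (ties resolve to the smallest class index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "TrainingSet",
    "ELMModel",
    "init_hidden",
    "hidden_output",
    "solve_beta",
    "train",
    "predict",
    "accuracy_sweep",
]

ACTIVATIONS = ("sigmoid", "rbf")
#: relative singular-value cutoff for the pseudoinverse
PINV_RCOND = 1e-12


@dataclass
class TrainingSet:
    """Labelled inputs: X is N x n, labels take values in 1..m."""

    X: np.ndarray
    labels: np.ndarray
    n_classes: int | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X and labels row counts differ")
        if self.X.shape[0] < 1:
            raise ValueError("need at least one sample")
        if self.labels.min(initial=1) < 1:
            raise ValueError("labels must be >= 1")
        if self.n_classes is None:
            self.n_classes = int(self.labels.max())
        elif self.labels.max() > self.n_classes:
            raise ValueError("label exceeds n_classes")

    @property
    def one_hot(self) -> np.ndarray:
        T = np.zeros((self.labels.size, self.n_classes))
        T[np.arange(self.labels.size), self.labels - 1] = 1.0
        return T


@dataclass
class ELMModel:
    """Trained classifier: hidden layer (A, B), output weights beta."""

    A: np.ndarray                     # n_hidden x n input weights
    B: np.ndarray                     # n_hidden biases
    beta: np.ndarray                  # n_hidden x m output weights
    activation: str = "sigmoid"
    seed: int | None = None
    feature_order: tuple[str, ...] | None = None
    scaler_denominators: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.asarray(self.B, dtype=float).ravel()
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.A.shape[0] != self.B.size or self.A.shape[0] != self.beta.shape[0]:
            raise ValueError("inconsistent A/B/beta shapes")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")

    @property
    def n_hidden(self) -> int:
        return self.A.shape[0]

    @property
    def n_features(self) -> int:
        return self.A.shape[1]

    @property
    def n_classes(self) -> int:
        return self.beta.shape[1]


def init_hidden(n: int, n_hidden: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Random hidden layer: entries of A (n_hidden x n) and B uniform on [-1, 1]."""
    if n < 1 or n_hidden < 1:
        raise ValueError("n and n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    A = rng.uniform(-1.0, 1.0, size=(n_hidden, n))
    B = rng.uniform(-1.0, 1.0, size=n_hidden)
    return A, B


def hidden_output(A: np.ndarray, B: np.ndarray, X: np.ndarray, activation: str = "sigmoid") -> np.ndarray:
    """Hidden-layer output matrix H (N x n_hidden).

    sigmoid: ``H[j, i] = 1 / (1 + exp(-(a_i . x_j + b_i)))``.
    rbf: ``H[j, i] = exp(-|b_i| * ||x_j - a_i||**2)``.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.asarray(B, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if A.shape[0] != B.size:
        raise ValueError("A and B sizes differ")
    if X.shape[1] != A.shape[1]:
        raise ValueError(f"X has {X.shape[1]} features, hidden layer expects {A.shape[1]}")
    if activation == "sigmoid":
        return expit(X @ A.T + B)
    if activation == "rbf":
        d2 = ((X[:, None, :] - A[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-np.abs(B) * d2)
    raise ValueError(f"unknown activation {activation!r}")


def solve_beta(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares solution of ``H beta = T``.

    Uses the SVD pseudoinverse with a relative singular-value cutoff of
    ``PINV_RCOND``.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if H.size == 0:
        raise ValueError("empty hidden matrix")
    if H.shape[0] != T.shape[0]:
        raise ValueError("H and T row counts differ")
    return np.linalg.pinv(H, rcond=PINV_RCOND) @ T


def train(
    train_set: TrainingSet,
    n_hidden: int = 70,
    activation: str = "sigmoid",
    seed=0,
    feature_order: tuple[str, ...] | None = None,
    scaler_denominators: np.ndarray | None = None,
) -> ELMModel:
    """Train an ELM: random hidden layer, then one pseudoinverse solve."""
    A, B = init_hidden(train_set.X.shape[1], n_hidden, seed)
    H = hidden_output(A, B, train_set.X, activation)
    beta = solve_beta(H, train_set.one_hot)
    return ELMModel(
        A, B, beta,
        activation=activation,
        seed=seed if isinstance(seed, int) else None,
        feature_order=feature_order,
        scaler_denominators=scaler_denominators,
    )


def predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels in 1..m (arg-max over output columns; ties -> lowest)."""
    H = hidden_output(model.A, model.B, np.atleast_2d(X), model.activation)
    scores = H @ model.beta
    return np.argmax(scores, axis=1) + 1


def accuracy_sweep(
    X: np.ndarray,
    labels: np.ndarray,
    sample_sizes=(100, 200, 300, 400, 500, 600, 700, 800),
    hidden_sizes=(30, 40, 50, 60, 70, 80, 90, 100, 110, 120),
    n_repeats: int = 10,
    activation: str = "sigmoid",
    seed: int = 0,
    scale: bool = True,
) -> pd.DataFrame:
    """Held-out accuracy over a (training size x hidden nodes) grid.

    For each repeat a random permutation of the dataset is drawn; the first
    ``size`` samples train the model and all remaining samples form the test
    pool.  When ``scale`` is set, a max-|q| scaler is fitted on the training
    split only and applied to both splits.  Returns a tidy DataFrame with
    columns ``sample_size, n_hidden, mean_accuracy``.
    """
    from .features import FeatureScaler

    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n_total = X.shape[0]
    if max(sample_sizes) >= n_total:
        raise ValueError("largest sample size leaves no held-out test pool")
    rng = np.random.default_rng(seed)
    acc = np.zeros((len(sample_sizes), len(hidden_sizes)))
    for rep in range(n_repeats):
        perm = rng.permutation(n_total)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        for i, size in enumerate(sample_sizes):
            tr, te = perm[:size], perm[size:]
            Xtr, Xte = X[tr], X[te]
            if scale:
                scaler = FeatureScaler.fit(Xtr)
                Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
            ts = TrainingSet(Xtr, labels[tr], n_classes=int(labels.max()))
            for j, nh in enumerate(hidden_sizes):
                model = train(ts, n_hidden=nh, activation=activation, seed=rep_seed + j)
                acc[i, j] += float(np.mean(predict(model, Xte) == labels[te]))
    acc /= n_repeats
    rows = [
        {"sample_size": s, "n_hidden": h, "mean_accuracy": acc[i, j]}
        for i, s in enumerate(sample_sizes)
        for j, h in enumerate(hidden_sizes)
    ]
    return pd.DataFrame(rows)
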