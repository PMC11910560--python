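"""Three-layer feed-forward network evaluated from a flat weight vector.

The network is the classification function only — there is no gradient
training here.  Its parameters live in a single flat vector so that a
derivative-free optimizer can search the weight space directly.  Layout of
the flat vector (fixed contract):

    [W1 (n_hidden x n_in, row-major), b1 (n_hidden),
     W2 (n_out x n_hidden, row-major), b2 (n_out)]

Hidden activation is tanh; the output layer is mapped through a softmax so
forward() returns a proper probability vector over the four task classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the classifier network.

    The default hidden width (4) is deliberately small: the weight vector is
    searched directly by a derivative-free optimizer, whose efficiency
    degrades with parameter count, and the band-power feature space needs
    little capacity.
    """

    n_in: int = 22
    n_hidden: int = 4
    n_out: int = 4
    hidden_activation: str = "tanh"
    output_mapping: str = "softmax"

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.hidden_activation != "tanh" or self.output_mapping != "softmax":
            raise ValueError("supported configuration is tanh hidden / softmax output")

    @property
    def n_params(self) -> int:
        """Search-space dimension D = (n_in + 1)*n_hidden + (n_hidden + 1)*n_out."""
        return (self.n_in + 1) * self.n_hidden + (self.n_hidden + 1) * self.n_out


def pack(w1: np.ndarray, b1: np.ndarray, w2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Flatten layer weights/biases into a single parameter vector."""
    n_hidden, n_in = w1.shape
    n_out = w2.shape[0]
    if b1.shape != (n_hidden,) or w2.shape != (n_out, n_hidden) or b2.shape != (n_out,):
        raise ValueError("inconsistent layer shapes")
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def unpack(theta: np.ndarray, spec: NetworkSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`pack`; validates the parameter count."""
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1 or theta.size != spec.n_params:
        raise ValueError(f"theta must be a flat vector of length {spec.n_params}, got {theta.shape}")
    i = 0
    w1 = theta[i : i + spec.n_hidden * spec.n_in].reshape(spec.n_hidden, spec.n_in)
    i += w1.size
    b1 = theta[i : i + spec.n_hidden]
    i += b1.size
    w2 = theta[i : i + spec.n_out * spec.n_hidden].reshape(spec.n_out, spec.n_hidden)
    i += w2.size
    b2 = theta[i : i + spec.n_out]
    return w1, b1, w2, b2


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(theta: np.ndarray, x: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    """Class probabilities for one feature vector or an (n x n_in) batch.

    Deterministic in (theta, x); outputs are nonnegative and each row sums
    to 1 to numerical precision.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    w1, b1, w2, b2 = unpack(theta, spec)
    h = np.tanh(x @ w1.T + b1)
    return _softmax(h @ w2.T + b2)


def predict(theta: np.ndarray, x: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    """Predicted class indices; ties break to the lowest index (argmax)."""
    return np.argmax(forward(theta, np.atleast_2d(x), spec), axis=-1)
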