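"""Single-hidden-layer perceptron with back-propagation, from scratch.

The network is deliberately minimal: one hidden layer (a single hidden layer
can approximate any functional form), a sigmoidal hidden activation —
``tansig`` (hyperbolic tangent sigmoid) or ``logsig`` (logistic sigmoid) —
and a linear output neuron.  Binary targets are coded 0/1 and the network is
trained by full-batch gradient descent on the mean squared output error,
stopping at a predefined error threshold or an epoch cap.  Weights are
initialized uniformly on (−0.5, 0.5) from a seeded generator, so training is
reproducible and re-initialization across bootstrap replications is cheap.

Weight matrices are plain numpy arrays exposed on :class:`NetworkParameters`;
the interpretation module reads importance and direction of effect directly
off them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ACTIVATIONS = ("tansig", "logsig")


def tansig(z: np.ndarray) -> np.ndarray:
    """Hyperbolic tangent sigmoid, 2/(1+e^(−2z)) − 1 (= tanh(z))."""
    return np.tanh(z)


def logsig(z: np.ndarray) -> np.ndarray:
    """Logistic sigmoid, 1/(1+e^(−z))."""
    return 1.0 / (1.0 + np.exp(-z))


def _act(kind: str):
    if kind == "tansig":
        return tansig
    if kind == "logsig":
        return logsig
    raise ValueError(f"unknown hidden activation {kind!r}")


def _act_deriv(kind: str, h: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation value h = sigma(z)
    if kind == "tansig":
        return 1.0 - h * h
    return h * (1.0 - h)


@dataclass
class NetworkParameters:
    """Weights of one trained network.

    ``W_in`` has shape (n_hidden, n_inputs); ``b_in`` (n_hidden,); ``w_out``
    (n_hidden,); ``b_out`` is a scalar.  The output neuron is always linear.
    """

    W_in: np.ndarray
    b_in: np.ndarray
    w_out: np.ndarray
    b_out: float
    hidden_activation: str = "tansig"

    def __post_init__(self) -> None:
        self.W_in = np.asarray(self.W_in, dtype=float)
        self.b_in = np.asarray(self.b_in, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        h, p = self.W_in.shape
        if self.b_in.shape != (h,) or self.w_out.shape != (h,):
            raise ValueError("inconsistent parameter dimensions")
        if self.hidden_activation not in ACTIVATIONS:
            raise ValueError(f"unknown hidden activation {self.hidden_activation!r}")
        for arr in (self.W_in, self.b_in, self.w_out):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite weight")

    @property
    def n_inputs(self) -> int:
        return self.W_in.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_in.shape[0]


@dataclass
class TrainingHyperparameters:
    """Knobs of back-propagation training.

    ``n_hidden=None`` lets the caller's model-fitting layer pick the size
    empirically (grid over {⌈p/2⌉, p, 2p+1} on validation balanced accuracy);
    :func:`train` itself falls back to ``p`` hidden neurons.
    ``error_threshold`` is the training-MSE stopping level.
    """

    n_hidden: int | None = None
    learning_rate: float = 0.5
    max_epochs: int = 2000
    error_threshold: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden is not None and self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def forward(params: NetworkParameters, x: np.ndarray) -> float | np.ndarray:
    """Network score b_out + Σ_j v_j σ(Σ_i w_ij x_i + b_j).

    Accepts a single input vector (returns a scalar) or a 2-D batch
    (returns a vector of scores).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {params.n_inputs}"
        )
    H = _act(params.hidden_activation)(X @ params.W_in.T + params.b_in)
    s = H @ params.w_out + params.b_out
    return float(s[0]) if single else s


def predict(params: NetworkParameters, x: np.ndarray, cutoff: float = 0.5):
    """Binarized score: 1 iff score >= cutoff (boundary counts as positive)."""
    s = forward(params, x)
    if np.isscalar(s):
        return int(s >= cutoff)
    return (s >= cutoff).astype(int)


def mse_and_gradients(
    params: NetworkParameters, X: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean squared error on (X, y) and its analytic gradients.

    Exposed separately so the back-propagation derivatives can be checked
    against finite differences.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    H = _act(params.hidden_activation)(X @ params.W_in.T + params.b_in)
    s = H @ params.w_out + params.b_out
    e = s - y
    mse = float(e @ e) / n
    g_s = 2.0 * e / n
    grads = {
        "w_out": H.T @ g_s,
        "b_out": np.array([g_s.sum()]),
    }
    g_Z = np.outer(g_s, params.w_out) * _act_deriv(params.hidden_activation, H)
    grads["W_in"] = g_Z.T @ X
    grads["b_in"] = g_Z.sum(axis=0)
    return mse, grads


def init_parameters(
    n_inputs: int, n_hidden: int, activation: str, rng: np.random.Generator
) -> NetworkParameters:
    """Seeded uniform(−0.5, 0.5) initialization of every weight and bias."""
    return NetworkParameters(
        W_in=rng.uniform(-0.5, 0.5, size=(n_hidden, n_inputs)),
        b_in=rng.uniform(-0.5, 0.5, size=n_hidden),
        w_out=rng.uniform(-0.5, 0.5, size=n_hidden),
        b_out=float(rng.uniform(-0.5, 0.5)),
        hidden_activation=activation,
    )


def train(
    X: np.ndarray,
    y: np.ndarray,
    hp: TrainingHyperparameters,
    activation: str = "tansig",
    rng: np.random.Generator | None = None,
) -> NetworkParameters:
    """Full-batch gradient-descent back-propagation on mean squared error.

    Deterministic given ``hp.seed`` (or the supplied generator).  Stops when
    the training MSE falls below ``hp.error_threshold`` or after
    ``hp.max_epochs`` epochs.  Both classes must be present in ``y``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts must match")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; nothing to learn")
    if rng is None:
        rng = np.random.default_rng(hp.seed)
    n_hidden = hp.n_hidden if hp.n_hidden is not None else X.shape[1]
    params = init_parameters(X.shape[1], n_hidden, activation, rng)
    # Adaptive step size (grow 1.05 on success, shrink 0.7 and reject a step
    # that worsens the MSE by more than 4%): keeps full-batch gradient
    # descent stable at any starting learning rate.
    lr = hp.learning_rate
    mse, grads = mse_and_gradients(params, X, y)
    for _ in range(hp.max_epochs):
        if mse <= hp.error_threshold:
            break
        cand = NetworkParameters(
            W_in=params.W_in - lr * grads["W_in"],
            b_in=params.b_in - lr * grads["b_in"],
            w_out=params.w_out - lr * grads["w_out"],
            b_out=params.b_out - lr * float(grads["b_out"][0]),
            hidden_activation=params.hidden_activation,
        )
        new_mse, new_grads = mse_and_gradients(cand, X, y)
        if np.isfinite(new_mse) and new_mse <= mse * 1.04:
            params, grads = cand, new_grads
            if new_mse < mse:
                lr *= 1.05
            mse = new_mse
        else:
            lr *= 0.7
    return params


def training_mse(params: NetworkParameters, X: np.ndarray, y: np.ndarray) -> float:
    mse, _ = mse_and_gradients(params, X, y)
    return mse


# ---------------------------------------------------------------------------
# Plain-text serialization (dims, activation, row-major matrices)

def save_parameters(params: NetworkParameters, path) -> None:
    """Write weights to a documented plain-text layout.

    Line 1: ``n_hidden n_inputs activation``; then W_in row-major (one hidden
    neuron per line), then b_in, w_out, b_out, one line each.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{params.n_hidden} {params.n_inputs} {params.hidden_activation}\n")
        for row in params.W_in:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
        fh.write(" ".join(repr(float(v)) for v in params.b_in) + "\n")
        fh.write(" ".join(repr(float(v)) for v in params.w_out) + "\n")
        fh.write(repr(float(params.b_out)) + "\n")


def load_parameters(path) -> NetworkParameters:
    with open(path, encoding="utf-8") as fh:
        h_s, p_s, activation = fh.readline().split()
        h, p = int(h_s), int(p_s)
        W_in = np.array([[float(v) for v in fh.readline().split()] for _ in range(h)])
        if W_in.shape != (h, p):
            raise ValueError(f"corrupt weight file: W_in shape {W_in.shape} != ({h}, {p})")
        b_in = np.array([float(v) for v in fh.readline().split()])
        w_out = np.array([float(v) for v in fh.readline().split()])
        b_out = float(fh.readline())
    return NetworkParameters(W_in, b_in, w_out, b_out, activation)
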