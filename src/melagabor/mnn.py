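"""Multilevel Neural Network (MNN) classifier with Levenberg-Marquardt
training.

The network is a fully connected perceptron (default 120-10-10-1) whose
hidden neurons use a *multilevel* sigmoidal activation

    phi_r(x) = sum_{lam=1}^{r-1} f(x - (lam - 1) * c),   f(x) = 1 / (1 + e^(-beta x))

— a staircase with r plateaus at about 0, 1, ..., r-1, spaced c apart.
With r = 2 the staircase collapses exactly to the plain sigmoid.  The
output neuron uses r = 2 by default so the score lives in (0, 1) and is
thresholded at 0.5 into benign (0) / malignant (1).

Weights are trained by damped Gauss-Newton (Levenberg-Marquardt): the
residual Jacobian J is backpropagated analytically, the damped normal
equations (J'J + mu I) dw = J'e are solved directly, and a step is
accepted only if the epoch MSE decreases (mu shrinks on acceptance and
grows on rejection), so the accepted-step MSE sequence is
non-increasing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import linalg

from .gabor_features import FeatureVector


@dataclasses.dataclass
class ActivationSpec:
    """Multilevel sigmoid parameters: steepness beta, level count r, spacing c."""

    beta: float = 1.0
    levels: int = 2
    c: float = 10.0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.levels < 2:
            raise ValueError("levels (r) must be >= 2")


#: default hidden activation: 3-level staircase
DEFAULT_HIDDEN = ActivationSpec(beta=1.0, levels=3, c=10.0)
#: default output activation: plain sigmoid, score in (0, 1)
DEFAULT_OUTPUT = ActivationSpec(beta=1.0, levels=2, c=10.0)


def _sigmoid(x: np.ndarray, beta: float) -> np.ndarray:
    # literal logistic form; exp overflow at very negative x harmlessly
    # saturates to 0 (1 / inf)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-beta * x))


def multilevel_sigmoid(x, spec: ActivationSpec) -> np.ndarray:
    """phi_r(x) = sum over lam = 1..r-1 of f(x - (lam-1) c)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for lam in range(1, spec.levels):
        out += _sigmoid(x - (lam - 1) * spec.c, spec.beta)
    return out


def multilevel_sigmoid_derivative(x, spec: ActivationSpec) -> np.ndarray:
    """d/dx phi_r(x) = sum over lam of beta f_lam (1 - f_lam); always > 0."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for lam in range(1, spec.levels):
        f = _sigmoid(x - (lam - 1) * spec.c, spec.beta)
        out += spec.beta * f * (1.0 - f)
    return out


@dataclasses.dataclass
class TrainConfig:
    """Levenberg-Marquardt schedule and stopping rule."""

    mse_threshold: float = 1e-4
    max_epochs: int = 1000
    mu_init: float = 1e-3
    mu_up: float = 10.0
    mu_down: float = 0.1
    max_failures: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.mu_init <= 0:
            raise ValueError("mu_init must be positive")
        if not (self.mu_up > 1.0 > self.mu_down > 0.0):
            raise ValueError("require mu_up > 1 > mu_down > 0")


@dataclasses.dataclass
class TrainTrace:
    epoch_mse: List[float]
    converged: bool
    epochs_run: int


@dataclasses.dataclass
class MNNModel:
    """Layer sizes, weights and activation specs of one trained network.

    ``weights`` holds per-layer (W, b) pairs with W of shape (out, in);
    the forward map of layer l is ``a_l = phi(a_{l-1} @ W_l.T + b_l)``.
    """

    layer_sizes: List[int]
    weights: List[Tuple[np.ndarray, np.ndarray]]
    hidden_activation: ActivationSpec = dataclasses.field(
        default_factory=lambda: dataclasses.replace(DEFAULT_HIDDEN))
    output_activation: ActivationSpec = dataclasses.field(
        default_factory=lambda: dataclasses.replace(DEFAULT_OUTPUT))
    seed: int = 0

    @property
    def n_weights(self) -> int:
        return sum(W.size + b.size for W, b in self.weights)

    def get_flat_weights(self) -> np.ndarray:
        return np.concatenate([np.concatenate([W.ravel(), b.ravel()])
                               for W, b in self.weights])

    def set_flat_weights(self, flat: np.ndarray) -> None:
        pos = 0
        new = []
        for W, b in self.weights:
            w = flat[pos:pos + W.size].reshape(W.shape)
            pos += W.size
            bb = flat[pos:pos + b.size].copy()
            pos += b.size
            new.append((w, bb))
        self.weights = new


def init_model(layer_sizes: Sequence[int] = (120, 10, 10, 1),
               seed: int = 0,
               hidden_activation: Optional[ActivationSpec] = None,
               output_activation: Optional[ActivationSpec] = None,
               init_scale: float = 0.5) -> MNNModel:
    """Random weights, uniform on (-init_scale, init_scale), seeded."""
    rng = np.random.default_rng(seed)
    weights = []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        W = rng.uniform(-init_scale, init_scale, size=(n_out, n_in))
        b = rng.uniform(-init_scale, init_scale, size=n_out)
        weights.append((W, b))
    return MNNModel(layer_sizes=list(layer_sizes), weights=weights,
                    hidden_activation=hidden_activation or
                    dataclasses.replace(DEFAULT_HIDDEN),
                    output_activation=output_activation or
                    dataclasses.replace(DEFAULT_OUTPUT),
                    seed=seed)


def _as_matrix(features, n_inputs: int, require_normalized: bool = False
               ) -> np.ndarray:
    if isinstance(features, FeatureVector):
        if require_normalized and not features.normalized:
            raise ValueError("feature vector is not normalized; fit a "
                             "MinMaxNormalizer on the training set and "
                             "transform first")
        X = features.values[None, :]
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != n_inputs:
        raise ValueError(f"expected {n_inputs} inputs, got {X.shape[1]}")
    return X


def _forward_pass(model: MNNModel, X: np.ndarray):
    """Activations and pre-activations per layer, batch-vectorized."""
    n_layers = len(model.weights)
    a = X
    acts, zs = [a], []
    for l, (W, b) in enumerate(model.weights):
        z = a @ W.T + b
        spec = model.output_activation if l == n_layers - 1 \
            else model.hidden_activation
        a = multilevel_sigmoid(z, spec)
        zs.append(z)
        acts.append(a)
    return acts, zs


def forward(model: MNNModel, features) -> np.ndarray:
    """Network score(s) for one FeatureVector or an (n, d) matrix."""
    X = _as_matrix(features, model.layer_sizes[0])
    acts, _ = _forward_pass(model, X)
    out = acts[-1][:, 0]
    return float(out[0]) if isinstance(features, FeatureVector) or \
        np.asarray(features).ndim == 1 else out


def jacobian(model: MNNModel, X: np.ndarray, y: np.ndarray
             ) -> Tuple[np.ndarray, np.ndarray]:
    """Residuals e = y - out and the matrix J with J[i, w] = d out_i / d w.

    Weight columns follow the flat ordering of
    :meth:`MNNModel.get_flat_weights` (W then b, layer by layer).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    acts, zs = _forward_pass(model, X)
    out = acts[-1][:, 0]
    residuals = y - out

    n_layers = len(model.weights)
    n = X.shape[0]
    # delta_l[i, j] = d out_i / d z_l[i, j]
    deltas = [None] * n_layers
    d_out = multilevel_sigmoid_derivative(zs[-1], model.output_activation)
    deltas[-1] = d_out  # shape (n, 1)
    for l in range(n_layers - 2, -1, -1):
        W_next = model.weights[l + 1][0]
        d_hidden = multilevel_sigmoid_derivative(zs[l], model.hidden_activation)
        deltas[l] = (deltas[l + 1] @ W_next) * d_hidden

    cols = []
    for l in range(n_layers):
        dW = deltas[l][:, :, None] * acts[l][:, None, :]  # (n, out, in)
        cols.append(dW.reshape(n, -1))
        cols.append(deltas[l])
    return residuals, np.hstack(cols)


def lm_step(flat_weights: np.ndarray, J: np.ndarray, e: np.ndarray,
            mu: float) -> np.ndarray:
    """Damped Gauss-Newton update dw = (J'J + mu I)^-1 J'e."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    JtJ = J.T @ J
    Jte = J.T @ e
    A = JtJ + mu * np.eye(JtJ.shape[0])
    try:
        c, low = linalg.cho_factor(A, check_finite=False)
        return linalg.cho_solve((c, low), Jte, check_finite=False)
    except linalg.LinAlgError:
        return linalg.lstsq(A, Jte, check_finite=False)[0]


def mse(model: MNNModel, X: np.ndarray, y: np.ndarray) -> float:
    acts, _ = _forward_pass(model, np.atleast_2d(X))
    return float(np.mean((np.asarray(y, float).ravel() - acts[-1][:, 0]) ** 2))


def train(model: MNNModel, X: np.ndarray, y: np.ndarray,
          config: Optional[TrainConfig] = None) -> Tuple[MNNModel, TrainTrace]:
    """Levenberg-Marquardt training until MSE < threshold or max_epochs.

    One epoch is one accepted step (or a run of rejections exhausting
    ``max_failures``).  Deterministic for a fixed initial model.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    mu = config.mu_init
    current_mse = mse(model, X, y)
    trace = [current_mse]
    converged = current_mse < config.mse_threshold
    epochs = 0
    while not converged and epochs < config.max_epochs:
        e, J = jacobian(model, X, y)
        w0 = model.get_flat_weights()
        accepted = False
        for _ in range(config.max_failures):
            dw = lm_step(w0, J, e, mu)
            model.set_flat_weights(w0 + dw)
            new_mse = mse(model, X, y)
            if new_mse < current_mse:
                accepted = True
                mu = max(mu * config.mu_down, 1e-20)
                current_mse = new_mse
                break
            model.set_flat_weights(w0)
            mu *= config.mu_up
        epochs += 1
        if not accepted:
            break
        trace.append(current_mse)
        converged = current_mse < config.mse_threshold
    return model, TrainTrace(epoch_mse=trace, converged=bool(converged),
                             epochs_run=epochs)


def predict_label(model: MNNModel, features,
                  threshold: float = 0.5) -> Tuple[int, float]:
    """(label, score): label = 1 iff score >= threshold (default 0.5)."""
    X = _as_matrix(features, model.layer_sizes[0], require_normalized=True)
    acts, _ = _forward_pass(model, X)
    score = float(acts[-1][0, 0])
    return int(score >= threshold), score


def predict_scores(model: MNNModel, X: np.ndarray) -> np.ndarray:
    """Scores for an (n, d) matrix of normalized features."""
    acts, _ = _forward_pass(model, np.atleast_2d(np.asarray(X, float)))
    return acts[-1][:, 0]


# ---------------------------------------------------------------------------
# multilevel-vs-plain-sigmoid learning-curve harness

def three_level_task(n_per_class: int = 30, seed: int = 0
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Fixed synthetic task with three target levels 0, 1 and 2.

    Three 2-D Gaussian clusters (sd 0.3) centred on a line, with
    targets 0, 1, 2 — a grading-style problem a multilevel output can
    represent exactly while a plain sigmoid (range (0, 1)) cannot.
    """
    rng = np.random.default_rng(seed)
    centers = np.array([[-2.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
    X = np.vstack([rng.normal(c, 0.3, size=(n_per_class, 2)) for c in centers])
    y = np.repeat([0.0, 1.0, 2.0], n_per_class)
    return X, y


def compare_learning_curves(n_runs: int = 10, seed: int = 0,
                            max_epochs: int = 60
                            ) -> List[Tuple[float, float]]:
    """Final training MSE of multilevel vs plain-sigmoid networks.

    For each of ``n_runs`` matched seeds, a 2-8-1 network is trained on
    the fixed three-level task twice from the same random init: once
    with 3-level staircase activations (r=3 throughout) and once with
    plain sigmoids (r=2).  Returns [(mse_multilevel, mse_plain), ...].
    """
    X, y = three_level_task(seed=seed)
    config = TrainConfig(mse_threshold=0.0, max_epochs=max_epochs, seed=seed)
    results = []
    for run in range(n_runs):
        run_seed = seed + run
        specs = {
            "multilevel": ActivationSpec(beta=1.0, levels=3, c=10.0),
            "plain": ActivationSpec(beta=1.0, levels=2, c=10.0),
        }
        final = {}
        for name, spec in specs.items():
            model = init_model((2, 8, 1), seed=run_seed,
                               hidden_activation=spec, output_activation=spec)
            _, trace = train(model, X, y, config)
            final[name] = trace.epoch_mse[-1]
        results.append((final["multilevel"], final["plain"]))
    return results


# ---------------------------------------------------------------------------
# persistence

def _spec_to_dict(spec: ActivationSpec) -> dict:
    return {"beta": spec.beta, "levels": spec.levels, "c": spec.c}


def save_model(model: MNNModel, path, normalizer=None,
               metadata: Optional[dict] = None) -> None:
    """Persist a model (and optionally its feature normalizer) as JSON."""
    doc = {
        "layer_sizes": model.layer_sizes,
        "weights": [{"W": W.tolist(), "b": b.tolist()} for W, b in model.weights],
        "hidden_activation": _spec_to_dict(model.hidden_activation),
        "output_activation": _spec_to_dict(model.output_activation),
        "seed": model.seed,
        "metadata": metadata or {},
    }
    if normalizer is not None:
        doc["normalizer"] = normalizer.to_dict()
    Path(path).write_text(json.dumps(doc))


def load_model(path):
    """Load a model saved by :func:`save_model`.

    Returns (model, normalizer_or_None, metadata).
    """
    from .gabor_features import MinMaxNormalizer
    doc = json.loads(Path(path).read_text())
    weights = [(np.asarray(w["W"], float), np.asarray(w["b"], float))
               for w in doc["weights"]]
    model = MNNModel(layer_sizes=list(doc["layer_sizes"]), weights=weights,
                     hidden_activation=ActivationSpec(**doc["hidden_activation"]),
                     output_activation=ActivationSpec(**doc["output_activation"]),
                     seed=doc.get("seed", 0))
    norm = MinMaxNormalizer.from_dict(doc["normalizer"]) \
        if "normalizer" in doc else None
    return model, norm, doc.get("metadata", {})
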