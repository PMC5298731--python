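"""Multilayer-perceptron engine trained with scaled conjugate gradients.

One engine serves two roles: the 20-10-8-3 softmax classifier that
discriminates normal beats, supraventricular ectopics (SVEB) and
ventricular ectopics (VEB), and a linear-output regressor (used by the
pulse-morphology blood-pressure estimator).  Training follows Moller's
scaled conjugate gradient (SCG) with his published defaults
(sigma = 1e-4, initial lambda = 1e-6), full-batch, on cross-entropy
(classifier) or mean squared error (regressor).

Early stopping holds out a random validation fraction (default 10 %) and
stops once the validation error has not improved for ``patience``
consecutive iterations; the weights of the best validation iteration are
returned.

The scikit-learn estimator surface (:class:`EctopicBeatClassifier`,
:class:`SCGNetworkRegressor`) wraps the functional API
(:func:`init_mlp`, :func:`train`, :func:`forward`, :func:`classify_beat`)
and composes with sklearn model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

CLASSES = ("N", "S", "V")

# Moller's published SCG constants.
SCG_SIGMA = 1e-4
SCG_LAMBDA_INIT = 1e-6
SCG_LAMBDA_MAX = 1e15


# ---------------------------------------------------------------------------
# Model container + functional API
# ---------------------------------------------------------------------------

@dataclass
class MLPModel:
    """Layered perceptron weights + activation spec + training history."""

    layer_sizes: list[int]
    weights: list[np.ndarray]          # W[l] has shape (n_out, n_in)
    biases: list[np.ndarray]
    hidden_activation: str = "tanh"    # "tanh" | "logistic"
    output_mode: str = "softmax_class"  # "softmax_class" | "linear_regression"
    rng_seed: int = 0
    training_history: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "layer_sizes": self.layer_sizes,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "hidden_activation": self.hidden_activation,
            "output_mode": self.output_mode,
            "rng_seed": self.rng_seed,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MLPModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            layer_sizes=list(d["layer_sizes"]),
            weights=[np.array(w, dtype=float) for w in d["weights"]],
            biases=[np.array(b, dtype=float) for b in d["biases"]],
            hidden_activation=d["hidden_activation"],
            output_mode=d["output_mode"],
            rng_seed=int(d["rng_seed"]),
        )


@dataclass
class TrainConfig:
    """Training-loop parameters.

    ``patience=1`` stops at the first validation-error increase; real SCG
    validation curves are noisy, so a larger patience is usually the better
    choice (the estimator classes default to 8).
    """

    validation_fraction: float = 0.10
    patience: int = 1
    max_iterations: int = 400
    seed: int = 0
    balance: str = "none"  # "undersample" | "none" (applied by callers)

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def init_mlp(
    layer_sizes: list[int],
    seed: int = 0,
    hidden_activation: str = "tanh",
    output_mode: str = "softmax_class",
) -> MLPModel:
    """Random symmetric-breaking initialization, scaled by 1/sqrt(fan_in)."""
    if len(layer_sizes) < 3:
        raise ValueError("need at least one hidden layer (>= 3 layer sizes)")
    if any(s < 1 for s in layer_sizes):
        raise ValueError(f"layer sizes must be >= 1, got {layer_sizes}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(rng.standard_normal((n_out, n_in)) / np.sqrt(n_in))
        biases.append(np.zeros(n_out))
    return MLPModel(
        layer_sizes=list(layer_sizes),
        weights=weights,
        biases=biases,
        hidden_activation=hidden_activation,
        output_mode=output_mode,
        rng_seed=seed,
    )


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {kind!r}")


def _activate_deriv(a: np.ndarray, kind: str) -> np.ndarray:
    # Derivative expressed through the activation value itself.
    if kind == "tanh":
        return 1.0 - a**2
    if kind == "logistic":
        return a * (1.0 - a)
    raise ValueError(f"unknown activation {kind!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - np.max(z, axis=1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=1, keepdims=True)


def _forward_pass(model: MLPModel, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; the last entry is the network output."""
    a = X
    acts = [a]
    n_layers = len(model.weights)
    for l, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W.T + b
        if l < n_layers - 1:
            a = _activate(z, model.hidden_activation)
        elif model.output_mode == "softmax_class":
            a = _softmax(z)
        else:
            a = z
        acts.append(a)
    return acts


def forward(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Network output for one sample or a batch of samples."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"input size {X.shape[1]} != model input {model.layer_sizes[0]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    out = _forward_pass(model, X)[-1]
    return out[0] if single else out


def _flatten(weights, biases) -> np.ndarray:
    return np.concatenate([w.ravel() for w in weights] + [b.ravel() for b in biases])


def _unflatten(model: MLPModel, w: np.ndarray) -> tuple[list, list]:
    weights, biases, pos = [], [], 0
    for W in model.weights:
        weights.append(w[pos : pos + W.size].reshape(W.shape))
        pos += W.size
    for b in model.biases:
        biases.append(w[pos : pos + b.size])
        pos += b.size
    return weights, biases


def loss_and_grad(
    model: MLPModel, w: np.ndarray, X: np.ndarray, T: np.ndarray
) -> tuple[float, np.ndarray]:
    """Full-batch loss and flat gradient at weight vector ``w``.

    Cross-entropy for softmax classification, 0.5*MSE for regression; both
    averaged over samples so gradients are size-independent.
    """
    weights, biases = _unflatten(model, w)
    tmp = MLPModel(
        layer_sizes=model.layer_sizes,
        weights=weights,
        biases=biases,
        hidden_activation=model.hidden_activation,
        output_mode=model.output_mode,
    )
    acts = _forward_pass(tmp, X)
    out = acts[-1]
    n = X.shape[0]
    if model.output_mode == "softmax_class":
        loss = -float(np.sum(T * np.log(np.clip(out, 1e-300, None)))) / n
    else:
        loss = 0.5 * float(np.sum((out - T) ** 2)) / n
    # Both losses share the delta (out - T)/n at the output pre-activation.
    delta = (out - T) / n
    gw = [np.empty_like(W) for W in weights]
    gb = [np.empty_like(b) for b in biases]
    for l in range(len(weights) - 1, -1, -1):
        gw[l] = delta.T @ acts[l]
        gb[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ weights[l]) * _activate_deriv(
                acts[l], model.hidden_activation
            )
    return loss, _flatten(gw, gb)


def scg_minimize(fun, w0: np.ndarray, max_iter: int = 400, tol: float = 1e-8,
                 callback=None) -> np.ndarray:
    """Moller's scaled conjugate gradient.

    ``fun(w) -> (loss, grad)``.  ``callback(k, w, loss)`` runs after every
    accepted step and may return True to stop early.  The training loss is
    non-increasing over accepted steps by construction.
    """
    w = w0.copy()
    loss, g = fun(w)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite initial loss")
    r = -g
    p = r.copy()
    lamb, lamb_bar = SCG_LAMBDA_INIT, 0.0
    success = True
    delta_raw = 0.0
    n_dim = len(w)
    for k in range(1, max_iter + 1):
        p2 = float(p @ p)
        if p2 == 0.0:
            break
        if success:
            sigma_k = SCG_SIGMA / np.sqrt(p2)
            _, g_sigma = fun(w + sigma_k * p)
            delta_raw = float(p @ (g_sigma - g)) / sigma_k
        delta = delta_raw + (lamb - lamb_bar) * p2
        if delta <= 0:  # make the Hessian approximation positive definite
            lamb_bar = 2.0 * (lamb - delta / p2)
            delta = -delta + lamb * p2
            lamb = lamb_bar
        mu = float(p @ r)
        alpha = mu / delta
        loss_new, g_new = fun(w + alpha * p)
        comparison = 2.0 * delta * (loss - loss_new) / mu**2
        if np.isfinite(comparison) and comparison >= 0:
            w = w + alpha * p
            loss, g = loss_new, g_new
            r_new = -g
            lamb_bar = 0.0
            success = True
            if k % n_dim == 0:
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lamb = max(lamb * 0.25, 1e-20)
            if callback is not None and callback(k, w, loss):
                break
            if float(r @ r) < tol**2:
                break
        else:
            lamb_bar = lamb
            success = False
        if np.isfinite(comparison) and comparison < 0.25:
            lamb = lamb + delta * (1.0 - comparison) / p2
        if lamb > SCG_LAMBDA_MAX:
            break
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite loss during SCG")
    return w


def train(model: MLPModel, X: np.ndarray, Y: np.ndarray,
          config: TrainConfig | None = None) -> MLPModel:
    """Train ``model`` on (X, Y) with SCG + validation-based early stopping.

    ``Y`` is a one-of-k incidence matrix for classification or a target
    matrix for regression.  Returns a new model carrying the weights of the
    best validation iteration and a per-iteration ``training_history``.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, Y_tr = X[tr_idx], Y[tr_idx]
    X_val, Y_val = X[val_idx], Y[val_idx]

    history = {"train": [], "val": []}
    best = {"val": np.inf, "w": _flatten(model.weights, model.biases)}
    state = {"bad": 0}

    def val_loss(w: np.ndarray) -> float:
        loss, _ = loss_and_grad(model, w, X_val, Y_val)
        return loss

    def callback(k: int, w: np.ndarray, tr: float) -> bool:
        v = val_loss(w)
        history["train"].append(tr)
        history["val"].append(v)
        if v < best["val"]:
            best["val"] = v
            best["w"] = w.copy()
            state["bad"] = 0
        else:
            state["bad"] += 1
        return state["bad"] >= config.patience

    w0 = _flatten(model.weights, model.biases)
    scg_minimize(
        lambda w: loss_and_grad(model, w, X_tr, Y_tr),
        w0,
        max_iter=config.max_iterations,
        callback=callback,
    )
    weights, biases = _unflatten(model, best["w"])
    return MLPModel(
        layer_sizes=list(model.layer_sizes),
        weights=[w.copy() for w in weights],
        biases=[b.copy() for b in biases],
        hidden_activation=model.hidden_activation,
        output_mode=model.output_mode,
        rng_seed=model.rng_seed,
        training_history=history,
    )


def balance_classes(
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "undersample",
    seed: int = 0,
    required: tuple | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by undersampling to the minority-class count."""
    X = np.asarray(X)
    y = np.asarray(y)
    labels = list(required) if required is not None else sorted(set(y.tolist()))
    for c in labels:
        if not np.any(y == c):
            raise ValueError(f"class absent from training data: {c!r}")
    if mode == "none":
        return X, y
    if mode != "undersample":
        raise ValueError(f"unknown balance mode {mode!r}")
    rng = np.random.default_rng(seed)
    counts = {c: int(np.sum(y == c)) for c in labels}
    m = min(counts.values())
    keep = []
    for c in labels:
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=m, replace=False))
    keep = np.sort(np.concatenate(keep))
    return X[keep], y[keep]


def classify_beat(model: MLPModel, fv: np.ndarray) -> tuple[str, bool]:
    """Class of one feature vector and the derived binary ectopic flag.

    Argmax with deterministic tie-break to the lowest class index
    (N < S < V); a beat is ectopic whenever the winning class is not N.
    """
    out = forward(model, np.asarray(fv, dtype=float))
    label = CLASSES[int(np.argmax(out))]
    return label, label != "N"


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------

class _SCGNetBase(BaseEstimator):
    def __init__(
        self,
        hidden_layer_sizes=(10, 8),
        activation="tanh",
        max_iter=400,
        validation_fraction=0.1,
        patience=8,
        standardize=True,
        random_state=0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.max_iter = max_iter
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.standardize = standardize
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            validation_fraction=self.validation_fraction,
            patience=self.patience,
            max_iterations=self.max_iter,
            seed=self.random_state,
        )

    def _fit_scaler(self, X: np.ndarray) -> np.ndarray:
        if self.standardize:
            self.scale_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_std_ = np.where(sd > 0, sd, 1.0)
        else:
            self.scale_mean_ = np.zeros(X.shape[1])
            self.scale_std_ = np.ones(X.shape[1])
        return self._transform(X)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_mean_) / self.scale_std_


class EctopicBeatClassifier(ClassifierMixin, _SCGNetBase):
    """20-10-8-3 beat classifier (normal / SVEB / VEB), SCG-trained.

    The input layer resizes automatically to the number of feature columns,
    so ECG-only (14) and PPG-only (6) subsets train without further changes.
    Classes are balanced by undersampling the majority classes before
    training (``balance="undersample"``), mirroring equally represented
    training classes; ``predict_ectopic`` collapses S and V onto the binary
    ectopic flag.
    """

    def __init__(
        self,
        hidden_layer_sizes=(10, 8),
        activation="tanh",
        max_iter=400,
        validation_fraction=0.1,
        patience=8,
        balance="undersample",
        standardize=True,
        random_state=0,
    ):
        super().__init__(
            hidden_layer_sizes=hidden_layer_sizes,
            activation=activation,
            max_iter=max_iter,
            validation_fraction=validation_fraction,
            patience=patience,
            standardize=standardize,
            random_state=random_state,
        )
        self.balance = balance

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=object), dtype=float)
        y = y.astype(str)
        self.classes_ = np.array(sorted(set(y.tolist())))
        Xb, yb = balance_classes(
            X, y, mode=self.balance, seed=self.random_state,
            required=tuple(self.classes_),
        )
        Xb = self._fit_scaler(Xb)
        onehot = (yb[:, None] == self.classes_[None, :]).astype(float)
        sizes = [X.shape[1], *self.hidden_layer_sizes, len(self.classes_)]
        model = init_mlp(
            sizes, seed=self.random_state, hidden_activation=self.activation,
            output_mode="softmax_class",
        )
        self.model_ = train(model, Xb, onehot, self._config())
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        return forward(self.model_, self._transform(X))

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def predict_ectopic(self, X):
        return self.predict(X) != "N"


class SCGNetworkRegressor(RegressorMixin, _SCGNetBase):
    """Linear-output MLP regressor on the shared SCG engine."""

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, multi_output=True)
        Y = y[:, None] if y.ndim == 1 else y
        self._y_1d = y.ndim == 1
        Xs = self._fit_scaler(X)
        self.y_mean_ = Y.mean(axis=0)
        self.y_std_ = np.where(Y.std(axis=0) > 0, Y.std(axis=0), 1.0)
        Ys = (Y - self.y_mean_) / self.y_std_
        sizes = [X.shape[1], *self.hidden_layer_sizes, Y.shape[1]]
        model = init_mlp(
            sizes, seed=self.random_state, hidden_activation=self.activation,
            output_mode="linear_regression",
        )
        self.model_ = train(model, Xs, Ys, self._config())
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        out = forward(self.model_, self._transform(X))
        out = out * self.y_std_ + self.y_mean_
        return out[:, 0] if self._y_1d else out
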