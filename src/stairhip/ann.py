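"""Shallow feed-forward network for hip angle/moment regression.

Architecture and training follow the wearable-ANN recipe: 28 inputs per
timestep (13 channels per IMU x 2 sensors, vertical GRF, activity duration),
two tanh hidden layers of five nodes each, a linear 4-unit output layer
(sagittal angle, sagittal moment, frontal angle, frontal moment).  Inputs and
outputs are min-max scaled to [-1, 1]; weights are initialized with the
Nguyen-Widrow rule; training is full-batch Levenberg-Marquardt with the
stopping rule that the error-gradient norm has failed to improve its running
minimum for more than ``stall_limit`` consecutive passes.

The model/results split mirrors statsmodels: build a :class:`HipAnn` from the
feature/target matrices, call :meth:`HipAnn.fit`, and work with the returned
:class:`HipAnnResults` (prediction, diagnostics, ``summary()``, text
serialization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HipAnn", "HipAnnResults", "TrainConfig", "TrainingFailure",
           "minmax_scale", "apply_minmax", "invert_minmax",
           "nguyen_widrow_init", "forward", "train_lm",
           "DEFAULT_LAYER_SIZES"]

DEFAULT_HIDDEN = (5, 5)
DEFAULT_LAYER_SIZES = (28, 5, 5, 4)


class TrainingFailure(RuntimeError):
    """Levenberg-Marquardt could not make progress (damping exhausted)."""


@dataclass(frozen=True)
class TrainConfig:
    """Levenberg-Marquardt training configuration."""

    max_epochs: int = 120
    lambda0: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    lambda_max: float = 1e10
    stall_limit: int = 6  # stop when the gradient stalls for > stall_limit passes
    seed: int = 0

    def __post_init__(self):
        if self.stall_limit < 1:
            raise ValueError("stall_limit must be >= 1")
        if self.lambda0 <= 0:
            raise ValueError("initial damping must be positive")


# ---------------------------------------------------------------------------
# scaling

def minmax_scale(X):
    """Map each column affinely onto [-1, 1].

    Returns ``(X_scaled, params)`` where ``params`` is a dict with per-column
    ``min``, ``max`` and a ``constant`` mask.  Constant columns map to zero and
    are retained (the activity-duration feature is constant within a trial).
    """
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    constant = hi <= lo
    params = {"min": lo, "max": hi, "constant": constant}
    return apply_minmax(X, params), params


def apply_minmax(X, params):
    lo, hi, constant = params["min"], params["max"], params["constant"]
    span = np.where(constant, 1.0, hi - lo)
    Xs = 2.0 * (np.asarray(X, dtype=float) - lo) / span - 1.0
    Xs[:, constant] = 0.0
    return Xs


def invert_minmax(Xs, params):
    lo, hi, constant = params["min"], params["max"], params["constant"]
    span = np.where(constant, 1.0, hi - lo)
    X = (np.asarray(Xs, dtype=float) + 1.0) * span / 2.0 + lo
    X[:, constant] = lo[constant]
    return X


# ---------------------------------------------------------------------------
# initialization / forward pass

def nguyen_widrow_init(layer_sizes, seed=0):
    """Nguyen-Widrow initial weights.

    Hidden layers: random-direction rows rescaled to norm
    ``beta = 0.7 * H**(1/n_in)`` with biases uniform in ``[-beta, beta]``;
    the linear output layer gets small uniform weights and zero biases.
    """
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    n_layers = len(layer_sizes) - 1
    for li in range(n_layers):
        n_in, n_out = layer_sizes[li], layer_sizes[li + 1]
        if li < n_layers - 1:  # tanh hidden layer
            beta = 0.7 * n_out ** (1.0 / n_in)
            W = rng.uniform(-1.0, 1.0, (n_out, n_in))
            norms = np.linalg.norm(W, axis=1, keepdims=True)
            W = beta * W / norms
            b = rng.uniform(-beta, beta, n_out)
        else:  # linear output layer
            W = rng.uniform(-0.5, 0.5, (n_out, n_in))
            b = np.zeros(n_out)
        weights.append(W)
        biases.append(b)
    return weights, biases


def forward(weights, biases, X, return_hidden=False):
    """Forward pass on scaled inputs: tanh, tanh, linear."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != weights[0].shape[1]:
        raise ValueError(
            f"expected {weights[0].shape[1]} features, got {X.shape[1]}")
    a1 = np.tanh(X @ weights[0].T + biases[0])
    a2 = np.tanh(a1 @ weights[1].T + biases[1])
    y = a2 @ weights[2].T + biases[2]
    if return_hidden:
        return y, a1, a2
    return y


def _pack(weights, biases):
    return np.concatenate([np.concatenate([W.ravel(), b])
                           for W, b in zip(weights, biases)])


def _unpack(theta, layer_sizes):
    weights, biases = [], []
    k = 0
    for li in range(len(layer_sizes) - 1):
        n_in, n_out = layer_sizes[li], layer_sizes[li + 1]
        weights.append(theta[k:k + n_out * n_in].reshape(n_out, n_in))
        k += n_out * n_in
        biases.append(theta[k:k + n_out])
        k += n_out
    return weights, biases


def _jacobian(weights, X, a1, a2):
    """Jacobian of all residuals w.r.t. all parameters.

    Residual ordering: sample-major, output-minor -> shape
    ``(N * n_out, n_params)``; parameter ordering matches :func:`_pack`.
    """
    W1, W2, W3 = weights
    n, n_in = X.shape
    h1, h2 = W1.shape[0], W2.shape[0]
    n_out = W3.shape[0]
    d2 = 1.0 - a2 ** 2  # (n, h2)
    d1 = 1.0 - a1 ** 2  # (n, h1)
    # G2[n,k,j] = dy_k/dz2_j ; G1[n,k,i] = dy_k/dz1_i
    G2 = W3[None, :, :] * d2[:, None, :]
    G1 = (G2 @ W2) * d1[:, None, :]
    J_W1 = (G1[:, :, :, None] * X[:, None, None, :]).reshape(n, n_out, -1)
    J_b1 = G1
    J_W2 = (G2[:, :, :, None] * a1[:, None, None, :]).reshape(n, n_out, -1)
    J_b2 = G2
    eye = np.eye(n_out)
    J_W3 = (eye[None, :, :, None] * a2[:, None, None, :]).reshape(n, n_out, -1)
    J_b3 = np.broadcast_to(eye, (n, n_out, n_out))
    J = np.concatenate([J_W1, J_b1, J_W2, J_b2, J_W3, J_b3], axis=2)
    return J.reshape(n * n_out, -1)


def train_lm(weights, biases, X, Y, config=None):
    """Full-batch Levenberg-Marquardt on scaled data.

    Iterates ``(J'J + lambda I) delta = -J'r``; the damping shrinks on
    accepted steps and grows on rejected ones.  Stops at ``max_epochs``, when
    the damping exceeds ``lambda_max`` mid-epoch (step rejected beyond
    recovery), or when the gradient infinity-norm has not improved its running
    minimum for more than ``stall_limit`` consecutive passes.

    Returns ``(weights, biases, log)`` with a log dict carrying per-epoch SSE,
    gradient norms, the accepted-step flags and the stop reason.
    """
    if config is None:
        config = TrainConfig()
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have matching rows")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training rows")
    layer_sizes = (weights[0].shape[1], weights[0].shape[0],
                   weights[1].shape[0], weights[2].shape[0])
    theta = _pack(weights, biases)
    lam = config.lambda0

    def evaluate(th):
        w, b = _unpack(th, layer_sizes)
        y, A1, A2 = forward(w, b, X, return_hidden=True)
        r = (y - Y).ravel()
        return w, b, A1, A2, r

    w, b, a1, a2, r = evaluate(theta)
    sse = float(r @ r)
    log = {"sse": [sse], "grad_norm": [], "lambda": [], "stop_reason": None,
           "epochs": 0}
    best_grad = np.inf
    stall = 0
    eye = None
    for epoch in range(config.max_epochs):
        J = _jacobian(w, X, a1, a2)
        g = J.T @ r
        gnorm = float(np.max(np.abs(g)))
        if gnorm < best_grad - 1e-15:
            best_grad = gnorm
            stall = 0
        else:
            stall += 1
        log["grad_norm"].append(gnorm)
        if stall > config.stall_limit:
            log["stop_reason"] = "gradient_stall"
            break
        JtJ = J.T @ J
        if eye is None:
            eye = np.eye(JtJ.shape[0])
        accepted = False
        while lam <= config.lambda_max:
            try:
                delta = np.linalg.solve(JtJ + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= config.lambda_up
                continue
            w2, b2, A1, A2, r2 = evaluate(theta + delta)
            sse2 = float(r2 @ r2)
            if np.isfinite(sse2) and sse2 < sse:
                theta = theta + delta
                w, b, a1, a2, r = w2, b2, A1, A2, r2
                sse = sse2
                lam = max(lam * config.lambda_down, 1e-20)
                accepted = True
                break
            lam *= config.lambda_up
        log["sse"].append(sse)
        log["lambda"].append(lam)
        log["epochs"] = epoch + 1
        if not accepted:
            if epoch == 0 and lam > config.lambda_max:
                log["stop_reason"] = "training_failure"
                raise TrainingFailure(
                    "no acceptable Levenberg-Marquardt step at maximum damping")
            log["stop_reason"] = "lambda_max"
            break
    if log["stop_reason"] is None:
        log["stop_reason"] = "max_epochs"
    return w, b, log


# ---------------------------------------------------------------------------
# model / results objects

FEATURE_GROUPS = (
    [f"shank_{c}" for c in ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y",
                            "gyr_z", "mag_x", "mag_y", "mag_z", "quat_w",
                            "quat_x", "quat_y", "quat_z")]
    + [f"thigh_{c}" for c in ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y",
                              "gyr_z", "mag_x", "mag_y", "mag_z", "quat_w",
                              "quat_x", "quat_y", "quat_z")]
    + ["grf_v", "duration_s"]
)

DEFAULT_TARGETS = ("sagittal_angle", "sagittal_moment",
                   "frontal_angle", "frontal_moment")


class HipAnn:
    """Shallow ANN regression model of hip angles/moments from wearables.

    Parameters
    ----------
    X : (N, 28) per-timestep feature matrix (two 13-channel IMUs, vertical
        GRF, activity duration)
    Y : (N, 4) targets in original units (deg / Nm/kg)
    hidden : hidden layer sizes, default (5, 5)
    seed : Nguyen-Widrow initialization seed
    """

    def __init__(self, X, Y, hidden=DEFAULT_HIDDEN, seed=0,
                 feature_names=None, target_names=DEFAULT_TARGETS):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have matching rows")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("features and targets must be finite")
        self.X, self.Y = X, Y
        self.hidden = tuple(hidden)
        self.seed = seed
        self.layer_sizes = (X.shape[1], *self.hidden, Y.shape[1])
        self.feature_names = list(feature_names) if feature_names else \
            [f"x{i}" for i in range(X.shape[1])]
        self.target_names = list(target_names)[: Y.shape[1]]

    @classmethod
    def from_trials(cls, prepared, stride=1, **kwargs):
        """Stack feature/target matrices of prepared trials (see
        :mod:`stairhip.pipeline`), optionally subsampling rows."""
        X = np.vstack([p.X[::stride] for p in prepared])
        Y = np.vstack([p.Y[::stride] for p in prepared])
        kwargs.setdefault("feature_names", FEATURE_GROUPS)
        return cls(X, Y, **kwargs)

    def fit(self, config=None):
        if config is None:
            config = TrainConfig(seed=self.seed)
        Xs, xparams = minmax_scale(self.X)
        Ys, yparams = minmax_scale(self.Y)
        weights, biases = nguyen_widrow_init(self.layer_sizes, seed=config.seed)
        weights, biases, log = train_lm(weights, biases, Xs, Ys, config)
        return HipAnnResults(self, weights, biases, xparams, yparams, log,
                             config)


class HipAnnResults:
    """Fitted wearable-ANN model."""

    def __init__(self, model, weights, biases, xscale, yscale, log, config):
        self.model = model
        self.weights = weights
        self.biases = biases
        self.xscale = xscale
        self.yscale = yscale
        self.log = log
        self.config = config

    def predict(self, X):
        """Predict targets in original units for raw features ``X``."""
        Xs = apply_minmax(np.atleast_2d(np.asarray(X, dtype=float)),
                          self.xscale)
        Ys = forward(self.weights, self.biases, Xs)
        return invert_minmax(Ys, self.yscale)

    @property
    def fittedvalues(self):
        return self.predict(self.model.X)

    @property
    def n_params(self):
        return sum(W.size + b.size
                   for W, b in zip(self.weights, self.biases))

    def score(self):
        """Training-set R^2 and rRMSE (%) per output."""
        from .evaluation import r_squared, rrmse

        yhat = self.fittedvalues
        rows = {}
        for k, name in enumerate(self.model.target_names):
            rows[name] = {"r2": r_squared(self.model.Y[:, k], yhat[:, k]),
                          "rrmse": rrmse(self.model.Y[:, k], yhat[:, k])}
        return rows

    def summary(self):
        lines = [
            "Wearable-ANN hip angle/moment regression",
            "=" * 56,
            f"layers: {'-'.join(map(str, self.model.layer_sizes))} "
            "(tanh, tanh, linear)",
            f"parameters: {self.n_params}   training rows: "
            f"{self.model.X.shape[0]}",
            f"epochs: {self.log['epochs']}   stop: {self.log['stop_reason']}"
            f"   final SSE (scaled): {self.log['sse'][-1]:.6g}",
            "-" * 56,
            f"{'output':<18}{'R^2':>10}{'rRMSE %':>12}",
        ]
        for name, row in self.score().items():
            lines.append(f"{name:<18}{row['r2']:>10.3f}{row['rrmse']:>12.2f}")
        return "\n".join(lines)

    def save(self, path):
        """Serialize to a structured text (JSON) file."""
        payload = {
            "layer_sizes": list(self.model.layer_sizes),
            "target_names": self.model.target_names,
            "feature_names": self.model.feature_names,
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "xscale": {k: np.asarray(v).tolist()
                       for k, v in self.xscale.items()},
            "yscale": {k: np.asarray(v).tolist()
                       for k, v in self.yscale.items()},
            "seed": self.config.seed,
            "log": {"epochs": self.log["epochs"],
                    "stop_reason": self.log["stop_reason"],
                    "final_sse": self.log["sse"][-1]},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        weights = [np.asarray(W) for W in payload["weights"]]
        biases = [np.asarray(b) for b in payload["biases"]]

        def scale(d):
            return {"min": np.asarray(d["min"]), "max": np.asarray(d["max"]),
                    "constant": np.asarray(d["constant"], dtype=bool)}

        model = HipAnn.__new__(HipAnn)
        model.layer_sizes = tuple(payload["layer_sizes"])
        model.hidden = tuple(payload["layer_sizes"][1:-1])
        model.feature_names = payload["feature_names"]
        model.target_names = payload["target_names"]
        model.seed = payload["seed"]
        model.X = model.Y = None
        log = {"epochs": payload["log"]["epochs"],
               "stop_reason": payload["log"]["stop_reason"],
               "sse": [payload["log"]["final_sse"]]}
        return cls(model, weights, biases, scale(payload["xscale"]),
                   scale(payload["yscale"]), log,
                   TrainConfig(seed=payload["seed"]))
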