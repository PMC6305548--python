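"""Three-layer back-propagation neural network (16-20-2) with momentum.

The classifier is a fully connected logistic-activation network trained
by per-sample gradient descent with momentum on the squared error between
the 2-bit class code and the network output.  Class coding:

    FB -> (0, 0),  RB -> (0, 1),  LS -> (1, 0),  RS -> (1, 1)

Raw outputs are thresholded at 0.5 (>= 0.5 reads as bit 1) and decoded
through the same map.  Training stops when the epoch mean squared error
falls below the error threshold or after ``max_epochs`` passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import normalize_features

#: 2-bit target code per class and its inverse.
LABEL_CODING = {"FB": (0, 0), "RB": (0, 1), "LS": (1, 0), "RS": (1, 1)}
CODE_TO_LABEL = {v: k for k, v in LABEL_CODING.items()}


@dataclass
class NetworkParams:
    input_nodes: int = 16
    hidden_nodes: int = 20
    output_nodes: int = 2
    learning_rate: float = 0.5
    momentum: float = 0.9
    error_threshold: float = 0.01
    max_epochs: int = 5000
    init_range: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.input_nodes, self.hidden_nodes, self.output_nodes) < 1:
            raise ValueError("layer sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.1 <= self.learning_rate <= 0.9:
            import logging
            logging.getLogger(__name__).warning(
                "learning rate %.3g outside the recommended [0.1, 0.9] range",
                self.learning_rate)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class BPNN:
    """Back-propagation network with one hidden layer.

    Weights are initialised uniformly in +/- ``init_range``; updates use
    sequential (per-sample) gradient descent with momentum.
    """

    def __init__(self, params: NetworkParams | None = None):
        self.params = params or NetworkParams()
        p = self.params
        rng = np.random.default_rng(p.seed)
        self.W_in = rng.uniform(-p.init_range, p.init_range,
                                (p.hidden_nodes, p.input_nodes))
        self.b_in = rng.uniform(-p.init_range, p.init_range, p.hidden_nodes)
        self.W_out = rng.uniform(-p.init_range, p.init_range,
                                 (p.output_nodes, p.hidden_nodes))
        self.b_out = rng.uniform(-p.init_range, p.init_range, p.output_nodes)
        self.loss_trace: list = []

    # -- forward / backward ------------------------------------------------

    def forward(self, x):
        """Hidden and output activations for one sample (1-D input)."""
        h = _sigmoid(self.W_in @ x + self.b_in)
        o = _sigmoid(self.W_out @ h + self.b_out)
        return h, o

    def _grads(self, x, target):
        """Per-sample gradients of E = 0.5 * ||t - o||^2."""
        h, o = self.forward(x)
        delta_o = (o - target) * o * (1 - o)
        delta_h = (self.W_out.T @ delta_o) * h * (1 - h)
        return {
            "W_out": np.outer(delta_o, h), "b_out": delta_o,
            "W_in": np.outer(delta_h, x), "b_in": delta_h,
        }, o

    def batch_loss(self, X, T):
        """Mean squared error over a batch (for diagnostics and gradient
        checking)."""
        errs = [np.mean((t - self.forward(x)[1]) ** 2) for x, t in zip(X, T)]
        return float(np.mean(errs))

    def batch_grads(self, X, T):
        """Summed per-sample gradients of the epoch MSE (same scale as
        ``batch_loss``), used by the finite-difference check."""
        total = {k: 0.0 for k in ("W_in", "b_in", "W_out", "b_out")}
        n, n_out = len(X), self.params.output_nodes
        for x, t in zip(X, T):
            g, _ = self._grads(x, t)
            for k in total:
                total[k] = total[k] + g[k] * (2.0 / (n * n_out))
        return total

    # -- training ----------------------------------------------------------

    def train(self, features, targets):
        """Sequential training pass with momentum until the epoch MSE
        drops below the error threshold.  Returns the loss trace."""
        X = np.asarray(features, dtype=float)
        T = np.asarray(targets, dtype=float)
        p = self.params
        vel = {k: np.zeros_like(getattr(self, k))
               for k in ("W_in", "b_in", "W_out", "b_out")}
        self.loss_trace = []
        for epoch_i in range(p.max_epochs):
            sq_err = 0.0
            for x, t in zip(X, T):
                g, o = self._grads(x, t)
                sq_err += np.mean((t - o) ** 2)
                for k in vel:
                    vel[k] = -p.learning_rate * g[k] + p.momentum * vel[k]
                    setattr(self, k, getattr(self, k) + vel[k])
            mse = sq_err / len(X)
            if np.isnan(mse):
                raise FloatingPointError(f"NaN loss at epoch {epoch_i}")
            self.loss_trace.append(mse)
            if mse < p.error_threshold:
                break
        return self.loss_trace

    # -- inference ---------------------------------------------------------

    def predict(self, features):
        """Class labels and raw outputs for a feature matrix."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        raw = np.array([self.forward(x)[1] for x in X])
        bits = (raw >= 0.5).astype(int)
        labels = [CODE_TO_LABEL[tuple(b)] for b in bits]
        return labels, raw


def encode_labels(labels):
    return np.array([LABEL_CODING[lab] for lab in labels], dtype=float)


def train_classifier(features, labels, params: NetworkParams | None = None):
    """Train a BPNN on an (n, 16) feature matrix with string labels."""
    if len(set(labels)) < 1:
        raise ValueError("need at least one class")
    net = BPNN(params)
    net.train(features, encode_labels(labels))
    return net


def crossvalidate(features, labels, k: int = 5, seed: int = 0,
                  params: NetworkParams | None = None):
    """Stratified k-fold cross-validation with fold-local normalisation.

    The min-max scaler is fit inside each training fold only, so no test
    information leaks into scaling.  Returns a dict with per-fold
    accuracies (percent), their mean and standard deviation.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    counts = {lab: int(np.sum(y == lab)) for lab in set(labels)}
    if min(counts.values()) < k:
        raise ValueError(f"every class needs >= {k} samples, got {counts}")
    params = params or NetworkParams()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, fold_indices = [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, _, scaler = normalize_features(X[tr])
        Xte = scaler.transform(X[te])
        fold_params = NetworkParams(**{**params.__dict__,
                                       "seed": params.seed + fold})
        net = train_classifier(Xtr, list(y[tr]), fold_params)
        pred, _ = net.predict(Xte)
        accs.append(100.0 * np.mean(np.asarray(pred) == y[te]))
        fold_indices.append((tr, te))
    accs = np.array(accs)
    return {"fold_accuracies": accs, "mean": float(accs.mean()),
            "sd": float(accs.std(ddof=1)), "folds": fold_indices}
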