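"""Feed-forward neural-network activity model (6-3-1 by default).

A deliberately small, fully deterministic trainer: one sigmoid hidden layer,
identity output, full-batch gradient descent with momentum on halved mean
squared error, inputs min-max scaled to [0, 1], target left unscaled.
Training is a pure function of (data, spec): the same seed and data give
bit-identical weights.

With 6 inputs and 3 hidden units the network has 25 free parameters — as
many as there are training compounds in the study — so near-interpolation
of the training set (R-squared close to 1) is expected and is a capacity
statement, not evidence of predictivity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import MODEL_TERMS
from .regression import FitStatistics, _design, _ols_statistics


@dataclass
class NetworkSpec:
    """Architecture and training hyper-parameters of the network.

    ``rho`` — the ratio of input to hidden units — is recorded as metadata
    with its conventional validity range of 1..3; it does not constrain
    training.
    """

    n_inputs: int = 6
    n_hidden: int = 3
    n_outputs: int = 1
    hidden_activation: str = "sigmoid"
    output_activation: str = "identity"
    seed: int = 20250
    epochs: int = 50000
    learning_rate: float = 0.2
    momentum: float = 0.9
    input_scaling: str = "minmax"

    @property
    def rho(self) -> float:
        return self.n_inputs / self.n_hidden

    def validate(self) -> None:
        if self.n_hidden < 1 or self.n_inputs < 1:
            raise ValueError("network needs at least one input and one hidden unit")
        if self.hidden_activation != "sigmoid" or self.output_activation != "identity":
            raise ValueError("only sigmoid hidden / identity output is supported")
        if self.input_scaling != "minmax":
            raise ValueError("only min-max input scaling is supported")
        if not np.isfinite(self.rho):
            raise ValueError("architecture ratio rho must be finite")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rho"] = self.rho
        d["rho_in_recommended_range"] = bool(1.0 <= self.rho <= 3.0)
        return d


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


class ANNQSAR(RegressorMixin, BaseEstimator):
    """Seeded feed-forward network regressor.

    Parameters mirror :class:`NetworkSpec`; ``n_inputs`` is inferred from
    the data at fit time and checked against the spec.

    Attributes
    ----------
    W1_, b1_, W2_, b2_ : ndarray
        Trained weights (input->hidden matrix, hidden biases, hidden->output
        vector, output bias).
    x_min_, x_max_ : ndarray
        Min-max scaling parameters frozen from the training inputs.
    stats_ : FitStatistics
        Training-set fit summary (mse here is residual SS / (n - p - 1)
        with p the number of descriptors, matching the linear model's
        convention for comparability).
    loss_curve_ : ndarray
        Halved-MSE training loss per epoch.
    """

    def __init__(self, n_hidden=3, epochs=50000, learning_rate=0.2,
                 momentum=0.9, seed=20250, terms=None):
        self.n_hidden = n_hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.seed = seed
        self.terms = terms

    @property
    def terms_(self):
        return list(self.terms) if self.terms is not None else list(MODEL_TERMS)

    def spec(self, n_inputs=None) -> NetworkSpec:
        return NetworkSpec(
            n_inputs=n_inputs if n_inputs is not None else len(self.terms_),
            n_hidden=self.n_hidden, epochs=self.epochs,
            learning_rate=self.learning_rate, momentum=self.momentum,
            seed=self.seed)

    def fit(self, X, y):
        Xd = _design(X, self.terms_)
        y = np.asarray(y, dtype=float)
        if len(Xd) == 0:
            raise ValueError("no training records")
        spec = self.spec(n_inputs=Xd.shape[1])
        spec.validate()

        self.x_min_ = Xd.min(axis=0)
        self.x_max_ = Xd.max(axis=0)
        span = np.where(self.x_max_ > self.x_min_, self.x_max_ - self.x_min_, 1.0)
        Xs = (Xd - self.x_min_) / span

        rng = np.random.default_rng(spec.seed)
        h = spec.n_hidden
        W1 = rng.uniform(-0.5, 0.5, size=(Xd.shape[1], h))
        b1 = rng.uniform(-0.5, 0.5, size=h)
        W2 = rng.uniform(-0.5, 0.5, size=h)
        b2 = float(y.mean())  # start the output at the target mean

        vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
        vW2 = np.zeros_like(W2); vb2 = 0.0
        n = len(y)
        lr, mom = spec.learning_rate, spec.momentum
        losses = np.empty(spec.epochs)
        for epoch in range(spec.epochs):
            H = _sigmoid(Xs @ W1 + b1)
            yhat = H @ W2 + b2
            err = yhat - y
            loss = 0.5 * float(err @ err) / n
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            losses[epoch] = loss
            gy = err / n
            gW2 = H.T @ gy
            gb2 = float(gy.sum())
            gH = np.outer(gy, W2) * H * (1.0 - H)
            gW1 = Xs.T @ gH
            gb1 = gH.sum(axis=0)
            vW2 = mom * vW2 - lr * gW2; W2 = W2 + vW2
            vb2 = mom * vb2 - lr * gb2; b2 = b2 + vb2
            vW1 = mom * vW1 - lr * gW1; W1 = W1 + vW1
            vb1 = mom * vb1 - lr * gb1; b1 = b1 + vb1

        self.W1_, self.b1_, self.W2_, self.b2_ = W1, b1, W2, b2
        self.loss_curve_ = losses
        self.n_features_in_ = Xd.shape[1]
        yhat = self._forward(Xs)
        self.stats_ = _ols_statistics(y, yhat, Xd.shape[1])
        return self

    def _forward(self, Xs):
        return _sigmoid(Xs @ self.W1_ + self.b1_) @ self.W2_ + self.b2_

    def predict(self, X):
        check_is_fitted(self, "W1_")
        Xd = _design(X, self.terms_)
        span = np.where(self.x_max_ > self.x_min_, self.x_max_ - self.x_min_, 1.0)
        return self._forward((Xd - self.x_min_) / span)

    def to_json(self) -> str:
        check_is_fitted(self, "W1_")
        return json.dumps({
            "spec": self.spec(n_inputs=self.n_features_in_).to_dict(),
            "terms": self.terms_,
            "W1": self.W1_.tolist(), "b1": self.b1_.tolist(),
            "W2": self.W2_.tolist(), "b2": self.b2_,
            "x_min": self.x_min_.tolist(), "x_max": self.x_max_.tolist(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ANNQSAR":
        payload = json.loads(text)
        spec = payload["spec"]
        model = cls(n_hidden=spec["n_hidden"], epochs=spec["epochs"],
                    learning_rate=spec["learning_rate"],
                    momentum=spec.get("momentum", 0.9),
                    seed=spec["seed"], terms=payload["terms"])
        model.W1_ = np.asarray(payload["W1"], dtype=float)
        model.b1_ = np.asarray(payload["b1"], dtype=float)
        model.W2_ = np.asarray(payload["W2"], dtype=float)
        model.b2_ = float(payload["b2"])
        model.x_min_ = np.asarray(payload["x_min"], dtype=float)
        model.x_max_ = np.asarray(payload["x_max"], dtype=float)
        model.n_features_in_ = model.W1_.shape[0]
        return model


def train_ann(records: pd.DataFrame, spec: NetworkSpec | None = None) -> ANNQSAR:
    """Train the network on modeling records (``pIC50_obs`` as target)."""
    spec = spec or NetworkSpec()
    model = ANNQSAR(n_hidden=spec.n_hidden, epochs=spec.epochs,
                    learning_rate=spec.learning_rate, momentum=spec.momentum,
                    seed=spec.seed)
    return model.fit(records, records["pIC50_obs"])
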