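"""Ordinal outcome model families on tabular design matrices.

Four families predict the seven-category 6-month GOSE from a prepared
design matrix:

* :class:`MultinomialLogit` (MNLR) -- maximum-likelihood multinomial
  logistic regression; multinomial outcome encoding.
* :class:`ProportionalOddsLogit` (POLR) -- cumulative-link ordinal logistic
  regression, ``P(Y <= k) = sigmoid(theta_k - x'beta)`` so positive
  coefficients shift patients towards better outcomes.
* :class:`DeepMultinomial` (DeepMN) -- class-weighted feedforward network
  with a 7-node softmax output layer.
* :class:`DeepOrdinal` (DeepOR) -- class-weighted feedforward network with
  a 6-node constrained-sigmoid output layer (negative-ReLU monotonicity).

All estimators expose ``predict_proba`` (7 category probabilities,
summing to one), ``predict_threshold_probs`` (6 exceedance probabilities,
non-increasing), ``predict`` (modal category code) and ``risk_score``
(expected number of thresholds exceeded). Network training uses Adam with
early stopping on a class-weighted validation loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted
from statsmodels.miscmodels.ordinal_model import OrderedModel

from ._net import Adam, EarlyStopper, MLPCore, minibatches
from .probability import (
    N_CATEGORIES,
    N_THRESHOLDS,
    class_to_threshold_probs,
    class_weights,
    ordinal_output_transform,
    softmax_to_class_probs,
    threshold_to_class_probs,
)

CATEGORY_CODES = np.arange(1, N_CATEGORIES + 1)


class ConvergenceWarning(UserWarning):
    pass


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _sample_weights(y: np.ndarray, class_weighted: bool) -> np.ndarray:
    """Per-sample inverse-frequency weights (mean one over present classes)."""
    if not class_weighted:
        return np.ones(len(y))
    codes, counts = np.unique(y, return_counts=True)
    w = len(y) / (len(codes) * counts)
    w = w / w.mean()
    lookup = dict(zip(codes, w))
    return np.array([lookup[c] for c in y])


class OrdinalPredictorMixin:
    """Shared prediction surface over the 7 categories / 6 thresholds."""

    def predict_threshold_probs(self, X) -> np.ndarray:
        return class_to_threshold_probs(self.predict_proba(X))

    def predict(self, X) -> np.ndarray:
        return CATEGORY_CODES[np.argmax(self.predict_proba(X), axis=1)]

    def risk_score(self, X) -> np.ndarray:
        """Expected number of thresholds exceeded; monotone in stochastic order."""
        return self.predict_threshold_probs(X).sum(axis=1)


def _expand_to_seven(probs: np.ndarray, classes: np.ndarray) -> np.ndarray:
    full = np.zeros((len(probs), N_CATEGORIES))
    for j, c in enumerate(classes):
        full[:, int(c) - 1] = probs[:, j]
    return full


class MultinomialLogit(OrdinalPredictorMixin, BaseEstimator):
    """Maximum-likelihood multinomial logistic regression (MNLR)."""

    def __init__(self, max_iter: int = 2000):
        self.max_iter = max_iter

    def fit(self, X, y, validation_data=None):
        X = _as_array(X)
        y = np.asarray(y, dtype=int)
        self.model_ = LogisticRegression(penalty=None, solver="lbfgs",
                                         max_iter=self.max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        self.converged_ = bool(np.all(self.model_.n_iter_ < self.max_iter))
        if not self.converged_:
            warnings.warn("multinomial logistic fit hit the iteration limit",
                          ConvergenceWarning, stacklevel=2)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return _expand_to_seven(self.model_.predict_proba(_as_array(X)),
                                self.classes_)


class ProportionalOddsLogit(OrdinalPredictorMixin, BaseEstimator):
    """Cumulative-link (proportional odds) ordinal logistic regression (POLR).

    Fitted by maximum likelihood via statsmodels' ordered model. The design
    matrix must not contain a complete one-hot group (use
    ``drop_first=True`` in the design builder): the thresholds absorb the
    intercept. Exposes ``coef_`` (named Series), ``conf_int_`` (95% Wald
    intervals for the predictor coefficients) and ``converged_``.
    """

    def __init__(self, max_iter: int = 200, method: str = "bfgs"):
        self.max_iter = max_iter
        self.method = method

    def fit(self, X, y, validation_data=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            exog = X.to_numpy(dtype=float)
        else:
            exog = np.asarray(X, dtype=float)
            self.feature_names_ = [f"x{j}" for j in range(exog.shape[1])]
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        endog = pd.Series(pd.Categorical(y, categories=list(self.classes_),
                                         ordered=True))
        model = OrderedModel(endog, exog, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.result_ = model.fit(method=self.method, maxiter=self.max_iter,
                                     disp=False)
        self.converged_ = bool(self.result_.mle_retvals.get("converged", True))
        if not self.converged_:
            warnings.warn("ordinal logistic fit did not converge",
                          ConvergenceWarning, stacklevel=2)
        k = exog.shape[1]
        self.coef_ = pd.Series(np.asarray(self.result_.params)[:k],
                               index=self.feature_names_)
        self.bse_ = pd.Series(np.asarray(self.result_.bse)[:k],
                              index=self.feature_names_)
        ci = np.asarray(self.result_.conf_int())[:k]
        self.conf_int_ = pd.DataFrame(ci, index=self.feature_names_,
                                      columns=["low", "high"])
        self.llf_ = float(self.result_.llf)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "result_")
        probs = self.result_.model.predict(self.result_.params, exog=_as_array(X))
        return _expand_to_seven(probs, self.classes_)


class _DeepBase(OrdinalPredictorMixin, BaseEstimator):
    """Shared minibatch Adam training loop for the network families."""

    def __init__(self, hidden_layer_sizes=(), dropout: float = 0.0,
                 learning_rate: float = 3e-3, epochs: int = 200,
                 batch_size: int = 128, patience: int = 10,
                 class_weighted: bool = True, validation_fraction: float = 0.15,
                 random_state: int = 0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.class_weighted = class_weighted
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    _n_out: int = N_CATEGORIES

    def _loss_and_grad(self, z, y, w):
        raise NotImplementedError

    def _loss_only(self, z, y, w) -> float:
        return self._loss_and_grad(z, y, w)[0]

    def fit(self, X, y, validation_data=None):
        X = _as_array(X)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng([17, self.random_state])
        if validation_data is None and self.patience and len(y) >= 40:
            try:
                X, X_val, y, y_val = train_test_split(
                    X, y, test_size=self.validation_fraction,
                    stratify=y, random_state=self.random_state)
                validation_data = (X_val, y_val)
            except ValueError:
                validation_data = None
        w = _sample_weights(y, self.class_weighted)
        codes = np.unique(y)
        weight_by_code = {c: w[y == c][0] for c in codes}

        self.net_ = MLPCore([X.shape[1], *self.hidden_layer_sizes, self._n_out],
                            rng, dropout=self.dropout)
        opt = Adam(self.net_.params, lr=self.learning_rate)
        stopper = EarlyStopper(self.patience) if (self.patience and
                                                  validation_data is not None) else None
        if validation_data is not None:
            X_val = _as_array(validation_data[0])
            y_val = np.asarray(validation_data[1], dtype=int)
            w_val = np.array([weight_by_code.get(c, 1.0) for c in y_val])
        self.loss_curve_, self.val_loss_curve_ = [], []
        for _ in range(self.epochs):
            epoch_loss, n_seen = 0.0, 0
            for idx in minibatches(len(y), self.batch_size, rng):
                z, cache = self.net_.forward(X[idx], train=True, rng=rng)
                loss, dz = self._loss_and_grad(z, y[idx], w[idx])
                grads, _ = self.net_.backward(dz, cache)
                opt.step(self.net_.params, grads)
                epoch_loss += loss * len(idx)
                n_seen += len(idx)
            self.loss_curve_.append(epoch_loss / n_seen)
            if validation_data is not None:
                z_val, _ = self.net_.forward(X_val)
                val_loss = self._loss_only(z_val, y_val, w_val)
                self.val_loss_curve_.append(val_loss)
                if stopper is not None and stopper.update(val_loss, self.net_.params):
                    break
        if stopper is not None and stopper.best_params is not None:
            self.net_.set_params_flat(stopper.best_params)
        return self

    def _forward(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        z, _ = self.net_.forward(_as_array(X))
        return z


class DeepMultinomial(_DeepBase):
    """Class-weighted feedforward network with a 7-node softmax head (DeepMN)."""

    _n_out = N_CATEGORIES

    def _loss_and_grad(self, z, y, w):
        p = softmax_to_class_probs(z)
        onehot = np.zeros_like(p)
        onehot[np.arange(len(y)), y - 1] = 1.0
        eps = 1e-12
        loss = float(-(w * np.log(p[np.arange(len(y)), y - 1] + eps)).mean())
        dz = w[:, None] * (p - onehot) / len(y)
        return loss, dz

    def predict_proba(self, X) -> np.ndarray:
        return softmax_to_class_probs(self._forward(X))


class DeepOrdinal(_DeepBase):
    """Class-weighted feedforward network with a 6-node constrained-sigmoid
    head (DeepOR); threshold probabilities are non-increasing by construction."""

    _n_out = N_THRESHOLDS

    @staticmethod
    def _head(z):
        h = np.empty_like(z)
        h[:, 0] = z[:, 0]
        for k in range(1, N_THRESHOLDS):
            h[:, k] = h[:, k - 1] - np.maximum(z[:, k], 0.0)
        return h, expit(h)

    def _loss_and_grad(self, z, y, w):
        h, p = DeepOrdinal._head(z)
        targets = (y[:, None] > np.arange(1, N_THRESHOLDS + 1)[None, :]).astype(float)
        eps = 1e-12
        bce = -(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps))
        loss = float((w[:, None] * bce).sum(axis=1).mean())
        g = w[:, None] * (p - targets) / len(y)        # dL/dh
        suffix = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]  # sum_{k>=j} g_k
        dz = np.empty_like(z)
        dz[:, 0] = suffix[:, 0]
        dz[:, 1:] = -(z[:, 1:] > 0).astype(float) * suffix[:, 1:]
        return loss, dz

    def predict_threshold_probs(self, X) -> np.ndarray:
        return ordinal_output_transform(self._forward(X))

    def predict_proba(self, X) -> np.ndarray:
        return threshold_to_class_probs(self.predict_threshold_probs(X))


@dataclass
class ModelConfig:
    """Configuration of one model family instance."""

    family: str  # 'MNLR' | 'POLR' | 'DeepMN' | 'DeepOR'
    hidden_layer_sizes: tuple = ()
    dropout: float = 0.0
    learning_rate: float = 3e-3
    epochs: int = 200
    batch_size: int = 128
    patience: int = 10
    class_weighted: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)


def make_model(config: ModelConfig):
    """Instantiate the estimator for a model configuration."""
    if config.family == "MNLR":
        return MultinomialLogit(**config.extra)
    if config.family == "POLR":
        return ProportionalOddsLogit(**config.extra)
    cls = {"DeepMN": DeepMultinomial, "DeepOR": DeepOrdinal}.get(config.family)
    if cls is None:
        raise ValueError(f"unknown model family {config.family!r}")
    return cls(hidden_layer_sizes=config.hidden_layer_sizes,
               dropout=config.dropout, learning_rate=config.learning_rate,
               epochs=config.epochs, batch_size=config.batch_size,
               patience=config.patience, class_weighted=config.class_weighted,
               random_state=config.seed, **config.extra)


def fit_model(config: ModelConfig, X, y, validation_data=None):
    """Fit one model family on a training design matrix.

    Linear families are fitted by maximum likelihood; network families by
    seeded stochastic gradient training with class-weighted loss and early
    stopping on the validation loss.
    """
    return make_model(config).fit(X, y, validation_data=validation_data)
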