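"""Token-embedding all-predictor models (APM).

A patient is represented by the set of unique tokens extracted from their
first 24 hours of ICU data. The model learns, for every vocabulary entry,
a low-dimensional embedding vector ``v_i`` and a significance parameter
``s_i`` whose exponential is the token's positive weight. A patient with
token set T (|T| = N) is summarised as

    u = (1/N) * sum_{i in T} exp(s_i) * v_i,

i.e. a significance-weighted average of embeddings divided by the token
count. The summary vector feeds a (possibly zero-hidden-layer) dense trunk
with either a multinomial softmax head (APM_MN) or a constrained-sigmoid
ordinal head (APM_OR). Everything -- embeddings, significance weights,
trunk, head -- is trained jointly by seeded minibatch Adam with a
class-weighted loss and early stopping on validation loss.

Token sequences are sets: aggregation is invariant to token order. Index 0
is the unrecognised-token placeholder; its embedding is initialised at zero
so tokens first seen at test time are near-neutral.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from ._net import Adam, EarlyStopper, MLPCore, minibatches
from .models import DeepMultinomial, DeepOrdinal, OrdinalPredictorMixin, _sample_weights
from .probability import (
    N_CATEGORIES,
    N_THRESHOLDS,
    class_to_threshold_probs,
    ordinal_output_transform,
    softmax_to_class_probs,
    threshold_to_class_probs,
)


def embed_and_aggregate(indices, embeddings: np.ndarray,
                        significance: np.ndarray) -> np.ndarray:
    """Significance-weighted mean embedding of one token set.

    ``u = (1/N) sum_i exp(s_i) v_i`` with N the token count. The divisor is
    the token count, not the weight total, so the overall scale of a
    patient's summary reflects how significant their tokens are.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty token set cannot be aggregated")
    if idx.max() >= len(embeddings):
        raise ValueError("token index outside vocabulary")
    w = np.exp(significance[idx])
    return (w[:, None] * embeddings[idx]).sum(axis=0) / len(idx)


def _sequences_to_indices(sequences) -> list[np.ndarray]:
    out = []
    for s in sequences:
        idx = s if isinstance(s, (list, tuple, np.ndarray)) else s.indices
        out.append(np.asarray(idx, dtype=int))
    return out


class TokenEmbeddingModel(OrdinalPredictorMixin, BaseEstimator):
    """Jointly trained embedding + significance-weighted averaging + ordinal head.

    Parameters
    ----------
    vocab_size : int or None
        Vocabulary size including the placeholder; inferred from the
        training sequences when None.
    embedding_dim : int
        Embedding dimension (default 64).
    head : str
        'MN' (softmax over 7 categories) or 'OR' (constrained sigmoid over
        6 thresholds).
    hidden_layer_sizes : tuple
        Trunk hidden layers; empty for the logistic-regression-like model.
    """

    def __init__(self, vocab_size: int | None = None, embedding_dim: int = 64,
                 head: str = "MN", hidden_layer_sizes=(), dropout: float = 0.0,
                 learning_rate: float = 3e-3, epochs: int = 150,
                 batch_size: int = 64, patience: int = 10,
                 class_weighted: bool = True, validation_fraction: float = 0.15,
                 random_state: int = 0):
        self.vocab_size = vocab_size
        self.embedding_dim = embedding_dim
        self.head = head
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.class_weighted = class_weighted
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _aggregate_batch(self, seqs: list[np.ndarray]) -> np.ndarray:
        U = np.zeros((len(seqs), self.embedding_dim))
        for r, idx in enumerate(seqs):
            if idx.size:
                w = np.exp(self.significance_[idx])
                U[r] = (w[:, None] * self.embeddings_[idx]).sum(axis=0) / len(idx)
        return U

    def _head_loss_and_grad(self, z, y, w):
        if self.head == "MN":
            return DeepMultinomial._loss_and_grad(self, z, y, w)
        return DeepOrdinal._loss_and_grad(self, z, y, w)

    def fit(self, sequences, y, validation_data=None):
        if self.head not in ("MN", "OR"):
            raise ValueError("head must be 'MN' or 'OR'")
        seqs = _sequences_to_indices(sequences)
        y = np.asarray(y, dtype=int)
        if len(seqs) != len(y):
            raise ValueError("sequences and outcomes differ in length")
        n_vocab = self.vocab_size or int(max(ix.max() for ix in seqs if ix.size) + 1)
        for ix in seqs:
            if ix.size and ix.max() >= n_vocab:
                raise ValueError("sequence index outside the stated vocabulary")
        self.n_tokens_ = n_vocab
        rng = np.random.default_rng([19, self.random_state])
        self.embeddings_ = rng.normal(0.0, 0.1, size=(n_vocab, self.embedding_dim))
        self.embeddings_[0] = 0.0       # placeholder starts neutral
        self.significance_ = np.zeros(n_vocab)
        n_out = N_CATEGORIES if self.head == "MN" else N_THRESHOLDS
        self.net_ = MLPCore([self.embedding_dim, *self.hidden_layer_sizes, n_out],
                            rng, dropout=self.dropout)

        if validation_data is None and self.patience and len(y) >= 40:
            try:
                tr_idx, val_idx = train_test_split(
                    np.arange(len(y)), test_size=self.validation_fraction,
                    stratify=y, random_state=self.random_state)
                validation_data = ([seqs[i] for i in val_idx], y[val_idx])
                seqs = [seqs[i] for i in tr_idx]
                y = y[tr_idx]
            except ValueError:
                validation_data = None

        w = _sample_weights(y, self.class_weighted)
        weight_by_code = {c: w[y == c][0] for c in np.unique(y)}
        if validation_data is not None:
            val_seqs = _sequences_to_indices(validation_data[0])
            y_val = np.asarray(validation_data[1], dtype=int)
            w_val = np.array([weight_by_code.get(c, 1.0) for c in y_val])

        params = [self.embeddings_, self.significance_] + self.net_.params
        opt = Adam(params, lr=self.learning_rate)
        stopper = (EarlyStopper(self.patience)
                   if self.patience and validation_data is not None else None)
        self.loss_curve_, self.val_loss_curve_ = [], []
        for _ in range(self.epochs):
            epoch_loss, n_seen = 0.0, 0
            for idx in minibatches(len(y), self.batch_size, rng):
                batch = [seqs[i] for i in idx]
                U = self._aggregate_batch(batch)
                z, cache = self.net_.forward(U, train=True, rng=rng)
                loss, dz = self._head_loss_and_grad(z, y[idx], w[idx])
                net_grads, dU = self.net_.backward(dz, cache)
                gE = np.zeros_like(self.embeddings_)
                gs = np.zeros_like(self.significance_)
                for r, tok in enumerate(batch):
                    if not tok.size:
                        continue
                    scale = np.exp(self.significance_[tok]) / len(tok)
                    gE[tok] += scale[:, None] * dU[r]
                    gs[tok] += scale * (self.embeddings_[tok] @ dU[r])
                opt.step(params, [gE, gs] + net_grads)
                epoch_loss += loss * len(idx)
                n_seen += len(idx)
            self.loss_curve_.append(epoch_loss / n_seen)
            if validation_data is not None:
                z_val, _ = self.net_.forward(self._aggregate_batch(val_seqs))
                val_loss = self._head_loss_and_grad(z_val, y_val, w_val)[0]
                self.val_loss_curve_.append(val_loss)
                if stopper is not None and stopper.update(val_loss, params):
                    break
        if stopper is not None and stopper.best_params is not None:
            best = stopper.best_params
            self.embeddings_ = best[0].copy()
            self.significance_ = best[1].copy()
            self.net_.set_params_flat(best[2:])
        return self

    # -- prediction --------------------------------------------------------

    def _forward_sequences(self, sequences) -> np.ndarray:
        check_is_fitted(self, "net_")
        seqs = _sequences_to_indices(sequences)
        for ix in seqs:
            if ix.size == 0:
                raise ValueError("cannot predict for an empty token sequence")
            if ix.max() >= self.n_tokens_:
                raise ValueError("sequence encoded under a different vocabulary")
        z, _ = self.net_.forward(self._aggregate_batch(seqs))
        return z

    def predict_proba(self, sequences) -> np.ndarray:
        z = self._forward_sequences(sequences)
        if self.head == "MN":
            return softmax_to_class_probs(z)
        return threshold_to_class_probs(ordinal_output_transform(z))

    def predict_threshold_probs(self, sequences) -> np.ndarray:
        z = self._forward_sequences(sequences)
        if self.head == "OR":
            return ordinal_output_transform(z)
        return class_to_threshold_probs(softmax_to_class_probs(z))

    def output_for_subset(self, indices, kind: str, position: int) -> float:
        """Model output for an arbitrary token subset (Shapley evaluations).

        ``kind`` is 'class' (softmax category probability, 0-based position
        over the 7 categories) or 'threshold' (exceedance probability,
        0-based over the 6 thresholds). The empty subset aggregates to the
        zero vector -- the model's natural no-information reference.
        """
        check_is_fitted(self, "net_")
        idx = np.asarray(list(indices), dtype=int)
        if idx.size == 0:
            U = np.zeros((1, self.embedding_dim))
        else:
            U = self._aggregate_batch([idx])
        z, _ = self.net_.forward(U)
        if self.head == "MN":
            probs = softmax_to_class_probs(z)[0]
            if kind == "class":
                return float(probs[position])
            return float(class_to_threshold_probs(probs[None, :])[0, position])
        t = ordinal_output_transform(z)[0]
        if kind == "threshold":
            return float(t[position])
        return float(threshold_to_class_probs(t[None, :])[0, position])


def fit_apm(config: dict, sequences, y, validation_data=None,
            vocab_size: int | None = None) -> TokenEmbeddingModel:
    """Fit a token-embedding model from a plain configuration mapping."""
    model = TokenEmbeddingModel(vocab_size=vocab_size, **config)
    return model.fit(sequences, y, validation_data=validation_data)


def predict_apm(model: TokenEmbeddingModel, sequences) -> np.ndarray:
    """Per-patient probabilities: category probs for MN heads, threshold
    exceedance probs for OR heads."""
    if model.head == "OR":
        return model.predict_threshold_probs(sequences)
    return model.predict_proba(sequences)
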