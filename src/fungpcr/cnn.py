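"""A 1D convolutional network for binary GPCR/non-GPCR sequence
classification, implemented directly on numpy.

Architecture: one-hot encoded, zero-padded sequences feed a 1D convolution
(32 filters, kernel 3, ReLU), max-pooling (pool 2), a flattened dense layer
(64 units, ReLU) and a sigmoid output. Training minimizes binary
cross-entropy with Adam (default rate), 10 epochs, batch size 32, on a
stratified 80/20 split. All randomness (initialization, split, shuffling)
derives from a single seed, so repeated runs are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .io_formats import ProteinRecord

__all__ = ["CnnConfig", "Cnn1dClassifier", "build", "train", "predict",
           "encode", "AMINO_ALPHABET"]

#: Fixed residue order for one-hot encoding.
AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ALPHABET)}
_PAD_CODE = len(AMINO_ALPHABET)  # padding / non-standard residues


@dataclass
class CnnConfig:
    """Architecture and training hyperparameters.

    ``max_len=None`` derives the padding length from the training data
    (95th percentile of sequence lengths, capped at 2000).
    """

    max_len: int | None = None
    conv_filters: int = 32
    kernel: int = 3
    pool: int = 2
    dense_units: int = 64
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 32
    validation_split: float = 0.2
    seed: int = 0


def encode(seq: str, max_len: int) -> np.ndarray:
    """One-hot encode a sequence into a ``max_len x 20`` binary matrix.

    Row i indicates residue i; rows past the sequence end are all-zero
    padding, as are rows for non-standard residues. Longer sequences are
    right-truncated with a warning.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    if len(seq) > max_len:
        warnings.warn(
            f"sequence of length {len(seq)} truncated to max_len={max_len}")
    codes = _codes(seq, max_len)
    eye = np.eye(len(AMINO_ALPHABET) + 1, len(AMINO_ALPHABET),
                 dtype=np.float32)
    return eye[codes]


def _codes(seq: str, max_len: int) -> np.ndarray:
    codes = np.full(max_len, _PAD_CODE, dtype=np.uint8)
    for i, aa in enumerate(seq[:max_len]):
        codes[i] = _AA_INDEX.get(aa, _PAD_CODE)
    return codes


def _codes_matrix(seqs: Sequence[str], max_len: int) -> np.ndarray:
    out = np.empty((len(seqs), max_len), dtype=np.uint8)
    for i, s in enumerate(seqs):
        out[i] = _codes(s, max_len)
    return out


class _Adam:
    """Adam update rule over a list of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class Cnn1dClassifier(ClassifierMixin, BaseEstimator):
    """Binary sequence classifier with the fixed conv/pool/dense topology.

    Scikit-learn estimator over raw amino-acid strings: ``fit(X, y)`` with
    ``X`` a sequence of strings and ``y`` binary labels, ``predict_proba``
    / ``decision_function`` emit scores in [0, 1].

    Fitted attributes: ``max_len_``, weight arrays ``weights_``, the
    training ``history_`` (per-epoch loss), and held-out metrics
    ``test_accuracy_`` / ``test_f1_`` from the internal stratified split.
    """

    def __init__(self, max_len=None, conv_filters=32, kernel=3, pool=2,
                 dense_units=64, learning_rate=1e-3, epochs=10,
                 batch_size=32, validation_split=0.2, seed=0):
        self.max_len = max_len
        self.conv_filters = conv_filters
        self.kernel = kernel
        self.pool = pool
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_split = validation_split
        self.seed = seed

    # -- architecture ------------------------------------------------------

    def _init_weights(self, max_len: int, rng: np.random.Generator):
        a = len(AMINO_ALPHABET)
        k, f, d = self.kernel, self.conv_filters, self.dense_units
        if max_len < k:
            raise ValueError(f"max_len {max_len} smaller than kernel {k}")
        conv_len = max_len - k + 1
        pooled = conv_len // self.pool
        flat = pooled * f

        def glorot(fan_in, fan_out, shape):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape).astype(np.float32)

        return {
            "Wc": glorot(k * a, k * f, (k * a, f)),
            "bc": np.zeros(f, dtype=np.float32),
            "W1": glorot(flat, d, (flat, d)),
            "b1": np.zeros(d, dtype=np.float32),
            "W2": glorot(d, 1, (d, 1)),
            "b2": np.zeros(1, dtype=np.float32),
        }

    def parameter_counts(self) -> dict[str, int]:
        """Trainable parameters per layer for the current configuration.

        Closed forms: conv = kernel*|alphabet|*filters + filters; output =
        dense_units + 1. The dense layer depends on ``max_len`` (use after
        fit, or with an explicit ``max_len``).
        """
        a = len(AMINO_ALPHABET)
        counts = {
            "conv": self.kernel * a * self.conv_filters + self.conv_filters,
            "output": self.dense_units + 1,
        }
        max_len = getattr(self, "max_len_", self.max_len)
        if max_len is not None:
            pooled = (max_len - self.kernel + 1) // self.pool
            counts["dense"] = (pooled * self.conv_filters
                               * self.dense_units + self.dense_units)
        return counts

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, cache: bool = False):
        W = self.weights_
        k = self.kernel
        # (B, L, 20) -> windows (B, Lc, k*20)
        win = sliding_window_view(X, k, axis=1)        # (B, Lc, 20, k)
        win = win.transpose(0, 1, 3, 2)                # (B, Lc, k, 20)
        B, Lc = win.shape[0], win.shape[1]
        win = np.ascontiguousarray(win).reshape(B, Lc, -1)
        conv = win @ W["Wc"] + W["bc"]                 # (B, Lc, F)
        relu1 = np.maximum(conv, 0.0)
        Lp = Lc // self.pool
        pool_in = relu1[:, :Lp * self.pool].reshape(
            B, Lp, self.pool, self.conv_filters)
        pooled = pool_in.max(axis=2)                   # (B, Lp, F)
        flat = pooled.reshape(B, -1)
        z1 = flat @ W["W1"] + W["b1"]
        h1 = np.maximum(z1, 0.0)
        z2 = h1 @ W["W2"] + W["b2"]                    # (B, 1)
        p = 1.0 / (1.0 + np.exp(-z2))
        if not cache:
            return p
        return p, {"win": win, "conv": conv, "pool_in": pool_in,
                   "pooled": pooled, "flat": flat, "z1": z1, "h1": h1}

    def _backward(self, X, y, p, c):
        W = self.weights_
        B = X.shape[0]
        dz2 = (p - y[:, None]) / B                     # BCE + sigmoid
        gW2 = c["h1"].T @ dz2
        gb2 = dz2.sum(axis=0)
        dh1 = dz2 @ W["W2"].T
        dz1 = dh1 * (c["z1"] > 0)
        gW1 = c["flat"].T @ dz1
        gb1 = dz1.sum(axis=0)
        dflat = dz1 @ W["W1"].T
        Lp = c["pooled"].shape[1]
        dpooled = dflat.reshape(B, Lp, self.conv_filters)
        # route pooled gradient to the argmax position in each pool window
        pool_in = c["pool_in"]
        mask = pool_in == pool_in.max(axis=2, keepdims=True)
        # break ties toward the first max, as a hard max-pool would
        first = np.cumsum(mask, axis=2) == 1
        mask = mask & first
        drelu1 = np.zeros_like(c["conv"])
        drelu1[:, :Lp * self.pool] = (
            mask * dpooled[:, :, None, :]
        ).reshape(B, Lp * self.pool, self.conv_filters)
        dconv = drelu1 * (c["conv"] > 0)
        Lc = dconv.shape[1]
        gWc = c["win"].reshape(B * Lc, -1).T @ dconv.reshape(B * Lc, -1)
        gbc = dconv.sum(axis=(0, 1))
        return [gWc.astype(np.float32), gbc.astype(np.float32),
                gW1.astype(np.float32), gb1.astype(np.float32),
                gW2.astype(np.float32), gb2.astype(np.float32)]

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        seqs = [r.seq if isinstance(r, ProteinRecord) else str(r) for r in X]
        y = np.asarray(y, dtype=np.float32)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        if not set(classes).issubset({0.0, 1.0}):
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])

        if self.max_len is not None:
            max_len = int(self.max_len)
        else:
            max_len = int(min(np.percentile([len(s) for s in seqs], 95), 2000))
        self.max_len_ = max_len

        idx_train, idx_test = train_test_split(
            np.arange(len(seqs)), test_size=self.validation_split,
            stratify=y, random_state=self.seed)
        self.split_indices_ = (idx_train, idx_test)

        codes = _codes_matrix(seqs, max_len)
        eye = np.eye(len(AMINO_ALPHABET) + 1, len(AMINO_ALPHABET),
                     dtype=np.float32)
        rng = np.random.default_rng(self.seed)
        self.weights_ = self._init_weights(max_len, rng)
        param_order = ["Wc", "bc", "W1", "b1", "W2", "b2"]
        params = [self.weights_[k] for k in param_order]
        opt = _Adam(params, lr=self.learning_rate)

        n_train = len(idx_train)
        history = []
        for _ in range(self.epochs):
            order = rng.permutation(n_train)
            epoch_loss = 0.0
            for start in range(0, n_train, self.batch_size):
                batch = idx_train[order[start:start + self.batch_size]]
                Xb = eye[codes[batch]]
                yb = y[batch]
                p, cache = self._forward(Xb, cache=True)
                eps = 1e-7
                pc = np.clip(p[:, 0], eps, 1 - eps)
                loss = -np.mean(yb * np.log(pc) + (1 - yb) * np.log(1 - pc))
                epoch_loss += loss * len(batch)
                grads = self._backward(Xb, yb, p, cache)
                opt.step(params, grads)
            history.append(epoch_loss / n_train)
        self.history_ = history

        p_test = self._predict_codes(codes[idx_test])
        y_test = y[idx_test]
        self.test_accuracy_ = float(accuracy_score(y_test, p_test > 0.5))
        self.test_f1_ = float(f1_score(y_test, p_test > 0.5))
        return self

    def _predict_codes(self, codes: np.ndarray,
                       batch_size: int = 256) -> np.ndarray:
        eye = np.eye(len(AMINO_ALPHABET) + 1, len(AMINO_ALPHABET),
                     dtype=np.float32)
        out = np.empty(len(codes), dtype=np.float64)
        for start in range(0, len(codes), batch_size):
            Xb = eye[codes[start:start + batch_size]]
            out[start:start + batch_size] = self._forward(Xb)[:, 0]
        return out

    def decision_function(self, X) -> np.ndarray:
        """Per-sequence GPCR score in [0, 1]."""
        check_is_fitted(self, "weights_")
        seqs = [r.seq if isinstance(r, ProteinRecord) else str(r) for r in X]
        too_long = sum(len(s) > self.max_len_ for s in seqs)
        if too_long:
            warnings.warn(
                f"{too_long} sequence(s) longer than max_len={self.max_len_} "
                "right-truncated")
        return self._predict_codes(_codes_matrix(seqs, self.max_len_))

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0.5).astype(int)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a checkpoint (weights + config + alphabet order)."""
        check_is_fitted(self, "weights_")
        np.savez(path, alphabet=AMINO_ALPHABET, max_len=self.max_len_,
                 params=np.array(self.get_params()),  # dict in 0-d object array
                 **{f"w_{k}": v for k, v in self.weights_.items()})

    @classmethod
    def load(cls, path: str | Path) -> "Cnn1dClassifier":
        with np.load(path, allow_pickle=True) as data:
            if str(data["alphabet"]) != AMINO_ALPHABET:
                raise ValueError("checkpoint alphabet does not match")
            est = cls(**data["params"].item())
            est.max_len_ = int(data["max_len"])
            est.weights_ = {k[2:]: data[k] for k in data.files
                            if k.startswith("w_")}
            est.classes_ = np.array([0, 1])
        return est


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def build(config: CnnConfig) -> Cnn1dClassifier:
    """An untrained classifier with the configured architecture."""
    if config.max_len is not None and config.max_len < config.kernel:
        raise ValueError(
            f"max_len {config.max_len} smaller than kernel {config.kernel}")
    return Cnn1dClassifier(
        max_len=config.max_len, conv_filters=config.conv_filters,
        kernel=config.kernel, pool=config.pool,
        dense_units=config.dense_units, learning_rate=config.learning_rate,
        epochs=config.epochs, batch_size=config.batch_size,
        validation_split=config.validation_split, seed=config.seed)


def train(model: Cnn1dClassifier,
          positives: Sequence[ProteinRecord | str],
          negatives: Sequence[ProteinRecord | str]) -> Cnn1dClassifier:
    """Train on labeled positive/negative sequence sets (in place)."""
    X = list(positives) + list(negatives)
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    return model.fit(X, y)


def predict(model: Cnn1dClassifier,
            records: Sequence[ProteinRecord]) -> dict[str, float]:
    """Score records into an id -> score table."""
    scores = model.decision_function(records)
    return {r.id: float(s) for r, s in zip(records, scores)}
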