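"""Convolutional text classifier over padded token-index sequences.

Architecture: trainable word-embedding lookup (dimension k, default 400)
-> 1-D convolution over word windows (default 5 x k, stride 1, 128
filters) -> ReLU -> global max pooling over positions -> dropout (0.5)
-> batch normalization -> dense softmax over the code classes.  Trained
with Adam on categorical cross-entropy.

The network is implemented directly in numpy with handwritten
backpropagation: the stack is small and fixed, which keeps training
bit-reproducible for a given seed and the package free of heavyweight
dependencies.  The padding embedding (index 0) is pinned at zero so
predictions do not depend on how much trailing padding a document
carries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CNNConfig",
    "TextCNN",
    "ConfigurationError",
    "TrainingError",
    "DivergedTrainingError",
]


class ConfigurationError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


class DivergedTrainingError(TrainingError):
    """Loss became non-finite; try a smaller learning rate."""


@dataclass
class CNNConfig:
    """Architecture and training hyperparameters.

    Defaults are the reference operating point for full-scale corpora:
    embedding dimension 400, one convolution of window 5 and stride 1 with
    128 filters, ReLU, global max pooling, dropout 0.5 after pooling and
    before the output layer, batch normalization before the output layer,
    Adam at learning rate 1e-3, 100 epochs, batch size 64, document
    length 218.  Smaller corpora train well (and much faster) with a
    smaller embedding/filter count and fewer epochs.
    """

    embedding_dim: int = 400
    conv_window: int = 5
    conv_stride: int = 1
    n_filters: int = 128
    batch_norm_before_output: bool = True
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    max_len: int = 218
    seed: int = 0
    trainable_embeddings: bool = True
    early_stopping: bool = False
    early_stopping_patience: int = 5

    def validate(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.conv_window > self.max_len:
            raise ConfigurationError(
                f"conv_window ({self.conv_window}) cannot exceed max_len ({self.max_len})"
            )
        for name in ("embedding_dim", "conv_window", "conv_stride", "n_filters",
                     "epochs", "batch_size", "max_len"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")


class _Adam:
    """Adam state for one parameter array."""

    def __init__(self, shape, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = np.zeros(shape, dtype=np.float32)
        self.v = np.zeros(shape, dtype=np.float32)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self, param, grad):
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class TextCNN:
    """The convolutional classifier plus its class <-> code mapping.

    Parameters
    ----------
    config
        Hyperparameters; ``config.seed`` drives parameter initialization,
        epoch shuffling, and dropout masks.
    vocab_size
        Number of token indices (including padding 0 and OOV 1).
    class_codes
        ICD-9 code string for each class index; the mapping must be a
        bijection.
    """

    def __init__(self, config: CNNConfig, vocab_size: int, class_codes: Sequence[str]):
        config.validate()
        n_classes = len(class_codes)
        if vocab_size < 2:
            raise ConfigurationError("vocab_size must be >= 2 (padding + OOV)")
        if n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if len(set(class_codes)) != n_classes:
            raise ConfigurationError("class_codes must be distinct")
        self.config = config
        self.vocab_size = vocab_size
        self.class_codes = list(class_codes)
        self.n_classes = n_classes
        self._rng = np.random.default_rng(config.seed)
        k, w, F, C = config.embedding_dim, config.conv_window, config.n_filters, n_classes
        rng = self._rng
        self.E = rng.normal(0.0, 0.1, size=(vocab_size, k)).astype(np.float32)
        self.E[0] = 0.0  # padding embedding pinned at zero
        self.Wc = rng.normal(0.0, np.sqrt(2.0 / (w * k)), size=(w * k, F)).astype(np.float32)
        self.bc = np.zeros(F, dtype=np.float32)
        # zero-initialized output layer: an untrained model is exactly
        # uniform over classes, and gradients still flow through it
        self.Wo = np.zeros((F, C), dtype=np.float32)
        self.bo = np.zeros(C, dtype=np.float32)
        self.gamma = np.ones(F, dtype=np.float32)
        self.beta = np.zeros(F, dtype=np.float32)
        self.running_mean = np.zeros(F, dtype=np.float32)
        self.running_var = np.ones(F, dtype=np.float32)
        self.bn_momentum = 0.9
        self.bn_eps = 1e-5
        self.loss_history: list[float] = []
        self.trained = False

    # -- shape accounting -------------------------------------------------

    def parameter_counts(self) -> dict[str, int]:
        cfg = self.config
        counts = {
            "embedding": self.vocab_size * cfg.embedding_dim,
            "convolution": cfg.conv_window * cfg.embedding_dim * cfg.n_filters + cfg.n_filters,
            "output": cfg.n_filters * self.n_classes + self.n_classes,
        }
        if cfg.batch_norm_before_output:
            counts["batch_norm"] = 2 * cfg.n_filters
        return counts

    # -- forward / backward ----------------------------------------------

    def _windows(self, emb: np.ndarray) -> np.ndarray:
        """(B, L, k) -> (B, P, w*k) sliding windows with the configured
        stride."""
        w, stride = self.config.conv_window, self.config.conv_stride
        B, L, k = emb.shape
        view = np.lib.stride_tricks.sliding_window_view(emb, w, axis=1)  # (B, L-w+1, k, w)
        view = view[:, ::stride]
        # -> (B, P, w, k) -> (B, P, w*k)
        return np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(B, view.shape[1], w * k)

    def _forward(self, X: np.ndarray, train: bool):
        cfg = self.config
        emb = self.E[X]  # (B, L, k)
        win = self._windows(emb)  # (B, P, wk)
        Z = win @ self.Wc + self.bc  # (B, P, F)
        A = np.maximum(Z, 0.0)
        pool_arg = A.argmax(axis=1)  # (B, F)
        h = np.take_along_axis(A, pool_arg[:, None, :], axis=1)[:, 0, :]  # (B, F)
        cache = {"X": X, "win": win, "Z": Z, "pool_arg": pool_arg, "h": h}
        if train and cfg.dropout_rate > 0:
            mask = (self._rng.random(h.shape) >= cfg.dropout_rate).astype(np.float32)
            mask /= 1.0 - cfg.dropout_rate
            hd = h * mask
            cache["drop_mask"] = mask
        else:
            hd = h
        if cfg.batch_norm_before_output:
            if train:
                mu = hd.mean(axis=0)
                var = hd.var(axis=0)
                self.running_mean = (
                    self.bn_momentum * self.running_mean + (1 - self.bn_momentum) * mu
                ).astype(np.float32)
                self.running_var = (
                    self.bn_momentum * self.running_var + (1 - self.bn_momentum) * var
                ).astype(np.float32)
            else:
                mu, var = self.running_mean, self.running_var
            inv_std = 1.0 / np.sqrt(var + self.bn_eps)
            xhat = (hd - mu) * inv_std
            out = xhat * self.gamma + self.beta
            cache.update({"hd": hd, "xhat": xhat, "inv_std": inv_std})
        else:
            out = hd
            cache["hd"] = hd
        logits = out @ self.Wo + self.bo
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        cache["bn_out"] = out
        return probs, cache

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict:
        cfg = self.config
        B = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = cache["bn_out"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dout = dlogits @ self.Wo.T  # (B, F)
        if cfg.batch_norm_before_output:
            xhat, inv_std = cache["xhat"], cache["inv_std"]
            grads["gamma"] = (dout * xhat).sum(axis=0)
            grads["beta"] = dout.sum(axis=0)
            dxhat = dout * self.gamma
            dhd = inv_std / B * (
                B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
        else:
            dhd = dout
        if "drop_mask" in cache:
            dh = dhd * cache["drop_mask"]
        else:
            dh = dhd
        # un-pool: route gradient to the argmax position of each filter
        dA = np.zeros_like(cache["Z"])
        np.put_along_axis(dA, cache["pool_arg"][:, None, :], dh[:, None, :], axis=1)
        dZ = dA * (cache["Z"] > 0)
        win = cache["win"]
        P = win.shape[1]
        wk = win.shape[2]
        grads["Wc"] = win.reshape(-1, wk).T @ dZ.reshape(-1, dZ.shape[2])
        grads["bc"] = dZ.sum(axis=(0, 1))
        if cfg.trainable_embeddings:
            dwin = dZ @ self.Wc.T  # (B, P, wk)
            k, w, stride = cfg.embedding_dim, cfg.conv_window, cfg.conv_stride
            B_, L = cache["X"].shape
            demb = np.zeros((B_, L, k), dtype=np.float32)
            dwin = dwin.reshape(B_, P, w, k)
            for j in range(w):
                pos = np.arange(P) * stride + j
                np.add.at(demb, (slice(None), pos), dwin[:, :, j, :])
            dE = np.zeros_like(self.E)
            np.add.at(dE, cache["X"].ravel(), demb.reshape(-1, k))
            dE[0] = 0.0  # padding embedding stays zero
            grads["E"] = dE
        return grads

    # -- training ---------------------------------------------------------

    def fit(self, vectors: np.ndarray, labels: np.ndarray) -> "TextCNN":
        """Train in place on (N, max_len) index vectors and class labels.

        Every class must appear at least once; training is reproducible
        for a fixed config seed.
        """
        cfg = self.config
        X = np.asarray(vectors, dtype=np.int64)
        y = np.asarray(labels, dtype=np.int64)
        if X.ndim != 2 or X.shape[1] != cfg.max_len:
            raise TrainingError(
                f"expected document vectors of length {cfg.max_len}, got shape {X.shape}"
            )
        if len(X) != len(y):
            raise TrainingError("vectors and labels differ in length")
        if len(X) < self.n_classes:
            raise TrainingError("need at least as many records as classes")
        if y.min() < 0 or y.max() >= self.n_classes:
            raise TrainingError(
                f"label {int(y.max() if y.max() >= self.n_classes else y.min())} "
                f"outside [0, {self.n_classes})"
            )
        counts = np.bincount(y, minlength=self.n_classes)
        missing = np.nonzero(counts == 0)[0]
        if missing.size:
            raise TrainingError(
                "classes absent from training data: "
                + ", ".join(self.class_codes[i] for i in missing[:10])
            )

        params = {"Wc": self.Wc, "bc": self.bc, "Wo": self.Wo, "bo": self.bo}
        if cfg.batch_norm_before_output:
            params.update({"gamma": self.gamma, "beta": self.beta})
        if cfg.trainable_embeddings:
            params["E"] = self.E
        adam = {name: _Adam(p.shape, cfg.learning_rate) for name, p in params.items()}

        n = len(X)
        best = np.inf
        stall = 0
        for _epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                probs, cache = self._forward(X[idx], train=True)
                loss = -np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12).mean()
                if not np.isfinite(loss):
                    raise DivergedTrainingError(
                        "training loss is not finite; try a smaller learning rate"
                    )
                epoch_loss += loss * len(idx)
                grads = self._backward(probs, y[idx], cache)
                for name, grad in grads.items():
                    adam[name].step(params[name], grad.astype(np.float32))
                self.E[0] = 0.0
            epoch_loss /= n
            self.loss_history.append(float(epoch_loss))
            if cfg.early_stopping:
                if epoch_loss < best - 1e-4:
                    best, stall = epoch_loss, 0
                else:
                    stall += 1
                    if stall >= cfg.early_stopping_patience:
                        break
        self.trained = True
        return self

    # -- inference --------------------------------------------------------

    def predict_proba(self, vectors: np.ndarray) -> np.ndarray:
        """Class-probability matrix; dropout off, batch-norm running stats."""
        X = np.asarray(vectors, dtype=np.int64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.config.max_len:
            raise ValueError(
                f"expected vectors of length {self.config.max_len}, got {X.shape[1]}"
            )
        if len(X) == 0:
            return np.zeros((0, self.n_classes), dtype=np.float32)
        out = []
        for start in range(0, len(X), 256):
            probs, _ = self._forward(X[start : start + 256], train=False)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def predict_labels(self, vectors: np.ndarray) -> list[str]:
        """Arg-max code per document; ties break toward the lowest class
        index."""
        probs = self.predict_proba(vectors)
        return [self.class_codes[i] for i in probs.argmax(axis=1)]

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write config (JSON), class mapping (TSV), and weights (npz)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(
            json.dumps({**asdict(self.config), "vocab_size": self.vocab_size}, indent=2),
            encoding="utf-8",
        )
        with open(directory / "classes.tsv", "w", encoding="utf-8") as fh:
            for i, code in enumerate(self.class_codes):
                fh.write(f"{i}\t{code}\n")
        np.savez(
            directory / "weights.npz",
            E=self.E, Wc=self.Wc, bc=self.bc, Wo=self.Wo, bo=self.bo,
            gamma=self.gamma, beta=self.beta,
            running_mean=self.running_mean, running_var=self.running_var,
        )

    @classmethod
    def load(cls, directory: str | Path) -> "TextCNN":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text(encoding="utf-8"))
        vocab_size = meta.pop("vocab_size")
        config = CNNConfig(**meta)
        codes: list[str] = []
        with open(directory / "classes.tsv", encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    _, code = line.rstrip("\n").split("\t")
                    codes.append(code)
        model = cls(config, vocab_size, codes)
        with np.load(directory / "weights.npz") as npz:
            for name in ("E", "Wc", "bc", "Wo", "bo", "gamma", "beta",
                         "running_mean", "running_var"):
                setattr(model, name, npz[name])
        model.trained = True
        return model
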