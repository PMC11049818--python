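"""Deep classifiers over fixed-length feature vectors.

Three architectures consume either the 320-D protein-language-model
embedding or the 1200-D PSSM feature vector:

* **DNN** — a multilayer perceptron with hidden layers of 180, 60 and 30
  ReLU units, dropout 0.5, and a single sigmoid output; binary
  cross-entropy, Adam at learning rate 1e-3, batches of 10.
* **CapsNet** — 1-D convolutions (kernel 3, stride 1, never any
  pooling) feeding 8-D primary capsules; routing-by-agreement over 3
  iterations produces two 16-D class capsules whose vector norms are the
  class existence probabilities.
* **BiLSTM** — forward and backward LSTM passes (hidden width 64 each)
  whose final hidden states are concatenated (width 128) into a 2-unit
  softmax output; batches of 16.

All training paths are deterministic given a seed on one CPU thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .sequence_io import ValidationError

EPS = 1e-9


@dataclass(frozen=True)
class DNNConfig:
    hidden_sizes: tuple[int, ...] = (180, 60, 30)
    dropout: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 10

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValidationError("hidden sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class CapsNetConfig:
    conv_channels: int = 8
    kernel_size: int = 3
    stride: int = 1
    primary_caps_dim: int = 8
    primary_caps_types: int = 2
    class_caps_dim: int = 16
    n_classes: int = 2
    routing_iters: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 10

    def __post_init__(self) -> None:
        if self.kernel_size < 1:
            raise ValidationError("kernel_size must be >= 1")
        if self.routing_iters < 1:
            raise ValidationError("routing_iters must be >= 1")


@dataclass(frozen=True)
class BiLSTMConfig:
    input_dim: int = 320
    hidden_dim: int = 64
    output_dim: int = 2
    n_steps: int = 1  # the flat feature vector is framed as n_steps x step_dim
    learning_rate: float = 1e-3
    batch_size: int = 16

    def __post_init__(self) -> None:
        if min(self.input_dim, self.hidden_dim, self.output_dim, self.n_steps) <= 0:
            raise ValidationError("all dimensions must be positive")
        if self.input_dim % self.n_steps:
            raise ValidationError("input_dim must divide into n_steps")


@dataclass
class FitResult:
    model: "BaseClassifier"
    epoch_losses: list[float]
    seed: int
    validation_losses: list[float] = field(default_factory=list)


def _check_training_inputs(features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValidationError(f"features must be 2-D, got shape {X.shape}")
    if len(X) != len(y):
        raise ValidationError("features and labels disagree in length")
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("labels must be binary with both classes present")
    return X, y


class BaseClassifier:
    """Shared minibatch-Adam training loop; subclasses define the forward pass."""

    def __init__(self) -> None:
        self.fitted = False
        self.input_dim: Optional[int] = None

    # subclass API ---------------------------------------------------------
    def _build(self, input_dim: int, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def _forward(self, X: np.ndarray, training: bool, rng: np.random.Generator) -> Tensor:
        """Return per-sample druggable probability as a 1-D tensor."""
        raise NotImplementedError

    @property
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    @property
    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters))

    def architecture_summary(self) -> list[str]:
        raise NotImplementedError

    # training -------------------------------------------------------------
    def fit(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        epochs: int = 100,
        seed: int = 0,
        learning_rate: Optional[float] = None,
        batch_size: Optional[int] = None,
        validation_data: Optional[tuple[np.ndarray, np.ndarray]] = None,
        patience: int = 10,
    ) -> FitResult:
        X, y = _check_training_inputs(features, labels)
        rng = np.random.default_rng(seed)
        self._build(X.shape[1], rng)
        self.input_dim = X.shape[1]
        lr = self.config.learning_rate if learning_rate is None else learning_rate
        bs = self.config.batch_size if batch_size is None else batch_size
        opt = ad.Adam(self.parameters, lr=lr)
        result = FitResult(model=self, epoch_losses=[], seed=seed)
        best_val, stale = np.inf, 0
        for _ in range(epochs):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), bs):
                idx = order[start : start + bs]
                opt.zero_grad()
                probs = self._forward(X[idx], training=True, rng=rng)
                loss = self._loss(probs, y[idx])
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            result.epoch_losses.append(float(np.mean(losses)))
            if validation_data is not None:
                Xv, yv = validation_data
                self.fitted = True
                val_loss = float(self._loss(
                    self._forward(np.asarray(Xv, float), training=False, rng=rng),
                    np.asarray(yv, int)).data)
                result.validation_losses.append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val, stale = val_loss, 0
                else:
                    stale += 1
                    if stale >= patience:
                        break
        self.fitted = True
        return result

    def _loss(self, probs: Tensor, y: np.ndarray) -> Tensor:
        return ad.bce_loss(probs, y)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValidationError("model is not fitted")
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValidationError(
                f"expected features of width {self.input_dim}, got shape {X.shape}"
            )
        return self._forward(X, training=False, rng=np.random.default_rng(0)).data

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.predict_proba(features) >= 0.5).astype(int)


# -- DNN ---------------------------------------------------------------------

class DNNClassifier(BaseClassifier):
    """MLP with ReLU hidden layers, dropout, and one sigmoid output unit."""

    def __init__(self, config: DNNConfig = DNNConfig()):
        super().__init__()
        self.config = config
        self._params: list[Tensor] = []

    def _build(self, input_dim: int, rng: np.random.Generator) -> None:
        dims = [input_dim, *self.config.hidden_sizes, 1]
        self.weights, self.biases = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.weights.append(
                Tensor(rng.normal(0, np.sqrt(2.0 / d_in), size=(d_in, d_out)),
                       requires_grad=True))
            self.biases.append(ad.init_zeros(d_out))
        self._params = [*self.weights, *self.biases]

    @property
    def parameters(self) -> list[Tensor]:
        return self._params

    def _forward(self, X: np.ndarray, training: bool, rng: np.random.Generator) -> Tensor:
        h = Tensor(X)
        p_drop = self.config.dropout
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < len(self.weights) - 1:
                h = h.relu()
                if training and p_drop > 0:
                    keep = (rng.random(h.shape) >= p_drop) / (1.0 - p_drop)
                    h = h * Tensor(keep)
        return h.sigmoid().reshape(-1)

    def architecture_summary(self) -> list[str]:
        layers = [f"dense({h})+relu+dropout({self.config.dropout})"
                  for h in self.config.hidden_sizes]
        return [*layers, "dense(1)+sigmoid"]


# -- CapsNet -----------------------------------------------------------------

def squash(s: Tensor, axis: int = -1) -> Tensor:
    """Capsule nonlinearity: ``(|s|^2 / (1 + |s|^2)) * s / |s|``; squash(0) = 0."""
    sq_norm = (s * s).sum(axis=axis, keepdims=True)
    scale = sq_norm / (1.0 + sq_norm) / ((sq_norm + EPS) ** 0.5)
    return s * scale


def dynamic_routing(u_hat: Tensor, iters: int = 3) -> Tensor:
    """Routing-by-agreement over vote vectors.

    ``u_hat``: (batch, n_primary, n_classes, class_dim) votes.  Coupling
    logits start at zero; each iteration softmax-normalizes them over
    classes (so couplings sum to 1 per primary capsule), aggregates the
    coupled votes, squashes, and reinforces agreement.  Aggregation is
    the MEAN over primary capsules (not the raw sum): with hundreds of
    primary capsules a raw sum saturates the squash at norm ~1, which
    kills the cross-entropy gradient; the mean keeps class-capsule norms
    in the responsive range while preserving every routing fixed point
    up to scale.  Returns the class capsule vectors
    (batch, n_classes, class_dim).
    """
    if iters < 1:
        raise ValidationError("routing_iters must be >= 1")
    B, N, C, _ = u_hat.shape
    b_logits = Tensor(np.zeros((B, N, C, 1)))
    v = None
    for it in range(iters):
        c = ad.softmax(b_logits, axis=2)
        s = (u_hat * c).sum(axis=1) * (1.0 / N)  # B x C x dim
        v = squash(s, axis=-1)
        if it < iters - 1:
            agreement = (u_hat * v.reshape(B, 1, C, -1)).sum(axis=-1, keepdims=True)
            b_logits = b_logits + agreement
    return v


def routing_couplings(u_hat: np.ndarray, iters: int = 3) -> np.ndarray:
    """Final coupling coefficients (batch, n_primary, n_classes); rows sum to 1."""
    u_hat = np.asarray(u_hat, dtype=float)
    B, N, C, _ = u_hat.shape
    b = np.zeros((B, N, C))
    for it in range(iters):
        c = np.exp(b - b.max(axis=2, keepdims=True))
        c /= c.sum(axis=2, keepdims=True)
        if it == iters - 1:
            return c
        s = (u_hat * c[..., None]).sum(axis=1) / u_hat.shape[1]
        n2 = (s ** 2).sum(-1, keepdims=True)
        vv = s * n2 / (1 + n2) / np.sqrt(n2 + EPS)
        b = b + (u_hat * vv[:, None]).sum(-1)
    return c


class CapsNetClassifier(BaseClassifier):
    """1-D convolutional capsule network without pooling layers.

    The feature vector is treated as a single-channel signal; two
    convolutions (kernel 3, stride 1) build primary capsules whose votes
    are routed to two class capsules.  The druggable probability is the
    norm of the class-1 capsule; training penalizes both capsule norms
    with binary cross-entropy.
    """

    def __init__(self, config: CapsNetConfig = CapsNetConfig()):
        super().__init__()
        self.config = config
        self._params: list[Tensor] = []

    def _build(self, input_dim: int, rng: np.random.Generator) -> None:
        c = self.config
        k, C1 = c.kernel_size, c.conv_channels
        C2 = c.primary_caps_types * c.primary_caps_dim
        if input_dim < 2 * k:
            raise ValidationError(f"input width {input_dim} too small for two kernel-{k} convolutions")
        self.W1 = Tensor(rng.normal(0, np.sqrt(2.0 / k), size=(k, C1)), requires_grad=True)
        self.b1 = ad.init_zeros(C1)
        self.W2 = Tensor(rng.normal(0, np.sqrt(2.0 / (k * C1)), size=(k, C1, C2)),
                         requires_grad=True)
        self.b2 = ad.init_zeros(C2)
        # per-primary-capsule vote transforms, as in the original capsule design
        L2 = input_dim - 2 * (k - 1)
        n_primary = L2 * c.primary_caps_types
        self.W_vote = Tensor(
            rng.normal(0, 1.0, size=(n_primary, c.primary_caps_dim,
                                     c.n_classes * c.class_caps_dim)),
            requires_grad=True)
        self._params = [self.W1, self.b1, self.W2, self.b2, self.W_vote]

    @property
    def parameters(self) -> list[Tensor]:
        return self._params

    def _conv1(self, x: Tensor, L_out: int) -> Tensor:
        k = self.config.kernel_size
        out = None
        for o in range(k):
            term = x[:, o : o + L_out].reshape(-1, L_out, 1) * self.W1[o].reshape(1, 1, -1)
            out = term if out is None else out + term
        return (out + self.b1).relu()

    def _conv2(self, h: Tensor, L_out: int) -> Tensor:
        k = self.config.kernel_size
        out = None
        for o in range(k):
            term = h[:, o : o + L_out, :] @ self.W2[o]
            out = term if out is None else out + term
        return out + self.b2

    def _class_capsules(self, X: np.ndarray) -> Tensor:
        c = self.config
        k = c.kernel_size
        L1 = X.shape[1] - k + 1
        L2 = L1 - k + 1
        h1 = self._conv1(Tensor(X), L1)                       # B x L1 x C1
        h2 = self._conv2(h1, L2)                              # B x L2 x (types*dim)
        B = X.shape[0]
        n_primary = L2 * c.primary_caps_types
        primary = squash(h2.reshape(B, n_primary, c.primary_caps_dim))
        votes = primary.reshape(B, n_primary, 1, c.primary_caps_dim) @ self.W_vote
        u_hat = votes.reshape(B, n_primary, c.n_classes, c.class_caps_dim)
        return dynamic_routing(u_hat, c.routing_iters)        # B x n_classes x dim

    def class_scores(self, X: np.ndarray) -> np.ndarray:
        """Capsule norms per class — each in [0, 1) by the squash bound."""
        v = self._class_capsules(np.asarray(X, float))
        return np.sqrt((v.data ** 2).sum(-1))

    def _forward(self, X: np.ndarray, training: bool, rng: np.random.Generator) -> Tensor:
        v = self._class_capsules(X)
        norms = ((v * v).sum(axis=-1) + EPS) ** 0.5  # B x n_classes
        self._last_norms = norms
        return norms[:, 1]

    def _loss(self, probs: Tensor, y: np.ndarray) -> Tensor:
        norms = self._last_norms
        return ad.bce_loss(norms[:, 1], y) + ad.bce_loss(norms[:, 0], 1 - y)

    def architecture_summary(self) -> list[str]:
        c = self.config
        return [
            f"conv1d(k={c.kernel_size},s={c.stride},ch={c.conv_channels})+relu",
            f"conv1d(k={c.kernel_size},s={c.stride},ch={c.primary_caps_types * c.primary_caps_dim})",
            f"primary_capsules(dim={c.primary_caps_dim})+squash",
            f"dynamic_routing(iters={c.routing_iters})",
            f"class_capsules(n={c.n_classes},dim={c.class_caps_dim})",
        ]


# -- BiLSTM ------------------------------------------------------------------

class _LSTMDirection:
    """One LSTM pass; gates packed as [i, f, g, o] in a fused weight matrix."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(hidden)
        self.W = Tensor(rng.uniform(-s, s, size=(in_dim, 4 * hidden)), requires_grad=True)
        self.U = Tensor(rng.uniform(-s, s, size=(hidden, 4 * hidden)), requires_grad=True)
        self.b = ad.init_zeros(4 * hidden)
        self.hidden = hidden

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W, self.U, self.b]

    def run(self, steps: Sequence[Tensor]) -> Tensor:
        """Consume step tensors (B x in_dim each); return final hidden state."""
        H = self.hidden
        B = steps[0].shape[0]
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        for x in steps:
            z = x @ self.W + h @ self.U + self.b
            i = z[:, :H].sigmoid()
            f = z[:, H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class BiLSTMClassifier(BaseClassifier):
    """Bidirectional LSTM over the feature vector framed as a short sequence.

    The forward and backward final hidden states are concatenated
    (width 2 * hidden_dim = 128 by default) and mapped to two logits;
    the druggable probability is the softmax component for class 1.
    """

    def __init__(self, config: BiLSTMConfig = BiLSTMConfig()):
        super().__init__()
        self.config = config
        self._params: list[Tensor] = []

    def _build(self, input_dim: int, rng: np.random.Generator) -> None:
        c = self.config
        if input_dim != c.input_dim:
            raise ValidationError(
                f"BiLSTMConfig.input_dim = {c.input_dim} but features have width {input_dim}")
        step_dim = c.input_dim // c.n_steps
        self.fwd = _LSTMDirection(step_dim, c.hidden_dim, rng)
        self.bwd = _LSTMDirection(step_dim, c.hidden_dim, rng)
        s = 1.0 / np.sqrt(2 * c.hidden_dim)
        self.W_out = Tensor(rng.uniform(-s, s, size=(2 * c.hidden_dim, c.output_dim)),
                            requires_grad=True)
        self.b_out = ad.init_zeros(c.output_dim)
        self._params = [*self.fwd.parameters, *self.bwd.parameters, self.W_out, self.b_out]

    @property
    def parameters(self) -> list[Tensor]:
        return self._params

    def _logits(self, X: np.ndarray) -> Tensor:
        c = self.config
        step_dim = c.input_dim // c.n_steps
        x = Tensor(X)
        steps = [x[:, t * step_dim : (t + 1) * step_dim] for t in range(c.n_steps)]
        h_fwd = self.fwd.run(steps)
        h_bwd = self.bwd.run(list(reversed(steps)))
        h = ad.concat([h_fwd, h_bwd], axis=1)  # width 2*hidden_dim
        return h @ self.W_out + self.b_out

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        return self._logits(np.asarray(X, float)).data

    def _forward(self, X: np.ndarray, training: bool, rng: np.random.Generator) -> Tensor:
        probs = ad.softmax(self._logits(X), axis=-1)
        self._last_probs = probs
        return probs[:, 1]

    def architecture_summary(self) -> list[str]:
        c = self.config
        return [
            f"lstm_forward(hidden={c.hidden_dim})",
            f"lstm_backward(hidden={c.hidden_dim})",
            f"concat(width={2 * c.hidden_dim})",
            f"dense({c.output_dim})+softmax",
        ]


MODEL_REGISTRY = {
    "dnn": (DNNClassifier, DNNConfig),
    "capsnet": (CapsNetClassifier, CapsNetConfig),
    "bilstm": (BiLSTMClassifier, BiLSTMConfig),
}


def fit(model_name: str, features: np.ndarray, labels: np.ndarray,
        epochs: int = 100, seed: int = 0, config=None, **kwargs) -> FitResult:
    """Train one of the registered deep architectures on fixed-length features."""
    if model_name not in MODEL_REGISTRY:
        raise ValidationError(f"unknown model {model_name!r}; choose from {sorted(MODEL_REGISTRY)}")
    cls, cfg_cls = MODEL_REGISTRY[model_name]
    if config is None:
        if model_name == "bilstm":
            config = cfg_cls(input_dim=np.asarray(features).shape[1])
        else:
            config = cfg_cls()
    model = cls(config)
    return model.fit(features, labels, epochs=epochs, seed=seed, **kwargs)


def predict_proba(fit_result: FitResult, features: np.ndarray) -> np.ndarray:
    return fit_result.model.predict_proba(features)
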