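"""Temporal convolutional network for per-sample gait-event likelihoods.

The network maps a normalized N x 6 IMU stream to two length-N traces in
[0, 1]: the likelihood of an initial contact and of a final contact at
every time step.  It stacks residual blocks with exponentially
increasing dilation (1, 2, 4, ...); each block applies two sequences of
dilated convolution -> batch normalization -> ReLU -> dropout, with an
additive shortcut (a 1x1 convolution when the channel count changes,
identity otherwise).  All convolutions are of the "same" type — centered
and zero-padded — so the prediction at sample n sees input both before
and after n and the output length always equals the input length,
letting complete trials of any length be fed at test time.  Two
time-distributed single-unit dense heads (1x1 convolutions) with
sigmoid activations produce the IC and FC traces; training minimizes
the mean of the two heads' MSE with Adam.

Everything — forward pass, backpropagation, Adam — is implemented on
NumPy arrays; correctness is pinned by finite-difference gradient
checks and a receptive-field perturbation probe in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocessing import WindowSet

__all__ = [
    "TcnConfig", "TrainConfig", "LikelihoodTraces", "TcnModel",
    "build_model", "receptive_field", "count_params", "train_model",
    "predict_trial", "probe_receptive_field", "random_search",
    "save_model", "load_model",
    "DEFAULT_SEARCH_SPACE",
]


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TcnConfig:
    """Architecture hyperparameters of the event-detection TCN."""

    n_filters: int = 16
    kernel_size: int = 5
    dilations: tuple[int, ...] = (1, 2, 4)
    dropout_rate: float = 0.1
    window: int = 400
    in_channels: int = 6

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise InvalidConfigError("n_filters must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise InvalidConfigError("kernel_size must be odd and >= 1")
        d = tuple(self.dilations)
        if not d or d[0] != 1 or any(b != 2 * a for a, b in zip(d, d[1:])):
            raise InvalidConfigError(
                "dilations must be ascending powers of two starting at 1")
        if not 0 <= self.dropout_rate < 1:
            raise InvalidConfigError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("all training hyperparameters must be positive")


@dataclass
class LikelihoodTraces:
    """Predicted per-sample IC/FC likelihoods for one trial."""

    yic: np.ndarray
    yfc: np.ndarray
    fs: float


def receptive_field(config: TcnConfig) -> int:
    """Input span (samples) that can influence one output sample.

    Each centered convolution with kernel k and dilation d reaches
    (k-1)/2 * d samples to either side; reaches add over the two conv
    sub-layers of every residual block, and the 1x1 shortcut contributes
    nothing.
    """
    half = sum(2 * ((config.kernel_size - 1) // 2) * d for d in config.dilations)
    return 1 + 2 * half


# ---------------------------------------------------------------------------
# layers


class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class _Conv1D:
    """Dilated, centered ("same") 1-D convolution over (batch, time, channel)."""

    def __init__(self, cin: int, cout: int, kernel: int, dilation: int,
                 rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / (kernel * cin))        # He fan-in init
        self.W = _Param(rng.normal(0.0, scale, (kernel, cin, cout)).astype(dtype))
        self.b = _Param(np.zeros(cout, dtype=dtype))
        self.cin, self.cout = cin, cout
        self.kernel, self.dilation = kernel, dilation
        self.pad = (kernel - 1) // 2 * dilation

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        p, d, k = self.pad, self.dilation, self.kernel
        xp = np.pad(x, ((0, 0), (p, p), (0, 0))) if p else x
        self._xp, self._n = xp, x.shape[1]
        y = xp[:, 0:self._n, :] @ self.W.value[0]
        for j in range(1, k):
            y += xp[:, j * d:j * d + self._n, :] @ self.W.value[j]
        y += self.b.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p, d, k, n = self.pad, self.dilation, self.kernel, self._n
        xp = self._xp
        self.b.grad += dy.sum(axis=(0, 1))
        dy2 = np.ascontiguousarray(dy).reshape(-1, self.cout)
        dxp = np.zeros_like(xp)
        for j in range(k):
            xs = np.ascontiguousarray(xp[:, j * d:j * d + n, :])
            self.W.grad[j] += xs.reshape(-1, self.cin).T @ dy2
            dxp[:, j * d:j * d + n, :] += dy @ self.W.value[j].T
        self._xp = None
        return dxp[:, p:p + n, :] if p else dxp

    def params(self) -> list[_Param]:
        return [self.W, self.b]


class _BatchNorm:
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = _Param(np.ones(channels, dtype=dtype))
        self.beta = _Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._ivar = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu) * self._ivar
            return self.gamma.value * self._xhat + self.beta.value
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._xhat, self._ivar
        m = dy.shape[0] * dy.shape[1]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.value
        dx = (ivar / m) * (m * dxhat - dxhat.sum(axis=(0, 1))
                           - xhat * (dxhat * xhat).sum(axis=(0, 1)))
        self._xhat = None
        return dx

    def params(self) -> list[_Param]:
        return [self.gamma, self.beta]


class _ReLU:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self) -> list[_Param]:
        return []


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate)
                      .astype(x.dtype) / (1 - self.rate))
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask

    def params(self) -> list[_Param]:
        return []


class _ResBlock:
    """Two dilated conv -> BN -> ReLU -> dropout sequences plus a shortcut."""

    def __init__(self, cin: int, cout: int, kernel: int, dilation: int,
                 dropout: float, rng: np.random.Generator, dtype=np.float32):
        self.main = [
            _Conv1D(cin, cout, kernel, dilation, rng, dtype), _BatchNorm(cout, dtype=dtype),
            _ReLU(), _Dropout(dropout),
            _Conv1D(cout, cout, kernel, dilation, rng, dtype), _BatchNorm(cout, dtype=dtype),
            _ReLU(), _Dropout(dropout),
        ]
        self.shortcut = (_Conv1D(cin, cout, 1, 1, rng, dtype)
                         if cin != cout else None)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x
        for layer in self.main:
            h = layer.forward(h, training)
        s = self.shortcut.forward(x, training) if self.shortcut else x
        return h + s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = dy
        for layer in reversed(self.main):
            dh = layer.backward(dh)
        ds = self.shortcut.backward(dy) if self.shortcut else dy
        return dh + ds

    def params(self) -> list[_Param]:
        out = [p for layer in self.main for p in layer.params()]
        if self.shortcut:
            out += self.shortcut.params()
        return out


class TcnModel:
    """Fully convolutional IC/FC likelihood estimator."""

    def __init__(self, config: TcnConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.blocks = []
        cin = config.in_channels
        for d in config.dilations:
            self.blocks.append(_ResBlock(cin, config.n_filters,
                                         config.kernel_size, d,
                                         config.dropout_rate, rng, dtype))
            cin = config.n_filters
        self.head_ic = _Conv1D(cin, 1, 1, 1, rng, dtype)
        self.head_fc = _Conv1D(cin, 1, 1, 1, rng, dtype)

    # -- plumbing ----------------------------------------------------------

    def params(self) -> list[_Param]:
        out = [p for b in self.blocks for p in b.params()]
        out += self.head_ic.params() + self.head_fc.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def seed_dropout(self, seed: int) -> None:
        for i, layer in enumerate(l for b in self.blocks for l in b.main
                                  if isinstance(l, _Dropout)):
            layer.rng = np.random.default_rng((seed, i))

    def get_weights(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for b in self.blocks:
            for layer in b.main:
                if isinstance(layer, _BatchNorm):
                    state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, v in zip(params, state):
            p.value[...] = v
        i = len(params)
        for b in self.blocks:
            for layer in b.main:
                if isinstance(layer, _BatchNorm):
                    layer.running_mean[...] = state[i]
                    layer.running_var[...] = state[i + 1]
                    i += 2

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
        """x: (batch, N, in_channels) -> per-sample IC/FC likelihoods (batch, N)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3 or x.shape[2] != self.config.in_channels:
            raise ValueError(f"input must be (batch, N, "
                             f"{self.config.in_channels})")
        h = x
        for b in self.blocks:
            h = b.forward(h, training)
        self._h = h
        zic = self.head_ic.forward(h, training)[..., 0]
        zfc = self.head_fc.forward(h, training)[..., 0]
        self._yic = 1.0 / (1.0 + np.exp(-zic))
        self._yfc = 1.0 / (1.0 + np.exp(-zfc))
        return self._yic, self._yfc

    def backward(self, dyic: np.ndarray, dyfc: np.ndarray) -> None:
        dzic = (dyic * self._yic * (1 - self._yic))[..., None]
        dzfc = (dyfc * self._yfc * (1 - self._yfc))[..., None]
        dh = self.head_ic.backward(dzic) + self.head_fc.backward(dzfc)
        for b in reversed(self.blocks):
            dh = b.backward(dh)

    def loss_and_grad(self, x: np.ndarray, t: np.ndarray,
                      training: bool = True) -> float:
        """Mean over the two heads of the per-sample MSE; accumulates grads."""
        yic, yfc = self.forward(x, training=training)
        t = np.asarray(t, dtype=self.dtype)
        tic, tfc = t[..., 0], t[..., 1]
        m = yic.size
        loss = 0.5 * (np.mean((yic - tic) ** 2, dtype=np.float64)
                      + np.mean((yfc - tfc) ** 2, dtype=np.float64))
        if training:
            self.backward((yic - tic) / m, (yfc - tfc) / m)
        return float(loss)


def build_model(config: TcnConfig, seed: int = 0,
                dtype=np.float32) -> TcnModel:
    """Instantiate the network with seeded fan-in weight initialization.

    ``dtype`` selects the arithmetic precision; single precision is the
    training default, double precision is available for numerical
    verification (e.g., finite-difference gradient checks).
    """
    return TcnModel(config, seed=seed, dtype=dtype)


def count_params(model: TcnModel) -> int:
    """Number of trainable scalars (convolution and batch-norm affine weights)."""
    return sum(p.value.size for p in model.params())


def probe_receptive_field(model: TcnModel, seed: int = 0) -> int:
    """Measure the receptive field empirically by input perturbation.

    With dropout off and fixed weights the network is a deterministic
    map, and a centered architecture has a structurally exact cutoff:
    flipping an input sample farther than the half-width from a probe
    index cannot change the probe output, while flipping one at the
    half-width does (for generic random weights).  Returns the measured
    span ``2 * half + 1``.
    """
    nominal_half = (receptive_field(model.config) - 1) // 2
    n = 4 * nominal_half + 64
    probe = n // 2
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(1, n, model.config.in_channels))
    y0 = np.stack(model.forward(x, training=False))[..., probe]
    half = 0
    for dist in range(1, 2 * nominal_half + 2):
        xp = x.copy()
        xp[0, probe + dist, :] += 10.0
        y1 = np.stack(model.forward(xp, training=False))[..., probe]
        if np.any(y1 != y0):
            half = dist
    return 2 * half + 1


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self, params: list[_Param]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p in params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"epoch": self.epochs, "train_loss": self.train_loss,
                             "val_loss": self.val_loss})


def _eval_loss(model: TcnModel, ws: WindowSet, batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(ws), batch_size):
        x = ws.windows[i:i + batch_size]
        t = ws.targets[i:i + batch_size]
        total += model.loss_and_grad(x, t, training=False) * len(x)
        n += len(x)
    return total / n


def train_model(model: TcnModel, train: WindowSet, val: WindowSet | None,
                cfg: TrainConfig | None = None) -> TrainingHistory:
    """Mini-batch Adam on the mean two-head MSE with early stopping.

    Training stops after ``cfg.patience`` epochs without validation
    improvement; the weights of the best validation epoch are restored
    before returning.  Without a validation set the final weights are
    kept and early stopping is disabled.
    """
    cfg = cfg or TrainConfig()
    if len(train) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    model.seed_dropout(cfg.seed)
    opt = _Adam(cfg.learning_rate)
    history = TrainingHistory()
    best_val, best_state, since_best = np.inf, None, 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            model.zero_grad()
            loss = model.loss_and_grad(train.windows[idx], train.targets[idx],
                                       training=True)
            opt.step(model.params())
            epoch_loss += loss * len(idx)
            seen += len(idx)
        history.epochs.append(epoch)
        history.train_loss.append(epoch_loss / seen)
        if val is not None and len(val):
            vl = _eval_loss(model, val, cfg.batch_size)
            history.val_loss.append(vl)
            if not np.isfinite(vl):
                raise FloatingPointError("validation loss diverged")
            if vl < best_val - 1e-12:
                best_val, best_state, since_best = vl, model.get_weights(), 0
                history.best_epoch = epoch
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        else:
            history.val_loss.append(np.nan)
            history.best_epoch = epoch
    if best_state is not None:
        model.set_weights(best_state)
    return history


def predict_trial(model: TcnModel, X: np.ndarray, fs: float = 200.0
                  ) -> LikelihoodTraces:
    """Run inference on one complete (already normalized) trial.

    Deterministic: dropout is disabled and batch normalization uses its
    running statistics.  Any length N >= 1 is accepted; output lengths
    equal the input length.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.config.in_channels:
        raise ValueError(f"trial must be N x {model.config.in_channels}")
    rf = receptive_field(model.config)
    if X.shape[0] < rf:
        warnings.warn(f"trial length {X.shape[0]} is below the receptive "
                      f"field ({rf} samples); predictions use zero padding")
    yic, yfc = model.forward(X[None], training=False)
    return LikelihoodTraces(yic=yic[0], yfc=yfc[0], fs=fs)


# ---------------------------------------------------------------------------
# hyperparameter search

DEFAULT_SEARCH_SPACE = {
    "n_filters": (8, 16, 32, 64, 128),
    "kernel_size": (3, 5, 7),
    "dilations": ((1, 2), (1, 2, 4), (1, 2, 4, 8)),
}


def random_search(train: WindowSet, val: WindowSet, budget: int,
                  seed: int = 0, train_cfg: TrainConfig | None = None,
                  space: dict | None = None,
                  retrain_on_combined: bool = True,
                  ) -> tuple[TcnConfig, TcnModel, list[dict]]:
    """Uniform random search over the architecture grid.

    Samples ``budget`` configurations uniformly from the cross-product
    of the space, trains each on ``train`` and scores it on ``val``, and
    returns the configuration with the lowest validation loss together
    with its model and the full trial log.  With ``retrain_on_combined``
    the winning configuration is retrained on train+validation before
    being returned.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = space or DEFAULT_SEARCH_SPACE
    train_cfg = train_cfg or TrainConfig()
    rng = np.random.default_rng(seed)
    log = []
    best = None
    for trial in range(budget):
        cfg = TcnConfig(
            n_filters=space["n_filters"][rng.integers(len(space["n_filters"]))],
            kernel_size=space["kernel_size"][rng.integers(len(space["kernel_size"]))],
            dilations=space["dilations"][rng.integers(len(space["dilations"]))],
        )
        model = build_model(cfg, seed=int(rng.integers(2 ** 31)))
        hist = train_model(model, train, val, train_cfg)
        vl = min(hist.val_loss)
        log.append({"trial": trial, "config": cfg, "val_loss": vl})
        if best is None or vl < best[0]:
            best = (vl, cfg, model)
    _, best_cfg, best_model = best
    if retrain_on_combined:
        from .preprocessing import concat_window_sets
        combined = concat_window_sets([train, val])
        best_model = build_model(best_cfg, seed=seed)
        train_model(best_model, combined, None, train_cfg)
    return best_cfg, best_model, log


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: TcnModel, path: str | Path) -> None:
    """Serialize architecture + weights + BN running stats to one ``.npz``."""
    cfg = model.config
    state = model.get_weights()
    np.savez(path,
             config=json.dumps({"n_filters": cfg.n_filters,
                                "kernel_size": cfg.kernel_size,
                                "dilations": list(cfg.dilations),
                                "dropout_rate": cfg.dropout_rate,
                                "window": cfg.window,
                                "in_channels": cfg.in_channels}),
             n_arrays=len(state),
             **{f"arr_{i}": a for i, a in enumerate(state)})


def load_model(path: str | Path) -> TcnModel:
    with np.load(path, allow_pickle=False) as f:
        raw = json.loads(str(f["config"]))
        raw["dilations"] = tuple(raw["dilations"])
        model = build_model(TcnConfig(**raw))
        state = [f[f"arr_{i}"] for i in range(int(f["n_arrays"]))]
    model.set_weights(state)
    return model
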