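"""The inverse model: a spatial pre-filtering stage plus recurrent temporal
stage mapping sensor matrices to region-wise source waveforms.

The spatial module is a per-time-step fully connected residual stack that
learns a denoising/inverse operator on scalp topographies; the temporal
module is a stack of residual LSTM layers that integrates information over
time (helpful when instantaneous topographies are ambiguous, e.g. at phase
cancellations); a linear per-time-step readout emits one waveform per
cortical region.  Training minimizes the mean squared error to the ground
truth source activity with Adam.  The whole model is implemented on NumPy
(see ``_nn``) and is exposed both as a scikit-learn style regressor and as
thin functional wrappers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import _nn

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SourceEstimate",
    "SpatioTemporalNet",
    "TrainingDiverged",
    "NetworkESIRegressor",
    "build_network",
    "train_network",
    "estimate_sources",
    "save_checkpoint",
    "load_checkpoint",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_size`` defaults to the region count; the temporal stage is
    sequence-length agnostic, so ``time_points`` is informational only.
    """

    channels: int = 76
    regions: int = 994
    time_points: int = 500
    spatial_width: int = 500
    spatial_blocks: int = 3
    recurrent_layers: int = 3
    hidden_size: int | None = None
    skip: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.channels <= 0 or self.regions <= 0:
            raise ValueError("channels and regions must be positive")

    @property
    def hidden(self) -> int:
        return self.hidden_size or self.regions


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-4
    weight_decay: float = 1e-6
    batch_size: int = 64
    epochs: int = 50
    val_fraction: float = 0.05
    checkpoint_every: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")


class SpatioTemporalNet:
    """channels x T -> regions x T network; any T at inference time."""

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        W, H = cfg.spatial_width, cfg.hidden
        self.spatial = [_nn.Dense(cfg.channels, W, rng, dtype), _nn.ReLU()]
        for _ in range(cfg.spatial_blocks):
            self.spatial.append(_nn.ResidualBlock(W, rng, dtype))
        self.spatial.append(_nn.Dense(W, H, rng, dtype))
        self.temporal = [
            _nn.LSTM(H, H, rng, residual=cfg.skip, dtype=dtype)
            for _ in range(cfg.recurrent_layers)
        ]
        self.readout = _nn.Dense(H, cfg.regions, rng, dtype)
        self._layers = self.spatial + self.temporal + [self.readout]
        self.dtype = dtype

    # -- Sequential-compatible parameter API -------------------------------
    def parameters(self):
        out = []
        for li, layer in enumerate(self._layers):
            for name in layer.params:
                out.append((f"{li}.{name}", layer.params[name], layer.grads[name]))
        return out

    def zero_grad(self):
        for layer in self._layers:
            layer.zero_grad()

    def state_dict(self):
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, state):
        for name, p, _ in self.parameters():
            np.copyto(p, state[name])

    # ----------------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (batch, channels, T) -> (batch, regions, T)."""
        x = np.ascontiguousarray(np.swapaxes(np.asarray(x, self.dtype), 1, 2))
        B, T, C = x.shape
        if C != self.cfg.channels:
            raise ValueError(f"expected {self.cfg.channels} channels, got {C}")
        h = x.reshape(B * T, C)
        for layer in self.spatial:
            h = layer.forward(h)
        h = h.reshape(B, T, -1)
        for layer in self.temporal:
            h = layer.forward(h)
        self._bt = (B, T)
        y = self.readout.forward(h.reshape(B * T, -1))
        return np.swapaxes(y.reshape(B, T, -1), 1, 2)

    def backward(self, dy: np.ndarray) -> None:
        B, T = self._bt
        d = np.ascontiguousarray(np.swapaxes(dy.astype(self.dtype), 1, 2))
        d = self.readout.backward(d.reshape(B * T, -1))
        d = d.reshape(B, T, -1)
        for layer in reversed(self.temporal):
            d = layer.backward(d)
        d = d.reshape(B * T, -1)
        for layer in reversed(self.spatial):
            d = layer.backward(d)

    __call__ = forward


def build_network(cfg: ModelConfig, dtype=np.float32) -> SpatioTemporalNet:
    """Deterministically initialized network for a given config/seed."""
    return SpatioTemporalNet(cfg, dtype)


@dataclass
class SourceEstimate:
    """Region waveforms plus the derived per-region energy map."""

    waveforms: np.ndarray  # regions x time
    energy_map: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.energy_map is None:
            self.energy_map = np.sum(np.asarray(self.waveforms, float) ** 2, axis=1)
        self.energy_map = np.asarray(self.energy_map, float)
        if np.any(self.energy_map < 0):
            raise ValueError("energy map must be nonnegative")

    def recompute_energy(self) -> None:
        self.energy_map = np.sum(np.asarray(self.waveforms, float) ** 2, axis=1)


def _iter_batches(n, batch_size, rng=None):
    idx = np.arange(n) if rng is None else rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield idx[lo:lo + batch_size]


def _epoch(model, opt, X, y, batch_size, rng):
    losses = []
    for batch in _iter_batches(len(X), batch_size, rng):
        model.zero_grad()
        pred = model.forward(X[batch])
        loss, dpred = _nn.mse_loss(pred, y[batch])
        if not np.isfinite(loss):
            raise TrainingDiverged(
                f"non-finite training loss at optimizer step {opt.t}"
            )
        model.backward(dpred)
        opt.step()
        losses.append(loss)
    return float(np.mean(losses))


def _val_loss(model, X, y, batch_size):
    tot, n = 0.0, 0
    for batch in _iter_batches(len(X), batch_size):
        pred = model.forward(X[batch])
        tot += float(np.sum((pred - y[batch]) ** 2))
        n += pred.size
    return tot / max(n, 1)


def train_network(
    model: SpatioTemporalNet,
    X: np.ndarray,
    y: np.ndarray,
    tc: TrainConfig = TrainConfig(),
    groups=None,
    verbose: bool = False,
):
    """MSE/Adam training loop with a grouped validation split.

    ``groups`` (e.g. patch identifiers) keep all SNR copies of one patch on
    the same side of the train/validation split; the parameters of the
    best-validation epoch are restored before returning.  Returns the
    history as a dict of per-epoch lists.
    """
    X = np.asarray(X, model.dtype)
    y = np.asarray(y, model.dtype)
    rng = np.random.default_rng(tc.seed)
    if groups is None:
        groups = np.arange(len(X))
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    val_groups = rng.choice(
        uniq, size=max(1, int(round(tc.val_fraction * uniq.size))), replace=False
    )
    val_mask = np.isin(groups, val_groups)
    Xtr, ytr = X[~val_mask], y[~val_mask]
    Xva, yva = X[val_mask], y[val_mask]

    opt = _nn.Adam(model, lr=tc.learning_rate, weight_decay=tc.weight_decay)
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    best = (np.inf, model.state_dict())
    for epoch in range(tc.epochs):
        tr_loss = _epoch(model, opt, Xtr, ytr, tc.batch_size, rng)
        va_loss = _val_loss(model, Xva, yva, tc.batch_size)
        history["epoch"].append(epoch)
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(va_loss)
        if verbose:
            print(f"epoch {epoch}: train {tr_loss:.5f}  val {va_loss:.5f}")
        if va_loss < best[0] and epoch % tc.checkpoint_every == 0:
            best = (va_loss, model.state_dict())
    if np.isfinite(best[0]):
        model.load_state_dict(best[1])
    return history


def estimate_sources(model: SpatioTemporalNet, sensors: np.ndarray) -> SourceEstimate:
    """Inference on one sensor matrix (channels x time).

    The max-abs scaling used for the training data is applied to the input;
    no parameter is tuned at inference time.
    """
    sensors = np.asarray(sensors, float)
    if sensors.ndim != 2 or sensors.shape[0] != model.cfg.channels:
        raise ValueError(
            f"expected a ({model.cfg.channels}, T) sensor matrix, got {sensors.shape}"
        )
    peak = np.max(np.abs(sensors))
    if peak > 0:
        sensors = sensors / peak
    wave = model.forward(sensors[None])[0].astype(float)
    return SourceEstimate(wave, provenance={"method": "network"})


class NetworkESIRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style wrapper around the spatiotemporal inverse network.

    ``fit(X, y)`` expects ``X`` of shape (n_samples, channels, T) and ``y``
    of shape (n_samples, regions, T), both max-abs normalized; ``predict``
    returns region waveforms of the same layout.  ``fit`` accepts a
    ``groups`` keyword to keep related samples (e.g. SNR copies of one
    patch) on one side of the validation split.
    """

    def __init__(self, spatial_width=500, spatial_blocks=3, recurrent_layers=3,
                 hidden_size=None, skip=True, learning_rate=3e-4,
                 weight_decay=1e-6, batch_size=64, epochs=50,
                 val_fraction=0.05, seed=0, verbose=False):
        self.spatial_width = spatial_width
        self.spatial_blocks = spatial_blocks
        self.recurrent_layers = recurrent_layers
        self.hidden_size = hidden_size
        self.skip = skip
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.val_fraction = val_fraction
        self.seed = seed
        self.verbose = verbose

    def fit(self, X, y, groups=None):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 3 or y.ndim != 3 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, channels, T) and y (n, regions, T)")
        cfg = ModelConfig(
            channels=X.shape[1], regions=y.shape[1], time_points=X.shape[2],
            spatial_width=self.spatial_width, spatial_blocks=self.spatial_blocks,
            recurrent_layers=self.recurrent_layers, hidden_size=self.hidden_size,
            skip=self.skip, seed=self.seed,
        )
        tc = TrainConfig(
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            batch_size=self.batch_size, epochs=self.epochs,
            val_fraction=self.val_fraction, seed=self.seed,
        )
        self.model_ = build_network(cfg)
        self.history_ = train_network(
            self.model_, X, y, tc, groups=groups, verbose=self.verbose
        )
        self.config_ = cfg
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        X = np.asarray(X)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = []
        for lo in range(0, len(X), self.batch_size):
            out.append(self.model_.forward(X[lo:lo + self.batch_size]))
        pred = np.concatenate(out).astype(float)
        return pred[0] if single else pred

    def score(self, X, y):
        """Negative mean squared error (higher is better)."""
        pred = self.predict(X)
        return -float(np.mean((pred - np.asarray(y)) ** 2))


def save_checkpoint(path, model: SpatioTemporalNet, history=None,
                    manifest_hash: str = "") -> None:
    """Parameters + embedded config (+ dataset manifest hash) in one npz."""
    state = model.state_dict()
    meta = {
        "config": dataclasses.asdict(model.cfg),
        "manifest_hash": manifest_hash,
        "history": history or {},
    }
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    cfg = ModelConfig(**meta["config"])
    model = build_network(cfg)
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta
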