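"""Per-patient convolutional autoencoder over 48 x 12 profiles.

Architecture (one down-sampling and one up-sampling block):

    input (48, 12)
      -> 2D convolution, 64 filters, kernel 11 x 12 (the kernel spans the
         full feature width, "valid" along time)        -> (38, 64)
      -> LeakyReLU -> flatten -> dense                  -> latent (15,)
      -> dense -> LeakyReLU -> reshape                  -> (38, 64)
      -> transposed convolution, kernel 11 x 12         -> (48, 12)

Training minimizes the reconstruction mean squared error with Adam
(learning rate 1e-4 by default) on non-relapse profiles only, with early
stopping on validation MSE (patience 3, best-epoch weights restored).

The implementation is plain NumPy with hand-derived gradients; because the
kernel spans the full feature width the convolution reduces to a 1-D
valid correlation along time, and its transpose is the exact adjoint, so
both directions share two small primitives.  A finite-difference gradient
check lives in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .features import FEATURE_COLUMNS
from .profiles import Profile2D, WINDOW_SLOTS, stack_matrices

N_FEATURES = len(FEATURE_COLUMNS)


@dataclass
class CAEConfig:
    n_filters: int = 64
    kernel_h: int = 11  # kernel height (time); width always spans all 12 features
    latent_dim: int = 15
    learning_rate: float = 1e-4
    patience: int = 3  # epochs without validation improvement
    max_epochs: int = 200
    batch_size: int = 32
    leaky_alpha: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 1 <= self.kernel_h <= WINDOW_SLOTS:
            raise ValueError("kernel height must fit inside the window")

    @property
    def conv_h(self) -> int:
        return WINDOW_SLOTS - self.kernel_h + 1


# ---------------------------------------------------------------------------
# primitives: full-width valid correlation and its adjoint
# ---------------------------------------------------------------------------


def _conv_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """(B, H, W) x (F, kh, W) -> (B, H-kh+1, F) valid correlation."""
    kh = w.shape[1]
    patches = sliding_window_view(x, kh, axis=1)  # (B, H-kh+1, W, kh)
    return np.einsum("bhwk,fkw->bhf", patches, w, optimize=True)


def _conv_transpose(h: np.ndarray, w: np.ndarray, out_h: int) -> np.ndarray:
    """Adjoint of :func:`_conv_valid`: (B, Hc, F) x (F, kh, W) -> (B, out_h, W)."""
    b, hc, _ = h.shape
    kh, width = w.shape[1], w.shape[2]
    contrib = np.einsum("bhf,fkw->bhkw", h, w, optimize=True)
    out = np.zeros((b, out_h, width))
    for i in range(kh):
        out[:, i:i + hc, :] += contrib[:, :, i, :]
    return out


def _conv_weight_grad(x: np.ndarray, dz: np.ndarray, kh: int) -> np.ndarray:
    """Gradient of _conv_valid w.r.t. w: returns (F, kh, W)."""
    patches = sliding_window_view(x, kh, axis=1)  # (B, Hc, W, kh)
    return np.einsum("bhwk,bhf->fkw", patches, dz, optimize=True)


def _lrelu(z: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(z > 0, z, alpha * z)


def _lrelu_grad(z: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(z > 0, 1.0, alpha)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: CAEConfig) -> Dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    f, kh, w = config.n_filters, config.kernel_h, N_FEATURES
    hidden = config.conv_h * f
    lat = config.latent_dim
    return {
        "w_conv": _glorot(rng, (f, kh, w), kh * w, f),
        "b_conv": np.zeros(f),
        "w_enc": _glorot(rng, (lat, hidden), hidden, lat),
        "b_enc": np.zeros(lat),
        "w_dec": _glorot(rng, (hidden, lat), lat, hidden),
        "b_dec": np.zeros(hidden),
        "w_tconv": _glorot(rng, (f, kh, w), f, kh * w),
        "b_tconv": np.zeros(1),
    }


def _forward(params: Dict[str, np.ndarray], x: np.ndarray, config: CAEConfig,
             need_cache: bool = False):
    alpha = config.leaky_alpha
    b = x.shape[0]
    z1 = _conv_valid(x, params["w_conv"]) + params["b_conv"]
    a1 = _lrelu(z1, alpha)
    flat = a1.reshape(b, -1)
    latent = flat @ params["w_enc"].T + params["b_enc"]
    z3 = latent @ params["w_dec"].T + params["b_dec"]
    a3 = _lrelu(z3, alpha)
    h = a3.reshape(b, config.conv_h, config.n_filters)
    recon = _conv_transpose(h, params["w_tconv"], WINDOW_SLOTS) + params["b_tconv"]
    if not need_cache:
        return latent, recon, None
    return latent, recon, {"x": x, "z1": z1, "flat": flat, "latent": latent,
                           "z3": z3, "h": h}


def _backward(params, cache, recon, config: CAEConfig) -> Dict[str, np.ndarray]:
    """Gradients of the mean squared reconstruction error."""
    alpha = config.leaky_alpha
    x = cache["x"]
    b = x.shape[0]
    d_recon = 2.0 * (recon - x) / recon.size
    grads: Dict[str, np.ndarray] = {}
    grads["b_tconv"] = np.array([d_recon.sum()])
    grads["w_tconv"] = np.einsum(
        "bhf,bhwk->fkw",
        cache["h"],
        sliding_window_view(d_recon, config.kernel_h, axis=1),
        optimize=True)
    dh = _conv_valid(d_recon, params["w_tconv"])  # adjoint of the transpose
    da3 = dh.reshape(b, -1)
    dz3 = da3 * _lrelu_grad(cache["z3"], alpha)
    grads["w_dec"] = dz3.T @ cache["latent"]
    grads["b_dec"] = dz3.sum(axis=0)
    d_latent = dz3 @ params["w_dec"]
    grads["w_enc"] = d_latent.T @ cache["flat"]
    grads["b_enc"] = d_latent.sum(axis=0)
    d_flat = d_latent @ params["w_enc"]
    dz1 = d_flat.reshape(b, config.conv_h, config.n_filters)
    dz1 = dz1 * _lrelu_grad(cache["z1"], alpha)
    grads["w_conv"] = _conv_weight_grad(x, dz1, config.kernel_h)
    grads["b_conv"] = dz1.sum(axis=(0, 1))
    return grads


def batch_loss_and_grads(params, x, config):
    """Mean squared error and its gradients on one batch (testing hook)."""
    _, recon, cache = _forward(params, x, config, need_cache=True)
    loss = float(np.mean((recon - x) ** 2))
    return loss, _backward(params, cache, recon, config)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedCAE:
    params: Dict[str, np.ndarray]
    config: CAEConfig
    history: Dict[str, List[float]] = field(default_factory=dict)
    best_epoch: int = -1
    norm_stats_patient: Optional[str] = None

    def save(self, path: Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {"config": asdict(self.config), "history": self.history,
                "best_epoch": self.best_epoch,
                "norm_stats_patient": self.norm_stats_patient}
        np.savez(path.with_suffix(".npz"), **self.params)
        path.with_suffix(".json").write_text(json.dumps(meta))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: Path) -> "TrainedCAE":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as data:
            params = {k: data[k].copy() for k in data.files}
        return cls(params=params, config=CAEConfig(**meta["config"]),
                   history=meta["history"], best_epoch=meta["best_epoch"],
                   norm_stats_patient=meta["norm_stats_patient"])


def _as_array(profiles) -> np.ndarray:
    if isinstance(profiles, np.ndarray):
        x = profiles
        if x.ndim == 2:
            x = x[None]
    else:
        x = stack_matrices(profiles)
    if x.ndim != 3 or x.shape[1:] != (WINDOW_SLOTS, N_FEATURES):
        raise ValueError(f"expected (n, {WINDOW_SLOTS}, {N_FEATURES}) profiles, "
                         f"got {x.shape}")
    return np.asarray(x, dtype=np.float64)


def train_cae(train_profiles: Sequence[Profile2D] | np.ndarray,
              val_profiles: Sequence[Profile2D] | np.ndarray,
              config: Optional[CAEConfig] = None) -> TrainedCAE:
    """Fit the autoencoder on standardized non-relapse profiles.

    Enforces the anomaly-detection contract: a relapse-labelled profile in
    the training set is an error.  Early stopping monitors validation MSE
    and restores the best epoch's parameters.
    """
    config = config or CAEConfig()
    if not isinstance(train_profiles, np.ndarray):
        if len(train_profiles) == 0:
            raise ValueError("empty training set")
        if any(p.relapse_label == 1 for p in train_profiles):
            raise ValueError("relapse-labelled profile in the training set")
    x_train = _as_array(train_profiles)
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")
    x_val = _as_array(val_profiles)
    if x_val.shape[0] == 0:
        x_val = x_train  # degenerate fallback: monitor training loss

    params = init_params(config)
    opt = _Adam(params, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = x_train.shape[0]
    history = {"train_mse": [], "val_mse": []}
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = -1
    stall = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            xb = x_train[order[start:start + config.batch_size]]
            _, recon, cache = _forward(params, xb, config, need_cache=True)
            grads = _backward(params, cache, recon, config)
            opt.step(params, grads)
        history["train_mse"].append(reconstruct(params, x_train, config)[2])
        val_mse = reconstruct(params, x_val, config)[2]
        history["val_mse"].append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    return TrainedCAE(params=best_params, config=config, history=history,
                      best_epoch=best_epoch)


def encode(model: TrainedCAE | Dict[str, np.ndarray],
           profiles, config: Optional[CAEConfig] = None) -> np.ndarray:
    """Latent vectors, one row of length ``latent_dim`` per profile."""
    params, config = _unpack(model, config)
    x = _as_array(profiles)
    latent, _, _ = _forward(params, x, config)
    return latent


def reconstruct(model: TrainedCAE | Dict[str, np.ndarray],
                profiles, config: Optional[CAEConfig] = None
                ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Reconstructions, per-profile MSE and mean MSE."""
    params, config = _unpack(model, config)
    x = _as_array(profiles)
    _, recon, _ = _forward(params, x, config)
    per = np.mean((recon - x) ** 2, axis=(1, 2))
    return recon, per, float(per.mean()) if per.size else float("nan")


def mse_to_rms(mse: float) -> float:
    """Per-element root-mean-square error implied by a mean squared error."""
    return float(np.sqrt(mse))


def _unpack(model, config):
    if isinstance(model, TrainedCAE):
        return model.params, model.config
    if config is None:
        raise ValueError("config required when passing a raw parameter dict")
    return model, config
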