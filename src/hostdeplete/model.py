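"""The variable-length convolutional classifier, in pure NumPy.

Architecture: ``[conv(k, F) -> ReLU -> avg-pool(p)] x n`` followed by global
average pooling over the positional axis and a single logistic output unit.
Convolutions use same-padding and stride 1; pooling windows are
non-overlapping with a partial final window averaged over its actual element
count, so any input length >= 1 survives every stage and the network accepts
reads of arbitrary length without padding.

The module also provides the layer primitives (forward, backward, and the
adjoint pass used for double-backprop of the input-gradient penalty) that
:mod:`hostdeplete.training` and :mod:`hostdeplete.attribution` build on.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import asdict, dataclass
from typing import Dict, List, Tuple

import numpy as np

from hostdeplete.errors import ConfigError, LengthError, ModelLoadError

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    num_conv_layers: int = 4
    filters_per_layer: int = 128
    kernel_length: int = 15
    pool_length: int = 5
    input_channels: int = 4
    output_units: int = 1
    min_input_length: int = 50

    def __post_init__(self) -> None:
        for name in (
            "num_conv_layers",
            "filters_per_layer",
            "kernel_length",
            "pool_length",
            "input_channels",
            "output_units",
            "min_input_length",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.kernel_length % 2 == 0:
            raise ConfigError("kernel_length must be odd (same-padding)")
        if self.output_units != 1:
            raise ConfigError("only a single logistic output unit is supported")


# ---------------------------------------------------------------------------
# layer primitives (channels-last: batch x length x channels)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Same-padded sliding windows: (N, L, C) -> (N, L, k*C)."""
    n, length, c = x.shape
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (N, L, C, k)
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n, length, k * c)


def conv_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None) -> np.ndarray:
    """x: (N, L, Cin); weight: (k*Cin, Cout) laid out (tap, channel)-major."""
    cin = x.shape[2]
    k = weight.shape[0] // cin
    z = _im2col(x, k) @ weight
    if bias is not None:
        z += bias
    return z


def conv_backward_input(dz: np.ndarray, weight: np.ndarray, cin: int) -> np.ndarray:
    """Gradient w.r.t. the conv input (the transposed convolution)."""
    n, length, _ = dz.shape
    k = weight.shape[0] // cin
    pad = (k - 1) // 2
    dcols = (dz @ weight.T).reshape(n, length, k, cin)
    dxp = np.zeros((n, length + 2 * pad, cin), dtype=dz.dtype)
    for tap in range(k):
        dxp[:, tap : tap + length, :] += dcols[:, :, tap, :]
    return dxp[:, pad : pad + length, :]


def conv_backward_params(x: np.ndarray, dz: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Gradients w.r.t. the flattened weight and the bias."""
    n, length, cin = x.shape
    cols = _im2col(x, k).reshape(n * length, k * cin)
    dw = cols.T @ dz.reshape(n * length, -1)
    db = dz.sum(axis=(0, 1))
    return dw, db


def avgpool_forward(x: np.ndarray, p: int) -> np.ndarray:
    """Non-overlapping average pooling; the final partial window averages
    over its actual element count (ceiling division on the length)."""
    n, length, c = x.shape
    out_len = -(-length // p)
    padded = length if length % p == 0 else out_len * p
    if padded != length:
        x = np.pad(x, ((0, 0), (0, padded - length), (0, 0)))
    sums = x.reshape(n, out_len, p, c).sum(axis=2)
    counts = np.full(out_len, p, dtype=x.dtype)
    counts[-1] = length - p * (out_len - 1)
    return sums / counts[None, :, None]


def avgpool_backward(dout: np.ndarray, p: int, in_length: int) -> np.ndarray:
    out_len = dout.shape[1]
    counts = np.full(out_len, p, dtype=dout.dtype)
    counts[-1] = in_length - p * (out_len - 1)
    return np.repeat(dout / counts[None, :, None], p, axis=1)[:, :in_length, :]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class ConvNet:
    """Variable-length CNN mapping one-hot read batches to host probabilities.

    Parameters are float32 arrays in ``self.params``:
    ``conv{i}_W`` of shape (k * C_in, C_out), ``conv{i}_b`` of shape (C_out,),
    ``fc_w`` of shape (C,), and scalar ``fc_b``.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: Dict[str, np.ndarray] = {}
        cin = config.input_channels
        for i in range(config.num_conv_layers):
            fan_in = config.kernel_length * cin
            self.params[f"conv{i}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(fan_in, config.filters_per_layer)
            ).astype(np.float32)
            self.params[f"conv{i}_b"] = np.zeros(config.filters_per_layer, dtype=np.float32)
            cin = config.filters_per_layer
        self.params["fc_w"] = rng.normal(0.0, np.sqrt(1.0 / cin), size=cin).astype(np.float32)
        self.params["fc_b"] = np.zeros((), dtype=np.float32)

    # -- inference ----------------------------------------------------------

    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        if batch.ndim != 3 or batch.shape[2] != self.config.input_channels:
            raise ValueError(f"expected an N x L x {self.config.input_channels} batch, got {batch.shape}")
        if batch.shape[1] < self.config.min_input_length:
            raise LengthError(
                f"input length {batch.shape[1]} below the minimum supported "
                f"length {self.config.min_input_length}"
            )
        if batch.dtype == np.float64:  # keep float64 for gradient checks
            return batch
        return np.asarray(batch, dtype=np.float32)

    def forward_cache(self, batch: np.ndarray) -> Tuple[np.ndarray, dict]:
        """Logits plus the intermediate values needed for backprop."""
        x = self._check_batch(batch)
        cfg = self.config
        a = x
        layers: List[dict] = []
        for i in range(cfg.num_conv_layers):
            z = conv_forward(a, self.params[f"conv{i}_W"], self.params[f"conv{i}_b"])
            mask = z > 0
            r = z * mask
            layers.append({"a_in": a, "mask": mask, "in_length": a.shape[1]})
            a = avgpool_forward(r, cfg.pool_length)
        s = a.mean(axis=1)  # global average pooling -> (N, C)
        logit = s @ self.params["fc_w"] + self.params["fc_b"]
        cache = {"layers": layers, "s": s, "gap_length": a.shape[1], "x": x}
        return logit, cache

    def logits(self, batch: np.ndarray) -> np.ndarray:
        logit, _ = self.forward_cache(batch)
        return logit

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Host probability for each read in the batch."""
        return _sigmoid(self.logits(batch))

    # -- gradients ----------------------------------------------------------

    def backward(self, cache: dict, dlogit: np.ndarray, need_dx: bool = False):
        """Backprop a gradient on the logits to parameters (and the input)."""
        cfg = self.config
        grads: Dict[str, np.ndarray] = {}
        grads["fc_w"] = cache["s"].T @ dlogit
        grads["fc_b"] = dlogit.sum()
        da = np.repeat(
            np.outer(dlogit, self.params["fc_w"])[:, None, :] / cache["gap_length"],
            cache["gap_length"],
            axis=1,
        )
        for i in reversed(range(cfg.num_conv_layers)):
            layer = cache["layers"][i]
            dr = avgpool_backward(da, cfg.pool_length, layer["in_length"])
            dz = dr * layer["mask"]
            dw, db = conv_backward_params(layer["a_in"], dz, cfg.kernel_length)
            grads[f"conv{i}_W"] = dw
            grads[f"conv{i}_b"] = db
            if i > 0 or need_dx:
                da = conv_backward_input(dz, self.params[f"conv{i}_W"], layer["a_in"].shape[2])
        dx = da if need_dx else None
        return grads, dx

    def input_gradient(self, cache: dict, keep_dz: bool = False):
        """d logit / d input for every read in the cached batch.

        With ``keep_dz`` the per-layer pre-activation gradients are returned
        too (needed by the double-backprop adjoint pass).
        """
        cfg = self.config
        n = cache["s"].shape[0]
        c = self.params["fc_w"].shape[0]
        ga = np.broadcast_to(
            self.params["fc_w"] / cache["gap_length"], (n, cache["gap_length"], c)
        )
        dz_list: List[np.ndarray] = []
        for i in reversed(range(cfg.num_conv_layers)):
            layer = cache["layers"][i]
            gr = avgpool_backward(np.ascontiguousarray(ga), cfg.pool_length, layer["in_length"])
            gz = gr * layer["mask"]
            if keep_dz:
                dz_list.append(gz)
            ga = conv_backward_input(gz, self.params[f"conv{i}_W"], layer["a_in"].shape[2])
        if keep_dz:
            return ga, dz_list[::-1]  # dz_list[i] matches conv layer i
        return ga

    def input_grad_penalty(self, cache: dict) -> Tuple[float, Dict[str, np.ndarray]]:
        """Mean squared input-gradient norm and its parameter gradients.

        Double-backprop for a piecewise-linear network: ReLU has zero second
        derivative almost everywhere, so only the appearance of the weights
        in the backward graph contributes — the adjoint of the backprop chain
        is propagated forward through transposed-conv -> mask -> pool stages.
        """
        cfg = self.config
        n = cache["s"].shape[0]
        g, dz_list = self.input_gradient(cache, keep_dz=True)
        penalty = float((g.astype(np.float64) ** 2).sum() / n)
        grads: Dict[str, np.ndarray] = {
            name: np.zeros_like(p) for name, p in self.params.items()
        }
        u = (2.0 / n) * g
        for i in range(cfg.num_conv_layers):
            dz = dz_list[i]
            dw, _ = conv_backward_params(u, dz, cfg.kernel_length)
            grads[f"conv{i}_W"] += dw
            u = conv_forward(u, self.params[f"conv{i}_W"], None)
            u = u * cache["layers"][i]["mask"]
            u = avgpool_forward(u, cfg.pool_length)
        grads["fc_w"] += u.sum(axis=(0, 1)) / cache["gap_length"]
        return penalty, grads

    # -- bookkeeping --------------------------------------------------------

    def count_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def serialized_size_gb(self, precision: int = 4) -> float:
        """Storage footprint in GB, rounded to 3 decimals."""
        return round(self.count_parameters() * precision / 1e9, 3)

    def set_all_zero(self) -> "ConvNet":
        for p in self.params.values():
            p[...] = 0.0
        return self

    def copy_params(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_params(self, params: Dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            self.params[k][...] = v


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> ConvNet:
    """Reproducibly initialize a :class:`ConvNet` from a seed."""
    return ConvNet(config, seed=seed)


def save_model(model: ConvNet, path: os.PathLike | str) -> None:
    """Single-file checkpoint: weights + config + format version."""
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": asdict(model.config)})
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **model.params)
    with open(path, "wb") as handle:
        handle.write(buf.getvalue())


def load_model(path: os.PathLike | str) -> ConvNet:
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ModelLoadError(f"unsupported checkpoint version {meta.get('version')}")
            config = ModelConfig(**meta["config"])
            model = ConvNet(config, seed=0)
            for name in model.params:
                arr = data[name]
                if arr.shape != model.params[name].shape:
                    raise ModelLoadError(
                        f"shape mismatch for {name}: {arr.shape} vs {model.params[name].shape}"
                    )
                model.params[name] = arr.astype(np.float32)
    except ModelLoadError:
        raise
    except Exception as exc:  # zip/np errors on truncated or foreign files
        raise ModelLoadError(f"cannot load model from {path}: {exc}") from exc
    return model


def count_parameters(model: ConvNet) -> int:
    return model.count_parameters()


def serialized_size_gb(model: ConvNet, precision: int = 4) -> float:
    return model.serialized_size_gb(precision)
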