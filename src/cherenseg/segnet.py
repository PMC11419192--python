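"""Residual encoder-decoder segmentation network.

A 2-D SegResNet-style backbone mapping a grayscale image to a same-sized
per-pixel vessel probability map.  The encoder stacks pre-activation
residual blocks (batch norm -> ReLU -> 3x3 conv, twice, plus an additive
identity skip) with strided-convolution downsampling between spatial
levels; the decoder is symmetric but with a single block per level,
non-learned nearest-neighbour x2 upsampling after a 1x1 channel reduction,
and additive skip connections from the encoder.  A 1-channel head followed
by a sigmoid produces the probability map.

The whole network — forward pass, backpropagation and parameter
management — is implemented directly on numpy arrays.  Convolutions use an
im2col lowering so the inner loop is a single BLAS matmul; batch
normalization keeps running statistics so inference is deterministic.
Arrays are laid out (batch, channels, height, width); parameters default
to float32 (the conv lowering is memory-bandwidth-bound, so this nearly
halves step time), with float64 available for numerical verification.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass

import numpy as np

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class NetworkConfig:
    """Backbone layout.  Defaults follow the canonical published layout of
    this backbone family: 32 initial filters doubling per level, residual
    block counts [1, 2, 2, 4] over four spatial levels, one decoder block
    per level."""

    init_filters: int = 32
    kernel: int = 3
    levels: int = 4
    blocks_per_level: tuple[int, ...] = (1, 2, 2, 4)
    decoder_blocks: int = 1
    in_channels: int = 1
    out_channels: int = 1
    use_residual: bool = True     # ablation switch for the identity skips

    def __post_init__(self) -> None:
        if self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.levels < 2:
            raise ValueError("need at least 2 spatial levels")
        if len(self.blocks_per_level) != self.levels:
            raise ValueError("blocks_per_level must list one count per level")
        if self.init_filters < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")

    @property
    def filters(self) -> tuple[int, ...]:
        return tuple(self.init_filters * 2**i for i in range(self.levels))

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.levels - 1)


# ---------------------------------------------------------------------------
# layer primitives (forward + backward)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, ho, wo, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
    )
    # the reshape of the transposed view performs the one unavoidable copy
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    return cols, ho, wo


def _col2im(dcols, x_shape, k, stride, pad, ho, wo):
    b, c, h, w = x_shape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d:
    """k x k convolution, 'same' padding for stride 1 (pad = k // 2)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        self.dtype = dtype
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))   # He initialization
        self.params = {
            "W": rng.normal(0.0, scale, (cout, cin, k, k)).astype(dtype),
            "b": np.zeros(cout, dtype=dtype),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = x.astype(self.dtype, copy=False)
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.params["W"].reshape(self.cout, -1)
        y = cols @ wmat.T + self.params["b"]
        self._cache = (cols, x.shape, ho, wo)
        b = x.shape[0]
        return y.reshape(b, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        b = x_shape[0]
        dy_mat = dy.astype(self.dtype, copy=False)
        dy_mat = dy_mat.transpose(0, 2, 3, 1).reshape(b * ho * wo, self.cout)
        self.grads["W"] += (dy_mat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] += dy_mat.sum(axis=0)
        dcols = dy_mat @ self.params["W"].reshape(self.cout, -1)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)


class BatchNorm2d:
    """Per-channel batch normalization with running inference statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.dtype = dtype
        self.params = {"gamma": np.ones(c, dtype=dtype),
                       "beta": np.zeros(c, dtype=dtype)}
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = x.astype(self.dtype, copy=False)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(self.dtype)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(self.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        dy = dy.astype(self.dtype, copy=False)
        g = self.params["gamma"][:, None, None]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        dxhat = dy * g
        if not train:
            return dxhat * inv[:, None, None]
        n = shape[0] * shape[2] * shape[3]
        # standard batch-norm backward through the batch statistics
        return (
            inv[:, None, None]
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=(0, 2, 3))[:, None, None]
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
            )
        )


class ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class ResBlock:
    """Pre-activation residual block: (BN -> ReLU -> conv) x 2 + identity."""

    def __init__(self, c: int, k: int, rng, use_residual: bool = True,
                 dtype=np.float32):
        self.use_residual = use_residual
        self.bn1, self.relu1 = BatchNorm2d(c, dtype=dtype), ReLU()
        self.conv1 = Conv2d(c, c, k, rng=rng, dtype=dtype)
        self.bn2, self.relu2 = BatchNorm2d(c, dtype=dtype), ReLU()
        self.conv2 = Conv2d(c, c, k, rng=rng, dtype=dtype)

    @property
    def sublayers(self):
        return {"bn1": self.bn1, "conv1": self.conv1, "bn2": self.bn2, "conv2": self.conv2}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.conv1.forward(self.relu1.forward(self.bn1.forward(x, train)), train)
        h = self.conv2.forward(self.relu2.forward(self.bn2.forward(h, train)), train)
        return x + h if self.use_residual else h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.bn2.backward(self.relu2.backward(self.conv2.backward(dy)))
        dx = self.bn1.backward(self.relu1.backward(self.conv1.backward(dh)))
        return dx + dy if self.use_residual else dx


class Upsample2x:
    """Non-learned nearest-neighbour x2 upsampling."""

    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = dy.shape
        return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SegModel:
    """The assembled encoder-decoder with parameter management.

    ``forward``/``backward`` operate on logits for training; ``predict``
    applies the sigmoid and runs in inference mode (running batch-norm
    statistics), so repeated calls on the same input are identical.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        f = config.filters
        k = config.kernel
        self.stem = Conv2d(config.in_channels, f[0], k, rng=rng, dtype=dtype)
        self.downs: list[Conv2d] = []
        self.enc_levels: list[list[ResBlock]] = []
        for lvl in range(config.levels):
            if lvl > 0:
                self.downs.append(
                    Conv2d(f[lvl - 1], f[lvl], k, stride=2, rng=rng, dtype=dtype)
                )
            self.enc_levels.append(
                [
                    ResBlock(f[lvl], k, rng, config.use_residual, dtype=dtype)
                    for _ in range(config.blocks_per_level[lvl])
                ]
            )
        self.up_convs: list[Conv2d] = []
        self.upsamples: list[Upsample2x] = []
        self.dec_levels: list[list[ResBlock]] = []
        for lvl in range(config.levels - 2, -1, -1):
            self.up_convs.append(Conv2d(f[lvl + 1], f[lvl], 1, rng=rng, dtype=dtype))
            self.upsamples.append(Upsample2x())
            self.dec_levels.append(
                [
                    ResBlock(f[lvl], k, rng, config.use_residual, dtype=dtype)
                    for _ in range(config.decoder_blocks)
                ]
            )
        self.head = Conv2d(f[0], config.out_channels, 1, rng=rng, dtype=dtype)
        # provenance, filled by the trainer
        self.provenance: dict = {}

    # -- layer bookkeeping ---------------------------------------------------

    def _layers(self):
        yield "stem", self.stem
        for i, d in enumerate(self.downs):
            yield f"down{i}", d
        for lvl, blocks in enumerate(self.enc_levels):
            for b, blk in enumerate(blocks):
                for name, sub in blk.sublayers.items():
                    yield f"enc{lvl}.{b}.{name}", sub
        for i, (uc, blocks) in enumerate(zip(self.up_convs, self.dec_levels)):
            yield f"up{i}.conv", uc
            for b, blk in enumerate(blocks):
                for name, sub in blk.sublayers.items():
                    yield f"dec{i}.{b}.{name}", sub
        yield "head", self.head

    def parameters(self):
        for lname, layer in self._layers():
            for pname in layer.params:
                yield f"{lname}.{pname}", layer, pname

    def num_params(self) -> int:
        return sum(layer.params[p].size for _, layer, p in self.parameters())

    def zero_grads(self) -> None:
        for _, layer, p in self.parameters():
            layer.grads[p][...] = 0.0

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (B, C, H, W) batch; caches activations for backward."""
        h = self.stem.forward(x, train)
        skips = []
        for lvl in range(self.config.levels):
            if lvl > 0:
                h = self.downs[lvl - 1].forward(h, train)
            for blk in self.enc_levels[lvl]:
                h = blk.forward(h, train)
            skips.append(h)
        for i in range(len(self.dec_levels)):
            h = self.up_convs[i].forward(h, train)
            h = self.upsamples[i].forward(h, train)
            h = h + skips[self.config.levels - 2 - i]
            for blk in self.dec_levels[i]:
                h = blk.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.head.backward(dlogits)
        dskips = [None] * self.config.levels
        for i in range(len(self.dec_levels) - 1, -1, -1):
            for blk in reversed(self.dec_levels[i]):
                dh = blk.backward(dh)
            lvl = self.config.levels - 2 - i
            dskips[lvl] = dh.copy()      # additive skip branch
            dh = self.upsamples[i].backward(dh)
            dh = self.up_convs[i].backward(dh)
        for lvl in range(self.config.levels - 1, -1, -1):
            if dskips[lvl] is not None:
                dh = dh + dskips[lvl]
            for blk in reversed(self.enc_levels[lvl]):
                dh = blk.backward(dh)
            if lvl > 0:
                dh = self.downs[lvl - 1].backward(dh)
        return self.stem.backward(dh)

    # -- inference ---------------------------------------------------------

    def predict(self, img: np.ndarray) -> np.ndarray:
        """Vessel probability map for a 2-D image or a (B, H, W)/(B, 1, H, W)
        batch; inference mode, deterministic."""
        x = np.asarray(img, dtype=self.dtype)
        squeeze_batch = x.ndim == 2
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        h, w = x.shape[2:]
        f = self.config.downsample_factor
        if h % f or w % f:
            raise ValueError(
                f"input {(h, w)} not divisible by the downsampling factor {f}; "
                f"pad to a multiple of {f} first"
            )
        probs = _sigmoid(self.forward(x, train=False))[:, 0]
        return probs[0] if squeeze_batch else probs

    # -- checkpointing -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for lname, layer in self._layers():
            for pname, arr in layer.params.items():
                state[f"{lname}.{pname}"] = arr.copy()
            if isinstance(layer, BatchNorm2d):
                state[f"{lname}.running_mean"] = layer.running_mean.copy()
                state[f"{lname}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for lname, layer in self._layers():
            for pname in layer.params:
                layer.params[pname][...] = state[f"{lname}.{pname}"].astype(
                    layer.params[pname].dtype
                )
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{lname}.running_mean"]
                layer.running_var[...] = state[f"{lname}.running_var"]

    def save(self, path: str) -> None:
        """Single-archive checkpoint: parameter arrays (npz) plus a JSON
        manifest carrying the NetworkConfig and training provenance."""
        buf = io.BytesIO()
        np.savez(buf, **self.state_dict())
        manifest = {
            "config": {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in self.config.__dict__.items()
                }
            },
            "provenance": self.provenance,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("weights.npz", buf.getvalue())
            zf.writestr("manifest.json", json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path: str) -> "SegModel":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            with zf.open("weights.npz") as fh:
                arrays = dict(np.load(io.BytesIO(fh.read())))
        cfg_d = manifest["config"]
        cfg_d["blocks_per_level"] = tuple(cfg_d["blocks_per_level"])
        model = cls(NetworkConfig(**cfg_d))
        model.load_state_dict(arrays)
        model.provenance = manifest.get("provenance", {})
        return model


def build_model(
    cfg: NetworkConfig | None = None, seed: int = 0, dtype=np.float32
) -> SegModel:
    """Deterministically initialized model (He-normal weights per seed)."""
    return SegModel(cfg or NetworkConfig(), seed=seed, dtype=dtype)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask: 1 where the probability strictly exceeds the threshold."""
    return (np.asarray(prob) > threshold).astype(np.uint8)
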