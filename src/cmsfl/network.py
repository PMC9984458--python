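"""Full network assembly: N CMSFL blocks, each followed by 2x2 max-pooling,
then a classification head.

The default configuration stacks six blocks on 64x64 inputs, so the six
pooling halvings reduce the side 64 -> 1 and the flatten head is a clean
2F -> J linear map. The head is bias-free; by default it is the
cosine-normalized head (scaled cosine similarity between the flattened
feature and per-class weight vectors), with a plain dense head available.
The block count is configurable (4/6/8/10 are the studied sizes; other
values are permitted with a warning) subject to input_side >= 2**num_modules
so pooling never collapses below one pixel.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _ops
from .block import (
    CMSFLModuleParams,
    ConvUnitParams,
    cmsfl_backward,
    cmsfl_forward,
    init_module,
)

_STUDIED_SIZES = (4, 6, 8, 10)


@dataclass(frozen=True)
class NetworkConfig:
    num_modules: int = 6
    filters: int = 32
    num_classes: int = 2
    input_channels: int = 3
    input_side: int = 64
    pool_size: int = 2
    head: str = "flatten"
    use_cosine_head: bool = True

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.pool_size != 2:
            raise ValueError("pool_size is fixed at 2")
        if self.head not in ("flatten", "global_avg"):
            raise ValueError(f"head must be 'flatten' or 'global_avg', got {self.head!r}")
        if self.input_side < 2**self.num_modules:
            raise ValueError(
                f"input_side={self.input_side} is too small for "
                f"{self.num_modules} modules: each of the {self.num_modules} "
                f"poolings halves the side, so input_side must be >= "
                f"{2**self.num_modules}"
            )
        if self.num_modules not in _STUDIED_SIZES:
            warnings.warn(
                f"num_modules={self.num_modules} is outside the studied "
                f"sizes {_STUDIED_SIZES}", stacklevel=2,
            )

    @property
    def final_side(self) -> int:
        return self.input_side // 2**self.num_modules

    @property
    def head_in_dim(self) -> int:
        if self.head == "global_avg":
            return 2 * self.filters
        return 2 * self.filters * self.final_side**2


@dataclass
class CosineHeadParams:
    """Cosine-normalized last layer: per-class weight vectors plus a learned
    positive scale applied to the cosine similarities.

    The scale is stored as a one-element array so the optimizer can update
    it in place like every other parameter; read it via ``scale_value``.
    """

    class_vectors: np.ndarray  # (J, D)
    scale: np.ndarray | float = 10.0

    def __post_init__(self):
        self.scale = np.asarray(self.scale, dtype=np.float32).reshape(1)
        if self.scale[0] <= 0:
            raise ValueError(f"cosine scale must be positive, got {self.scale[0]}")
        if np.any(np.linalg.norm(self.class_vectors, axis=1) == 0):
            raise ValueError("cosine head class vectors must be nonzero")

    @property
    def scale_value(self) -> float:
        return float(self.scale[0])


@dataclass
class NetworkParams:
    config: NetworkConfig
    modules: list[CMSFLModuleParams]
    head_weight: np.ndarray | None = None  # dense head (J, D), no bias
    cosine_head: CosineHeadParams | None = None
    stats_digest: str | None = None  # provenance of the training statistics

    def named_arrays(self, trainable_only: bool = False):
        """Flat (name, array) view of every parameter, archive order."""
        for i, mod in enumerate(self.modules, 1):
            for uname, u in mod.units():
                yield f"module{i}.{uname}.weight", u.weights
                yield f"module{i}.{uname}.bn_gain", u.bn_gain
                yield f"module{i}.{uname}.bn_bias", u.bn_bias
                if not trainable_only:
                    yield f"module{i}.{uname}.bn_mean", u.bn_running_mean
                    yield f"module{i}.{uname}.bn_var", u.bn_running_var
        if self.cosine_head is not None:
            yield "head.class_vectors", self.cosine_head.class_vectors
            yield "head.scale", self.cosine_head.scale
        else:
            yield "head.weight", self.head_weight

    def n_trainable(self) -> int:
        return sum(a.size for _, a in self.named_arrays(trainable_only=True))


def max_pool(x: np.ndarray) -> np.ndarray:
    """2x2 max pooling, stride 2: halves H and W, channels unchanged."""
    y, _ = _ops.maxpool2x2_forward(x, want_cache=False)
    return y


def build_network(cfg: NetworkConfig, seed: int = 0) -> NetworkParams:
    """Wire num_modules CMSFL blocks plus the head; deterministic given seed."""
    rng = np.random.default_rng(seed)
    modules = []
    c_in = cfg.input_channels
    for _ in range(cfg.num_modules):
        modules.append(init_module(c_in, cfg.filters, rng))
        c_in = 2 * cfg.filters
    d = cfg.head_in_dim
    head_w = rng.normal(0.0, np.sqrt(2.0 / d), size=(cfg.num_classes, d)).astype(
        np.float32
    )
    if cfg.use_cosine_head:
        return NetworkParams(cfg, modules, cosine_head=CosineHeadParams(head_w))
    return NetworkParams(cfg, modules, head_weight=head_w)


def _head_forward(params: NetworkParams, feats: np.ndarray, want_cache: bool):
    cfg = params.config
    n = feats.shape[0]
    if cfg.head == "global_avg":
        flat = feats.mean(axis=(2, 3))
    else:
        flat = feats.reshape(n, -1)
    if params.cosine_head is not None:
        scores, cache = _ops.cosine_head_forward(
            flat, params.cosine_head.class_vectors,
            params.cosine_head.scale_value, want_cache,
        )
    else:
        scores, cache = _ops.dense_forward(flat, params.head_weight, want_cache)
    return scores, (cache, feats.shape)


def forward(params: NetworkParams, batch: np.ndarray, mode: str = "eval"
            ) -> np.ndarray:
    """Class-score matrix (M, J); scores are unnormalized."""
    cfg = params.config
    x = np.asarray(batch, dtype=np.float32)
    if x.ndim != 4 or x.shape[1] != cfg.input_channels or x.shape[2:] != (
        cfg.input_side, cfg.input_side,
    ):
        raise ValueError(
            f"batch must be (M, {cfg.input_channels}, {cfg.input_side}, "
            f"{cfg.input_side}), got {x.shape}"
        )
    for mod in params.modules:
        x = cmsfl_forward(x, mod, mode)
        x = max_pool(x)
    scores, _ = _head_forward(params, x, want_cache=False)
    return scores


def forward_with_cache(params: NetworkParams, batch: np.ndarray, mode: str = "train"):
    """Forward pass retaining every layer cache for backpropagation."""
    cfg = params.config
    x = np.asarray(batch, dtype=np.float32)
    mod_caches, pool_caches = [], []
    for mod in params.modules:
        x, c = cmsfl_forward(x, mod, mode, want_cache=True)
        mod_caches.append(c)
        x, pc = _ops.maxpool2x2_forward(x)
        pool_caches.append(pc)
    scores, head_cache = _head_forward(params, x, want_cache=True)
    return scores, (mod_caches, pool_caches, head_cache)


def backward(params: NetworkParams, dscores: np.ndarray, caches):
    """Gradients for every trainable array, keyed like named_arrays."""
    cfg = params.config
    mod_caches, pool_caches, (head_cache, feat_shape) = caches
    grads: dict[str, np.ndarray] = {}
    if params.cosine_head is not None:
        dflat, dw, dscale = _ops.cosine_head_backward(dscores, head_cache)
        grads["head.class_vectors"] = dw
        grads["head.scale"] = np.asarray([dscale])
    else:
        dflat, dw = _ops.dense_backward(dscores, head_cache)
        grads["head.weight"] = dw
    n, c, h, w = feat_shape
    if cfg.head == "global_avg":
        dx = np.broadcast_to(
            dflat[:, :, None, None] / (h * w), feat_shape
        ).astype(dflat.dtype).copy()
    else:
        dx = dflat.reshape(feat_shape)
    for i in range(len(params.modules) - 1, -1, -1):
        dx = _ops.maxpool2x2_backward(dx, pool_caches[i])
        dx, mg = cmsfl_backward(dx, params.modules[i], mod_caches[i])
        for uname, (dwt, dg, db) in mg.items():
            grads[f"module{i + 1}.{uname}.weight"] = dwt
            grads[f"module{i + 1}.{uname}.bn_gain"] = dg
            grads[f"module{i + 1}.{uname}.bn_bias"] = db
    return grads, dx


def save_checkpoint(params: NetworkParams, path) -> None:
    """Named-array archive of all parameters plus the serialized config."""
    arrays = dict(params.named_arrays())
    cfg_json = json.dumps(asdict(params.config))
    arrays["_config"] = np.frombuffer(cfg_json.encode(), dtype=np.uint8)
    if params.stats_digest:
        arrays["_stats_digest"] = np.frombuffer(
            params.stats_digest.encode(), dtype=np.uint8
        )
    np.savez(path, **arrays)


def load_checkpoint(path) -> NetworkParams:
    with np.load(path, allow_pickle=False) as z:
        cfg = NetworkConfig(**json.loads(bytes(z["_config"]).decode()))
        params = build_network(cfg, seed=0)
        arrays = {k: z[k].copy() for k in z.files if not k.startswith("_")}
        _assign_arrays(params, arrays)
        if "_stats_digest" in z.files:
            params.stats_digest = bytes(z["_stats_digest"]).decode()
        else:
            params.stats_digest = None
    return params


def _assign_arrays(params: NetworkParams, arrays: dict[str, np.ndarray]) -> None:
    for i, mod in enumerate(params.modules, 1):
        for uname, u in mod.units():
            u.weights = arrays[f"module{i}.{uname}.weight"]
            u.bn_gain = arrays[f"module{i}.{uname}.bn_gain"]
            u.bn_bias = arrays[f"module{i}.{uname}.bn_bias"]
            u.bn_running_mean = arrays[f"module{i}.{uname}.bn_mean"]
            u.bn_running_var = arrays[f"module{i}.{uname}.bn_var"]
    if params.cosine_head is not None:
        params.cosine_head.class_vectors = arrays["head.class_vectors"]
        params.cosine_head.scale = arrays["head.scale"].astype(np.float32)
    else:
        params.head_weight = arrays["head.weight"]
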