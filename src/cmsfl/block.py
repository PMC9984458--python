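"""The consecutive multiscale feature-learning (CMSFL) block.

One block holds a four-unit main branch (MB) and a three-unit secondary
branch (SB); every unit is a bias-free 3x3 convolution followed by batch
normalization and ReLU. The main branch deepens stage by stage — so the
leading receptive field grows 3, 5, 7, 9 — while each secondary-branch unit
convolves the *original block input* (receptive field 3) and is concatenated
onto the main-branch output of stages 2-4. The concatenation keeps
low-receptive-field information from the unpooled input alive next to the
progressively more abstract main-branch features, at a cost of only seven
3x3 convolutions for the receptive-field set (9, 7, 5, 3).

Wiring (channel counts for module input C_in, width F):

    u1 = CBA(mb1, input)                    # C_in -> F
    u2 = [CBA(mb2, u1) | CBA(sb1, input)]   # F -> F  |  C_in -> F
    u3 = [CBA(mb3, u2) | CBA(sb2, input)]   # 2F -> F |  C_in -> F
    u4 = [CBA(mb4, u3) | CBA(sb3, input)]   # 2F -> F |  C_in -> F

The block output is u4 (2F channels, spatial size preserved); main-branch
features occupy the first F channels of each concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _ops


@dataclass
class ConvUnitParams:
    """One Conv(3x3, no bias) + BN + ReLU unit."""

    weights: np.ndarray  # (F, C_in, 3, 3)
    bn_gain: np.ndarray
    bn_bias: np.ndarray
    bn_running_mean: np.ndarray
    bn_running_var: np.ndarray

    def __post_init__(self):
        if self.weights.ndim != 4 or self.weights.shape[2:] != (3, 3):
            raise ValueError(
                f"conv weights must be (F, C, 3, 3), got {self.weights.shape}"
            )
        f = self.weights.shape[0]
        for name in ("bn_gain", "bn_bias", "bn_running_mean", "bn_running_var"):
            v = getattr(self, name)
            if v.shape != (f,):
                raise ValueError(f"{name} must have shape ({f},), got {v.shape}")
        if np.any(self.bn_running_var <= 0):
            raise ValueError("bn_running_var entries must be positive")

    @property
    def in_channels(self) -> int:
        return self.weights.shape[1]

    @property
    def out_channels(self) -> int:
        return self.weights.shape[0]


@dataclass
class CMSFLModuleParams:
    """Learnable state of one CMSFL block: 4 MB + 3 SB conv units."""

    mb_units: list[ConvUnitParams]
    sb_units: list[ConvUnitParams]
    filters: int = 32

    def __post_init__(self):
        if len(self.mb_units) != 4 or len(self.sb_units) != 3:
            raise ValueError(
                f"a CMSFL module has 4 main and 3 secondary units, got "
                f"{len(self.mb_units)}/{len(self.sb_units)}"
            )
        c_in = self.in_channels
        f = self.filters
        expect_mb = [c_in, f, 2 * f, 2 * f]
        for k, (u, e) in enumerate(zip(self.mb_units, expect_mb), 1):
            if u.in_channels != e or u.out_channels != f:
                raise ValueError(
                    f"mb{k} must map {e}->{f} channels, got "
                    f"{u.in_channels}->{u.out_channels}"
                )
        for k, u in enumerate(self.sb_units, 1):
            if u.in_channels != c_in or u.out_channels != f:
                raise ValueError(
                    f"sb{k} must map {c_in}->{f} channels, got "
                    f"{u.in_channels}->{u.out_channels}"
                )

    @property
    def in_channels(self) -> int:
        return self.mb_units[0].in_channels

    @property
    def out_channels(self) -> int:
        return 2 * self.filters

    def units(self):
        """All seven units with their archive-style names, MB first."""
        for k, u in enumerate(self.mb_units, 1):
            yield f"mb{k}", u
        for k, u in enumerate(self.sb_units, 1):
            yield f"sb{k}", u


def conv_bn_act(x: np.ndarray, p: ConvUnitParams, mode: str = "eval",
                want_cache: bool = False):
    """Conv(3x3, pad 1, stride 1, no bias) -> BN -> ReLU.

    In train mode BN uses batch statistics and updates the running buffers;
    in eval mode it uses the running buffers. Returns the activation, or
    (activation, cache) when ``want_cache`` is set.
    """
    y, c_conv = _ops.conv3x3_forward(x, p.weights, want_cache)
    y, c_bn = _ops.bn_forward(
        y, p.bn_gain, p.bn_bias, p.bn_running_mean, p.bn_running_var,
        mode, want_cache,
    )
    y, c_relu = _ops.relu_forward(y, want_cache)
    if want_cache:
        return y, (c_conv, c_bn, c_relu)
    return y


def conv_bn_act_backward(dy: np.ndarray, cache):
    """Gradients of one unit: returns (dx, dweights, dgain, dbias)."""
    c_conv, c_bn, c_relu = cache
    dy = _ops.relu_backward(dy, c_relu)
    dy, dgain, dbias = _ops.bn_backward(dy, c_bn)
    dx, dw = _ops.conv3x3_backward(dy, c_conv)
    return dx, dw, dgain, dbias


def cmsfl_forward(iv: np.ndarray, p: CMSFLModuleParams, mode: str = "eval",
                  want_cache: bool = False):
    """Forward one CMSFL block: (N, C_in, H, W) -> (N, 2F, H, W)."""
    if iv.shape[1] != p.in_channels:
        raise ValueError(
            f"module expects {p.in_channels} input channels, got {iv.shape[1]}"
        )
    f = p.filters
    caches = []

    def cba(unit, x):
        if want_cache:
            y, c = conv_bn_act(x, unit, mode, True)
            caches.append(c)
            return y
        return conv_bn_act(x, unit, mode)

    u = cba(p.mb_units[0], iv)
    for stage in range(3):
        mb_out = cba(p.mb_units[stage + 1], u)
        sb_out = cba(p.sb_units[stage], iv)
        u = np.concatenate([mb_out, sb_out], axis=1)
    if want_cache:
        return u, caches
    return u


def cmsfl_backward(dout: np.ndarray, p: CMSFLModuleParams, caches):
    """Backward one block. Returns (d_input, grads) where grads maps the
    archive-style unit names to (dweights, dgain, dbias) triples."""
    f = p.filters
    grads: dict[str, tuple] = {}
    xp = caches[0][0][0]  # mb1's conv cache holds the padded module input
    div = np.zeros(
        (xp.shape[0], xp.shape[1], xp.shape[2] - 2, xp.shape[3] - 2),
        dtype=xp.dtype,
    )
    du = dout
    # stages in reverse: caches order is mb1, (mb2, sb1), (mb3, sb2), (mb4, sb3)
    for stage in (2, 1, 0):
        d_mb, d_sb = du[:, :f], du[:, f:]
        c_mb = caches[1 + 2 * stage]
        c_sb = caches[2 + 2 * stage]
        dx_sb, dw, dg, db = conv_bn_act_backward(d_sb, c_sb)
        grads[f"sb{stage + 1}"] = (dw, dg, db)
        div += dx_sb
        du, dw, dg, db = conv_bn_act_backward(d_mb, c_mb)
        grads[f"mb{stage + 2}"] = (dw, dg, db)
    dx, dw, dg, db = conv_bn_act_backward(du, caches[0])
    grads["mb1"] = (dw, dg, db)
    div += dx
    return div, grads


def _init_unit(rng: np.random.Generator, f: int, c_in: int,
               dtype=np.float32) -> ConvUnitParams:
    std = np.sqrt(2.0 / (9.0 * c_in))
    return ConvUnitParams(
        weights=rng.normal(0.0, std, size=(f, c_in, 3, 3)).astype(dtype),
        bn_gain=np.ones(f, dtype=dtype),
        bn_bias=np.zeros(f, dtype=dtype),
        bn_running_mean=np.zeros(f, dtype=dtype),
        bn_running_var=np.ones(f, dtype=dtype),
    )


def init_module(in_channels: int, filters: int = 32,
                seed: int | np.random.Generator = 0) -> CMSFLModuleParams:
    """He-initialized Gaussian weights (sd sqrt(2/(9*fan_in)), no bias);
    BN gain 1, bias 0, running stats (0, 1). Deterministic given seed."""
    if filters < 1:
        raise ValueError(f"filters must be >= 1, got {filters}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = filters
    mb = [
        _init_unit(rng, f, in_channels),
        _init_unit(rng, f, f),
        _init_unit(rng, f, 2 * f),
        _init_unit(rng, f, 2 * f),
    ]
    sb = [_init_unit(rng, f, in_channels) for _ in range(3)]
    return CMSFLModuleParams(mb_units=mb, sb_units=sb, filters=f)
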