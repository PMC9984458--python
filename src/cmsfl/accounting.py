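"""Exact receptive-field and cost arithmetic for the consecutive design.

A stack of k 3x3 convolutions has receptive field 2k+1, so after stage k
the consecutive block exposes the receptive-field set (2k+1, 2k-1, ..., 5, 3)
across its channel groups. Reaching that set costs the consecutive design
one convolution at stage 1 and two per later stage (one main-branch, one
secondary-branch), for 2k-1 in total; a traditional multiscale stack that
rebuilds each receptive field independently needs 1 + 2 + ... + k =
k(k+1)/2. For k = 4 that is 7 versus 10 convolutions.

Per-layer trainable parameters and multiply-accumulate FLOPs of a
convolution are

    P_tr  = ks^2 * c_in * c_out (+ c_out with bias)
    FLOPs = IV_H * IV_W * c_in * ks^2 * c_out

and the network-level ledger aggregates these over every conv unit (batch
norm contributes 2 trainable parameters per channel) plus the head, which
is cross-checkable against an exhaustive element count of the serialized
parameter archive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import NetworkConfig


@dataclass(frozen=True)
class RFState:
    """Ordered receptive-field set of a stack, largest first."""

    rfs: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "rfs", tuple(int(r) for r in self.rfs))
        if not self.rfs:
            raise ValueError("receptive-field set must be non-empty")
        if any(r < 3 or r % 2 == 0 for r in self.rfs):
            raise ValueError(f"receptive fields must be odd and >= 3: {self.rfs}")
        if any(a <= b for a, b in zip(self.rfs, self.rfs[1:])):
            raise ValueError(f"receptive fields must be strictly descending: {self.rfs}")

    @property
    def max_rf(self) -> int:
        return self.rfs[0]


@dataclass
class LayerCost:
    layer_id: str
    in_channels: int
    out_channels: int
    kernel: int
    params: int
    flops: int
    iv_h: int
    iv_w: int


@dataclass
class CostReport:
    per_layer: list[LayerCost] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(r.params for r in self.per_layer)

    @property
    def total_flops(self) -> int:
        return sum(r.flops for r in self.per_layer)

    def as_rows(self) -> list[tuple]:
        return [
            (r.layer_id, r.in_channels, r.out_channels, r.kernel, r.params,
             r.flops, r.iv_h, r.iv_w)
            for r in self.per_layer
        ]


def consecutive_rf(k: int) -> RFState:
    """Receptive-field set after stage k of the consecutive block:
    (2k+1, 2k-1, ..., 5, 3)."""
    if k < 1:
        raise ValueError(f"stage count must be >= 1, got {k}")
    return RFState(tuple(2 * j + 1 for j in range(k, 0, -1)))


def consecutive_conv_count(k: int) -> int:
    """3x3 convolutions the consecutive design spends to reach stage k:
    1 at stage 1 plus 2 per later stage = 2k - 1."""
    if k < 1:
        raise ValueError(f"stage count must be >= 1, got {k}")
    return 2 * k - 1


def traditional_conv_count(k: int) -> int:
    """3x3 convolutions a traditional multiscale stack needs for the same
    receptive-field set: each target 2j+1 is rebuilt from j stacked 3x3
    convolutions, so sum_{j=1..k} j = k(k+1)/2."""
    if k < 1:
        raise ValueError(f"stage count must be >= 1, got {k}")
    return k * (k + 1) // 2


def single_kernel_equivalent(k: int) -> int:
    """Side of the single square kernel with the same receptive field as k
    stacked 3x3 convolutions: 2k + 1."""
    if k < 1:
        raise ValueError(f"stage count must be >= 1, got {k}")
    return 2 * k + 1


def stacked_weight_sum(kernels) -> int:
    """Per-filter weight count of a set of square kernels: sum of ks^2.

    E.g. the single-kernel multiscale set [3, 5, 7, 11] costs 204 weights
    per filter and [3, 5, 7, 9] costs 164, versus 7 * 3x3 = 63 for the
    consecutive design.
    """
    return sum(int(k) ** 2 for k in kernels)


def layer_cost(ks: int, c_in: int, c_out: int, iv_h: int, iv_w: int,
               use_bias: bool = False) -> tuple[int, int]:
    """(trainable params, MAC FLOPs) of one convolutional layer."""
    for name, v in (("ks", ks), ("c_in", c_in), ("c_out", c_out),
                    ("iv_h", iv_h), ("iv_w", iv_w)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    params = ks * ks * c_in * c_out + (c_out if use_bias else 0)
    flops = iv_h * iv_w * c_in * ks * ks * c_out
    return params, flops


def network_cost(cfg: NetworkConfig) -> CostReport:
    """Per-layer ledger of the assembled network.

    Each conv unit's row includes its batch-norm gain+bias (2 per output
    channel) in the params column; FLOPs count the convolution's
    multiply-accumulates at that unit's input resolution. The head row
    covers the dense or cosine class vectors (+1 for the learned cosine
    scale).
    """
    report = CostReport()
    f = cfg.filters
    side = cfg.input_side
    c_in = cfg.input_channels
    for m in range(1, cfg.num_modules + 1):
        unit_ins = [("mb1", c_in), ("mb2", f), ("mb3", 2 * f), ("mb4", 2 * f),
                    ("sb1", c_in), ("sb2", c_in), ("sb3", c_in)]
        for uname, uc in unit_ins:
            p, fl = layer_cost(3, uc, f, side, side)
            report.per_layer.append(
                LayerCost(f"module{m}.{uname}", uc, f, 3, p + 2 * f, fl, side, side)
            )
        c_in = 2 * f
        side //= 2
    d = cfg.head_in_dim
    head_params = cfg.num_classes * d + (1 if cfg.use_cosine_head else 0)
    report.per_layer.append(
        LayerCost("head", d, cfg.num_classes, 1, head_params,
                  d * cfg.num_classes, 1, 1)
    )
    return report
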