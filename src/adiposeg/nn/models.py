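"""Three families of full-field-of-view 3D segmentation networks.

All operate on multi-contrast Dixon inputs (opposed-phase, water, fat
channels by default) and output per-voxel softmax probabilities over
{background, SAT, VAT}:

* ``unet3d`` — classic 3D U-Net: two 3x3x3 convolutions + normalization +
  nonlinearity per resolution level, max-pool downsampling, transposed-
  convolution upsampling, skip concatenation.
* ``acd_unet3d`` — attention-based competitive dense variant: incoming
  feature maps compete by element-wise maximum (maxout) instead of being
  concatenated, holding channel width constant, and the bottleneck gets a
  channel-then-spatial attention block.
* ``nnunet_like`` — the resolved nnU-Net-style configuration: instance
  normalization, leaky ReLU (0.01), strided-convolution downsampling,
  transposed-convolution upsampling, widths 32 doubling per stage and
  capped at 320.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .layers import (CBAM3d, BatchNorm3d, Conv3d, ConvTranspose3d,
                     InstanceNorm3d, Module, ModuleList)

ARCHS = ("unet3d", "acd_unet3d", "nnunet_like")


@dataclass
class NetworkConfig:
    """Architecture family plus every width/depth/normalization choice."""

    arch: str = "unet3d"
    in_channels: int = 3               # opposed-phase + water + fat
    n_classes: int = 3                 # background / SAT / VAT
    encoder_filters: tuple[int, ...] = (64, 128, 256, 512)
    convs_per_block: int = 2
    kernel: int = 3
    normalization: str = "batch"       # batch | instance
    nonlinearity: str = "relu"         # relu | leaky_relu
    leaky_slope: float = 0.01
    downsample: str = "maxpool"        # maxpool | strided_conv
    attention_bottleneck: bool = False
    attention_reduction: int = 8
    # nnunet_like extras
    initial_filters: int = 32
    filter_cap: int = 320
    n_stages: int = 5
    pool_factors: tuple[tuple[int, int, int], ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}; pick one of {ARCHS}")
        w = tuple(self.encoder_filters)
        if any(b <= a for a, b in zip(w, w[1:])):
            raise ValueError("encoder_filters must strictly increase")
        if self.arch == "nnunet_like":
            for wi in self.stage_widths():
                if wi > self.filter_cap:
                    raise ValueError("stage width exceeds filter_cap")

    def stage_widths(self) -> tuple[int, ...]:
        return tuple(
            min(self.initial_filters * 2 ** s, self.filter_cap)
            for s in range(self.n_stages)
        )

    def resolved_pool_factors(self) -> tuple[tuple[int, int, int], ...]:
        if self.pool_factors is not None:
            return tuple(tuple(f) for f in self.pool_factors)
        if self.arch == "nnunet_like":
            # anisotropy-aware default for thick-slice axial stacks:
            # stop pooling the slice axis after two halvings
            n = self.n_stages - 1
            return tuple((2, 2, 2) if i < 2 else (2, 2, 1) for i in range(n))
        return tuple((2, 2, 2) for _ in self.encoder_filters[:-1])


def acd_default_config(**kw) -> NetworkConfig:
    kw.setdefault("arch", "acd_unet3d")
    kw.setdefault("attention_bottleneck", True)
    return NetworkConfig(**kw)


def _act(cfg):
    if cfg.nonlinearity == "relu":
        return ad.relu
    if cfg.nonlinearity == "leaky_relu":
        slope = cfg.leaky_slope
        return lambda x: ad.leaky_relu(x, slope)
    raise ValueError(cfg.nonlinearity)


def _norm(cfg, n_ch):
    if cfg.normalization == "batch":
        return BatchNorm3d(n_ch)
    if cfg.normalization == "instance":
        return InstanceNorm3d(n_ch)
    raise ValueError(cfg.normalization)


class ConvBlock(Module):
    """`convs_per_block` x (conv -> norm -> nonlinearity), plain stacking."""

    def __init__(self, rng, cfg, in_ch, out_ch, first_stride=1):
        super().__init__()
        self.act = _act(cfg)
        self.convs = ModuleList()
        self.norms = ModuleList()
        c = in_ch
        for i in range(cfg.convs_per_block):
            stride = first_stride if i == 0 else 1
            self.convs.append(Conv3d(rng, c, out_ch, cfg.kernel, stride=stride))
            self.norms.append(_norm(cfg, out_ch))
            c = out_ch

    def forward(self, x):
        for conv, norm in zip(self.convs, self.norms):
            x = self.act(norm(conv(x)))
        return x


class CompetitiveDenseBlock(Module):
    """Dense block where incoming feature maps compete via element-wise
    maximum before each convolution, keeping width constant."""

    def __init__(self, rng, cfg, in_ch, out_ch):
        super().__init__()
        self.act = _act(cfg)
        self.convs = ModuleList()
        self.norms = ModuleList()
        c = in_ch
        for _ in range(cfg.convs_per_block):
            self.convs.append(Conv3d(rng, c, out_ch, cfg.kernel))
            self.norms.append(_norm(cfg, out_ch))
            c = out_ch

    def forward(self, x):
        feats = []
        for conv, norm in zip(self.convs, self.norms):
            inp = x if not feats else _max_all(feats)
            feats.append(self.act(norm(conv(inp))))
        return _max_all(feats)


def _max_all(tensors):
    out = tensors[0]
    for t in tensors[1:]:
        out = ad.maximum(out, t)
    return out


class UNet3D(Module):
    """Encoder-decoder with skip concatenation (plain or competitive)."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = tuple(cfg.encoder_filters)
        competitive = cfg.arch == "acd_unet3d"
        block_cls = CompetitiveDenseBlock if competitive else ConvBlock
        self.competitive = competitive

        self.enc = ModuleList()
        c = cfg.in_channels
        for w in widths:
            self.enc.append(block_cls(rng, cfg, c, w))
            c = w
        self.bottleneck_attention = (
            CBAM3d(rng, widths[-1], cfg.attention_reduction)
            if cfg.attention_bottleneck else None
        )
        self.ups = ModuleList()
        self.dec = ModuleList()
        for deep, skip in zip(widths[::-1][:-1], widths[::-1][1:]):
            self.ups.append(ConvTranspose3d(rng, deep, skip, factor=2))
            dec_in = skip if competitive else 2 * skip
            self.dec.append(block_cls(rng, cfg, dec_in, skip))
        self.head = Conv3d(rng, widths[0], cfg.n_classes, kernel=1)

    def pool_product(self):
        n = len(self.config.encoder_filters) - 1
        return (2 ** n,) * 3

    def forward(self, x):
        self._check_divisible(x.shape[2:])
        skips = []
        for i, block in enumerate(self.enc):
            if i > 0:
                x = ad.maxpool3d(x, 2)
            x = block(x)
            skips.append(x)
        if self.bottleneck_attention is not None:
            x = self.bottleneck_attention(x)
        for up, dec, skip in zip(self.ups, self.dec, skips[-2::-1]):
            x = up(x)
            if self.competitive:
                x = ad.maximum(x, skip)
            else:
                x = ad.concat([skip, x], axis=1)
            x = dec(x)
        return ad.softmax_channels(self.head(x))

    def _check_divisible(self, spatial):
        prod = self.pool_product()
        bad = [(s, p) for s, p in zip(spatial, prod) if s % p]
        if bad:
            need = tuple(int(np.ceil(s / p) * p) for s, p in zip(spatial, prod))
            raise ValueError(
                f"input spatial shape {tuple(spatial)} not divisible by "
                f"cumulative pooling factors {prod}; pad to {need}"
            )


class NNUNetLike(Module):
    """Fixed resolved configuration in the style of full-resolution nnU-Net."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        cfg = dataclasses.replace(
            cfg, normalization="instance", nonlinearity="leaky_relu",
            downsample="strided_conv",
        )
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = cfg.stage_widths()
        factors = cfg.resolved_pool_factors()
        if len(factors) != len(widths) - 1:
            raise ValueError("need one pool factor per downsampling step")
        self.factors = factors

        self.enc = ModuleList()
        c = cfg.in_channels
        for s, w in enumerate(widths):
            stride = factors[s - 1] if s > 0 else 1
            self.enc.append(ConvBlock(rng, cfg, c, w, first_stride=stride))
            c = w
        self.ups = ModuleList()
        self.dec = ModuleList()
        for s in range(len(widths) - 1, 0, -1):
            self.ups.append(
                ConvTranspose3d(rng, widths[s], widths[s - 1], factors[s - 1])
            )
            self.dec.append(ConvBlock(rng, cfg, 2 * widths[s - 1], widths[s - 1]))
        self.head = Conv3d(rng, widths[0], cfg.n_classes, kernel=1)

    def pool_product(self):
        prod = [1, 1, 1]
        for f in self.factors:
            for i in range(3):
                prod[i] *= f[i]
        return tuple(prod)

    def forward(self, x):
        spatial = x.shape[2:]
        prod = self.pool_product()
        bad = [(s, p) for s, p in zip(spatial, prod) if s % p]
        if bad:
            need = tuple(int(np.ceil(s / p) * p) for s, p in zip(spatial, prod))
            raise ValueError(
                f"input spatial shape {tuple(spatial)} not divisible by "
                f"cumulative pooling factors {prod}; pad to {need}"
            )
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
        for up, dec, skip in zip(self.ups, self.dec, skips[-2::-1]):
            x = dec(ad.concat([skip, up(x)], axis=1))
        return ad.softmax_channels(self.head(x))


def build_network(config: NetworkConfig) -> Module:
    """Construct a model from its configuration."""
    if config.arch in ("unet3d", "acd_unet3d"):
        return UNet3D(config)
    if config.arch == "nnunet_like":
        return NNUNetLike(config)
    raise ValueError(config.arch)


def count_trainable_parameters(model: Module) -> int:
    """Exact count of learnable scalars (weights, biases, norm affine)."""
    return int(sum(p.data.size for p in model.parameters()))


def layer_table(model: Module) -> list[tuple[str, tuple[int, ...], int]]:
    """(name, shape, size) per parameter; used by the CLI describe command."""
    return [(n, p.data.shape, p.data.size) for n, p in model.named_parameters()]


def forward_probs(model: Module, x: np.ndarray) -> np.ndarray:
    """Full-FOV single forward pass with symmetric zero padding to the
    nearest pooling-compatible shape, cropped back on output.

    ``x`` is (C, X, Y, Z); returns class probabilities (n_classes, X, Y, Z).
    """
    if x.ndim != 4:
        raise ValueError("expected a (C, X, Y, Z) input")
    if x.shape[0] != model.config.in_channels:
        raise ValueError(
            f"model expects {model.config.in_channels} channels, got {x.shape[0]}"
        )
    prod = model.pool_product()
    spatial = x.shape[1:]
    pads = []
    for s, p in zip(spatial, prod):
        total = (-s) % p
        pads.append((total // 2, total - total // 2))
    xp = np.pad(x, [(0, 0)] + pads).astype(np.float32, copy=False)
    was_training = model.training
    model.eval()
    try:
        with ad.no_grad():
            probs = model(ad.Tensor(xp[None])).data[0]
    finally:
        model.train(was_training)
    sl = tuple(
        slice(lo, lo + s) for (lo, _), s in zip(pads, spatial)
    )
    return probs[(slice(None),) + sl]


def save_checkpoint(model: Module, path):
    state = model.state_dict()
    cfg = dataclasses.asdict(model.config)
    np.savez(path, __config__=json.dumps(cfg), **state)


def load_checkpoint(path) -> Module:
    with np.load(path, allow_pickle=False) as npz:
        cfg_dict = json.loads(str(npz["__config__"]))
        for key in ("encoder_filters", "pool_factors"):
            if cfg_dict.get(key) is not None:
                cfg_dict[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in cfg_dict[key]
                )
        model = build_network(NetworkConfig(**cfg_dict))
        model.load_state_dict(
            {k: npz[k] for k in npz.files if k != "__config__"}
        )
    return model
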