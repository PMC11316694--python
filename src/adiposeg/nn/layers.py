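"""Layer building blocks for the 3D segmentation networks."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module container: parameter registry, train/eval mode,
    flat state dicts for checkpointing."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield f"{prefix}{k}", p
        for mk, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{mk}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for k, v in self._buffers.items():
            yield f"{prefix}{k}", v
        for mk, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{mk}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"param.{k}": p.data.copy() for k, p in self.named_parameters()}
        out.update({f"buffer.{k}": np.array(v) for k, v in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for key, val in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                params[name].data = np.asarray(val, dtype=params[name].data.dtype)
            else:
                mod = self
                *path, leaf = name.split(".")
                for part in path:
                    mod = mod._modules[part]
                mod.register_buffer(leaf, np.asarray(val))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._items)), m)
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


def _he_init(rng: np.random.Generator, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3d(Module):
    def __init__(self, rng, in_ch, out_ch, kernel=3, stride=1, padding=None,
                 bias=True):
        super().__init__()
        k = (kernel,) * 3 if np.isscalar(kernel) else tuple(kernel)
        if padding is None:
            padding = tuple(kk // 2 for kk in k)
        self.stride, self.padding = stride, padding
        fan_in = in_ch * int(np.prod(k))
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, *k), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ad.conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    """Upsampling transposed convolution with kernel == stride."""

    def __init__(self, rng, in_ch, out_ch, factor=2, bias=True):
        super().__init__()
        f = (factor,) * 3 if np.isscalar(factor) else tuple(factor)
        self.factor = f
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, *f), in_ch))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ad.conv_transpose3d(x, self.weight, self.bias, self.factor)


class _Norm(Module):
    axes: tuple[int, ...]

    def __init__(self, n_ch, eps=1e-5, momentum=0.1, track_running=True):
        super().__init__()
        shape = (1, n_ch, 1, 1, 1)
        self.eps, self.momentum = eps, momentum
        self.track_running = track_running
        self.weight = Parameter(np.ones(shape, dtype=np.float32))
        self.bias = Parameter(np.zeros(shape, dtype=np.float32))
        if track_running:
            self.register_buffer("running_mean", np.zeros(shape, dtype=np.float32))
            self.register_buffer("running_var", np.ones(shape, dtype=np.float32))

    def forward(self, x):
        if self.training or not self.track_running:
            out = ad.normalize(x, self.weight, self.bias, self.axes, self.eps)
            if self.track_running:
                m = x.data.mean(axis=self.axes, keepdims=True)
                v = x.data.var(axis=self.axes, keepdims=True)
                if m.shape[0] != 1:  # instance stats: average over the batch
                    m = m.mean(axis=0, keepdims=True)
                    v = v.mean(axis=0, keepdims=True)
                mom = self.momentum
                self.running_mean *= 1 - mom
                self.running_mean += mom * m
                self.running_var *= 1 - mom
                self.running_var += mom * v
            return out
        return ad.normalize(x, self.weight, self.bias, self.axes, self.eps,
                            mean=self.running_mean, var=self.running_var)


class BatchNorm3d(_Norm):
    axes = (0, 2, 3, 4)


class InstanceNorm3d(_Norm):
    axes = (2, 3, 4)

    def __init__(self, n_ch, eps=1e-5, momentum=0.1):
        # instance statistics are recomputed per volume at inference too
        super().__init__(n_ch, eps, momentum, track_running=False)


class Linear(Module):
    def __init__(self, rng, in_f, out_f, bias=True):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (out_f, in_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ad.linear(x, self.weight, self.bias)


class ChannelAttention(Module):
    """Channel gate from pooled descriptors (shared two-layer bottleneck MLP
    applied to global average- and max-pooled features)."""

    def __init__(self, rng, n_ch, reduction=8):
        super().__init__()
        hidden = max(n_ch // reduction, 1)
        self.fc1 = Linear(rng, n_ch, hidden)
        self.fc2 = Linear(rng, hidden, n_ch)

    def forward(self, x):
        n, c = x.shape[:2]
        gates = None
        for kind in ("mean", "max"):
            h = self.fc2(ad.relu(self.fc1(ad.global_pool(x, kind))))
            gates = h if gates is None else ad.add(gates, h)
        s = ad.sigmoid(ad.reshape(gates, (n, c, 1, 1, 1)))
        return ad.mul(x, s)


class SpatialAttention(Module):
    """Spatial gate from a convolution over channel-pooled maps."""

    def __init__(self, rng, kernel=3):
        super().__init__()
        self.conv = Conv3d(rng, 2, 1, kernel=kernel)

    def forward(self, x):
        pooled = ad.concat(
            [ad.channel_pool(x, "mean"), ad.channel_pool(x, "max")], axis=1
        )
        return ad.mul(x, ad.sigmoid(self.conv(pooled)))


class CBAM3d(Module):
    """Channel-then-spatial convolutional attention block."""

    def __init__(self, rng, n_ch, reduction=8, spatial_kernel=3):
        super().__init__()
        self.channel = ChannelAttention(rng, n_ch, reduction)
        self.spatial = SpatialAttention(rng, spatial_kernel)

    def forward(self, x):
        return self.spatial(self.channel(x))
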