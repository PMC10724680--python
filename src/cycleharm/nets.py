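"""3D U-net generator and patchGAN discriminator for whole-volume harmonization.

Architecture family
-------------------
The generator is a U-net built exclusively from strided convolutions: an
encoder of stride-2 4x4x4 convolutions (leaky rectifier, slope 0.2) and a
decoder of stride-2 transposed convolutions with concatenated skip
connections.  There are no stride-1 refinement blocks and no resize
convolutions.  The final activation clamps negative pre-activations to zero
and is the identity above zero, so the generator can emit arbitrarily large
positive intensities (unlike a tanh head) while remaining non-negative for
*any* weights.

The discriminator is a patchGAN: a stack of stride-2 4x4x4 convolutions
followed by a single stride-1 3x3x3 output convolution producing a 3D grid of
patch realism scores.  The default stack (4/2, 4/2, 4/2, then 3/1) has a
38-voxel receptive field per axis.

Instance normalization layers use the mean absolute deviation (MAD) in place
of the standard deviation:

    y = (x - mean(x)) / (mad(x) + eps) * gain + offset,
    mad(x) = mean(|x - mean(x)|),

with statistics per channel per instance over the spatial axes.  The MAD is
not rescaled by sqrt(pi/2) to mimic an SD (switchable).

Channel schedules are configurable; the test-scale defaults (depth 2, base 8)
keep whole 48^3 volumes tractable on a single CPU.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import _ad as ad
from ._ad import Tensor
from .core import Volume

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "Generator", "Discriminator",
    "build_generator", "build_discriminator", "masked_generate",
    "receptive_field", "mad_instance_norm", "gradient_footprint",
    "save_checkpoint", "load_checkpoint",
]


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Hyperparameters of the U-net generator."""

    depth: int = 2                  # number of stride-2 down/up stages
    base_channels: int = 8          # channels after the first downsampling
    kernel: int = 4
    leaky_slope: float = 0.2        # encoder activation slope
    up_slope: float = 0.0           # decoder activation slope (plain rectifier)
    normalization: bool = True      # MAD instance norm
    final_activation: bool = True   # clamp-at-zero head
    max_channels: int = 64
    eps: float = 1e-5
    mad_rescale: bool = False

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    def channels(self) -> list[int]:
        return [min(self.base_channels * 2 ** i, self.max_channels)
                for i in range(self.depth)]


@dataclasses.dataclass(frozen=True)
class DiscriminatorSpec:
    """Layer stack of the patchGAN discriminator as (kernel, stride, channels)."""

    layers: tuple[tuple[int, int, int], ...] = ((4, 2, 8), (4, 2, 16), (4, 2, 32),
                                                (3, 1, 1))
    leaky_slope: float = 0.2
    normalization: bool = True
    eps: float = 1e-5
    mad_rescale: bool = False

    def __post_init__(self):
        if not self.layers:
            raise ValueError("discriminator needs at least one layer")
        if self.layers[-1][2] != 1:
            raise ValueError("final discriminator stage must output one channel")


class _Module:
    """Parameter bookkeeping shared by the two networks."""

    def __init__(self) -> None:
        self.params: dict[str, Tensor] = {}

    def _param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array.astype(np.float32), requires_grad=True)
        self.params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state dict")
            if state[k].shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            t.data = state[k].astype(np.float32).copy()

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _init_conv(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    # DCGAN-style init: zero-mean normal, SD 0.02
    return rng.normal(0.0, 0.02, size=shape)


class Generator(_Module):
    """U-net volume-to-volume map; forward input/output (N, 1, D, H, W)."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        k = spec.kernel
        chans = spec.channels()
        prev = 1
        for i, c in enumerate(chans):
            self._param(f"down{i}.w", _init_conv(rng, (c, prev, k, k, k)))
            self._param(f"down{i}.b", np.zeros(c))
            if spec.normalization and i > 0:
                self._param(f"down{i}.g", np.ones(c))
                self._param(f"down{i}.o", np.zeros(c))
            prev = c
        # decoder mirrors the encoder; stage j upsamples from level depth-j
        for j in range(spec.depth):
            level = spec.depth - 1 - j          # level of the produced grid
            cin = prev
            cout = 1 if level == 0 else chans[level - 1]
            self._param(f"up{j}.w", _init_conv(rng, (cin, cout, k, k, k)))
            self._param(f"up{j}.b", np.zeros(cout))
            if spec.normalization and level > 0:
                self._param(f"up{j}.g", np.ones(cout))
                self._param(f"up{j}.o", np.zeros(cout))
            # the next stage consumes the concat of this output and the skip
            prev = cout * 2 if level > 0 else cout

    def __call__(self, x) -> Tensor:
        spec = self.spec
        t = ad.as_tensor(x)
        if t.data.ndim != 5:
            raise ValueError("generator expects (N, 1, D, H, W) input")
        for s in t.data.shape[2:]:
            if s % (2 ** spec.depth) != 0:
                raise ValueError(
                    f"input dims {t.data.shape[2:]} not divisible by 2^depth={2**spec.depth}")
        skips = []
        h = t
        for i in range(spec.depth):
            h = ad.conv3d(h, self.params[f"down{i}.w"], self.params[f"down{i}.b"],
                          stride=2, pad=1)
            if spec.normalization and i > 0:
                h = ad.mad_instance_norm(h, self.params[f"down{i}.g"],
                                         self.params[f"down{i}.o"], spec.eps,
                                         spec.mad_rescale)
            h = ad.leaky_relu(h, spec.leaky_slope)
            skips.append(h)
        for j in range(spec.depth):
            level = spec.depth - 1 - j
            h = ad.conv_transpose3d(h, self.params[f"up{j}.w"], self.params[f"up{j}.b"],
                                    stride=2, pad=1)
            if level > 0:
                if spec.normalization:
                    h = ad.mad_instance_norm(h, self.params[f"up{j}.g"],
                                             self.params[f"up{j}.o"], spec.eps,
                                             spec.mad_rescale)
                h = ad.leaky_relu(h, spec.up_slope)
                h = ad.concat_channels(h, skips[level - 1])
        if spec.final_activation:
            h = ad.clamp_min(h, 0.0)
        return h

    def predict(self, vol: np.ndarray) -> np.ndarray:
        """Plain-array forward pass on a single 3D volume."""
        out = self(np.asarray(vol, dtype=np.float32)[None, None])
        return np.asarray(out.data, dtype=np.float64)[0, 0]


class Discriminator(_Module):
    """PatchGAN: volume in, 3D grid of patch realism scores out."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        prev = 1
        n = len(spec.layers)
        for i, (k, _s, c) in enumerate(spec.layers):
            self._param(f"l{i}.w", _init_conv(rng, (c, prev, k, k, k)))
            self._param(f"l{i}.b", np.zeros(c))
            if spec.normalization and 0 < i < n - 1:
                self._param(f"l{i}.g", np.ones(c))
                self._param(f"l{i}.o", np.zeros(c))
            prev = c

    def __call__(self, x) -> Tensor:
        spec = self.spec
        h = ad.as_tensor(x)
        n = len(spec.layers)
        for i, (k, s, _c) in enumerate(spec.layers):
            pad = 1 if k > 1 else 0
            h = ad.conv3d(h, self.params[f"l{i}.w"], self.params[f"l{i}.b"],
                          stride=s, pad=pad)
            if spec.normalization and 0 < i < n - 1:
                h = ad.mad_instance_norm(h, self.params[f"l{i}.g"],
                                         self.params[f"l{i}.o"], spec.eps,
                                         spec.mad_rescale)
            if i < n - 1:
                h = ad.leaky_relu(h, spec.leaky_slope)
        return h


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    return Generator(spec, seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    return Discriminator(spec, seed)


def masked_generate(gen: Generator, vol: Volume) -> Volume:
    """Apply the generator and re-apply the original brain mask.

    Every background voxel of the output is exactly zero; brain structures
    outside the mask can never be hallucinated.
    """
    if vol.mask is None or not vol.mask.any():
        raise ValueError("masked generation requires a nonempty brain mask")
    out = gen.predict(vol.data)
    out[~vol.mask] = 0.0
    return vol.copy_with(out)


def masked_forward(gen: Generator, x: Tensor, mask: np.ndarray) -> Tensor:
    """Differentiable masked generation on an (N,1,D,H,W) tensor."""
    m = Tensor(np.asarray(mask, dtype=np.float32))
    return ad.mul(gen(x), m)


def mad_instance_norm(x: np.ndarray, gain: float | np.ndarray = 1.0,
                      offset: float | np.ndarray = 0.0, eps: float = 1e-5,
                      rescale: bool = False) -> np.ndarray:
    """Array-level MAD instance normalization (see module docstring).

    Accepts (C, D, H, W) or (N, C, D, H, W); statistics per channel per
    instance over the spatial axes.
    """
    a = np.asarray(x, dtype=np.float64)
    squeeze = a.ndim == 4
    if squeeze:
        a = a[None]
    if a.ndim != 5:
        raise ValueError("expected (C,D,H,W) or (N,C,D,H,W)")
    ax = (2, 3, 4)
    mu = a.mean(axis=ax, keepdims=True)
    mad = np.abs(a - mu).mean(axis=ax, keepdims=True)
    if rescale:
        mad = mad * np.sqrt(np.pi / 2.0)
    g = np.asarray(gain, dtype=np.float64).reshape(1, -1, 1, 1, 1) \
        if np.ndim(gain) else float(gain)
    o = np.asarray(offset, dtype=np.float64).reshape(1, -1, 1, 1, 1) \
        if np.ndim(offset) else float(offset)
    y = (a - mu) / (mad + eps) * g + o
    return y[0] if squeeze else y


def receptive_field(spec: DiscriminatorSpec) -> int:
    """Receptive field (voxels per axis) of one output unit.

    Recurrence: RF_n = RF_{n-1} + (k_n - 1) * prod(strides before layer n).
    """
    rf, jump = 1, 1
    for k, s, _c in spec.layers:
        rf += (k - 1) * jump
        jump *= s
    return rf


def gradient_footprint(spec: DiscriminatorSpec, input_size: int = 64,
                       seed: int = 0) -> tuple[int, int, int]:
    """Empirical receptive field: backpropagate from one central output unit
    and measure the nonzero-gradient extent per input axis.

    Instance normalization is disabled for the probe: its per-instance
    statistics couple all spatial positions and would report the whole grid
    rather than the convolutional footprint.
    """
    probe_spec = dataclasses.replace(spec, normalization=False)
    disc = Discriminator(probe_spec, seed=seed)
    rng = np.random.default_rng(seed)
    x = Tensor(rng.normal(size=(1, 1, input_size, input_size, input_size))
               .astype(np.float32), requires_grad=True)
    y = disc(x)
    g = np.zeros(y.data.shape, dtype=np.float32)
    center = tuple(s // 2 for s in y.data.shape[2:])
    g[(0, 0) + center] = 1.0
    y.backward(g)
    nz = np.abs(x.grad[0, 0]) > 0
    extents = []
    for axis in range(3):
        proj = nz.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        extents.append(int(idx[-1] - idx[0] + 1) if idx.size else 0)
    return tuple(extents)  # type: ignore[return-value]


def score_map_shape(spec: DiscriminatorSpec, input_size: int) -> tuple[int, ...]:
    """Spatial shape of the patch-score grid via the conv output recurrence."""
    s_out = input_size
    for k, s, _c in spec.layers:
        pad = 1 if k > 1 else 0
        s_out = (s_out + 2 * pad - k) // s + 1
    return (s_out,) * 3


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, modules: dict[str, _Module],
                    meta: dict | None = None) -> None:
    """Single-file checkpoint: every module's weights plus a JSON meta record
    (spec, seed, step)."""
    arrays: dict[str, np.ndarray] = {}
    specs: dict[str, dict] = {}
    for name, mod in modules.items():
        specs[name] = {"kind": type(mod).__name__,
                       "spec": dataclasses.asdict(mod.spec)}
        for k, v in mod.state_dict().items():
            arrays[f"{name}/{k}"] = v
    header = json.dumps({"modules": specs, "meta": meta or {}})
    arrays["__meta__"] = np.frombuffer(header.encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict[str, _Module], dict]:
    with np.load(str(path)) as z:
        header = json.loads(bytes(z["__meta__"].tobytes()).decode())
        modules: dict[str, _Module] = {}
        for name, rec in header["modules"].items():
            spec_d = rec["spec"]
            if rec["kind"] == "Generator":
                spec_d = dict(spec_d)
                mod: _Module = Generator(GeneratorSpec(**spec_d))
            else:
                spec_d = dict(spec_d)
                spec_d["layers"] = tuple(tuple(l) for l in spec_d["layers"])
                mod = Discriminator(DiscriminatorSpec(**spec_d))
            prefix = f"{name}/"
            state = {k[len(prefix):]: z[k] for k in z.files if k.startswith(prefix)}
            mod.load_state_dict(state)
            modules[name] = mod
    return modules, header["meta"]
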