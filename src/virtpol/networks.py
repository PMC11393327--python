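"""Network architectures: DSM-conditioned attention U-Net generator,
residual discriminator, and the displacement-field registration module.

All three run on the package's NumPy autograd backend (``virtpol.nn``) in
NCHW layout. Widths are configurable so desk-scale instantiations (base
width 8) train on a single CPU; the published configuration corresponds to
``NetworkConfig()`` defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .errors import CheckpointError, ShapeError, ValidationError
from .nn import Tensor

__all__ = [
    "MODALITIES",
    "DSM_VALUES",
    "DigitalStainingMatrix",
    "NetworkConfig",
    "Generator",
    "Discriminator",
    "RegistrationNet",
    "build_generator",
    "build_discriminator",
    "build_registration_module",
    "make_dsm",
    "save_checkpoint",
    "load_checkpoint",
]

DSM_VALUES = {"brightfield": 1.0, "crosspol": -1.0, "angleshift": 2.0}
MODALITIES = tuple(DSM_VALUES)

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class DigitalStainingMatrix:
    """Constant-valued modality selector channel."""

    values: np.ndarray
    modality: str

    def __post_init__(self):
        if self.modality not in DSM_VALUES:
            raise ValidationError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        expected = DSM_VALUES[self.modality]
        if not np.all(self.values == expected):
            raise ValidationError(f"DSM for {self.modality!r} must be constant {expected}")


def make_dsm(height: int, width: int, modality: str) -> DigitalStainingMatrix:
    """Constant H x W selector: 1 brightfield, -1 cross-polarized, 2 angle-shifted."""
    if modality not in DSM_VALUES:
        raise ValidationError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    values = np.full((height, width), DSM_VALUES[modality], dtype=np.float32)
    return DigitalStainingMatrix(values=values, modality=modality)


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 4
    base_width: int = 64
    generator_levels: int = 4
    discriminator_blocks: int = 5
    registration_levels: int = 7
    leaky_slope: float = 0.1
    condition_discriminator: bool = True
    instance_norm: bool = False
    # widest layer allowed; keeps the 7-level registration net desk-sized
    max_width: int = 512

    def __post_init__(self):
        if self.base_width < 4:
            raise ValidationError("base_width must be >= 4")
        if self.in_channels < 1:
            raise ValidationError("in_channels must be >= 1")

    @classmethod
    def tiny(cls, **overrides):
        """A CPU-friendly instantiation used throughout the test suite."""
        kwargs = dict(base_width=8, max_width=128)
        kwargs.update(overrides)
        return cls(**kwargs)

    def width(self, level: int) -> int:
        return min(self.base_width * (2**level), self.max_width)


def _dsm_channel(dsm, batch, height, width):
    """Broadcast a DSM (object, scalar or HxW array) to (N, 1, H, W)."""
    if isinstance(dsm, DigitalStainingMatrix):
        values = dsm.values
    else:
        values = np.asarray(dsm, dtype=np.float32)
    if values.ndim == 0:
        values = np.full((height, width), float(values), dtype=np.float32)
    if values.ndim == 2:
        values = np.broadcast_to(values, (batch, 1, height, width))
    elif values.ndim == 3:
        values = values[:, None]
    return np.ascontiguousarray(values, dtype=np.float32)


class Generator(nn.Module):
    """Attention U-Net mapping (in_channels+1, H, W) -> (3, H, W).

    Encoder: per level a three-conv residual block then 2x2 stride-2
    max-pool, doubling channels each level. Decoder: bilinear 2x upsample of
    the previous features, attention-gated skip concatenation, then a
    residual block cutting channels 4x. Head: residual block plus a single
    conv down to 3 channels, linear output.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        levels = config.generator_levels
        slope = config.leaky_slope
        enc_in = config.in_channels + 1
        self.down = []
        widths = []
        for lv in range(levels):
            w = config.width(lv)
            self.down.append(nn.ResBlock3(enc_in, w, rng, slope))
            widths.append(w)
            enc_in = w
        self.gates = [nn.AttentionGate(widths[lv], widths[lv], rng) for lv in reversed(range(levels))]
        self.up = []
        prev = widths[-1]
        for lv in reversed(range(levels)):
            merged = prev + widths[lv]
            out = max(merged // 4, 4)
            self.up.append(nn.ResBlock3(merged, out, rng, slope))
            prev = out
        self.head_res = nn.ResBlock3(prev, prev, rng, slope)
        self.head = nn.Conv2d(prev, 3, 3, rng=rng)
        # damp initial output magnitude so training starts near mid-gray
        self.head.weight.data *= 0.1

    def forward(self, stack, dsm):
        x = nn.as_tensor(stack)
        if x.data.ndim != 4:
            raise ShapeError("generator expects NCHW input")
        n, c, h, w = x.data.shape
        div = 2**self.config.generator_levels
        if h % div or w % div:
            raise ShapeError(f"spatial size {h}x{w} must be divisible by {div}")
        if c != self.config.in_channels:
            raise ShapeError(f"expected {self.config.in_channels} input channels, got {c}")
        x = nn.concat([x, Tensor(_dsm_channel(dsm, n, h, w))], axis=1)
        skips = []
        for block in self.down:
            feat = block(x)
            if self.config.instance_norm:
                feat = nn.instance_norm(feat)
            skips.append(feat)
            x = nn.maxpool2x(feat)
        for gate, block in zip(self.gates, self.up):
            x = nn.upsample2x_bilinear(x)
            skip = gate(skips.pop(), x)
            x = block(nn.concat([x, skip], axis=1))
        return self.head(self.head_res(x))


class Discriminator(nn.Module):
    """Residual critic: one conv to base width, five stride-2 two-conv
    residual blocks doubling channels, global average pooling, two dense
    layers, sigmoid probability."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        slope = config.leaky_slope
        in_ch = 3 + (1 if config.condition_discriminator else 0)
        self.stem = nn.Conv2d(in_ch, config.base_width, 3, rng=rng)
        self.blocks = []
        w = config.base_width
        for lv in range(config.discriminator_blocks):
            nw = min(w * 2, config.max_width)
            self.blocks.append(nn.ResBlock2Down(w, nw, rng, slope))
            w = nw
        self.fc1 = nn.Linear(w, max(w // 2, 4), rng)
        self.fc2 = nn.Linear(max(w // 2, 4), 1, rng)
        self.slope = slope

    def forward(self, image, dsm=None):
        x = nn.as_tensor(image)
        n, c, h, w = x.data.shape
        if self.config.condition_discriminator:
            if dsm is None:
                raise ValidationError("discriminator is conditioned: a DSM is required")
            x = nn.concat([x, Tensor(_dsm_channel(dsm, n, h, w))], axis=1)
        x = nn.leaky_relu(self.stem(x), self.slope)
        for block in self.blocks:
            x = block(x)
        x = nn.global_avg_pool(x)
        x = nn.leaky_relu(self.fc1(x), self.slope)
        return nn.sigmoid(self.fc2(x))


class RegistrationNet(nn.Module):
    """U-Net regressing a per-pixel displacement field.

    Input is the 6-channel concatenation (moving, fixed); output has two
    channels (dx, dy) in pixels. Seven down/up pairs by default, a widened
    three-residual-block bottleneck, and a zero-initialised final conv so
    training starts from the identity warp.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        levels = config.registration_levels
        slope = config.leaky_slope
        enc_in = 6
        self.down = []
        widths = []
        for lv in range(levels):
            w = config.width(lv)
            self.down.append(nn.ResBlock3(enc_in, w, rng, slope))
            widths.append(w)
            enc_in = w
        wide = min(widths[-1] * 2, config.max_width * 2)
        self.bott_in = nn.Conv2d(widths[-1], wide, 3, rng=rng)
        self.bottleneck = [nn.ResBlock3(wide, wide, rng, slope) for _ in range(3)]
        self.bott_out = nn.Conv2d(wide, widths[-1], 3, rng=rng)
        self.up = []
        prev = widths[-1]
        for lv in reversed(range(levels)):
            merged = prev + widths[lv]
            out = max(merged // 4, 4)
            self.up.append(nn.ResBlock3(merged, out, rng, slope))
            prev = out
        self.head = nn.Conv2d(prev, 2, 3, rng=rng, zero_init=True)
        self.slope = slope

    def forward(self, moving, fixed):
        m, f = nn.as_tensor(moving), nn.as_tensor(fixed)
        if m.data.shape != f.data.shape:
            raise ShapeError("moving/fixed shape mismatch")
        n, c, h, w = m.data.shape
        div = 2**self.config.registration_levels
        if h % div or w % div:
            raise ShapeError(f"spatial size {h}x{w} must be divisible by {div}")
        x = nn.concat([m, f], axis=1)
        skips = []
        for block in self.down:
            feat = block(x)
            skips.append(feat)
            x = nn.maxpool2x(feat)
        x = nn.leaky_relu(self.bott_in(x), self.slope)
        for block in self.bottleneck:
            x = block(x)
        x = nn.leaky_relu(self.bott_out(x), self.slope)
        for block in self.up:
            x = nn.upsample2x_bilinear(x)
            x = block(nn.concat([x, skips.pop()], axis=1))
        return self.head(x)


def build_generator(config: NetworkConfig, seed: int = 0) -> Generator:
    return Generator(config, np.random.default_rng(np.random.SeedSequence([seed, 101])))


def build_discriminator(config: NetworkConfig, seed: int = 0) -> Discriminator:
    return Discriminator(config, np.random.default_rng(np.random.SeedSequence([seed, 202])))


def build_registration_module(config: NetworkConfig, seed: int = 0) -> RegistrationNet:
    return RegistrationNet(config, np.random.default_rng(np.random.SeedSequence([seed, 303])))


# checkpoint container -----------------------------------------------------

def save_checkpoint(path, config: NetworkConfig, nets: dict, step: int = 0, norm_stats=None):
    """Write a versioned checkpoint directory: config.json + weights.npz.

    ``nets`` maps role names ("generator", ...) to modules; ``norm_stats``
    optionally freezes per-channel input normalisation into the checkpoint.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": CHECKPOINT_VERSION,
        "step": int(step),
        "config": asdict(config),
        "roles": sorted(nets),
        "norm_stats": None if norm_stats is None else [list(map(float, s)) for s in norm_stats],
    }
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    arrays = {}
    for role, net in nets.items():
        for i, arr in enumerate(net.state_arrays()):
            arrays[f"{role}/{i}"] = arr
    np.savez(path / "weights.npz", **arrays)


def load_checkpoint(path, seed: int = 0):
    """Load a checkpoint directory -> (config, nets dict, step, norm_stats)."""
    path = Path(path)
    cfg_file = path / "config.json"
    if not cfg_file.exists():
        raise CheckpointError(f"no checkpoint at {path}")
    meta = json.loads(cfg_file.read_text())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(f"unsupported checkpoint version {meta.get('version')}")
    config = NetworkConfig(**meta["config"])
    builders = {
        "generator": build_generator,
        "discriminator": build_discriminator,
        "registration": build_registration_module,
    }
    with np.load(path / "weights.npz") as data:
        nets = {}
        for role in meta["roles"]:
            if role not in builders:
                raise CheckpointError(f"unknown checkpoint role {role!r}")
            net = builders[role](config, seed=seed)
            arrays = []
            i = 0
            while f"{role}/{i}" in data:
                arrays.append(data[f"{role}/{i}"])
                i += 1
            net.load_state_arrays(arrays)
            nets[role] = net
    norm_stats = meta.get("norm_stats")
    if norm_stats is not None:
        norm_stats = [np.asarray(s, dtype=np.float32) for s in norm_stats]
    return config, nets, meta["step"], norm_stats
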