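"""Seeded synthetic phantoms: paired autofluorescence stacks and stained
ground-truth images with known amyloid/nuclei masks.

The forward model mirrors the statistical structure of the real data:
congophilic (amyloid) regions carry a correlated multi-channel
autofluorescence elevation and render pink-salmon in brightfield and
apple-green on a near-black background under crossed polarizers; nuclei are
dark red-purple disks visible in the first (DAPI-like) channel. The
angle-shifted target is derived from the cross-polarized one with the same
hue-scaling emulator used for real data.

Everything is bit-deterministic for a fixed spec + seed: sub-process seeds
(amyloid field, nuclei placement, texture, noise) are split from the master
seed with a counter scheme, so changing one knob does not reshuffle the
others.

Data conventions: stacks are (C, H, W) float32 in [0, 1]; stained images and
masks are (H, W, 3) / (H, W).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .evaluation import simulate_angle_shift

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "apply_synthetic_deformation",
    "add_gaussian_noise",
    "random_smooth_field",
]

# per-channel amyloid autofluorescence gains (DAPI, FITC, TxRed, Cy5);
# free parameters of the phantom — the real signature is not published
AMYLOID_GAINS = (0.15, 0.55, 0.65, 0.45)
NUCLEUS_DAPI_GAIN = 0.55

BF_BACKGROUND = np.array([0.93, 0.90, 0.92])
BF_AMYLOID = np.array([0.89, 0.52, 0.56])  # pink-salmon
BF_NUCLEUS = np.array([0.42, 0.20, 0.45])  # dark red-purple
CP_AMYLOID = np.array([0.18, 0.85, 0.22])  # apple-green, hue ~124 deg


@dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 256
    n_amyloid_blobs: int = 5
    amyloid_area_fraction: float = 0.12
    n_nuclei: int = 25
    nucleus_radius_px: int = 5
    background_texture_scale: int = 8
    noise_sigma: float = 0.01
    deformation_amplitude_px: float = 0.0
    n_channels: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValidationError("image_size must be >= 64")
        for name in ("n_amyloid_blobs", "n_nuclei", "nucleus_radius_px", "background_texture_scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("amyloid_area_fraction", "noise_sigma"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.deformation_amplitude_px < 0:
            raise ValidationError("deformation_amplitude_px must be >= 0")
        if not 1 <= self.n_channels <= 4:
            raise ValidationError("n_channels must be in [1, 4]")


@dataclass
class PhantomSample:
    stack: np.ndarray
    brightfield_gt: np.ndarray
    crosspol_gt: np.ndarray
    angleshift_gt: np.ndarray
    amyloid_mask: np.ndarray
    nuclei_mask: np.ndarray
    nuclei_count: int
    spec: PhantomSpec = None

    def validate(self):
        h, w = self.stack.shape[1:]
        for img in (self.brightfield_gt, self.crosspol_gt, self.angleshift_gt):
            if img.shape[:2] != (h, w):
                raise ValidationError("phantom images disagree on height/width")
        for m in (self.amyloid_mask, self.nuclei_mask):
            if m.shape != (h, w):
                raise ValidationError("mask shape mismatch")


def _sub_rngs(seed, n=4):
    """Counter-split sub-generators: stable per role."""
    return [np.random.default_rng(np.random.SeedSequence([int(seed), i])) for i in range(n)]


def _smooth_noise(rng, size, scale):
    field = rng.standard_normal((size, size))
    field = ndimage.gaussian_filter(field, sigma=max(scale, 1))
    std = field.std()
    return field / std if std > 0 else field


def _amyloid_field(rng, spec):
    """Irregular deposits: smooth noise modulated by random blob envelopes,
    thresholded at the quantile matching the requested area fraction."""
    size = spec.image_size
    if spec.n_amyloid_blobs == 0 or spec.amyloid_area_fraction == 0:
        return np.zeros((size, size), bool), np.zeros((size, size))
    envelope = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    blob_sigma = size * 0.45 / np.sqrt(spec.n_amyloid_blobs)
    for _ in range(spec.n_amyloid_blobs):
        cy, cx = rng.uniform(0.1 * size, 0.9 * size, 2)
        sy = blob_sigma * rng.uniform(0.6, 1.4)
        sx = blob_sigma * rng.uniform(0.6, 1.4)
        envelope += np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
    texture = _smooth_noise(rng, size, size / 32)
    field = envelope * (1.0 + 0.35 * texture)
    thr = np.quantile(field, 1.0 - spec.amyloid_area_fraction)
    mask = field > thr
    # per-pixel deposit intensity in [~0.45, 1] inside the mask
    inside = field[mask]
    lo, hi = inside.min(), inside.max()
    intensity = np.zeros((size, size))
    if hi > lo:
        intensity[mask] = 0.45 + 0.55 * (field[mask] - lo) / (hi - lo)
    else:
        intensity[mask] = 1.0
    intensity = ndimage.gaussian_filter(intensity, 1.0) * mask
    np.clip(intensity, 0.0, 1.0, out=intensity)
    return mask, intensity


def _place_nuclei(rng, spec):
    """Poisson-disk (dart-throwing) placement of non-overlapping disks."""
    size, r = spec.image_size, spec.nucleus_radius_px
    centers = []
    min_dist = 2.0 * r + 4.0
    attempts = 0
    max_attempts = 200 * max(spec.n_nuclei, 1)
    while len(centers) < spec.n_nuclei and attempts < max_attempts:
        attempts += 1
        cy = rng.uniform(r + 2, size - r - 2)
        cx = rng.uniform(r + 2, size - r - 2)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_dist**2 for y, x in centers):
            centers.append((cy, cx))
    mask = np.zeros((size, size), bool)
    yy, xx = np.mgrid[0:size, 0:size]
    for cy, cx in centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask, len(centers)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one paired sample from the phantom forward model."""
    rng_amyloid, rng_nuclei, rng_texture, rng_noise = _sub_rngs(spec.seed)
    size = spec.image_size

    amyloid_mask, amyloid_int = _amyloid_field(rng_amyloid, spec)
    nuclei_mask, n_placed = _place_nuclei(rng_nuclei, spec)

    # autofluorescence stack
    channels = []
    for c in range(spec.n_channels):
        base = 0.10 + 0.04 * c / max(spec.n_channels - 1, 1)
        tex = _smooth_noise(rng_texture, size, spec.background_texture_scale)
        ch = base + 0.05 * tex + AMYLOID_GAINS[c] * amyloid_int
        if c == 0:
            ch = ch + NUCLEUS_DAPI_GAIN * nuclei_mask
        channels.append(ch)
    stack = np.clip(np.stack(channels), 0.0, 1.0).astype(np.float32)
    if spec.noise_sigma > 0:
        stack = add_gaussian_noise(stack, spec.noise_sigma, seed=int(rng_noise.integers(2**31)))

    # brightfield: pale background, pink-salmon amyloid, dark nuclei on top
    a = amyloid_int[..., None]
    bf = BF_BACKGROUND[None, None, :] * (1.0 - a) + BF_AMYLOID[None, None, :] * a
    nmask = nuclei_mask[..., None]
    bf = bf * (1.0 - nmask) + BF_NUCLEUS[None, None, :] * nmask
    bf_tex = 0.015 * _smooth_noise(rng_texture, size, spec.background_texture_scale)
    brightfield = np.clip(bf + bf_tex[..., None], 0.0, 1.0).astype(np.float32)

    # cross-polarized: near-black background, apple-green deposits
    cp = 0.01 + np.zeros((size, size, 3))
    cp = cp + CP_AMYLOID[None, None, :] * a
    crosspol = np.clip(cp, 0.0, 1.0).astype(np.float32)

    angleshift = simulate_angle_shift(crosspol).astype(np.float32)

    sample = PhantomSample(
        stack=stack,
        brightfield_gt=brightfield,
        crosspol_gt=crosspol,
        angleshift_gt=angleshift,
        amyloid_mask=amyloid_mask.astype(np.uint8),
        nuclei_mask=nuclei_mask.astype(np.uint8),
        nuclei_count=n_placed,
        spec=spec,
    )
    sample.validate()
    if spec.deformation_amplitude_px > 0:
        sample, _ = apply_synthetic_deformation(sample, spec.deformation_amplitude_px, seed=spec.seed + 9999)
    return sample


def random_smooth_field(size, amplitude_px, seed, smooth_sigma=None):
    """Smooth random displacement field (2, H, W) with max magnitude equal to
    ``amplitude_px`` (zero field for amplitude 0)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 555]))
    if amplitude_px == 0:
        return np.zeros((2, size, size), dtype=np.float32)
    if smooth_sigma is None:
        smooth_sigma = size / 8
    comps = []
    for _ in range(2):
        f = ndimage.gaussian_filter(rng.standard_normal((size, size)), smooth_sigma)
        comps.append(f)
    field = np.stack(comps)
    mag = np.sqrt((field**2).sum(axis=0)).max()
    if mag > 0:
        field *= amplitude_px / mag
    return field.astype(np.float32)


def apply_synthetic_deformation(sample: PhantomSample, amplitude_px: float, seed: int):
    """Warp the stained ground-truth images (not the stack) by a smooth random
    field, emulating staining-induced morphology changes.

    Returns (deformed sample, true field) so recovery can be scored.
    """
    if amplitude_px < 0:
        raise ValidationError("amplitude_px must be >= 0")
    from .dataprep import DisplacementField, warp  # local import avoids cycle

    size = sample.stack.shape[1]
    field_arr = random_smooth_field(size, amplitude_px, seed)
    field = DisplacementField(dx=field_arr[0], dy=field_arr[1])
    if amplitude_px == 0:
        return replace_images(sample, sample.brightfield_gt, sample.crosspol_gt, sample.angleshift_gt), field
    deformed = replace_images(
        sample,
        warp(sample.brightfield_gt, field),
        warp(sample.crosspol_gt, field),
        warp(sample.angleshift_gt, field),
    )
    return deformed, field


def replace_images(sample: PhantomSample, brightfield, crosspol, angleshift) -> PhantomSample:
    return PhantomSample(
        stack=sample.stack,
        brightfield_gt=np.asarray(brightfield, dtype=np.float32),
        crosspol_gt=np.asarray(crosspol, dtype=np.float32),
        angleshift_gt=np.asarray(angleshift, dtype=np.float32),
        amyloid_mask=sample.amyloid_mask,
        nuclei_mask=sample.nuclei_mask,
        nuclei_count=sample.nuclei_count,
        spec=sample.spec,
    )


def add_gaussian_noise(stack: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Per-channel i.i.d. N(0, sigma^2) noise, clipped to [0, 1]."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    stack = np.asarray(stack, dtype=np.float32)
    if sigma == 0:
        return stack.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 777]))
    noisy = stack + rng.normal(0.0, sigma, stack.shape).astype(np.float32)
    return np.clip(noisy, 0.0, 1.0)
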