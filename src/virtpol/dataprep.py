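"""Two-step registration used to build pixel-aligned training pairs.

1. Global projective registration of whole images from matched local
   features with robust consensus, estimated on downsampled copies and
   rescaled to full resolution.
2. Tiling into fixed-size pairs, then correlation-based pyramid elastic
   registration per tile: per-block cross-correlation peaks at each pyramid
   level give sparse displacements that are interpolated to a dense smooth
   field; an optional style-transfer loop retrains a staining network (no
   registration submodule) to sharpen the correlation target and repeats.

Coordinate conventions (used everywhere in this package):

* arrays are 0-based (row, col), origin top-left;
* a :class:`DisplacementField` stores per-pixel offsets ``dx`` (columns) and
  ``dy`` (rows) in pixels, and maps moving -> fixed:
  ``warp(moving, field)(r, c) = moving(r + dy, c + dx)``;
* out-of-bounds samples replicate the border.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.registration import phase_cross_correlation
from skimage.transform import ProjectiveTransform as _SkProjective
from skimage.transform import rescale, warp as sk_warp

from .errors import RegistrationFailureError, ShapeError, ValidationError

__all__ = [
    "ProjectiveTransform",
    "DisplacementField",
    "TilePair",
    "PrepConfig",
    "global_register",
    "apply_projective",
    "tile_pairs",
    "elastic_register",
    "warp",
    "prepare_registered_dataset",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProjectiveTransform:
    """3x3 homography mapping moving -> fixed pixel coordinates.

    The matrix acts on homogeneous ``[col, row, 1]`` vectors (x = col,
    y = row, 0-based); the bottom-right element is normalised to 1.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValidationError("homography must be 3x3")
        if abs(m[2, 2]) < 1e-12 or not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e12:
            raise ValidationError("homography must be invertible")
        object.__setattr__(self, "matrix", m / m[2, 2])

    def apply(self, points_xy) -> np.ndarray:
        """Map (N, 2) array of (col, row) points."""
        pts = np.asarray(points_xy, dtype=np.float64)
        hom = np.concatenate([pts, np.ones((len(pts), 1))], axis=1)
        out = hom @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    @classmethod
    def identity(cls):
        return cls(np.eye(3))


@dataclass(frozen=True)
class DisplacementField:
    """Per-pixel displacement components in pixels (dx = col, dy = row)."""

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self):
        dx = np.asarray(self.dx, dtype=np.float32)
        dy = np.asarray(self.dy, dtype=np.float32)
        if dx.shape != dy.shape or dx.ndim != 2:
            raise ValidationError("dx/dy must be matching 2-D arrays")
        if not (np.isfinite(dx).all() and np.isfinite(dy).all()):
            raise ValidationError("displacement field must be finite")
        object.__setattr__(self, "dx", dx)
        object.__setattr__(self, "dy", dy)

    @property
    def shape(self):
        return self.dx.shape

    @property
    def height(self):
        return self.dx.shape[0]

    @property
    def width(self):
        return self.dx.shape[1]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.dx.astype(np.float64) ** 2 + self.dy.astype(np.float64) ** 2)

    def as_array(self) -> np.ndarray:
        """(2, H, W) with (dx, dy) ordering."""
        return np.stack([self.dx, self.dy])

    def __neg__(self):
        return DisplacementField(dx=-self.dx, dy=-self.dy)

    @classmethod
    def zero(cls, height, width):
        return cls(dx=np.zeros((height, width), np.float32), dy=np.zeros((height, width), np.float32))


@dataclass
class TilePair:
    stack: np.ndarray  # (C, h, w)
    target: np.ndarray  # (h, w, 3)
    modality: str
    tile_origin: tuple  # (row, col) in WSI coordinates

    def __post_init__(self):
        if self.stack.shape[1:] != self.target.shape[:2]:
            raise ValidationError("stack and target must share height/width")


def _to_gray(image) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 3:  # RGB, luminance
        return img @ np.array([0.299, 0.587, 0.114])
    if img.ndim == 3:  # channel-first stack: average channels
        return img.mean(axis=0)
    raise ShapeError(f"cannot interpret image of shape {img.shape}")


def global_register(moving, fixed, downsample_factor: int = 4, min_inliers: int = 10, n_keypoints: int = 800) -> ProjectiveTransform:
    """Estimate a projective transform from matched local features.

    Scale/rotation-invariant keypoints (ORB, a patent-free SURF equivalent)
    are detected on ``downsample_factor``-downsampled copies, matched, and a
    homography is fitted with RANSAC-style robust consensus (MSAC analogue);
    the result is rescaled to full resolution.
    """
    mv = _to_gray(moving)
    fx = _to_gray(fixed)
    if downsample_factor > 1:
        mv = rescale(mv, 1.0 / downsample_factor, anti_aliasing=True)
        fx = rescale(fx, 1.0 / downsample_factor, anti_aliasing=True)
    if min(mv.shape + fx.shape) < 128:
        raise ValidationError("images must be >= 128 px per side after downsampling")

    def detect(img):
        orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
        orb.detect_and_extract(img)
        return orb.keypoints, orb.descriptors

    try:
        kp_m, desc_m = detect(mv)
        kp_f, desc_f = detect(fx)
    except RuntimeError as exc:  # ORB raises when no keypoints survive
        raise RegistrationFailureError(f"feature detection failed: {exc}") from exc
    matches = match_descriptors(desc_m, desc_f, cross_check=True)
    if len(matches) < 4:
        raise RegistrationFailureError(f"only {len(matches)} feature matches; need >= 4")
    src = kp_m[matches[:, 0]][:, ::-1]  # (row, col) -> (x=col, y=row)
    dst = kp_f[matches[:, 1]][:, ::-1]
    model, inliers = ransac(
        (src, dst),
        _SkProjective,
        min_samples=4,
        residual_threshold=2.0,
        max_trials=2000,
        rng=0,
    )
    n_inliers = 0 if inliers is None else int(inliers.sum())
    if model is None or n_inliers < max(4, min_inliers):
        raise RegistrationFailureError(f"registration consensus failed: {n_inliers} inlier matches")
    scale = float(downsample_factor)
    s = np.diag([scale, scale, 1.0])
    matrix = s @ model.params @ np.linalg.inv(s)
    return ProjectiveTransform(matrix)


def apply_projective(image, transform: ProjectiveTransform, output_shape=None) -> np.ndarray:
    """Resample ``image`` so that it lands in the fixed frame."""
    tf = _SkProjective(matrix=transform.matrix)
    out = sk_warp(np.asarray(image, dtype=np.float64), tf.inverse, output_shape=output_shape, mode="edge", preserve_range=True)
    return out.astype(np.float32)


def tile_pairs(moving_wsi, fixed_wsi, tile_size: int = 2048, modality: str = "brightfield"):
    """Cut globally registered WSIs into a non-overlapping grid of pairs.

    ``fixed_wsi`` is the (C, H, W) autofluorescence stack; ``moving_wsi`` the
    already-warped stained image (H, W, 3). Edge remainders are dropped.
    """
    fixed_wsi = np.asarray(fixed_wsi)
    moving_wsi = np.asarray(moving_wsi)
    h, w = fixed_wsi.shape[1], fixed_wsi.shape[2]
    if moving_wsi.shape[:2] != (h, w):
        raise ShapeError("WSIs must share spatial shape after global registration")
    if tile_size > h or tile_size > w:
        raise ValidationError(f"tile_size {tile_size} exceeds WSI dimension {min(h, w)}")
    tiles = []
    for r in range(0, h - tile_size + 1, tile_size):
        for c in range(0, w - tile_size + 1, tile_size):
            tiles.append(
                TilePair(
                    stack=np.ascontiguousarray(fixed_wsi[:, r : r + tile_size, c : c + tile_size]),
                    target=np.ascontiguousarray(moving_wsi[r : r + tile_size, c : c + tile_size]),
                    modality=modality,
                    tile_origin=(r, c),
                )
            )
    return tiles


def warp(image, field: DisplacementField) -> np.ndarray:
    """Bilinear resampling at displaced coordinates with border replication.

    ``warp(I, f)(r, c) = I(r + dy(r, c), c + dx(r, c))``; all channels are
    warped identically.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = field.shape
    if img.shape[:2] != (h, w) and (img.ndim < 3 or img.shape[-2:] != (h, w)):
        raise ShapeError(f"image spatial shape does not match field {field.shape}")
    rows = np.arange(h)[:, None] + field.dy
    cols = np.arange(w)[None, :] + field.dx
    coords = np.stack([rows, cols])

    def warp_plane(plane):
        return ndimage.map_coordinates(plane, coords, order=1, mode="nearest")

    if img.ndim == 2:
        return warp_plane(img).astype(np.float32)
    if img.shape[:2] == (h, w):  # (H, W, C)
        return np.stack([warp_plane(img[..., c]) for c in range(img.shape[2])], axis=-1).astype(np.float32)
    # (C, H, W)
    return np.stack([warp_plane(img[c]) for c in range(img.shape[0])]).astype(np.float32)


def invert_field(field: DisplacementField, iters: int = 20) -> DisplacementField:
    """Numerically invert a displacement field by fixed-point iteration:
    inv(x) = -f(x + inv(x)). For a deformation applied as ``warp(I, f)``,
    ``warp(warp(I, f), invert_field(f)) ~ I``."""
    inv_dx = -field.dx.astype(np.float64)
    inv_dy = -field.dy.astype(np.float64)
    h, w = field.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(iters):
        coords = np.stack([rr + inv_dy, cc + inv_dx])
        fx = ndimage.map_coordinates(field.dx.astype(np.float64), coords, order=1, mode="nearest")
        fy = ndimage.map_coordinates(field.dy.astype(np.float64), coords, order=1, mode="nearest")
        inv_dx, inv_dy = -fx, -fy
    return DisplacementField(dx=inv_dx.astype(np.float32), dy=inv_dy.astype(np.float32))


def _block_grid(shape, block, step):
    rows = list(range(0, shape[0] - block + 1, step)) or [0]
    cols = list(range(0, shape[1] - block + 1, step)) or [0]
    return rows, cols


def _interp_to_dense(values, centers_r, centers_c, shape):
    """Interpolate sparse block values (grid) to a dense per-pixel array."""
    vr = np.asarray(centers_r, dtype=np.float64)
    vc = np.asarray(centers_c, dtype=np.float64)
    vals = np.asarray(values, dtype=np.float64)
    if vals.shape[0] >= 2 and vals.shape[1] >= 2:
        kx = min(3, vals.shape[0] - 1)
        ky = min(3, vals.shape[1] - 1)
        spline = RectBivariateSpline(vr, vc, vals, kx=kx, ky=ky)
        dense = spline(np.arange(shape[0]), np.arange(shape[1]))
    else:
        dense = np.full(shape, vals.mean())
    return dense


def elastic_register(
    moving,
    fixed,
    levels: int = 4,
    block_size: int = 64,
    overlap: float = 0.5,
    upsample_factor: int = 10,
    max_disp: Optional[float] = None,
    guard: bool = True,
    feature: str = "intensity",
) -> DisplacementField:
    """Coarse-to-fine block-correlation elastic registration.

    At each pyramid level (coarsest first) the current moving image estimate
    is compared block-by-block to the fixed image; the normalised
    cross-correlation peak of each block gives its displacement, sparse block
    displacements are splined to a dense smooth field, and the cumulative
    field is refined. Flat (zero-variance) blocks are excluded; if every
    block is flat a :class:`RegistrationFailureError` is raised.

    The returned field maps moving -> fixed. A guard (on by default) falls
    back to the zero field if warping would *increase* MAE by more than 1%.
    """
    mv_full = _to_gray(moving)
    fx_full = _to_gray(fixed)
    if mv_full.shape != fx_full.shape:
        raise ShapeError("moving and fixed must share shape")
    if feature == "gradient":
        # contrast-polarity-invariant features for cross-modality pairs
        mv_full = np.hypot(ndimage.sobel(mv_full, 0), ndimage.sobel(mv_full, 1))
        fx_full = np.hypot(ndimage.sobel(fx_full, 0), ndimage.sobel(fx_full, 1))
    elif feature != "intensity":
        raise ValidationError(f"unknown feature mode {feature!r}")
    h, w = mv_full.shape
    if max_disp is None:
        max_disp = block_size / 2.0
    field_dx = np.zeros((h, w))
    field_dy = np.zeros((h, w))
    any_valid = False
    for level in range(levels - 1, -1, -1):
        scale = 2**level
        if min(h, w) // scale < block_size:
            continue
        fx_l = _downscale(fx_full, scale)
        cur = warp(mv_full, DisplacementField(dx=field_dx.astype(np.float32), dy=field_dy.astype(np.float32)))
        mv_l = _downscale(cur, scale)
        step = max(int(block_size * (1.0 - overlap)), 1)
        rows, cols = _block_grid(fx_l.shape, block_size, step)
        disp_r = np.zeros((len(rows), len(cols)))
        disp_c = np.zeros((len(rows), len(cols)))
        weight = np.zeros((len(rows), len(cols)), bool)
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                fb = fx_l[r : r + block_size, c : c + block_size]
                mb = mv_l[r : r + block_size, c : c + block_size]
                if fb.std() < 1e-6 or mb.std() < 1e-6:
                    continue
                # demeaned cross-correlation peak (NCC-style); the returned
                # shift moves `mb` onto `fb`, so sampling offsets negate it
                shift, _, _ = phase_cross_correlation(
                    fb - fb.mean(), mb - mb.mean(), upsample_factor=upsample_factor, normalization=None
                )
                if np.abs(shift).max() > max_disp:
                    continue
                disp_r[i, j] = -shift[0] * scale
                disp_c[i, j] = -shift[1] * scale
                weight[i, j] = True
        if not weight.any():
            if level == 0 and not any_valid:
                raise RegistrationFailureError("all blocks flat: no structure to register")
            continue
        any_valid = True
        disp_r = _fill_invalid(disp_r, weight)
        disp_c = _fill_invalid(disp_c, weight)
        centers_r = (np.asarray(rows) + block_size / 2.0) * scale
        centers_c = (np.asarray(cols) + block_size / 2.0) * scale
        field_dy += _interp_to_dense(disp_r, centers_r, centers_c, (h, w))
        field_dx += _interp_to_dense(disp_c, centers_r, centers_c, (h, w))
    result = DisplacementField(dx=field_dx.astype(np.float32), dy=field_dy.astype(np.float32))
    if guard:
        before = float(np.abs(mv_full - fx_full).mean())
        after = float(np.abs(warp(mv_full, result) - fx_full).mean())
        if after > before * 1.01:
            log.warning("elastic_register guard: field increased MAE (%.4f -> %.4f), returning zero field", before, after)
            return DisplacementField.zero(h, w)
    return result


def _downscale(img, scale):
    if scale == 1:
        return img
    h, w = img.shape
    img = img[: h - h % scale, : w - w % scale]
    return img.reshape(h // scale, scale, w // scale, scale).mean(axis=(1, 3))


def _fill_invalid(values, valid):
    """Replace skipped blocks by the mean of valid neighbours (global mean
    fallback)."""
    if valid.all():
        return values
    out = values.copy()
    mean = values[valid].mean() if valid.any() else 0.0
    out[~valid] = mean
    return out


@dataclass
class PrepConfig:
    tile_size: int = 2048
    downsample_factor: int = 4
    pyramid_levels: int = 4
    block_size: int = 64
    block_overlap: float = 0.5
    max_rounds: int = 2
    residual_threshold_px: float = 0.5
    # style-transfer model training per round; 0 = correlate against the
    # stack's mean-channel luminance directly
    style_steps: int = 0
    style_seed: int = 0
    skip_global: bool = False


def prepare_registered_dataset(stacks, stained_images, config: PrepConfig, modality: str = "brightfield"):
    """Build pixel-aligned tile pairs from WSI-level inputs.

    For each (stack, stained) pair: global projective registration and warp
    (unless pre-aligned), tiling, then the iterated elastic loop — optionally
    retraining a style-transfer generator between rounds — until the mean
    residual displacement drops below the threshold or rounds run out.

    Tiles whose registration fails are skipped and logged, not fatal.
    Returns (tile_pairs, diagnostics) where diagnostics records per-round
    mean residual displacement.
    """
    if len(stacks) != len(stained_images):
        raise ValidationError("stacks and stained_images must pair up")
    all_tiles = []
    for stack, stained in zip(stacks, stained_images):
        stained = np.asarray(stained, dtype=np.float32)
        if not config.skip_global:
            try:
                tf = global_register(_to_gray(stained), _to_gray(stack), config.downsample_factor)
                stained = apply_projective(stained, tf, output_shape=stained.shape[:2])
            except RegistrationFailureError as exc:
                log.warning("global registration skipped: %s", exc)
        all_tiles.extend(tile_pairs(stained, stack, config.tile_size, modality))

    style_model = None
    diagnostics = {"rounds": []}
    for round_idx in range(config.max_rounds):
        if config.style_steps > 0:
            style_model = _train_style_model(all_tiles, config)
        residuals = []
        new_tiles = []
        feature = "intensity" if style_model is not None else "gradient"
        for tp in all_tiles:
            ref = _style_reference(tp, style_model)
            try:
                field = elastic_register(
                    tp.target, ref, config.pyramid_levels, config.block_size, config.block_overlap, feature=feature
                )
            except RegistrationFailureError as exc:
                log.warning("tile %s skipped: %s", tp.tile_origin, exc)
                new_tiles.append(tp)
                continue
            residuals.append(float(field.magnitude().mean()))
            new_tiles.append(
                TilePair(stack=tp.stack, target=warp(tp.target, field), modality=tp.modality, tile_origin=tp.tile_origin)
            )
        all_tiles = new_tiles
        mean_residual = float(np.mean(residuals)) if residuals else 0.0
        diagnostics["rounds"].append(mean_residual)
        if mean_residual < config.residual_threshold_px:
            break
    return all_tiles, diagnostics


def _style_reference(tile: TilePair, style_model):
    """Registration reference for a tile: the style-transferred stack if a
    model is available, otherwise the stack's mean-channel luminance."""
    if style_model is None:
        return tile.stack.mean(axis=0)
    from .inference import infer_tile

    return infer_tile(style_model, tile.stack, tile.modality)


def _train_style_model(tiles, config: PrepConfig):
    """Short training of a staining generator (no registration submodule)
    used purely as a style-transfer aid for correlation."""
    from .networks import NetworkConfig
    from .training import TrainConfig, train

    net_cfg = NetworkConfig.tiny(in_channels=tiles[0].stack.shape[0])
    train_cfg = TrainConfig(
        max_steps=config.style_steps,
        crop_size=min(64, tiles[0].stack.shape[1]),
        batch_size=4,
        seed=config.style_seed,
        use_registration=False,
        modalities=(tiles[0].modality,),
        lr_generator=2e-3,
        lr_discriminator=2e-4,
    )
    nets, _ = train(tiles, net_cfg, train_cfg)
    return nets["generator"]
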