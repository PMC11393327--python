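"""Quantitative evaluation of virtually stained images.

Implements the paired-image metric suite used for both output modalities:
pixel metrics (MAE, PSNR with the peak taken from the ground-truth image,
multiscale SSIM with per-scale weights), set-level Fréchet distance with a
pluggable feature extractor, apple-green birefringence segmentation and the
down-sampled IoU (D-IoU), YCbCr colour histograms, nuclei quantification via
stain deconvolution, and the hue-scaling emulator for angle-shifted
birefringence targets.

Images are float RGB in [0, 1], shaped (H, W, 3) unless noted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg, ndimage
from skimage import measure, morphology
from skimage.color import hsv2rgb, rgb2hsv
from skimage.filters import threshold_otsu

from .errors import ShapeError, ValidationError

__all__ = [
    "BirefringenceMask",
    "MetricReport",
    "SegmentationParams",
    "mae",
    "mse",
    "psnr",
    "ms_ssim",
    "BRIGHTFIELD_MSSSIM_WEIGHTS",
    "POLARIZATION_MSSSIM_WEIGHTS",
    "RandomConvExtractor",
    "fid",
    "fid_from_features",
    "adjust_polarization_brightness",
    "segment_birefringence",
    "d_iou",
    "rgb_to_ycbcr",
    "color_histograms",
    "StainBasis",
    "count_nuclei",
    "mean_hue_deg",
    "hue_difference_deg",
    "simulate_angle_shift",
    "evaluate_pair",
    "evaluate_dataset",
]

BRIGHTFIELD_MSSSIM_WEIGHTS = (0.05, 0.05, 0.1, 0.15, 0.2, 0.45)
POLARIZATION_MSSSIM_WEIGHTS = (0.45, 0.2, 0.15, 0.1, 0.05, 0.05)


@dataclass(frozen=True)
class BirefringenceMask:
    values: np.ndarray
    provenance: str = "virtual"  # {histochemical | virtual}

    def __post_init__(self):
        vals = np.unique(self.values)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("mask values must be binary {0,1}")


@dataclass
class MetricReport:
    modality: str
    fov_id: str = ""
    mae: float = np.nan
    ms_ssim: float = np.nan
    psnr_db: float = np.nan
    fid: Optional[float] = None
    d_iou: Optional[float] = None
    nuclei_count: Optional[int] = None
    nuclei_mean_area_px2: Optional[float] = None
    extras: dict = field(default_factory=dict)


def _check_pair(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mae(a, b) -> float:
    """Mean absolute pixel difference over all pixels and channels."""
    a, b = _check_pair(a, b)
    return float(np.abs(a - b).mean())


def mse(a, b) -> float:
    a, b = _check_pair(a, b)
    return float(((a - b) ** 2).mean())


def psnr(a, b) -> float:
    """10*log10(max(A)^2 / MSE); the peak is the observed maximum of the
    ground-truth image ``a``, not a fixed dynamic range. Returns +inf (with
    a warning) for identical images."""
    a, b = _check_pair(a, b)
    err = mse(a, b)
    if err == 0.0:
        warnings.warn("psnr: images identical, returning inf", stacklevel=2)
        return float("inf")
    peak = float(a.max())
    return float(10.0 * np.log10(peak**2 / err))


# ---------------------------------------------------------------------------
# MS-SSIM

_SSIM_WIN = 11
_SSIM_SIGMA = 1.5
_C1 = 0.01**2
_C2 = 0.03**2


def _gaussian_kernel1d(win=_SSIM_WIN, sigma=_SSIM_SIGMA):
    half = (win - 1) / 2.0
    x = np.arange(win) - half
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def _local_mean(img, kernel):
    out = ndimage.correlate1d(img, kernel, axis=0, mode="reflect")
    return ndimage.correlate1d(out, kernel, axis=1, mode="reflect")


def _ssim_components(a, b):
    """Mean luminance term and mean contrast-structure term for one scale
    (2-D single channel, data range 1)."""
    k = _gaussian_kernel1d()
    mu_a = _local_mean(a, k)
    mu_b = _local_mean(b, k)
    var_a = _local_mean(a * a, k) - mu_a**2
    var_b = _local_mean(b * b, k) - mu_b**2
    cov = _local_mean(a * b, k) - mu_a * mu_b
    lum = (2 * mu_a * mu_b + _C1) / (mu_a**2 + mu_b**2 + _C1)
    cs = (2 * cov + _C2) / (var_a + var_b + _C2)
    pad = _SSIM_WIN // 2
    sl = (slice(pad, -pad), slice(pad, -pad))
    return float(lum[sl].mean()), float(cs[sl].mean())


def _downsample2(img):
    h, w = img.shape
    img = img[: h - h % 2, : w - w % 2]
    return 0.25 * (img[0::2, 0::2] + img[1::2, 0::2] + img[0::2, 1::2] + img[1::2, 1::2])


def ms_ssim(a, b, weights=BRIGHTFIELD_MSSSIM_WEIGHTS) -> float:
    """Multiscale SSIM with per-scale weight exponents.

    Contrast-structure terms enter at every scale; the luminance term only at
    the final (coarsest) scale; scales are linked by 2x average-pool
    downsampling. Multi-channel images are averaged over channels. Symmetric
    in (a, b) except for the PSNR-style conventions it does not use; the
    luminance/CS terms themselves are symmetric.
    """
    a, b = _check_pair(a, b)
    n_scales = len(weights)
    min_dim = min(a.shape[0], a.shape[1])
    needed = _SSIM_WIN * 2 ** (n_scales - 1)
    if min_dim < needed:
        raise ShapeError(
            f"image min dimension {min_dim} too small for {n_scales} scales; "
            f"needs >= {needed} (11-px window at the coarsest scale)"
        )
    if a.ndim == 2:
        a = a[..., None]
        b = b[..., None]
    results = []
    for c in range(a.shape[2]):
        ca, cb = a[..., c], b[..., c]
        value = 1.0
        for s in range(n_scales):
            lum, cs = _ssim_components(ca, cb)
            if s == n_scales - 1:
                value *= np.sign(lum * cs) * np.abs(lum * cs) ** weights[s]
            else:
                value *= np.sign(cs) * np.abs(cs) ** weights[s]
                ca, cb = _downsample2(ca), _downsample2(cb)
        results.append(value)
    return float(np.mean(results))


# ---------------------------------------------------------------------------
# FID

class RandomConvExtractor:
    """Fixed-seed random convolutional feature extractor.

    The Fréchet distance is well defined for any feature map; this provides
    an offline, deterministic stand-in for the conventional pretrained
    network (whose 2048-feature layer is the usual choice).
    """

    def __init__(self, feature_dim: int = 256, seed: int = 0, n_layers: int = 3, width: int = 16):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        self.filters = []
        c_in = 3
        for _ in range(n_layers):
            f = rng.standard_normal((width, c_in, 3, 3)).astype(np.float32)
            f *= np.sqrt(2.0 / (c_in * 9))
            self.filters.append(f)
            c_in = width
        self.proj = rng.standard_normal((2 * width, feature_dim)).astype(np.float32) / np.sqrt(2 * width)
        self.feature_dim = feature_dim

    def __call__(self, image) -> np.ndarray:
        x = np.asarray(image, dtype=np.float32)
        if x.ndim == 2:
            x = np.repeat(x[..., None], 3, axis=2)
        x = x.transpose(2, 0, 1)[None]
        for f in self.filters:
            o, c, kh, kw = f.shape
            win = np.lib.stride_tricks.sliding_window_view(np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1))), (kh, kw), axis=(2, 3))
            x = np.einsum("ncijab,ocab->noij", win, f)
            x = np.maximum(x, 0.0)
            x = x[:, :, ::2, ::2]
        feats = np.concatenate([x.mean(axis=(2, 3)), x.max(axis=(2, 3))], axis=1)
        return (feats @ self.proj)[0]


def fid_from_features(feats_a, feats_b, jitter=1e-6) -> float:
    """Fréchet distance between Gaussian fits of two feature sets."""
    feats_a = np.asarray(feats_a, dtype=np.float64)
    feats_b = np.asarray(feats_b, dtype=np.float64)
    mu_a, mu_b = feats_a.mean(axis=0), feats_b.mean(axis=0)
    cov_a = np.cov(feats_a, rowvar=False)
    cov_b = np.cov(feats_b, rowvar=False)
    cov_a = np.atleast_2d(cov_a)
    cov_b = np.atleast_2d(cov_b)
    diff = mu_a - mu_b
    prod, _ = linalg.sqrtm(cov_a @ cov_b, disp=False)
    if not np.isfinite(prod).all():
        warnings.warn("fid: covariance sqrt failed, adding jitter", stacklevel=2)
        dim = cov_a.shape[0]
        prod, _ = linalg.sqrtm((cov_a + jitter * np.eye(dim)) @ (cov_b + jitter * np.eye(dim)), disp=False)
    if np.iscomplexobj(prod):
        prod = prod.real
    value = diff @ diff + np.trace(cov_a) + np.trace(cov_b) - 2.0 * np.trace(prod)
    return float(max(value, 0.0))


def adjust_polarization_brightness(image) -> np.ndarray:
    """YCbCr round trip with the luma channel scaled x1.5 (clipped)."""
    ycc = rgb_to_ycbcr(image)
    ycc[..., 0] = np.clip(ycc[..., 0] * 1.5, 0.0, 1.0)
    return _ycbcr_to_rgb(ycc)


def fid(set_a, set_b, extractor=None, polarization: bool = False) -> float:
    """FID between two image sets (lists of HxWx3 arrays)."""
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValidationError("fid requires at least 2 images per set")
    if extractor is None:
        extractor = RandomConvExtractor()
    if polarization:
        set_a = [adjust_polarization_brightness(im) for im in set_a]
        set_b = [adjust_polarization_brightness(im) for im in set_b]
    feats_a = np.stack([extractor(im) for im in set_a])
    feats_b = np.stack([extractor(im) for im in set_b])
    return fid_from_features(feats_a, feats_b)


# ---------------------------------------------------------------------------
# birefringence segmentation and D-IoU

@dataclass(frozen=True)
class SegmentationParams:
    """HSV band for apple-green birefringence plus clean-up morphology.

    The published pipeline used pathologist-tuned thresholds that were never
    printed; these defaults are calibrated on phantoms and fully exposed.
    """

    hue_lo_deg: float = 80.0
    hue_hi_deg: float = 170.0
    sat_min: float = 0.25
    val_min: float = 0.15
    disk_radius: int = 2


def segment_birefringence(image, params: SegmentationParams = SegmentationParams(), provenance="virtual") -> BirefringenceMask:
    """Threshold the HSV channels to the apple-green band, then open + close."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ShapeError("segment_birefringence expects an RGB image")
    hsv = rgb2hsv(img)
    hue_deg = hsv[..., 0] * 360.0
    mask = (
        (hue_deg >= params.hue_lo_deg)
        & (hue_deg <= params.hue_hi_deg)
        & (hsv[..., 1] >= params.sat_min)
        & (hsv[..., 2] >= params.val_min)
    )
    if params.disk_radius > 0:
        selem = morphology.disk(params.disk_radius)
        mask = morphology.opening(mask, selem)
        mask = morphology.closing(mask, selem)
    return BirefringenceMask(values=mask.astype(np.uint8), provenance=provenance)


def _block_downsample(mask, factor):
    """Area-averaged downsampling (zero-padded to a multiple of factor)."""
    h, w = mask.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        mask = np.pad(mask, ((0, ph), (0, pw)))
    h2, w2 = mask.shape[0] // factor, mask.shape[1] // factor
    return mask.reshape(h2, factor, w2, factor).mean(axis=(1, 3))


def d_iou(mask_a, mask_b, factor: int = 32, threshold: float = None) -> float:
    """Down-sampled IoU: area-average each binary mask by ``factor``,
    binarise at a small threshold (default: any coverage, 1/factor^2), then
    intersection / union. Two empty masks score 1.0 (agreement on absence).
    """
    a = mask_a.values if isinstance(mask_a, BirefringenceMask) else np.asarray(mask_a)
    b = mask_b.values if isinstance(mask_b, BirefringenceMask) else np.asarray(mask_b)
    if a.shape != b.shape:
        raise ShapeError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    if threshold is None:
        threshold = 1.0 / (factor * factor)
    a32 = _block_downsample(a.astype(np.float64), factor) >= threshold
    b32 = _block_downsample(b.astype(np.float64), factor) >= threshold
    inter = float(np.sum(a32 & b32))
    union = float(np.sum(a32 | b32))
    if union == 0.0:
        return 1.0
    return inter / union


# ---------------------------------------------------------------------------
# colour histograms (BT.601 full-range YCbCr)

_YCC_MAT = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)


def rgb_to_ycbcr(image) -> np.ndarray:
    """ITU-R BT.601 full-range: Y in [0,1], Cb/Cr in [-0.5, 0.5] + 0.5."""
    img = np.asarray(image, dtype=np.float64)
    ycc = img @ _YCC_MAT.T
    ycc[..., 1:] += 0.5
    return ycc


def _ycbcr_to_rgb(ycc) -> np.ndarray:
    ycc = np.asarray(ycc, dtype=np.float64).copy()
    ycc[..., 1:] -= 0.5
    rgb = ycc @ np.linalg.inv(_YCC_MAT).T
    return np.clip(rgb, 0.0, 1.0)


def color_histograms(image, mask=None, bins: int = 64, smooth_sigma: float = 1.0):
    """Per-channel (Y, Cb, Cr) normalised histograms + smoothed PDF curves.

    Returns {channel: (bin_centers, density, smoothed_density)}. Densities
    integrate to 1. Raises on an empty mask.
    """
    ycc = rgb_to_ycbcr(image)
    if mask is not None:
        m = mask.values if isinstance(mask, BirefringenceMask) else np.asarray(mask)
        if not m.any():
            raise ValidationError("color_histograms: empty mask")
        ycc = ycc[m.astype(bool)]
    else:
        ycc = ycc.reshape(-1, 3)
    out = {}
    for i, name in enumerate(("Y", "Cb", "Cr")):
        hist, edges = np.histogram(ycc[:, i], bins=bins, range=(0.0, 1.0), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        smoothed = ndimage.gaussian_filter1d(hist, smooth_sigma)
        out[name] = (centers, hist, smoothed)
    return out


# ---------------------------------------------------------------------------
# nuclei quantification

@dataclass(frozen=True)
class StainBasis:
    """Optical-density stain vectors (rows normalised).

    The nuclear vector defaults to the widely used hematoxylin direction
    (Ruifrok & Johnston); the counterstain vector approximates the
    pink-salmon dye colour. The third axis is their cross product.
    """

    nuclear: tuple = (0.650, 0.704, 0.286)
    counter: tuple = (0.120, 0.760, 0.640)

    def matrix(self) -> np.ndarray:
        v1 = np.asarray(self.nuclear, dtype=np.float64)
        v2 = np.asarray(self.counter, dtype=np.float64)
        v1 = v1 / np.linalg.norm(v1)
        v2 = v2 / np.linalg.norm(v2)
        v3 = np.cross(v1, v2)
        v3 = v3 / np.linalg.norm(v3)
        return np.stack([v1, v2, v3])


def count_nuclei(
    brightfield,
    basis: StainBasis = StainBasis(),
    min_od: float = 0.25,
    min_area_px: int = 4,
    disk_radius: int = 1,
):
    """Count nuclei in a brightfield image via stain deconvolution.

    Optical densities are unmixed against the stain basis; Otsu's threshold
    on the nuclear channel (skipped for blank images) is followed by a
    dilation + erosion clean-up; 8-connected components are counted.

    Returns (count, mean_area_px2).
    """
    img = np.asarray(brightfield, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ShapeError("count_nuclei expects an RGB image")
    od = -np.log10(np.clip(img, 1e-6, 1.0))
    conc = od.reshape(-1, 3) @ np.linalg.inv(basis.matrix())
    nuclear = conc[:, 0].reshape(img.shape[:2])
    if nuclear.max() < min_od:
        return 0, 0.0
    thr = max(threshold_otsu(nuclear), min_od)
    mask = nuclear > thr
    if disk_radius > 0:
        selem = morphology.disk(disk_radius)
        mask = morphology.dilation(mask, selem)
        mask = morphology.erosion(mask, selem)
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())[1:]
    areas = areas[areas >= min_area_px]
    if areas.size == 0:
        return 0, 0.0
    return int(areas.size), float(areas.mean())


def mean_hue_deg(image, mask=None, min_sat: float = 0.1, min_val: float = 0.1) -> float:
    """Circular mean hue (degrees, [0, 360)) over selected pixels.

    Hue is an angle: a naive arithmetic mean is meaningless for colours near
    the red wrap-around, so pixels are averaged as unit phasors. Low
    saturation/value pixels (where hue is ill-defined) are excluded.
    """
    img = np.asarray(image, dtype=np.float64)
    hsv = rgb2hsv(img)
    sel = (hsv[..., 1] > min_sat) & (hsv[..., 2] > min_val)
    if mask is not None:
        m = mask.values if isinstance(mask, BirefringenceMask) else np.asarray(mask)
        sel &= m.astype(bool)
    if not sel.any():
        raise ValidationError("mean_hue_deg: no pixels with well-defined hue")
    angles = hsv[..., 0][sel] * 2.0 * np.pi
    mean_angle = np.angle(np.exp(1j * angles).mean())
    return float(np.degrees(mean_angle) % 360.0)


def hue_difference_deg(hue_a: float, hue_b: float) -> float:
    """Smallest angular difference between two hues in degrees, in [0, 180]."""
    d = abs(hue_a - hue_b) % 360.0
    return min(d, 360.0 - d)


# ---------------------------------------------------------------------------
# angle-shift emulation

def simulate_angle_shift(
    crosspol,
    amyloid_factor: float = 0.6,
    background_factor: float = 1.1,
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Emulate a small polarizer rotation on a cross-polarized image.

    Hue of segmented apple-green (amyloid) pixels is scaled by ~0.6 (green to
    yellow); hue elsewhere is scaled by ~1.1 and clipped at 1. Saturation and
    value are untouched, so brightness is preserved exactly.
    """
    img = np.asarray(crosspol, dtype=np.float64)
    mask = segment_birefringence(img, params).values.astype(bool)
    hsv = rgb2hsv(img)
    hue = hsv[..., 0]
    hue = np.where(mask, hue * amyloid_factor, np.minimum(hue * background_factor, 1.0))
    out = hsv.copy()
    out[..., 0] = hue
    return hsv2rgb(out)


# ---------------------------------------------------------------------------
# dispatch

def evaluate_pair(virtual, histochemical, modality: str, fov_id: str = "", seg_params=SegmentationParams()) -> MetricReport:
    """Compute the modality-appropriate metric set for one registered pair.

    Brightfield: MAE / MS-SSIM (brightfield weights) / PSNR + nuclei stats.
    Polarization (crosspol or angleshift): MAE / MS-SSIM (polarization
    weights) / PSNR + segmentation D-IoU + colour histograms. Set-level FID
    is left to :func:`evaluate_dataset`.
    """
    if modality not in ("brightfield", "crosspol", "angleshift"):
        raise ValidationError(f"unknown modality {modality!r}")
    v, h = _check_pair(virtual, histochemical)
    report = MetricReport(modality=modality, fov_id=fov_id)
    report.mae = mae(h, v)
    report.psnr_db = psnr(h, v)
    if modality == "brightfield":
        report.ms_ssim = ms_ssim(h, v, BRIGHTFIELD_MSSSIM_WEIGHTS)
        count, area = count_nuclei(v)
        report.nuclei_count = count
        report.nuclei_mean_area_px2 = area
        gt_count, gt_area = count_nuclei(h)
        report.extras["gt_nuclei_count"] = gt_count
        report.extras["gt_nuclei_mean_area_px2"] = gt_area
    else:
        report.ms_ssim = ms_ssim(h, v, POLARIZATION_MSSSIM_WEIGHTS)
        mask_v = segment_birefringence(v, seg_params, provenance="virtual")
        mask_h = segment_birefringence(h, seg_params, provenance="histochemical")
        report.d_iou = d_iou(mask_h, mask_v)
        if mask_v.values.any():
            report.extras["virtual_histograms"] = color_histograms(v, mask_v)
        if mask_h.values.any():
            report.extras["histochemical_histograms"] = color_histograms(h, mask_h)
    return report


def evaluate_dataset(virtual_images, histochemical_images, modality: str, extractor=None):
    """Evaluate a list of registered pairs; returns (reports, set_fid)."""
    if len(virtual_images) != len(histochemical_images):
        raise ValidationError("paired evaluation needs equal-length sets")
    reports = [
        evaluate_pair(v, h, modality, fov_id=str(i))
        for i, (v, h) in enumerate(zip(virtual_images, histochemical_images))
    ]
    set_fid = None
    if len(virtual_images) >= 2:
        set_fid = fid(
            histochemical_images,
            virtual_images,
            extractor=extractor,
            polarization=(modality != "brightfield"),
        )
        for r in reports:
            r.fid = set_fid
    return reports, set_fid
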