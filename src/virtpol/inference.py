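"""Deterministic tile-wise virtual staining with seam-free stitching.

Only the generator runs at inference; the discriminator and registration
module are training-time aids. Outputs are clipped to [0, 1] and returned
channel-last (H, W, 3) to match the evaluation module's conventions.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError, ValidationError
from .networks import make_dsm

__all__ = ["infer_tile", "infer_wsi"]


def _pad_to_multiple(stack, multiple):
    c, h, w = stack.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        stack = np.pad(stack, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    return stack, h, w


def infer_tile(generator, stack, modality: str) -> np.ndarray:
    """Virtually stain one tile: clip(G(stack ⊕ DSM), 0, 1).

    Sizes not divisible by the generator's downsampling factor are padded
    by reflection internally and cropped back, so output spatial size always
    equals input spatial size. Bit-deterministic for fixed inputs/weights.
    """
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 3:
        raise ShapeError("stack must be (C, H, W)")
    multiple = 2**generator.config.generator_levels
    padded, h, w = _pad_to_multiple(stack, multiple)
    dsm = make_dsm(padded.shape[1], padded.shape[2], modality)
    out = generator(padded[None], dsm).data[0]
    out = np.clip(out, 0.0, 1.0)
    return out[:, :h, :w].transpose(1, 2, 0).astype(np.float32)


def _feather_window(tile_h, tile_w, overlap):
    """Separable linear feathering ramp over the overlap margin."""

    def ramp(n):
        wgt = np.ones(n, dtype=np.float64)
        if overlap > 0:
            edge = np.linspace(1.0 / (overlap + 1), 1.0, overlap)
            wgt[:overlap] = edge
            wgt[-overlap:] = edge[::-1]
        return wgt

    return np.outer(ramp(tile_h), ramp(tile_w))


def infer_wsi(generator, wsi_stack, modalities, tile: int = 1024, overlap: int = 64):
    """Tile-wise inference over a whole-slide stack with feathered blending.

    Tiles are laid on a grid with the given overlap; contributions in
    overlap zones are blended by linear feathering. Accumulation runs in a
    streaming row-major order but the result is independent of traversal
    order (weighted average). Returns {modality: (H, W, 3) image}.
    """
    wsi_stack = np.asarray(wsi_stack, dtype=np.float32)
    if wsi_stack.ndim != 3:
        raise ShapeError("wsi_stack must be (C, H, W)")
    if overlap < 0 or overlap >= tile / 2:
        raise ValidationError("overlap must satisfy 0 <= overlap < tile/2")
    if isinstance(modalities, str):
        modalities = [modalities]
    c, h, w = wsi_stack.shape
    tile = min(tile, h, w)
    step = tile - overlap
    row_starts = sorted({min(r, h - tile) for r in range(0, h, step) if min(r, h - tile) >= 0} | {0})
    col_starts = sorted({min(cs, w - tile) for cs in range(0, w, step) if min(cs, w - tile) >= 0} | {0})
    out = {}
    for modality in modalities:
        acc = np.zeros((h, w, 3), dtype=np.float64)
        wacc = np.zeros((h, w, 1), dtype=np.float64)
        for r in row_starts:
            for cs in col_starts:
                patch = infer_tile(generator, wsi_stack[:, r : r + tile, cs : cs + tile], modality)
                wgt = _feather_window(patch.shape[0], patch.shape[1], overlap)[..., None]
                acc[r : r + tile, cs : cs + tile] += patch * wgt
                wacc[r : r + tile, cs : cs + tile] += wgt
        out[modality] = np.clip(acc / np.maximum(wacc, 1e-12), 0.0, 1.0).astype(np.float32)
    return out
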