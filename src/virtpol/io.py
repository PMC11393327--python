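"""File I/O boundaries: multi-channel TIFF stacks, RGB images, fields.

All in-memory images are float in [0, 1]; quantisation to 8/16 bit happens
only here. 16-bit export/import round-trips the quantised values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import ShapeError

__all__ = [
    "save_stack",
    "load_stack",
    "save_rgb",
    "load_rgb",
    "save_mask",
    "load_mask",
    "save_field",
    "load_field",
    "save_manifest",
    "load_manifest",
]


def save_stack(path, stack):
    """(C, H, W) float [0,1] -> multi-page uint16 TIFF."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ShapeError("stack must be (C, H, W)")
    tifffile.imwrite(str(path), np.round(np.clip(stack, 0, 1) * 65535).astype(np.uint16), photometric="minisblack")


def load_stack(path) -> np.ndarray:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return (data.astype(np.float32) / np.float32(65535.0)) if data.dtype == np.uint16 else data.astype(np.float32) / 255.0


def save_rgb(path, image):
    """(H, W, 3) float [0,1] -> uint16 TIFF (bit-exact at 16-bit)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeError("image must be (H, W, 3)")
    tifffile.imwrite(str(path), np.round(np.clip(image, 0, 1) * 65535).astype(np.uint16))


def load_rgb(path) -> np.ndarray:
    data = tifffile.imread(str(path))
    if data.dtype == np.uint16:
        return data.astype(np.float32) / np.float32(65535.0)
    if data.dtype == np.uint8:
        return data.astype(np.float32) / np.float32(255.0)
    return data.astype(np.float32)


def save_mask(path, mask):
    tifffile.imwrite(str(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def load_mask(path) -> np.ndarray:
    return (tifffile.imread(str(path)) > 0).astype(np.uint8)


def save_field(path, field):
    """DisplacementField -> 2-channel float32 TIFF (dx, dy)."""
    tifffile.imwrite(str(path), field.as_array().astype(np.float32))


def load_field(path):
    from .dataprep import DisplacementField

    arr = tifffile.imread(str(path))
    return DisplacementField(dx=arr[0], dy=arr[1])


def save_manifest(path, manifest: dict):
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
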