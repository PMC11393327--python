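"""Independent brute-force loop implementations of every closed-form loss
and metric, used as oracles. Deliberately written with explicit Python
loops and no shared code with the package internals."""

import math

import numpy as np


def smooth_l1_loop(a, b, phi=1.0):
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    total = 0.0
    for x, y in zip(a, b):
        d = abs(x - y)
        if d < phi:
            total += 0.5 * d * d / phi
        else:
            total += d - 0.5 * phi
    return total / len(a)


def bce_loop(p, label, eps=1e-7):
    p = min(max(float(p), eps), 1.0 - eps)
    label = float(label)
    return -(label * math.log(p) + (1.0 - label) * math.log(1.0 - p))


def tv_loop(img):
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        img = img[None]
    total = 0.0
    for plane in img.reshape(-1, img.shape[-2], img.shape[-1]):
        h, w = plane.shape
        for p in range(h - 1):
            for q in range(w):
                total += abs(plane[p + 1, q] - plane[p, q])
        for p in range(h):
            for q in range(w - 1):
                total += abs(plane[p, q + 1] - plane[p, q])
    return total


def smoothness_loop(field):
    field = np.asarray(field, dtype=np.float64)
    assert field.ndim == 3 and field.shape[0] == 2
    _, h, w = field.shape
    total = 0.0
    for comp in field:
        for x in range(h - 1):
            for y in range(w):
                total += (comp[x + 1, y] - comp[x, y]) ** 2
        for x in range(h):
            for y in range(w - 1):
                total += (comp[x, y + 1] - comp[x, y]) ** 2
    return total / (h * w)


def mae_loop(a, b):
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    return sum(abs(x - y) for x, y in zip(a, b)) / len(a)


def mse_loop(a, b):
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    return sum((x - y) ** 2 for x, y in zip(a, b)) / len(a)


def psnr_loop(a, b):
    peak = float(np.asarray(a).max())
    return 10.0 * math.log10(peak * peak / mse_loop(a, b))


def d_iou_loop(mask_a, mask_b, factor=32, threshold=None):
    if threshold is None:
        threshold = 1.0 / (factor * factor)
    a = np.asarray(mask_a, dtype=np.float64)
    b = np.asarray(mask_b, dtype=np.float64)
    h, w = a.shape
    ph, pw = (-h) % factor, (-w) % factor
    a = np.pad(a, ((0, ph), (0, pw)))
    b = np.pad(b, ((0, ph), (0, pw)))
    hh, ww = a.shape[0] // factor, a.shape[1] // factor
    inter = 0
    union = 0
    for i in range(hh):
        for j in range(ww):
            block_a = a[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor].mean()
            block_b = b[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor].mean()
            va = 1 if block_a >= threshold else 0
            vb = 1 if block_b >= threshold else 0
            inter += va * vb
            union += min(va + vb, 1)
    if union == 0:
        return 1.0
    return inter / union
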