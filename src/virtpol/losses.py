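"""Training objectives for the staining generator, critic and registration net.

Each primitive loss (:func:`smooth_l1`, :func:`bce`, :func:`total_variation`,
:func:`smoothness`) works on either plain ndarrays — returning a Python float
— or on autograd tensors, returning a scalar tensor suitable for
backpropagation. The composite losses assemble the full objectives used by
the training loop and report their individual components for logging.

Conventions:

* images are averaged over every element (batch, channels and pixels) in the
  pixelwise terms, so multi-channel inputs need no special casing;
* total variation is *un-normalised* (a plain sum of absolute forward
  differences) — the tiny default weight ``gamma`` compensates;
* displacement-field smoothness is the mean (over field elements, both
  components) of squared forward differences;
* finite differences run up to the last valid index; no padding or
  wraparound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ShapeError
from .nn import Tensor

__all__ = [
    "LossWeights",
    "smooth_l1",
    "bce",
    "total_variation",
    "smoothness",
    "generator_loss",
    "discriminator_loss",
    "registration_loss",
]

BCE_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Loss coefficients; defaults follow the published training recipe."""

    alpha: float = 10.0
    beta: float = 1.0
    gamma: float = 1e-4
    lam: float = 20.0
    mu: float = 10.0
    phi: float = 1.0

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "lam", "mu", "phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss weight {name} must be >= 0")


def _is_tracked(*args):
    return any(isinstance(a, Tensor) and (a.requires_grad or a._parents) for a in args)


def _ret(value, *args):
    return value if _is_tracked(*args) else float(value.data)


def smooth_l1(a, b, phi: float = 1.0):
    """Huber-style smooth L1: mean of 0.5*d^2/phi where |d| < phi, else
    |d| - 0.5*phi. Continuous at |d| = phi (both branches give 0.5*phi)."""
    if phi <= 0:
        raise ValueError("phi must be > 0")
    ta, tb = nn.as_tensor(a), nn.as_tensor(b)
    if ta.data.shape != tb.data.shape:
        raise ShapeError(f"smooth_l1 shape mismatch: {ta.data.shape} vs {tb.data.shape}")
    d = nn.sub(ta, tb)
    quad_mask = (np.abs(d.data) < phi).astype(np.float32)
    quad = nn.mul(nn.square(d), 0.5 / phi)
    lin = nn.add(nn.absolute(d), -0.5 * phi)
    per_px = nn.add(nn.mul(quad, quad_mask), nn.mul(lin, 1.0 - quad_mask))
    return _ret(nn.tmean(per_px), a, b)


def bce(p_pred, label):
    """Binary cross-entropy with predictions clamped to [eps, 1-eps]."""
    tp = nn.as_tensor(p_pred)
    tl = np.asarray(label, dtype=np.float32)
    pc = nn.clip(tp, BCE_EPS, 1.0 - BCE_EPS)
    loss = nn.neg(nn.add(nn.mul(tl, nn.log(pc)), nn.mul(1.0 - tl, nn.log(nn.sub(1.0, pc)))))
    return _ret(nn.tmean(loss), p_pred)


def _shift_diff(t, axis):
    """t[..., i+1, ...] - t[..., i, ...] along a spatial axis, valid range."""
    nd = t.data.ndim
    sl_hi = [slice(None)] * nd
    sl_lo = [slice(None)] * nd
    sl_hi[axis] = slice(1, None)
    sl_lo[axis] = slice(None, -1)
    return nn.sub(_tslice(t, tuple(sl_hi)), _tslice(t, tuple(sl_lo)))


def _tslice(t, index):
    """Differentiable slicing helper."""
    t = nn.as_tensor(t)
    out = t.data[index]

    def bwd(g):
        gx = np.zeros_like(t.data)
        gx[index] = g
        return ((t, gx),)

    from .nn.autograd import _node

    return _node(out, (t,), bwd)


def total_variation(image):
    """Anisotropic, un-normalised TV: sum over all valid forward differences
    (rows then columns), summed over any leading channel/batch axes."""
    t = nn.as_tensor(image)
    if t.data.ndim < 2:
        raise ShapeError("total_variation expects at least a 2-D image")
    dr = nn.tsum(nn.absolute(_shift_diff(t, t.data.ndim - 2)))
    dc = nn.tsum(nn.absolute(_shift_diff(t, t.data.ndim - 1)))
    return _ret(nn.add(dr, dc), image)


def smoothness(field):
    """Displacement-field regulariser: (1/XY) * sum of squared forward
    differences, accumulated over both (dx, dy) components.

    Accepts (2, H, W) or (N, 2, H, W); batches are averaged.
    """
    t = nn.as_tensor(field)
    shape = t.data.shape
    if len(shape) == 3:
        if shape[0] != 2:
            raise ShapeError("smoothness expects a 2-component field")
        norm = shape[1] * shape[2]
    elif len(shape) == 4:
        if shape[1] != 2:
            raise ShapeError("smoothness expects a 2-component field")
        norm = shape[0] * shape[2] * shape[3]
    else:
        raise ShapeError("smoothness expects (2,H,W) or (N,2,H,W)")
    dr = nn.tsum(nn.square(_shift_diff(t, t.data.ndim - 2)))
    dc = nn.tsum(nn.square(_shift_diff(t, t.data.ndim - 1)))
    return _ret(nn.mul(nn.add(dr, dc), 1.0 / norm), field)


def generator_loss(
    i_input,
    dsm,
    i_target,
    generator,
    discriminator,
    registration=None,
    weights: LossWeights = LossWeights(),
):
    """Full generator objective.

    alpha * smoothL1(target, warp(G(x, c), R(G(x, c), target)))
    + beta * BCE(D(G(x, c)[, c]), 1)
    + gamma * TV(G(x, c))

    ``registration=None`` drops the warp (identity alignment). Returns
    ``(total, components)`` where components is a dict of floats.
    """
    g_out = generator(i_input, dsm)
    if registration is not None:
        field = registration(g_out, i_target)
        aligned = nn.grid_warp(g_out, field)
    else:
        aligned = g_out
    l1 = smooth_l1(i_target, aligned, weights.phi)
    d_pred = discriminator(g_out, dsm)
    adv = bce(d_pred, 1.0)
    tv = total_variation(g_out)
    total = nn.add(nn.add(nn.mul(l1, weights.alpha), nn.mul(adv, weights.beta)), nn.mul(tv, weights.gamma))
    components = {
        "smooth_l1": float(l1.data) if isinstance(l1, Tensor) else float(l1),
        "adversarial": float(adv.data) if isinstance(adv, Tensor) else float(adv),
        "tv": float(tv.data) if isinstance(tv, Tensor) else float(tv),
        "total": float(total.data),
    }
    return total, components


def discriminator_loss(fake_pred, real_pred):
    """BCE(fake, 0) + BCE(real, 1)."""
    fake = bce(fake_pred, 0.0)
    real = bce(real_pred, 1.0)
    if isinstance(fake, Tensor) or isinstance(real, Tensor):
        return nn.add(nn.as_tensor(fake), nn.as_tensor(real))
    return fake + real


def registration_loss(i_target, g_out, registration, weights: LossWeights = LossWeights()):
    """lambda * smoothL1(target, warp(g_out, field)) + mu * smoothness(field)
    with field = R(g_out, target). Returns (total, components)."""
    field = registration(g_out, i_target)
    warped = nn.grid_warp(g_out, field)
    l1 = smooth_l1(i_target, warped, weights.phi)
    smth = smoothness(field)
    total = nn.add(nn.mul(l1, weights.lam), nn.mul(smth, weights.mu))
    components = {
        "smooth_l1": float(l1.data) if isinstance(l1, Tensor) else float(l1),
        "smoothness": float(smth.data) if isinstance(smth, Tensor) else float(smth),
        "total": float(total.data) if isinstance(total, Tensor) else float(total),
    }
    return total, components
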