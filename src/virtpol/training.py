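"""Adversarial training loop with modality mixing and the 4:1:1 schedule.

One *step* is one optimizer update of one module; the scheduler cycles
[G, G, G, G, D, R] so 60 steps yield 40 generator, 10 discriminator and 10
registration updates. Each update draws a fresh batch of random crops whose
modality is sampled uniformly from the configured set, with the matching
constant DSM concatenated downstream.

Learning-rate defaults are the published ones (2e-5 / 2e-6 / 2e-6); the
desk-scale test configurations override them upward since the toy networks
train for only a few hundred steps.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .errors import CheckpointError, ValidationError, VirtpolError
from .losses import LossWeights, discriminator_loss, generator_loss, registration_loss, smooth_l1
from .networks import (
    DSM_VALUES,
    MODALITIES,
    NetworkConfig,
    build_discriminator,
    build_generator,
    build_registration_module,
    load_checkpoint,
    save_checkpoint,
)

__all__ = ["TrainConfig", "TrainingDivergedError", "train", "fine_tune", "sample_batch"]

log = logging.getLogger(__name__)


class TrainingDivergedError(VirtpolError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    lr_generator: float = 2e-5
    lr_discriminator: float = 2e-6
    lr_registration: float = 2e-6
    batch_size: int = 32
    crop_size: int = 256
    update_ratio: tuple = (4, 1, 1)
    max_steps: int = 600
    seed: int = 0
    modalities: Sequence[str] = ("brightfield", "crosspol")
    use_registration: bool = True
    weights: LossWeights = field(default_factory=LossWeights)
    checkpoint_every: int = 0  # 0 = only final
    min_crop_variance: float = 1e-4
    # optional step decay ("starting with" rates; off by default)
    lr_decay_gamma: float = 1.0
    lr_decay_every: int = 0

    def __post_init__(self):
        if any(r <= 0 or int(r) != r for r in self.update_ratio):
            raise ValidationError("update_ratio entries must be positive integers")
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValidationError(f"unknown modality {m!r}")
        if self.use_registration and self.crop_size % 128:
            raise ValidationError("crop_size must be divisible by 128 when the registration net is active")
        if self.crop_size % 16:
            raise ValidationError("crop_size must be divisible by 16")


def _schedule(update_ratio):
    g, d, r = update_ratio
    return ["G"] * g + ["D"] * d + ["R"] * r


def sample_batch(dataset, modalities, crop, batch_size, rng, min_var=1e-4, max_tries=20):
    """Random crops with per-sample modality mixing.

    Each sample draws its modality uniformly from ``modalities`` (a single
    string is also accepted), takes a random crop of a random tile of that
    modality, and gets the matching constant DSM value — targets from the
    different modalities are mixed within one batch. Crops are rejected (up
    to ``max_tries``) if the target patch is essentially constant.

    Returns (stacks (N,C,h,w), targets (N,3,h,w), dsm_channels (N,h,w)).
    """
    if isinstance(modalities, str):
        modalities = (modalities,)
    pools = {}
    for m in modalities:
        pools[m] = [tp for tp in dataset if tp.modality == m]
        if not pools[m]:
            raise ValidationError(f"dataset has no tiles for modality {m!r}")
    stacks, targets, dsms = [], [], []
    for _ in range(batch_size):
        modality = modalities[rng.integers(len(modalities))]
        pool = pools[modality]
        for attempt in range(max_tries):
            tp = pool[rng.integers(len(pool))]
            h, w = tp.stack.shape[1:]
            r = int(rng.integers(0, h - crop + 1))
            c = int(rng.integers(0, w - crop + 1))
            tgt = tp.target[r : r + crop, c : c + crop]
            if tgt.var() >= min_var or attempt == max_tries - 1:
                break
        stacks.append(tp.stack[:, r : r + crop, c : c + crop])
        targets.append(tgt.transpose(2, 0, 1))
        dsms.append(np.full((crop, crop), DSM_VALUES[modality], dtype=np.float32))
    return (
        np.stack(stacks).astype(np.float32),
        np.stack(targets).astype(np.float32),
        np.stack(dsms).astype(np.float32),
    )


def _history_writer(out_dir):
    if out_dir is None:
        return None, None
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = open(out_dir / "history.csv", "w", newline="")
    writer = csv.DictWriter(fh, fieldnames=["step", "module", "modality", "total", "smooth_l1", "adversarial", "tv", "smoothness"])
    writer.writeheader()
    return fh, writer


def train(
    dataset,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    nets: Optional[dict] = None,
    out_dir=None,
    val_pairs=None,
):
    """Run the adversarial loop; returns (nets, history).

    ``nets`` may carry pre-built modules (resume / fine-tune); missing roles
    are freshly initialised from ``train_cfg.seed``. History is a list of
    per-step dicts; if ``out_dir`` is given it is also streamed to CSV and a
    final checkpoint is written.
    """
    if not dataset:
        raise ValidationError("empty dataset")
    for m in train_cfg.modalities:
        if not any(tp.modality == m for tp in dataset):
            raise ValidationError(f"dataset is missing modality {m!r}")
    for tp in dataset:
        if tp.stack.shape[0] != net_cfg.in_channels:
            raise ValidationError(
                f"tile has {tp.stack.shape[0]} channels, network expects {net_cfg.in_channels}"
            )

    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 4242]))
    nets = dict(nets) if nets else {}
    nets.setdefault("generator", build_generator(net_cfg, seed=train_cfg.seed))
    nets.setdefault("discriminator", build_discriminator(net_cfg, seed=train_cfg.seed))
    if train_cfg.use_registration:
        nets.setdefault("registration", build_registration_module(net_cfg, seed=train_cfg.seed))
    gen, disc = nets["generator"], nets["discriminator"]
    reg = nets.get("registration") if train_cfg.use_registration else None

    opt_g = nn.Adam(gen.parameters(), train_cfg.lr_generator)
    opt_d = nn.Adam(disc.parameters(), train_cfg.lr_discriminator)
    opt_r = nn.Adam(reg.parameters(), train_cfg.lr_registration) if reg is not None else None

    schedule = _schedule(train_cfg.update_ratio)
    weights = train_cfg.weights
    history = []
    fh, writer = _history_writer(out_dir)
    modalities = tuple(train_cfg.modalities)

    try:
        for step in range(train_cfg.max_steps):
            if (
                train_cfg.lr_decay_every
                and step > 0
                and step % train_cfg.lr_decay_every == 0
                and train_cfg.lr_decay_gamma != 1.0
            ):
                for opt in (opt_g, opt_d, opt_r):
                    if opt is not None:
                        opt.lr *= train_cfg.lr_decay_gamma
            role = schedule[step % len(schedule)]
            if role == "R" and reg is None:
                role = "G"  # keep step count; registration disabled
            stacks, targets, dsm = sample_batch(
                dataset, modalities, train_cfg.crop_size, train_cfg.batch_size, rng, train_cfg.min_crop_variance
            )
            row = {"step": step, "module": role, "modality": "mixed", "total": np.nan,
                   "smooth_l1": np.nan, "adversarial": np.nan, "tv": np.nan, "smoothness": np.nan}
            if role == "G":
                loss, comps = generator_loss(stacks, dsm, targets, gen, disc, reg, weights)
                if not np.isfinite(loss.data):
                    raise TrainingDivergedError(f"generator loss non-finite at step {step}")
                gen.zero_grad()
                disc.zero_grad()
                if reg is not None:
                    reg.zero_grad()
                loss.backward()
                opt_g.step()
                row.update(total=comps["total"], smooth_l1=comps["smooth_l1"],
                           adversarial=comps["adversarial"], tv=comps["tv"])
            elif role == "D":
                fake = gen(stacks, dsm).detach()
                d_loss = discriminator_loss(disc(fake, dsm), disc(nn.Tensor(targets), dsm))
                disc.zero_grad()
                d_loss.backward()
                opt_d.step()
                row.update(total=float(d_loss.data))
            else:  # R
                g_out = gen(stacks, dsm).detach()
                r_loss, comps = registration_loss(nn.Tensor(targets), g_out, reg, weights)
                reg.zero_grad()
                r_loss.backward()
                opt_r.step()
                row.update(total=comps["total"], smooth_l1=comps["smooth_l1"], smoothness=comps["smoothness"])
            history.append(row)
            if writer is not None:
                writer.writerow(row)
            if out_dir and train_cfg.checkpoint_every and (step + 1) % train_cfg.checkpoint_every == 0:
                save_checkpoint(Path(out_dir) / f"step_{step + 1}", net_cfg, nets, step=step + 1)
    finally:
        if fh is not None:
            fh.close()

    if val_pairs is not None:
        val = validate(nets["generator"], val_pairs, train_cfg)
        log.info("validation smooth-L1: %.5f", val)
    if out_dir is not None:
        save_checkpoint(Path(out_dir) / "final", net_cfg, nets, step=train_cfg.max_steps)
    return nets, history


def validate(generator, pairs, train_cfg: TrainConfig) -> float:
    """Mean smooth-L1 between generator output and targets on full tiles."""
    from .inference import infer_tile

    losses = []
    for tp in pairs:
        out = infer_tile(generator, tp.stack, tp.modality)
        losses.append(smooth_l1(tp.target, out, train_cfg.weights.phi))
    return float(np.mean(losses))


def fine_tune(checkpoint, noisy_dataset, train_cfg: TrainConfig, out_dir=None):
    """Resume all modules from a checkpoint and continue training (identical
    loop) on a noise-augmented dataset. ``checkpoint`` is a path or an
    in-memory (net_cfg, nets) tuple."""
    if isinstance(checkpoint, (str, Path)):
        net_cfg, nets, step, _ = load_checkpoint(checkpoint, seed=train_cfg.seed)
    else:
        net_cfg, nets = checkpoint
        if not isinstance(net_cfg, NetworkConfig) or "generator" not in nets:
            raise CheckpointError("in-memory checkpoint must be (NetworkConfig, nets dict)")
    if train_cfg.use_registration and "registration" not in nets:
        train_cfg = replace(train_cfg, use_registration=False)
    return train(noisy_dataset, net_cfg, train_cfg, nets=nets, out_dir=out_dir)
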