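"""Variational force matching: fit a trainable potential to delta forces.

The objective is the mean squared force mismatch per Cartesian component,

    chi^2 = < 1/(3N) sum_I | F_target,I - F_model,I |^2 >,

with the ensemble average taken as the empirical mean over dataset frames
and F_model = -grad U.  Targets are delta forces (mapped atomistic forces
minus prior forces), so the model learns only the residual the prior misses.
Optimization is Adam with plateau-based learning-rate decay; runs are fully
reproducible under a fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from cglipid.mapping import CGFrame

__all__ = [
    "FMDataset",
    "TrainConfig",
    "DivergenceError",
    "fm_loss",
    "train_potential",
    "force_rmse",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class FMDataset:
    """Frames with delta-force targets, split into train/validation."""

    frames: list[CGFrame]
    targets: list[np.ndarray]
    train_idx: np.ndarray
    val_idx: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        if len(self.frames) != len(self.targets):
            raise ValueError("frames/targets length mismatch")
        for t in self.targets:
            if not np.all(np.isfinite(t)):
                raise ValueError("non-finite force target")
        if set(self.train_idx.tolist()) & set(self.val_idx.tolist()):
            raise ValueError("train/validation splits overlap")

    @classmethod
    def from_frames(
        cls, frames, targets, val_fraction: float = 0.1, seed: int = 0, provenance: str = ""
    ) -> "FMDataset":
        n = len(frames)
        order = np.random.default_rng(seed).permutation(n)
        n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
        return cls(
            frames=list(frames),
            targets=[np.asarray(t, dtype=np.float64) for t in targets],
            train_idx=np.sort(order[n_val:]),
            val_idx=np.sort(order[:n_val]),
            provenance=provenance,
        )


@dataclass
class TrainConfig:
    batch_size: int = 8
    learning_rate: float = 1e-3
    max_epochs: int = 50
    seed: int = 0
    patience: int = 5  # epochs without val improvement before lr decay
    lr_decay: float = 0.5
    min_lr: float = 1e-6
    early_stop_patience: int = 15

    def __post_init__(self):
        if self.batch_size < 1 or self.max_epochs < 0:
            raise ValueError("batch size and epochs must be positive")


def fm_loss(predicted_forces, target_delta_forces, n_beads: int | None = None) -> float:
    """Force-matching loss for one frame or a list of frames.

    For arrays of shape (N, 3): 1/(3N) * sum |target - predicted|^2.
    For lists, the mean of the per-frame losses.
    """
    if isinstance(predicted_forces, (list, tuple)):
        vals = [fm_loss(p, t) for p, t in zip(predicted_forces, target_delta_forces)]
        return float(np.mean(vals))
    p = np.asarray(predicted_forces, dtype=np.float64)
    t = np.asarray(target_delta_forces, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: predicted {p.shape} vs target {t.shape}")
    n = n_beads if n_beads is not None else p.shape[0]
    return float(np.sum((t - p) ** 2) / (3.0 * n))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _dataset_loss(model, data: FMDataset, idx) -> float:
    vals = []
    for i in idx:
        _, f = model.energy_and_forces(data.frames[i])
        vals.append(fm_loss(f, data.targets[i]))
    return float(np.mean(vals)) if vals else float("nan")


def train_potential(model, data: FMDataset, cfg: TrainConfig):
    """Minimize the force-matching loss over model parameters.

    Returns (model, history): the model carries the best-validation
    parameters; history is a list of per-epoch records with train and
    validation losses and the learning rate.
    """
    if len(data.train_idx) == 0:
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_params = copy.deepcopy(model.params)
    stale = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(data.train_idx)
        train_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            acc = None
            batch_loss = 0.0
            for i in batch:
                loss, grads = model.force_loss_and_grads(data.frames[i], data.targets[i])
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss on frame {i} (epoch {epoch})")
                batch_loss += loss
                if acc is None:
                    acc = [g.copy() for g in grads]
                else:
                    for a, g in zip(acc, grads):
                        a += g
            nb = len(batch)
            opt.step([a / nb for a in acc])
            train_losses.append(batch_loss / nb)
        val = _dataset_loss(model, data, data.val_idx)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(train_losses)),
                "val_loss": val,
                "lr": opt.lr,
            }
        )
        if np.isfinite(val) and val < best_val - 1e-12:
            best_val = val
            best_params = copy.deepcopy(model.params)
            stale = 0
        else:
            stale += 1
            if stale % cfg.patience == 0:
                opt.lr = max(opt.lr * cfg.lr_decay, cfg.min_lr)
            if stale >= cfg.early_stop_patience:
                break
    # keep the best-validation checkpoint
    if len(data.val_idx):
        for p, b in zip(model.params, best_params):
            p[...] = b
    return model, history


def force_rmse(model, prior, topo, frames: list[CGFrame]) -> float:
    """Root-mean-square force error per component of prior + model against
    the mapped forces carried by the frames (kcal/mol/A)."""
    from cglipid.potential import total_force_field

    sq, count = 0.0, 0
    for frame in frames:
        if frame.forces is None:
            raise ValueError("frame carries no mapped forces")
        f = total_force_field(frame, topo, prior, model)
        sq += float(np.sum((frame.forces - f) ** 2))
        count += frame.forces.size
    return float(np.sqrt(sq / count))
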