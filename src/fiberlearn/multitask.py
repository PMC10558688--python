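"""Configurable multi-task training on fiber volumes.

One *trial configuration* fixes the data representation (full 3D volume or
three 2.5D slices at a chosen spacing, with optional downsampling,
augmentation and random erasing), the prior-integration level, the backbone
capacity, and the optimizer settings. Training minimizes an
uncertainty-weighted sum of per-output losses

    L = sum_i ( L_i / sigma_i^2 + log sigma_i )

with one learnable sigma per labelled task and per auxiliary prior head;
missing labels are masked so they contribute exactly zero loss and gradient.
Early stopping watches a 10-epoch moving average of the total dev meta-loss
with a 50-epoch patience that only becomes active after epoch 75, so every
trial runs at least 125 epochs when the loss never improves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from fiberlearn import nn
from fiberlearn.io import FiberImage

REPRESENTATIONS = ("3D", "2.5D_1", "2.5D_5", "2.5D_10", "2.5D_20")
INTEGRATIONS = ("NoPriors", "AuxLosses", "Branches", "AuxLosses@Branches", "PriorsOnly")
CAPACITIES = (1, 2, 3, 4, 5, 6)
OPTIMIZERS = ("sgd", "adam")
BATCH_SIZES = (4, 8, 16)
DOWNSAMPLED_SPACING = 0.75  # µm
MOVING_AVERAGE_WINDOW = 10
PATIENCE_EPOCHS = 50
WARMUP_EPOCHS = 75

# backbone channel plans; parameter count strictly increases with capacity
CAPACITY_CHANNELS = {
    1: (8, 16),
    2: (10, 20),
    3: (12, 24),
    4: (12, 24, 32),
    5: (16, 32, 40),
    6: (16, 32, 48),
}


@dataclass(frozen=True)
class TrialConfiguration:
    """One point in the joint configuration space."""

    contrast_enhancement: bool = False
    downsample: bool = False
    augment: bool = False
    random_erasing: bool = False
    representation: str = "2.5D_5"
    prior_integration: str = "NoPriors"
    capacity: int = 1
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 8
    gradient_clipping: bool = False
    imbalance_sampling: bool = False

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.prior_integration not in INTEGRATIONS:
            raise ValueError(f"unknown prior integration {self.prior_integration!r}")
        if self.capacity not in CAPACITIES:
            raise ValueError(f"capacity must be in {CAPACITIES}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if self.batch_size not in BATCH_SIZES:
            raise ValueError(f"batch size must be in {BATCH_SIZES}")
        if not 1e-5 <= self.learning_rate <= 1e-1:
            raise ValueError("learning rate outside sane range")

    @property
    def slice_offset_um(self) -> float | None:
        if self.representation.startswith("2.5D"):
            return float(self.representation.split("_")[1])
        return None

    def as_dict(self) -> dict:
        return {
            "contrast_enhancement": self.contrast_enhancement,
            "downsample": self.downsample,
            "augment": self.augment,
            "random_erasing": self.random_erasing,
            "representation": self.representation,
            "prior_integration": self.prior_integration,
            "capacity": self.capacity,
            "optimizer": self.optimizer,
            "learning_rate": self.learning_rate,
            "momentum": self.momentum,
            "batch_size": self.batch_size,
            "gradient_clipping": self.gradient_clipping,
            "imbalance_sampling": self.imbalance_sampling,
        }


def slice_indices(center: int, offset_um: float, spacing: float, n: int) -> list[int]:
    """Indices of the center slice and the two peripheral slices, clamped."""
    off = int(round(offset_um / spacing))
    return [int(np.clip(center - off, 0, n - 1)), center,
            int(np.clip(center + off, 0, n - 1))]


def build_representation(img: FiberImage, config: TrialConfiguration) -> np.ndarray:
    """Model input tensor: (1, D, H, W) for 3D, (3, H, W) for 2.5D."""
    voxels = np.asarray(img.voxels, dtype=np.float64)
    spacing = img.spacing
    if config.downsample:
        zoom = tuple(s / DOWNSAMPLED_SPACING for s in spacing)
        voxels = ndimage.zoom(voxels, zoom, order=1, mode="nearest", grid_mode=True)
        spacing = (DOWNSAMPLED_SPACING,) * 3
    if config.representation == "3D":
        return voxels[None]
    center = voxels.shape[0] // 2
    idx = slice_indices(center, config.slice_offset_um, spacing[0], voxels.shape[0])
    return voxels[idx]


def augment_input(x: np.ndarray, config: TrialConfiguration,
                  rng: np.random.Generator) -> np.ndarray:
    """Randomized flips, small rotations, shifts, noise, and random erasing.

    Applied to train inputs only; a fixed generator state gives identical
    output.
    """
    out = x.copy()
    spatial = out.shape[1:]
    if config.augment:
        # flips along each spatial axis
        for ax in range(1, out.ndim):
            if rng.random() < 0.5:
                out = np.flip(out, axis=ax)
        angle = rng.uniform(-10, 10)
        out = ndimage.rotate(out, angle, axes=(out.ndim - 2, out.ndim - 1),
                             reshape=False, order=1, mode="nearest")
        shift = [0.0] + [rng.uniform(-2, 2) for _ in spatial]
        out = ndimage.shift(out, shift, order=1, mode="nearest")
        out = out + rng.normal(0, 0.05 * (np.std(out) + 1e-9), out.shape)
    if config.random_erasing:
        n_rects = int(rng.integers(1, 4))
        for _ in range(n_rects):
            frac = rng.uniform(0.02, 0.10)
            # rectangle with the requested fractional volume, aspect jittered
            dims = []
            remaining = frac
            for k, s in enumerate(spatial):
                if k == len(spatial) - 1:
                    side = remaining ** 1.0
                else:
                    side = rng.uniform(remaining ** (1 / (len(spatial) - k)), 1.0)
                dims.append(max(1, int(round(side * s))))
                remaining = remaining / max(side, 1e-9)
            starts = [int(rng.integers(0, max(1, s - d + 1)))
                      for s, d in zip(spatial, dims)]
            sl = (slice(None),) + tuple(slice(a, a + d) for a, d in zip(starts, dims))
            out[sl] = 0.0
    return np.ascontiguousarray(out)


class FiberNet(nn.Module):
    """Compact convolutional backbone with task heads and prior integration.

    A strided-conv pyramid (2D for slice inputs, 3D for volumes) feeds a
    global-average-pooled feature vector. Task heads are always present;
    auxiliary prior-regression heads exist for AuxLosses(@Branches); the prior
    values are concatenated into the final fully connected layer for
    Branches/AuxLosses@Branches.
    """

    def __init__(self, config: TrialConfiguration, n_tasks: int, n_priors: int,
                 in_channels: int | None = None, seed: int = 0):
        if config.prior_integration == "PriorsOnly":
            raise ValueError("PriorsOnly configurations do not build a network")
        rng = np.random.default_rng(seed)
        self.config = config
        self.nd = 3 if config.representation == "3D" else 2
        if in_channels is None:
            in_channels = 1 if self.nd == 3 else 3
        channels = CAPACITY_CHANNELS[config.capacity]
        self.blocks = []
        c_prev = in_channels
        for c in channels:
            self.blocks.append(nn.ConvBlock(c_prev, c, rng, nd=self.nd))
            c_prev = c
        self.use_aux = config.prior_integration in ("AuxLosses", "AuxLosses@Branches")
        self.use_branch = config.prior_integration in ("Branches", "AuxLosses@Branches")
        self.n_tasks = n_tasks
        self.n_priors = n_priors
        n_features = c_prev + (n_priors if self.use_branch else 0)
        n_out = n_tasks + (n_priors if self.use_aux else 0)
        self.head = nn.Linear(n_features, n_out, rng)

    @property
    def n_outputs(self) -> int:
        return self.n_tasks + (self.n_priors if self.use_aux else 0)

    def __call__(self, x: nn.Tensor, priors: nn.Tensor | None = None) -> nn.Tensor:
        h = x
        for block in self.blocks:
            h = block(h)
        feats = nn.global_avg_pool(h)
        if self.use_branch:
            if priors is None:
                raise ValueError("branch integration requires prior inputs")
            feats = nn.concat([feats, priors], axis=1)
        return self.head(feats)


def build_model(config: TrialConfiguration, n_tasks: int, n_priors: int,
                seed: int = 0) -> FiberNet:
    return FiberNet(config, n_tasks, n_priors, seed=seed)


@dataclass
class LossWeights:
    """Learnable log(sigma) per model output (tasks then aux prior heads)."""

    log_sigma: nn.Tensor

    @classmethod
    def create(cls, n_outputs: int) -> "LossWeights":
        return cls(log_sigma=nn.Tensor(np.zeros(n_outputs), requires_grad=True))

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.log_sigma.data)


def masked_uncertainty_loss(
    predictions: nn.Tensor,
    targets: np.ndarray,
    mask: np.ndarray,
    weights: LossWeights,
    kinds: list[str],
) -> nn.Tensor:
    """Uncertainty-weighted multi-task loss with exact masking.

    Per output: binary heads use logit BCE, continuous heads squared error,
    each averaged over the unmasked samples of the batch; the total is
    ``sum_k L_k / sigma_k^2 + log sigma_k`` over outputs with at least one
    unmasked sample. Masked entries contribute exactly zero value and
    gradient. With everything masked the loss is the zero scalar.
    """
    n, k = predictions.shape
    if targets.shape != (n, k) or mask.shape != (n, k):
        raise ValueError("predictions, targets and mask shapes must align")
    targets = np.where(mask, np.nan_to_num(targets), 0.0)
    total: nn.Tensor | None = None
    for j in range(k):
        mcol = mask[:, j].astype(np.float64)
        count = mcol.sum()
        if count == 0:
            continue
        pred_j = predictions[:, j]
        t_j = targets[:, j]
        if kinds[j] == "binary":
            # logit BCE: softplus(z) - t z, stable for both signs
            per = pred_j.softplus() - pred_j * t_j
        else:
            per = (pred_j - t_j) ** 2
        loss_j = (per * mcol).sum() * (1.0 / count)
        ls_j = weights.log_sigma[j]
        term = loss_j * (ls_j * (-2.0)).exp() + ls_j
        total = term if total is None else total + term
    if total is None:
        return nn.Tensor(0.0)
    return total


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Pairwise-concordance AUC with ties counted 0.5; NaN if single-class."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return math.nan
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def r_squared(targets: np.ndarray, predictions: np.ndarray) -> float:
    targets = np.asarray(targets, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if len(targets) < 2:
        return math.nan
    ss_tot = ((targets - targets.mean()) ** 2).sum()
    if ss_tot == 0:
        return math.nan
    ss_res = ((targets - predictions) ** 2).sum()
    return float(1.0 - ss_res / ss_tot)


def evaluate_metrics(
    predictions: np.ndarray,
    targets: np.ndarray,
    mask: np.ndarray,
    kinds: list[str],
    task_names: list[str],
) -> dict[str, float]:
    """Per-task dev metric: AUC (classification) or R² (regression).

    Tasks with fewer than 2 labelled samples, or a single class, are excluded
    (NaN) with a warning.
    """
    import warnings

    out: dict[str, float] = {}
    for j, name in enumerate(task_names):
        sel = mask[:, j]
        if sel.sum() < 2:
            warnings.warn(f"task {name!r}: fewer than 2 labelled samples")
            out[name] = math.nan
            continue
        t = targets[sel, j]
        p = predictions[sel, j]
        if kinds[j] == "binary":
            value = roc_auc(t, 1.0 / (1.0 + np.exp(-np.clip(p, -500, 500))))
            if math.isnan(value):
                warnings.warn(f"task {name!r}: single-class, AUC undefined")
        else:
            value = r_squared(t, p)
        out[name] = value
    return out


def meta_losses_from_metrics(metrics: dict[str, float]) -> dict[str, float]:
    """Dev metric -> minimized meta-loss: 1 − AUC or 1 − R²."""
    return {k: (math.nan if math.isnan(v) else 1.0 - v) for k, v in metrics.items()}


def total_meta_loss(meta: dict[str, float], weights: dict[str, float] | None) -> float:
    """Weighted sum of finite per-task meta-losses."""
    total = 0.0
    any_term = False
    for k, v in meta.items():
        if math.isnan(v):
            continue
        w = 1.0 if weights is None else weights.get(k, 1.0)
        total += w * v
        any_term = True
    return total if any_term else math.nan


class TrainState:
    """Early-stopping bookkeeping on the smoothed total dev meta-loss.

    ``record`` returns True when training should stop: no strict new minimum
    of the 10-epoch moving average for 50 consecutive epochs, with the
    criterion inactive before epoch 75 — a never-improving sequence therefore
    runs exactly 125 epochs.
    """

    def __init__(self, window: int = MOVING_AVERAGE_WINDOW,
                 patience: int = PATIENCE_EPOCHS, warmup: int = WARMUP_EPOCHS):
        self.window = window
        self.patience = patience
        self.warmup = warmup
        self.history: list[float] = []
        self.smoothed: list[float] = []
        self.best_smoothed = math.inf
        self.best_epoch = 0
        self.stopped_epoch: int | None = None

    @property
    def epoch(self) -> int:
        return len(self.history)

    def record(self, total_meta: float) -> bool:
        self.history.append(total_meta)
        tail = self.history[-self.window:]
        smoothed = float(np.mean(tail))
        self.smoothed.append(smoothed)
        epoch = self.epoch  # 1-based
        if smoothed < self.best_smoothed:
            self.best_smoothed = smoothed
            self.best_epoch = epoch
        stalled_since = max(self.best_epoch, self.warmup)
        if epoch > self.warmup and epoch - stalled_since >= self.patience:
            self.stopped_epoch = epoch
            return True
        return False


@dataclass
class TrainResult:
    state: TrainState
    model: FiberNet
    weights: LossWeights
    dev_metrics_history: list[dict[str, float]]
    best_snapshots: dict[str, list]  # per task + "__total__"
    best_metrics: dict[str, float]
    best_meta: dict[str, float]
    best_total_meta: float
    failed: bool = False
    epochs_run: int = 0


def _predict(model: FiberNet, inputs: np.ndarray, priors: np.ndarray | None,
             batch: int = 32) -> np.ndarray:
    outs = []
    for i in range(0, len(inputs), batch):
        x = nn.Tensor(inputs[i:i + batch])
        p = nn.Tensor(priors[i:i + batch]) if priors is not None else None
        outs.append(model(x, p).data)
    return np.concatenate(outs, axis=0)


def _sample_weights_for_imbalance(targets, mask, kinds) -> np.ndarray | None:
    """Inverse-class-frequency weights on the rarest-labelled binary task."""
    rare_j, rare_n = None, np.inf
    for j, kind in enumerate(kinds):
        if kind != "binary":
            continue
        n = mask[:, j].sum()
        if 0 < n < rare_n:
            rare_j, rare_n = j, n
    if rare_j is None:
        return None
    w = np.ones(len(targets))
    sel = mask[:, rare_j]
    if sel.sum() >= 2:
        vals = targets[sel, rare_j]
        p1 = vals.mean()
        if 0 < p1 < 1:
            w[sel] = np.where(vals == 1, 0.5 / p1, 0.5 / (1 - p1))
    return w / w.sum()


def train_trial(
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    train_mask: np.ndarray,
    train_priors: np.ndarray | None,
    dev_inputs: np.ndarray,
    dev_targets: np.ndarray,
    dev_mask: np.ndarray,
    dev_priors: np.ndarray | None,
    task_names: list[str],
    task_kinds: list[str],
    config: TrialConfiguration,
    budget: int = 200,
    seed: int = 0,
    task_weights: dict[str, float] | None = None,
    min_epochs_rule: bool = True,
) -> TrainResult:
    """Full training loop for one trial configuration.

    ``train_inputs``/``dev_inputs`` are stacked representation tensors (the
    output of :func:`build_representation`), targets/masks are (N, n_tasks +
    n_aux) with auxiliary prior columns appended when the integration uses
    AuxLosses. Deterministic for fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_tasks = len(task_names)
    n_aux = train_targets.shape[1] - n_tasks
    model = FiberNet(config, n_tasks, n_aux if n_aux > 0 else (
        train_priors.shape[1] if train_priors is not None else 0),
        in_channels=train_inputs.shape[1], seed=seed)
    weights = LossWeights.create(train_targets.shape[1])
    kinds_all = list(task_kinds) + ["continuous"] * n_aux

    params = model.parameters() + [weights.log_sigma]
    if config.optimizer == "sgd":
        opt = nn.SGD(params, lr=config.learning_rate, momentum=config.momentum)
    else:
        opt = nn.Adam(params, lr=config.learning_rate)

    accum_steps = 1
    if config.representation == "3D" and config.batch_size < 8:
        accum_steps = math.ceil(8 / config.batch_size)

    sample_p = (_sample_weights_for_imbalance(train_targets, train_mask, kinds_all)
                if config.imbalance_sampling else None)

    state = TrainState() if min_epochs_rule else TrainState(warmup=0, patience=PATIENCE_EPOCHS)
    n_train = len(train_inputs)
    dev_history: list[dict[str, float]] = []
    best_snapshots: dict[str, list] = {}
    best_task_meta = {t: math.inf for t in task_names}
    best_metrics: dict[str, float] = {}
    best_meta: dict[str, float] = {}
    best_total = math.inf
    failed = False

    for epoch in range(1, budget + 1):
        if sample_p is not None:
            order = rng.choice(n_train, size=n_train, replace=True, p=sample_p)
        else:
            order = rng.permutation(n_train)
        micro = 0
        for start in range(0, n_train, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = train_inputs[idx]
            if config.augment or config.random_erasing:
                xb = np.stack([augment_input(x, config, rng) for x in xb])
            x = nn.Tensor(xb)
            p = nn.Tensor(train_priors[idx]) if (model.use_branch and train_priors
                                                 is not None) else None
            preds = model(x, p)
            loss = masked_uncertainty_loss(preds, train_targets[idx],
                                           train_mask[idx], weights, kinds_all)
            if not np.isfinite(loss.data):
                failed = True
                break
            if loss.requires_grad:
                if micro == 0:
                    opt.zero_grad()
                loss.backward(np.full_like(loss.data, 1.0 / accum_steps))
                micro += 1
                if micro >= accum_steps:
                    if config.gradient_clipping:
                        opt.clip_global_norm(1.0)
                    opt.step()
                    micro = 0
        if micro > 0 and not failed:
            if config.gradient_clipping:
                opt.clip_global_norm(1.0)
            opt.step()
        if failed:
            break

        dev_pred = _predict(model, dev_inputs,
                            dev_priors if model.use_branch else None)
        metrics = evaluate_metrics(dev_pred[:, :n_tasks], dev_targets[:, :n_tasks],
                                   dev_mask[:, :n_tasks], task_kinds, task_names)
        meta = meta_losses_from_metrics(metrics)
        total = total_meta_loss(meta, task_weights)
        dev_history.append(metrics)

        for t in task_names:
            if not math.isnan(meta[t]) and meta[t] < best_task_meta[t]:
                best_task_meta[t] = meta[t]
                best_snapshots[t] = model.state()
        if not math.isnan(total) and total < best_total:
            best_total = total
            best_snapshots["__total__"] = model.state()
            best_metrics = dict(metrics)
            best_meta = dict(meta)
        if state.record(total if not math.isnan(total) else math.inf):
            break

    return TrainResult(
        state=state, model=model, weights=weights,
        dev_metrics_history=dev_history, best_snapshots=best_snapshots,
        best_metrics=best_metrics, best_meta=best_meta,
        best_total_meta=best_total, failed=failed, epochs_run=state.epoch,
    )
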