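"""VNC-Net: a 2D U-Net that maps contrast-enhanced CT slices to virtual
non-contrast slices.

The network sees min-max-normalised inputs: HU are clamped to
``[-1024, 3071]``, shifted by +1024 onto a 0-4095 scale and divided by 4095.
Training minimises pixel-wise MSE with Adam (batch 20, learning rate 1e-4,
300 epochs by default). Center-crop augmentation — crop the central part of
a slice and resize it back — is applied to a seeded 10% subset of the
training data by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, RegressorMixin

from .image import CTImage, clamp_hu
from .nn import Adam, MSELoss, UNet

HU_OFFSET = 1024.0
HU_SCALE = 4095.0


def normalize_hu(values):
    """Clamp to [-1024, 3071], then map to [0, 1] via (HU + 1024) / 4095."""
    return ((clamp_hu(np.asarray(values, dtype=np.float32)) + HU_OFFSET) / HU_SCALE).astype(np.float32)


def denormalize_hu(values):
    """Exact inverse of :func:`normalize_hu` on its range."""
    return np.asarray(values, dtype=np.float32) * HU_SCALE - HU_OFFSET


@dataclass
class UNetConfig:
    """Architecture hyper-parameters of VNC-Net.

    The encoder widths double per stage (32..256); the bottleneck continues
    the doubling pattern to 512 but is configurable.
    """

    encoder_channels: tuple = (32, 64, 128, 256)
    bottleneck_channels: int = 512
    input_channels: int = 1
    output_channels: int = 1

    def __post_init__(self):
        self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
        if any(b <= a for a, b in zip(self.encoder_channels, self.encoder_channels[1:])):
            raise ValueError("encoder_channels must be strictly increasing")

    @property
    def depth(self) -> int:
        return len(self.encoder_channels)


@dataclass
class TrainConfig:
    """Optimisation hyper-parameters (MSE loss, Adam with default moments)."""

    batch_size: int = 20
    learning_rate: float = 1e-4
    epochs: int = 300
    rng_seed: int = 0
    augment_fraction: float = 0.10
    lr_schedule: str = "constant"  # or "cosine" (decay to 0 over the run)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0.0 <= self.augment_fraction <= 1.0:
            raise ValueError("augment_fraction must lie in [0, 1]")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")


@dataclass
class PairedSliceDataset:
    """Normalised (input, target) slice pairs with augmentation bookkeeping.

    ``inputs`` and ``targets`` are ``(n, H, W)`` arrays in [0, 1];
    ``augmented_flags`` marks slices appended by augmentation.
    """

    inputs: np.ndarray
    targets: np.ndarray
    augmented_flags: np.ndarray = field(default=None)

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=np.float32)
        self.targets = np.asarray(self.targets, dtype=np.float32)
        if self.inputs.shape != self.targets.shape:
            raise ValueError("inputs and targets must have identical shapes")
        if self.inputs.min() < 0.0 or self.inputs.max() > 1.0:
            raise ValueError("dataset values must be normalised to [0, 1]")
        if self.augmented_flags is None:
            self.augmented_flags = np.zeros(len(self.inputs), dtype=bool)
        self.augmented_flags = np.asarray(self.augmented_flags, dtype=bool)

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @classmethod
    def from_hu(cls, input_slices, target_slices) -> "PairedSliceDataset":
        """Build a dataset from HU-valued slice stacks."""
        return cls(normalize_hu(input_slices), normalize_hu(target_slices))


def _center_crop_resize(slices: np.ndarray, crop_ratio: float) -> np.ndarray:
    """Crop the central ``crop_ratio`` of each slice and resize back."""
    n, h, w = slices.shape
    ch, cw = max(1, int(round(h * crop_ratio))), max(1, int(round(w * crop_ratio)))
    r0, c0 = (h - ch) // 2, (w - cw) // 2
    rows = r0 + (np.arange(h) + 0.5) * ch / h - 0.5
    cols = c0 + (np.arange(w) + 0.5) * cw / w - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.empty_like(slices)
    for i in range(n):
        out[i] = ndimage.map_coordinates(slices[i].astype(np.float64), [rr, cc],
                                         order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def augment_center_crop(dataset: PairedSliceDataset, fraction: float = 0.10,
                        crop_ratio: float = 0.75, seed: int = 0) -> PairedSliceDataset:
    """Append crop-and-resize copies of a seeded random subset.

    ``floor(fraction * n)`` slices are drawn without replacement, centre
    cropped to ``crop_ratio`` of their extent, resized back, and appended;
    the originals are retained (6390 slices at 10% -> 7029).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if not 0.0 < crop_ratio <= 1.0:
        raise ValueError("crop_ratio must lie in (0, 1]")
    n_aug = int(np.floor(fraction * len(dataset)))
    if n_aug == 0:
        return PairedSliceDataset(dataset.inputs.copy(), dataset.targets.copy(),
                                  dataset.augmented_flags.copy())
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(dataset), size=n_aug, replace=False)
    aug_in = _center_crop_resize(dataset.inputs[chosen], crop_ratio)
    aug_tg = _center_crop_resize(dataset.targets[chosen], crop_ratio)
    return PairedSliceDataset(
        np.concatenate([dataset.inputs, aug_in]),
        np.concatenate([dataset.targets, aug_tg]),
        np.concatenate([dataset.augmented_flags, np.ones(n_aug, dtype=bool)]),
    )


def build_vncnet(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    """Instantiate the U-Net described by ``config`` with seeded weights."""
    config = config or UNetConfig()
    return UNet(
        in_channels=config.input_channels,
        out_channels=config.output_channels,
        encoder_channels=config.encoder_channels,
        bottleneck_channels=config.bottleneck_channels,
        seed=seed,
    )


class VNCNet(BaseEstimator, RegressorMixin):
    """Contrast-removal U-Net with a scikit-learn estimator surface.

    ``fit(X, y)`` takes HU-valued slice stacks ``(n, H, W)`` (contrast-
    enhanced inputs, non-contrast targets), normalises them, and runs
    seeded mini-batched MSE/Adam optimisation. ``predict(X)`` returns HU
    slices with the contrast removed. H and W must be divisible by
    ``2**depth`` (16 for the default depth-4 encoder).

    Fitted attributes
    -----------------
    model_ : the underlying network (final-epoch weights)
    history_ : dict with per-epoch ``train_loss`` (and ``val_loss``)
    best_val_state_ : weights of the best-validation epoch, when a
        validation set was supplied
    """

    def __init__(self, encoder_channels=(32, 64, 128, 256), bottleneck_channels=512,
                 batch_size=20, learning_rate=1e-4, epochs=300, rng_seed=0,
                 augment_fraction=0.0, crop_ratio=0.75, lr_schedule="constant"):
        self.encoder_channels = encoder_channels
        self.bottleneck_channels = bottleneck_channels
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.rng_seed = rng_seed
        self.augment_fraction = augment_fraction
        self.crop_ratio = crop_ratio
        self.lr_schedule = lr_schedule

    # -- training -------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        """Train on HU slice stacks; see class docstring."""
        ds = PairedSliceDataset.from_hu(np.asarray(X), np.asarray(y))
        val = None
        if validation_data is not None:
            val = PairedSliceDataset.from_hu(*validation_data)
        return self.fit_dataset(ds, validation=val)

    def fit_dataset(self, dataset: PairedSliceDataset, validation: PairedSliceDataset | None = None):
        """Train on an already-normalised :class:`PairedSliceDataset`."""
        if len(dataset) == 0:
            raise ValueError("training dataset is empty")
        cfg = TrainConfig(batch_size=self.batch_size, learning_rate=self.learning_rate,
                          epochs=self.epochs, rng_seed=self.rng_seed,
                          augment_fraction=self.augment_fraction,
                          lr_schedule=self.lr_schedule)
        if cfg.augment_fraction > 0:
            dataset = augment_center_crop(dataset, cfg.augment_fraction,
                                          self.crop_ratio, seed=cfg.rng_seed)
        config = UNetConfig(encoder_channels=tuple(self.encoder_channels),
                            bottleneck_channels=self.bottleneck_channels)
        self.config_ = config
        self.model_ = build_vncnet(config, seed=cfg.rng_seed)
        self.history_ = {"train_loss": [], "val_loss": []}
        self.best_val_state_ = None
        best_val = np.inf

        rng = np.random.default_rng(cfg.rng_seed + 1)
        loss_fn = MSELoss()
        optim = Adam(self.model_.roots(), lr=cfg.learning_rate)
        x_all = dataset.inputs[:, None]  # (n, 1, H, W)
        y_all = dataset.targets[:, None]
        n = len(dataset)
        warmup = min(2, cfg.epochs // 10) if cfg.lr_schedule == "cosine" else 0
        for epoch in range(cfg.epochs):
            if cfg.lr_schedule == "cosine":
                if epoch < warmup:
                    optim.lr = cfg.learning_rate * (epoch + 1) / (warmup + 1)
                else:
                    t = (epoch - warmup) / max(cfg.epochs - warmup, 1)
                    optim.lr = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * t))
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                pred = self.model_.forward(x_all[sel], training=True)
                loss = loss_fn.forward(pred, y_all[sel])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: loss={loss} at epoch "
                        f"{len(self.history_['train_loss'])}, batch {start // cfg.batch_size}"
                    )
                self.model_.backward(loss_fn.backward())
                optim.step()
                epoch_loss += loss * sel.size
                seen += sel.size
            self.history_["train_loss"].append(epoch_loss / seen)
            if validation is not None:
                vloss = self._eval_loss(validation)
                self.history_["val_loss"].append(vloss)
                if vloss < best_val:
                    best_val = vloss
                    self.best_val_state_ = self.model_.state_dict()
        if validation is None:
            self.history_.pop("val_loss")
        return self

    def _eval_loss(self, dataset: PairedSliceDataset) -> float:
        total, count = 0.0, 0
        for start in range(0, len(dataset), self.batch_size):
            xb = dataset.inputs[start:start + self.batch_size, None]
            yb = dataset.targets[start:start + self.batch_size, None]
            pred = self.model_.forward(xb, training=False)
            total += float(((pred - yb) ** 2).sum())
            count += pred.size
        return total / count

    # -- inference ------------------------------------------------------

    def predict(self, X):
        """Map HU slices ``(n, H, W)`` or a single ``(H, W)`` slice to VNC HU."""
        if not hasattr(self, "model_"):
            raise AttributeError("VNCNet is not fitted")
        arr = np.asarray(X, dtype=np.float32)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        norm = normalize_hu(arr)[:, None]
        out = np.empty_like(norm)
        for start in range(0, norm.shape[0], self.batch_size):
            out[start:start + self.batch_size] = self.model_.forward(
                norm[start:start + self.batch_size], training=False
            )
        hu = denormalize_hu(out[:, 0])
        return hu[0] if single else hu

    # -- persistence ----------------------------------------------------

    def save(self, path) -> None:
        """Store weights + architecture + normalisation constants (.npz)."""
        if not hasattr(self, "model_"):
            raise AttributeError("VNCNet is not fitted")
        meta = {
            "encoder_channels": list(self.config_.encoder_channels),
            "bottleneck_channels": self.config_.bottleneck_channels,
            "hu_offset": HU_OFFSET,
            "hu_scale": HU_SCALE,
            "params": self.get_params(),
        }
        state = {f"state/{k}": v for k, v in self.model_.state_dict().items()}
        np.savez(path, meta=json.dumps(meta), **state)

    @classmethod
    def load(cls, path) -> "VNCNet":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            state = {k[len("state/"):]: npz[k] for k in npz.files if k.startswith("state/")}
        est = cls(**{k: v for k, v in meta["params"].items()})
        est.config_ = UNetConfig(encoder_channels=tuple(meta["encoder_channels"]),
                                 bottleneck_channels=meta["bottleneck_channels"])
        est.model_ = build_vncnet(est.config_, seed=0)
        est.model_.load_state_dict(state)
        est.history_ = {"train_loss": []}
        return est


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def train(model: VNCNet, dataset: PairedSliceDataset, cfg: TrainConfig | None = None,
          validation: PairedSliceDataset | None = None):
    """Train ``model`` on ``dataset``; returns ``(model, history)``."""
    if cfg is not None:
        model.set_params(batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                         epochs=cfg.epochs, rng_seed=cfg.rng_seed,
                         augment_fraction=cfg.augment_fraction)
    model.fit_dataset(dataset, validation=validation)
    return model, model.history_


def predict(model: VNCNet, image: CTImage) -> CTImage:
    """Slice-wise VNC inference on a CTImage; geometry is preserved."""
    slices = image.voxels if image.ndim == 3 else image.voxels[None]
    out = model.predict(slices)
    out = out if image.ndim == 3 else out[0]
    result = image.with_voxels(out)
    result.domain_tag = "vnc"
    return result
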