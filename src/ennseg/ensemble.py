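"""Ensembles of independently trained binary-segmentation networks.

The segmentation model is an ensemble of M identical networks ("members"),
each trained independently with its own random initialization, its own
shuffle order of the training slices, and its own stream of random
augmentations. At inference every member predicts the same slice; the
sigmoid outputs are averaged voxelwise into a fused probability map and
rounded (threshold 0.5, ties to foreground) into the binary prediction.
The fused pre-rounding map is the voxelwise confidence that the
visualization and foreground-entropy confidence modules consume.

Default hyperparameters: M = 10 members, 20 epochs, batch size 64, SGD with
learning rate 0.1 and momentum 0.9, soft Dice loss. Per-member weights are
taken from the epoch with the best validation soft Dice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import CTSlice, MaskSlice
from .nn import SGDMomentum, TinyUNet, sigmoid, soft_dice_loss_grad, standardize_slice

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "EnsemblePrediction",
    "TrainedMember",
    "EnsembleModel",
    "member_seed",
    "augment",
    "soft_dice_loss",
    "fuse",
    "train_member",
    "train_ensemble",
    "predict_slice",
]

DEFAULT_AUGMENTATIONS = ("hflip", "vflip", "rotate", "intensity")


@dataclass(frozen=True)
class EnsembleConfig:
    """Training configuration; defaults follow the published protocol."""

    n_members: int = 10
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 0.1
    momentum: float = 0.9
    backbone: str = "tiny_unet"
    channels: int = 8
    augmentations: tuple[str, ...] = DEFAULT_AUGMENTATIONS
    rotation_degrees: float = 15.0
    intensity_jitter: tuple[float, float] = (0.9, 1.1)
    smooth: float = 1.0
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.backbone != "tiny_unet":
            raise ValueError(
                f"unknown backbone {self.backbone!r}; available: 'tiny_unet'"
            )
        unknown = set(self.augmentations) - set(DEFAULT_AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentations {sorted(unknown)}")


@dataclass
class EnsemblePrediction:
    """Per-member and fused outputs for one slice."""

    member_probs: np.ndarray  # (M, H, W)
    fused_prob: np.ndarray  # (H, W), mean over members
    binary_mask: np.ndarray  # (H, W) bool, fused_prob >= 0.5
    patient_id: str = ""
    slice_index: int = -1
    phase: str = "synthetic"


@dataclass
class TrainedMember:
    model: TinyUNet
    member_index: int
    seed_key: tuple[int, int]
    log: list[dict]  # per-epoch: epoch, train_loss, val_loss
    best_epoch: int


@dataclass
class EnsembleModel:
    members: list[TrainedMember]
    config: EnsembleConfig

    @property
    def n_members(self) -> int:
        return len(self.members)

    def save(self, out_dir: "str | Path") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "n_members": self.n_members,
            "config": _config_dict(self.config),
            "normalization": "per_slice_standardize",
            "members": [],
        }
        for m in self.members:
            fname = f"member_{m.member_index:02d}.npz"
            np.savez(out_dir / fname, **m.model.state_dict())
            (out_dir / f"member_{m.member_index:02d}_log.csv").write_text(
                "epoch,train_loss,val_loss\n"
                + "\n".join(
                    f"{r['epoch']},{r['train_loss']:.10f},{r['val_loss']:.10f}"
                    for r in m.log
                )
                + "\n"
            )
            manifest["members"].append(
                {
                    "file": fname,
                    "member_index": m.member_index,
                    "seed_key": list(m.seed_key),
                    "best_epoch": m.best_epoch,
                    "checksum": m.model.checksum(),
                }
            )
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, in_dir: "str | Path") -> "EnsembleModel":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "manifest.json").read_text())
        cfg_dict = dict(manifest["config"])
        for key in ("augmentations", "intensity_jitter"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = EnsembleConfig(**cfg_dict)
        members = []
        for entry in manifest["members"]:
            model = TinyUNet(channels=config.channels, rng=np.random.default_rng(0))
            with np.load(in_dir / entry["file"]) as state:
                model.load_state_dict({k: state[k] for k in state.files})
            members.append(
                TrainedMember(
                    model=model,
                    member_index=entry["member_index"],
                    seed_key=tuple(entry["seed_key"]),
                    log=[],
                    best_epoch=entry["best_epoch"],
                )
            )
        return cls(members=members, config=config)


def _config_dict(config: EnsembleConfig) -> dict:
    d = asdict(config)
    d["augmentations"] = list(d["augmentations"])
    d["intensity_jitter"] = list(d["intensity_jitter"])
    return d


def member_seed(base_seed: int, member_index: int) -> tuple[int, int]:
    """Deterministic per-member seed key; distinct members get distinct
    independent RNG streams via numpy's SeedSequence hashing."""
    return (int(base_seed), int(member_index))


def augment(
    pixels: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    ops: Sequence[str] = DEFAULT_AUGMENTATIONS,
    rotation_degrees: float = 15.0,
    intensity_jitter: tuple[float, float] = (0.9, 1.1),
) -> tuple[np.ndarray, np.ndarray]:
    """Random augmentation of one (image, mask) pair.

    Geometric transforms (flips, small rotation) are applied identically to
    image and mask; the mask stays strictly binary (nearest-neighbour
    resampling). Intensity jitter scales the image only.
    """
    img = np.asarray(pixels, dtype=np.float64)
    msk = np.asarray(mask).astype(bool)
    if "hflip" in ops and rng.random() < 0.5:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    if "vflip" in ops and rng.random() < 0.5:
        img = img[::-1, :]
        msk = msk[::-1, :]
    if "rotate" in ops:
        angle = rng.uniform(-rotation_degrees, rotation_degrees)
        if angle != 0.0:
            img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
            msk = ndimage.rotate(
                msk.astype(np.uint8), angle, reshape=False, order=0, mode="constant"
            ).astype(bool)
    if "intensity" in ops:
        img = img * rng.uniform(*intensity_jitter)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def soft_dice_loss(
    pred_prob: np.ndarray, target: "np.ndarray | MaskSlice", smooth: float = 1.0
) -> float:
    """Soft Dice loss 1 - (2 sum(pt) + s) / (sum(p^2) + sum(t^2) + s).

    Evaluated on probabilities in [0, 1] against a binary target; bounded in
    [0, 1] and, for binary predictions with smooth -> 0+, equal to
    1 - (hard) Dice.
    """
    if isinstance(target, MaskSlice):
        target = target.mask
    p = np.asarray(pred_prob, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("prediction/target shape mismatch")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    num = 2.0 * (p * t).sum() + smooth
    den = (p * p).sum() + (t * t).sum() + smooth
    return float(1.0 - num / den)


def fuse(
    member_probs: Sequence[np.ndarray],
    patient_id: str = "",
    slice_index: int = -1,
    phase: str = "synthetic",
) -> EnsemblePrediction:
    """Average member sigmoid outputs and round into the binary prediction.

    The fused map is the elementwise arithmetic mean (equal member weights);
    the binary mask is 1 exactly where the fused probability is >= 0.5
    (a tie at exactly 0.5 rounds to foreground).
    """
    if len(member_probs) < 1:
        raise ValueError("need at least one member probability map")
    maps = [np.asarray(m, dtype=np.float64) for m in member_probs]
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("member probability maps must share shape")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("member probabilities must lie in [0, 1]")
    stacked = np.stack(maps)
    fused = stacked.mean(axis=0)
    return EnsemblePrediction(
        member_probs=stacked,
        fused_prob=fused,
        binary_mask=fused >= 0.5,
        patient_id=patient_id,
        slice_index=slice_index,
        phase=phase,
    )


def _pairs_to_arrays(
    pairs: Sequence[tuple[CTSlice, MaskSlice]],
) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([standardize_slice(s.pixels) for s, _ in pairs])
    ys = np.stack([m.mask.astype(np.float64) for _, m in pairs])
    return xs, ys


def _per_sample_loss(model: TinyUNet, xs, ys, batch_size: int, smooth: float):
    losses = []
    for i in range(0, xs.shape[0], batch_size):
        p = model.predict_proba(xs[i : i + batch_size])
        t = ys[i : i + batch_size]
        num = 2.0 * (p * t).sum(axis=(1, 2)) + smooth
        den = (p * p).sum(axis=(1, 2)) + (t * t).sum(axis=(1, 2)) + smooth
        losses.extend((1.0 - num / den).tolist())
    return float(np.mean(losses))


def train_member(
    train_pairs: Sequence[tuple[CTSlice, MaskSlice]],
    val_pairs: Sequence[tuple[CTSlice, MaskSlice]],
    config: EnsembleConfig,
    member_index: int,
) -> TrainedMember:
    """Train one ensemble member.

    Diversity between members comes solely from the member-specific RNG
    stream (initial weights, shuffle order, augmentation draws); data and
    hyperparameters are identical. Returns the weights of the epoch with the
    best validation soft Dice loss (training loss if no validation slices
    are supplied) together with the full per-epoch loss log.
    """
    if len(train_pairs) == 0:
        raise ValueError("empty training set")
    if not 0 <= member_index < config.n_members:
        raise ValueError("member_index out of range")
    seed_key = member_seed(config.base_seed, member_index)
    rng = np.random.default_rng(np.random.SeedSequence(list(seed_key)))

    xs, ys = _pairs_to_arrays(train_pairs)
    xv, yv = _pairs_to_arrays(val_pairs) if len(val_pairs) else (None, None)

    model = TinyUNet(channels=config.channels, rng=rng)
    opt = SGDMomentum(config.learning_rate, config.momentum)
    n = xs.shape[0]
    log: list[dict] = []
    best = {"loss": np.inf, "epoch": -1, "state": model.state_dict()}

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            imgs, msks = [], []
            for j in idx:
                img, msk = augment(
                    xs[j],
                    ys[j],
                    rng,
                    config.augmentations,
                    config.rotation_degrees,
                    config.intensity_jitter,
                )
                imgs.append(img)
                msks.append(msk.astype(np.float64))
            xb = np.stack(imgs)
            yb = np.stack(msks)
            logits = model.forward(xb, train=True)
            loss, dlogits = soft_dice_loss_grad(logits, yb, config.smooth)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"member {member_index}: non-finite loss at epoch {epoch}"
                )
            grads = model.backward(dlogits)
            opt.step(model.params, grads)
            batch_losses.append(loss)
        train_loss = float(np.mean(batch_losses))
        if xv is not None:
            val_loss = _per_sample_loss(model, xv, yv, config.batch_size, config.smooth)
        else:
            val_loss = train_loss
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best["loss"]:
            best = {"loss": val_loss, "epoch": epoch, "state": model.state_dict()}

    model.load_state_dict(best["state"])
    logger.info(
        "member %d: best epoch %d (val loss %.4f)",
        member_index,
        best["epoch"],
        best["loss"],
    )
    return TrainedMember(
        model=model,
        member_index=member_index,
        seed_key=seed_key,
        log=log,
        best_epoch=int(best["epoch"]),
    )


def train_ensemble(
    train_pairs: Sequence[tuple[CTSlice, MaskSlice]],
    val_pairs: Sequence[tuple[CTSlice, MaskSlice]],
    config: EnsembleConfig,
) -> EnsembleModel:
    """Train all M members independently (sequentially, deterministic)."""
    members = [
        train_member(train_pairs, val_pairs, config, k)
        for k in range(config.n_members)
    ]
    return EnsembleModel(members=members, config=config)


def predict_slice(ensemble: EnsembleModel, ct_slice: CTSlice) -> EnsemblePrediction:
    """Run every member on the same standardized slice and fuse the outputs."""
    x = standardize_slice(ct_slice.pixels)[None]
    probs = [m.model.predict_proba(x)[0] for m in ensemble.members]
    return fuse(
        probs,
        patient_id=ct_slice.patient_id,
        slice_index=ct_slice.slice_index,
        phase=ct_slice.phase,
    )


def predict_slices(
    ensemble: EnsembleModel, slices: Sequence[CTSlice], batch_size: int = 32
) -> list[EnsemblePrediction]:
    """Batched inference over many slices (same fusion as predict_slice)."""
    preds: list[EnsemblePrediction] = []
    for i in range(0, len(slices), batch_size):
        chunk = slices[i : i + batch_size]
        x = np.stack([standardize_slice(s.pixels) for s in chunk])
        member_out = np.stack([m.model.predict_proba(x) for m in ensemble.members])
        for j, s in enumerate(chunk):
            preds.append(
                fuse(
                    list(member_out[:, j]),
                    patient_id=s.patient_id,
                    slice_index=s.slice_index,
                    phase=s.phase,
                )
            )
    return preds
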