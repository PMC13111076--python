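"""Training, evaluation and prediction pipeline.

Protocol: SGD (momentum 0.9, weight decay 5e-4), initial learning rate
0.01 with per-iteration polynomial decay of exponent 0.9, Dice loss with
equal-weight deep supervision over the four decoder heads, inputs resized
to a fixed square size, random horizontal flips, and per-channel
normalisation with the ImageNet statistics (grayscale frames are
replicated to three channels first).

One master seed fans out to weight initialisation, data ordering and
augmentation so a run is reproducible end to end in single-threaded mode.
"""

from __future__ import annotations

import csv as _csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import nn
from .decoder import RTSNet, build_model
from .errors import ConfigurationError, DatasetError
from .metrics import MetricsReport, evaluate_metrics, total_loss
from .phantom import PhantomConfig, generate_phantom

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    poly_power: float = 0.9
    image_size: int = 224
    batch_size: int = 8
    max_iterations: int = 20000
    hflip_prob: float = 0.5
    mean: tuple[float, float, float] = IMAGENET_MEAN
    std: tuple[float, float, float] = IMAGENET_STD
    seed: int = 0
    variant: str = "b2"

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ConfigurationError("lr0 must be positive")
        if self.poly_power <= 0:
            raise ConfigurationError("poly_power must be positive")
        if self.image_size % 32:
            raise ConfigurationError("image_size must be a multiple of 32")
        if self.batch_size < 1 or self.max_iterations < 1:
            raise ConfigurationError("batch_size and max_iterations must be "
                                     ">= 1")

    # -- flat key/value round-trip ---------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mean"] = list(self.mean)
        d["std"] = list(self.std)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        for k in ("mean", "std"):
            if k in d:
                d[k] = tuple(float(v) for v in d[k])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def poly_lr(t: int, T: int, config: TrainConfig) -> float:
    """Polynomial decay ``lr0 * (1 - t/T)**power`` indexed per iteration."""
    if not (0 <= t <= T):
        raise ValueError(f"iteration {t} outside [0, {T}]")
    return config.lr0 * (1.0 - t / T) ** config.poly_power


# --------------------------------------------------------------------------
# data
# --------------------------------------------------------------------------

@dataclass
class SegDataset:
    """Paired raw images (float [0,1]) and binary masks at a fixed size."""
    images: np.ndarray                 # (M, S, S) float32 in [0, 1]
    masks: np.ndarray                  # (M, S, S) uint8 in {0, 1}
    stems: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.images.shape[0]


def _resize(arr: np.ndarray, size: int, nearest: bool) -> np.ndarray:
    img = Image.fromarray(arr)
    img = img.resize((size, size),
                     Image.NEAREST if nearest else Image.BILINEAR)
    return np.asarray(img)


def load_dataset(root, split: str | None = None,
                 image_size: int = 224) -> SegDataset:
    """Read an images/ + masks/ directory pair with matching stems.

    Images are resized bilinearly, masks with nearest neighbour and
    binarised at >127.  Ordering is deterministic (sorted stems).
    """
    base = Path(root)
    if split is not None and (base / split / "images").is_dir():
        base = base / split
    img_dir, msk_dir = base / "images", base / "masks"
    if not img_dir.is_dir() or not msk_dir.is_dir():
        raise DatasetError(f"dataset root {base} must contain images/ and "
                           f"masks/")
    img_stems = {p.stem: p for p in sorted(img_dir.iterdir())
                 if p.suffix.lower() in (".png", ".bmp")}
    msk_stems = {p.stem: p for p in sorted(msk_dir.iterdir())
                 if p.suffix.lower() in (".png", ".bmp")}
    orphans = sorted(set(img_stems) ^ set(msk_stems))
    if orphans:
        raise DatasetError(f"unpaired stems in {base}: {orphans}")
    images, masks, stems = [], [], []
    for stem in sorted(img_stems):
        im = np.asarray(Image.open(img_stems[stem]).convert("L"))
        mk = np.asarray(Image.open(msk_stems[stem]).convert("L"))
        images.append(_resize(im, image_size, nearest=False)
                      .astype(np.float32) / 255.0)
        masks.append((_resize(mk, image_size, nearest=True) > 127)
                     .astype(np.uint8))
        stems.append(stem)
    if not images:
        return SegDataset(images=np.zeros((0, image_size, image_size),
                                          np.float32),
                          masks=np.zeros((0, image_size, image_size),
                                         np.uint8), stems=[])
    return SegDataset(images=np.stack(images), masks=np.stack(masks),
                      stems=stems)


def phantom_dataset(config: PhantomConfig, n: int,
                    image_size: int | None = None) -> SegDataset:
    """Generate ``n`` phantoms directly into memory (sample ``i`` uses seed
    ``config.seed + i``, matching :func:`rtsnet.phantom.write_dataset`)."""
    size = image_size or config.image_size
    cfg = dataclasses.replace(config, image_size=size)
    imgs, msks, stems = [], [], []
    for i in range(n):
        s = generate_phantom(dataclasses.replace(cfg, seed=cfg.seed + i))
        imgs.append(s.image)
        msks.append(s.mask)
        stems.append(f"phantom_{i:04d}")
    if not imgs:
        return SegDataset(images=np.zeros((0, size, size), np.float32),
                          masks=np.zeros((0, size, size), np.uint8), stems=[])
    return SegDataset(images=np.stack(imgs), masks=np.stack(msks),
                      stems=stems)


def normalize_image(gray: np.ndarray, config: TrainConfig) -> np.ndarray:
    """Replicate a grayscale [0,1] frame to 3 channels and normalise."""
    mean = np.asarray(config.mean, np.float32).reshape(3, 1, 1)
    std = np.asarray(config.std, np.float32).reshape(3, 1, 1)
    x3 = np.repeat(gray[None].astype(np.float32), 3, axis=0)
    return (x3 - mean) / std


def augment(image: np.ndarray, mask: np.ndarray, config: TrainConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Jointly flip image and mask left-right with ``hflip_prob``, then
    normalise the image only. ``image`` is grayscale (H, W) in [0, 1]."""
    if rng.random() < config.hflip_prob:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    return normalize_image(image, config), mask


# --------------------------------------------------------------------------
# run log / checkpoints
# --------------------------------------------------------------------------

@dataclass
class RunLog:
    losses: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    val_history: list[dict] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["iteration", "loss", "lr"])
            for i, (l, r) in enumerate(zip(self.losses, self.lrs)):
                w.writerow([i, repr(l), repr(r)])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "config": self.config,
             "losses": self.losses, "lrs": self.lrs,
             "val_history": self.val_history}, indent=2))


def save_checkpoint(path, model: RTSNet, config: TrainConfig) -> None:
    """Flat name->array archive plus the full resolved config."""
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[RTSNet, TrainConfig]:
    with np.load(path) as z:
        config = TrainConfig.from_dict(
            json.loads(bytes(z["__config__"]).decode()))
        state = {k[len("param/"):]: z[k] for k in z.files if
                 k.startswith("param/")}
    model = build_model(config.variant)
    model.load_state_dict(state)
    return model, config


# --------------------------------------------------------------------------
# fit / evaluate / predict
# --------------------------------------------------------------------------

def _forward_batch(model: RTSNet, images: np.ndarray):
    return model(nn.Tensor(np.ascontiguousarray(images, dtype=np.float32)))


def fit(config: TrainConfig, train_data: SegDataset, val_data: SegDataset
        | None = None, out_dir=None,
        val_every: int | None = None) -> tuple[RTSNet, RunLog]:
    """Train from scratch under the stated protocol.

    ``val_every`` (iterations) defaults to one epoch.  The checkpoint kept
    is the one with the best validation IoU (mean per image); with no
    validation data the final model is kept.  Raises on divergence
    (non-finite loss).
    """
    if len(train_data) == 0:
        raise DatasetError("training data is empty")
    nn.seed_all(config.seed)                    # weight initialisation stream
    model = build_model(config.variant)
    order_rng = np.random.default_rng(config.seed + 1)
    aug_rng = np.random.default_rng(config.seed + 2)
    nn.seed_all(config.seed + 3)                # drop-path stream
    opt = nn.SGD(model.parameters(), momentum=config.momentum,
                 weight_decay=config.weight_decay)
    T = config.max_iterations
    M = len(train_data)
    per_epoch = max(1, (M + config.batch_size - 1) // config.batch_size)
    val_every = val_every or per_epoch
    log = RunLog(seed=config.seed, config=config.to_dict())
    best_iou, best_state = -1.0, None
    t = 0
    while t < T:
        perm = order_rng.permutation(M)
        for b0 in range(0, M, config.batch_size):
            if t >= T:
                break
            idx = perm[b0:b0 + config.batch_size]
            xs, ys = [], []
            for j in idx:
                xi, yi = augment(train_data.images[j], train_data.masks[j],
                                 config, aug_rng)
                xs.append(xi)
                ys.append(yi)
            x = np.stack(xs)
            y = np.stack(ys)[:, None].astype(np.float32)
            model.train()
            out = _forward_batch(model, x)
            loss = total_loss(out, nn.Tensor(y))
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"training diverged at iteration {t}: loss={lval}")
            lr = poly_lr(t, T, config)
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            log.losses.append(lval)
            log.lrs.append(lr)
            t += 1
            if val_data is not None and len(val_data) and \
                    (t % val_every == 0 or t == T):
                report = evaluate(model, val_data, config)
                entry = {"iteration": t,
                         "val_iou": report.aggregates["mean_per_image"]["iou"],
                         "val_dice": report.aggregates["mean_per_image"]["dice"]}
                log.val_history.append(entry)
                if entry["val_iou"] > best_iou:
                    best_iou = entry["val_iou"]
                    best_state = {k: v.copy() for k, v in
                                  model.state_dict().items()}
    if best_state is not None:
        model.load_state_dict(best_state)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out / "checkpoint.npz", model, config)
        log.to_csv(out / "runlog.csv")
        log.to_json(out / "runlog.json")
    return model, log


def predict(model: RTSNet, data: SegDataset, config: TrainConfig,
            batch_size: int | None = None) -> list[np.ndarray]:
    """Fused probability maps for every sample, in dataset order."""
    model.eval()
    bs = batch_size or config.batch_size
    out = []
    with nn.no_grad():
        for b0 in range(0, len(data), bs):
            x = np.stack([normalize_image(im, config)
                          for im in data.images[b0:b0 + bs]])
            prob = _forward_batch(model, x).fused_probability.data
            out.extend(prob[:, 0])
    return out


def evaluate(model_or_checkpoint, data: SegDataset,
             config: TrainConfig | None = None) -> MetricsReport:
    """Forward passes in evaluation mode, threshold 0.5, full report with
    both aggregation modes."""
    if isinstance(model_or_checkpoint, (str, Path)):
        model, config = load_checkpoint(model_or_checkpoint)
    else:
        model = model_or_checkpoint
        if config is None:
            raise ConfigurationError("evaluate needs a TrainConfig when "
                                     "given a model instance")
    if len(data) == 0:
        raise DatasetError("evaluation data is empty")
    scores = predict(model, data, config)
    return evaluate_metrics(scores, list(data.masks))


def all_foreground_baseline(data: SegDataset) -> MetricsReport:
    """Reference scorer that marks every pixel foreground."""
    ones = [np.ones_like(m, dtype=np.float64) for m in data.masks]
    return evaluate_metrics(ones, list(data.masks))
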