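"""Training and inference driver.

Defaults mirror the reference recipe: SGD (momentum 0.937, weight
decay 5e-4), initial LR 0.01, batch 16, cosine annealing after a
3-epoch linear warmup, 150 epochs at 640 px input. Smoke runs use the
same machinery at reduced scene count / image side / epochs.
Determinism: given a seed, weight init, batch order and (optional)
augmentation are all driven by counter-based generators, so CPU reruns
are bit-identical.
"""

from __future__ import annotations

import csv
import json
import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import load_image, read_labels, letterbox, yolo_to_xyxy
from .losses import DetectionLoss, ImageExtent
from .metrics import Detection, mean_ap
from .model import Detector, ModelConfig, build_full_model
from .nn.head import decode_predictions


@dataclass
class TrainConfig:
    lr0: float = 0.01
    batch: int = 16
    optimizer: str = "sgd"
    momentum: float = 0.937
    weight_decay: float = 0.0005
    epochs: int = 150
    warmup_epochs: int = 3
    warmup_momentum: float = 0.8
    schedule: str = "cosine"
    final_lr_frac: float = 0.01
    imgsz: int = 640
    seed: int = 0
    augment: bool = False
    grad_clip: float = 10.0
    reshuffle_each_epoch: bool = True
    ema: bool = False
    ema_decay: float = 0.999

    def __post_init__(self):
        if self.epochs < 1 or self.batch < 1 or self.lr0 <= 0:
            raise ValueError("invalid training configuration")


class SGD:
    """SGD with momentum; weight decay on weight matrices only."""

    def __init__(self, params, lr, momentum, weight_decay):
        self.params = list(params)
        self.lr, self.momentum, self.wd = lr, momentum, weight_decay
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grad_clip=0.0):
        if grad_clip:
            sq = sum(float((p.grad ** 2).sum()) for p in self.params
                     if p.grad is not None)
            norm = math.sqrt(sq)
            scale = grad_clip / norm if norm > grad_clip else 1.0
        else:
            scale = 1.0
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.wd and p.data.ndim > 1:
                g = g + self.wd * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class WeightEMA:
    """Exponential moving average of model weights and buffers; the
    averaged weights are what gets evaluated and checkpointed."""

    def __init__(self, model, decay=0.999, warmup=500):
        self.decay, self.warmup = decay, warmup
        self.step = 0
        self.shadow = {k: v.copy() for k, v in model.state_dict().items()}

    def update(self, model):
        self.step += 1
        d = self.decay * (1 - math.exp(-self.step / self.warmup))
        for k, v in model.state_dict().items():
            s = self.shadow[k]
            s *= d
            s += (1 - d) * v

    def copy_to(self, model):
        model.load_state_dict(self.shadow)


class DetectionDataset:
    """YOLO-layout directory (images/ + labels/) or in-memory scene
    list, letterboxed to the training input side."""

    def __init__(self, source, imgsz: int = 640):
        self.imgsz = imgsz
        self.items = []
        if isinstance(source, (str, Path)):
            root = Path(source)
            imgs = sorted((root / "images").glob("*"))
            if not imgs:
                raise FileNotFoundError(f"no images under {root}/images")
            for ip in imgs:
                lp = root / "labels" / (ip.stem + ".txt")
                boxes = read_labels(lp) if lp.exists() else []
                self.items.append((ip, boxes))
        else:                                   # [(image ndarray, [BoxYOLO])]
            self.items = list(source)
        if not self.items:
            raise ValueError("empty dataset")

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        src, boxes = self.items[i]
        img = load_image(src) if isinstance(src, Path) else src
        img, aff = letterbox(img, self.imgsz)
        ext = ImageExtent(self.imgsz / aff.scale, self.imgsz / aff.scale)
        xyxy, cls = [], []
        for b in boxes:
            bb = aff.apply_box(yolo_to_xyxy(b, ext))
            xyxy.append([bb.x1, bb.y1, bb.x2, bb.y2])
            cls.append(b.class_id)
        x = img.astype(np.float32).transpose(2, 0, 1) / 255.0
        return x, (np.array(xyxy, np.float32).reshape(-1, 4),
                   np.array(cls, np.int64))


def _flip_sample(x, target):
    x = x[:, :, ::-1].copy()
    boxes, cls = target
    if len(boxes):
        w = x.shape[2]
        boxes = np.stack([w - boxes[:, 2], boxes[:, 1],
                          w - boxes[:, 0], boxes[:, 3]], axis=1)
    return x, (boxes, cls)


def lr_at(cfg: TrainConfig, epoch: int, step: int, steps_per_epoch: int) -> float:
    """Linear warmup then cosine annealing to final_lr_frac * lr0."""
    t = epoch + step / max(steps_per_epoch, 1)
    if t < cfg.warmup_epochs:
        return cfg.lr0 * t / cfg.warmup_epochs
    span = max(cfg.epochs - cfg.warmup_epochs, 1)
    frac = (t - cfg.warmup_epochs) / span
    if cfg.schedule == "cosine":
        return cfg.lr0 * (cfg.final_lr_frac
                          + (1 - cfg.final_lr_frac) * 0.5 * (1 + math.cos(math.pi * frac)))
    return cfg.lr0


def train(model_cfg: ModelConfig, train_data, tcfg: TrainConfig,
          val_data=None, log_path=None, checkpoint_path=None,
          progress=False) -> tuple[Detector, list[dict]]:
    """Seeded training loop; returns the trained model and epoch log."""
    model = build_full_model(model_cfg, seed=tcfg.seed)
    ds = (train_data if isinstance(train_data, DetectionDataset)
          else DetectionDataset(train_data, tcfg.imgsz))
    crit = DetectionLoss(model_cfg.num_classes, box_loss=model_cfg.box_loss,
                         extent=(tcfg.imgsz, tcfg.imgsz))
    opt = SGD(model.parameters(), tcfg.lr0, tcfg.momentum, tcfg.weight_decay)
    steps = max(1, math.ceil(len(ds) / tcfg.batch))
    ema = WeightEMA(model, tcfg.ema_decay, warmup=max(tcfg.epochs * steps // 10, 1)) \
        if tcfg.ema else None
    history = []
    for epoch in range(tcfg.epochs):
        shuffle_key = epoch if tcfg.reshuffle_each_epoch else 0
        rng = np.random.default_rng([tcfg.seed & 0x7FFFFFFF, 1000 + shuffle_key])
        order = rng.permutation(len(ds))
        model.train()
        sums = {"total": 0.0, "box": 0.0, "cls": 0.0, "dfl": 0.0}
        t0 = time.time()
        for s in range(steps):
            idx = order[s * tcfg.batch:(s + 1) * tcfg.batch]
            xs, targets = [], []
            for i in idx:
                x, t = ds[int(i)]
                if tcfg.augment and rng.uniform() < 0.5:
                    x, t = _flip_sample(x, t)
                xs.append(x)
                targets.append(t)
            batch = np.stack(xs)
            opt.lr = lr_at(tcfg, epoch, s, steps)
            mom_t = min((epoch * steps + s) / max(tcfg.warmup_epochs * steps, 1), 1.0)
            opt.momentum = (tcfg.warmup_momentum
                            + (tcfg.momentum - tcfg.warmup_momentum) * mom_t)
            out = model(batch, branch="both")
            loss, comps = crit(out, targets)
            opt.zero_grad()
            loss.backward()
            opt.step(tcfg.grad_clip)
            if ema is not None:
                ema.update(model)
            sums["total"] += float(loss.data)
            for k in ("box", "cls", "dfl"):
                sums[k] += comps[k]
        rec = {"epoch": epoch, **{k: v / steps for k, v in sums.items()},
               "lr": opt.lr, "seconds": time.time() - t0}
        if val_data is not None and (epoch == tcfg.epochs - 1):
            rec["map50"] = evaluate(model, val_data, imgsz=tcfg.imgsz)["map50"]
        history.append(rec)
        if progress:
            print(f"epoch {epoch:3d} loss {rec['total']:.3f} "
                  f"(box {rec['box']:.3f} cls {rec['cls']:.3f} dfl {rec['dfl']:.3f})"
                  + (f" map50 {rec.get('map50'):.3f}" if "map50" in rec else ""))
    if ema is not None:
        ema.copy_to(model)
    if log_path:
        with open(log_path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            w.writeheader()
            w.writerows(history)
    if checkpoint_path:
        save_checkpoint(model, checkpoint_path)
    return model, history


def predict(model: Detector, images: np.ndarray, conf_threshold=0.25,
            max_det=300):
    """NMS-free inference through the one-to-one branch."""
    model.eval()
    out = model(images, branch="one2one")
    return decode_predictions(out["one2one"], model.strides,
                              model.cfg.num_classes,
                              conf_threshold=conf_threshold, max_det=max_det)


def evaluate(model: Detector, data, conf_threshold=0.25, imgsz=None,
             batch=8) -> dict:
    ds = data if isinstance(data, DetectionDataset) else DetectionDataset(
        data, imgsz or model.cfg.input_side)
    dets, gts = [], {}
    for start in range(0, len(ds), batch):
        idx = range(start, min(start + batch, len(ds)))
        xs, metas = [], []
        for i in idx:
            x, (boxes, cls) = ds[i]
            xs.append(x)
            gts[i] = [(boxes[j], int(cls[j])) for j in range(len(boxes))]
            metas.append(i)
        res = predict(model, np.stack(xs), conf_threshold=0.001)
        for i, (bx, sc, cl) in zip(metas, res):
            for b, s, c in zip(bx, sc, cl):
                dets.append(Detection(box=b, confidence=float(s),
                                      class_id=int(c), image_id=i))
    return mean_ap(dets, gts, conf_threshold=conf_threshold)


def save_checkpoint(model: Detector, path):
    sd = model.state_dict()
    np.savez_compressed(path, __config__=json.dumps(model.cfg.to_dict()),
                        **{k: v for k, v in sd.items()})


def load_checkpoint(path) -> Detector:
    z = np.load(path, allow_pickle=False)
    cfg = ModelConfig.from_dict(json.loads(str(z["__config__"])))
    model = build_full_model(cfg, seed=0)
    sd = {k: z[k] for k in z.files if k != "__config__"}
    try:
        model.load_state_dict(sd)
    except (KeyError, ValueError) as e:
        raise ValueError(f"checkpoint does not match architecture "
                         f"{cfg.name!r}: {e}") from None
    return model
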