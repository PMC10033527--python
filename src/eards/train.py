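"""Training loop (RMSProp + plateau-decayed learning rate), evaluation
harness and batch prediction.

The published regime is followed: RMSProp at an initial learning rate of
1e-4, batch size 2, 30 epochs, with the learning rate decayed when the
validation mean dice (disc and cup averaged) stops improving.  Runs are
deterministic for a fixed seed: weight initialization, shuffling and the
synthetic data all derive from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import data as D
from . import metrics as M
from .exceptions import ConfigurationError
from .losses import LossConfig, fusion_loss, one_hot
from .model import EARDS, ModelConfig, build_eards, predict_masks
from .nn import RMSProp, ReduceLROnPlateau
from .nn import tensor as T


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 2
    epochs: int = 30
    max_steps: int | None = None          # cap on optimization steps (desk scale)
    validate_every: int = 1               # epochs between validation passes
    scheduler_factor: float = 0.1
    scheduler_patience: int = 2
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def validate(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        self.loss.validate(self.model.num_classes)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_dice_disc: float
    val_dice_cup: float
    learning_rate: float


@dataclass
class RunLog:
    epochs: list[EpochRecord] = field(default_factory=list)
    checkpoint_path: str | None = None
    steps: int = 0

    @property
    def train_losses(self):
        return [e.train_loss for e in self.epochs]


def _to_input(image: np.ndarray) -> np.ndarray:
    """HxWx3 float [0,1] -> 1x3xHxW float32."""
    return np.ascontiguousarray(image.transpose(2, 0, 1)[None]).astype(np.float32)


def _resolve_pairs(dataset):
    """Accept a manifest path or an iterable of (image, mask[, label])."""
    if isinstance(dataset, (str, Path)):
        rows = D.read_manifest(dataset)
        out = []
        for ip, mp, lab in rows:
            img, msk = D.load_pair(ip, mp)
            out.append((img, msk, lab))
        return out
    out = []
    for item in dataset:
        if isinstance(item, D.SyntheticSample):
            out.append((item.image, item.mask, item.glaucomatous))
        elif len(item) == 2:
            out.append((item[0], item[1], None))
        else:
            out.append(tuple(item[:3]))
    return out


def _mean_dice(model: EARDS, pairs) -> tuple[float, float]:
    model.eval()
    dd, dc = [], []
    with T.no_grad():
        for img, msk, _ in pairs:
            prob = model(_to_input(img)).data
            _, disc, cup = predict_masks(prob)
            rdisc, rcup = M.structure_masks(msk)
            dd.append(M.dice_coefficient(M.confusion_counts(disc, rdisc)))
            dc.append(M.dice_coefficient(M.confusion_counts(cup, rcup)))
    model.train()
    return float(np.mean(dd)), float(np.mean(dc))


def train(config: TrainConfig, dataset, val_dataset=None, checkpoint_path=None,
          log_file=None) -> tuple[EARDS, RunLog]:
    """Train a model; returns (model, run log).

    ``dataset``: manifest CSV path or iterable of (image, mask) pairs /
    synthetic samples.  ``val_dataset`` defaults to the training set (the
    scheduler then tracks training dice).
    """
    config.validate()
    pairs = _resolve_pairs(dataset)
    if not pairs:
        raise ConfigurationError("empty training dataset")
    val_pairs = _resolve_pairs(val_dataset) if val_dataset is not None else pairs
    k = config.model.num_classes

    model = build_eards(config.model)
    model.train()
    opt = RMSProp(model.parameters(), lr=config.learning_rate)
    sched = ReduceLROnPlateau(opt, factor=config.scheduler_factor,
                              patience=config.scheduler_patience)
    rng = np.random.default_rng(config.seed)
    log = RunLog()
    logf = open(log_file, "w") if log_file else None
    step = 0
    try:
        for epoch in range(1, config.epochs + 1):
            order = rng.permutation(len(pairs))
            losses = []
            for start in range(0, len(order), config.batch_size):
                batch = [pairs[i] for i in order[start:start + config.batch_size]]
                x = np.concatenate([_to_input(b[0]) for b in batch])
                m = np.stack([one_hot(b[1], k) for b in batch])
                opt.zero_grad()
                prob = model(x)
                loss = fusion_loss(m, prob, config.loss)
                lval = loss.item()
                if not np.isfinite(lval):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"batch starting at index {start} (step {step + 1})")
                loss.backward()
                opt.step()
                losses.append(lval)
                step += 1
                if config.max_steps is not None and step >= config.max_steps:
                    break
            validate = (epoch % config.validate_every == 0
                        or epoch == config.epochs
                        or (config.max_steps is not None and step >= config.max_steps))
            vd, vc = _mean_dice(model, val_pairs) if validate else (np.nan, np.nan)
            rec = EpochRecord(epoch=epoch, train_loss=float(np.mean(losses)),
                              val_dice_disc=vd, val_dice_cup=vc,
                              learning_rate=opt.lr)
            log.epochs.append(rec)
            if logf:
                logf.write(json.dumps(asdict(rec)) + "\n")
                logf.flush()
            if validate:
                sched.step((vd + vc) / 2.0)
            if config.max_steps is not None and step >= config.max_steps:
                break
    finally:
        if logf:
            logf.close()
    log.steps = step
    model.eval()
    if checkpoint_path:
        save_checkpoint(checkpoint_path, model)
        log.checkpoint_path = str(checkpoint_path)
    return model, log


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: EARDS):
    """Single-file npz: weights, buffers and the embedded model config."""
    cfg = asdict(model.config)
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> EARDS:
    archive = np.load(path)
    cfg_json = archive["__config__"].tobytes().decode()
    raw = json.loads(cfg_json)
    enc = raw.pop("encoder", None)
    cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in raw.items()})
    if enc:
        from .encoder import EncoderConfig
        enc["stage_specs"] = tuple(tuple(s) for s in enc["stage_specs"])
        cfg.encoder = EncoderConfig(**enc)
    model = build_eards(cfg)
    model.load_state_dict({k: v for k, v in archive.items() if k != "__config__"})
    model.eval()
    return model


# ---------------------------------------------------------------------------
# evaluation / prediction
# ---------------------------------------------------------------------------

def evaluate(model_or_checkpoint, dataset, csv_path=None, json_path=None,
             screen_threshold: float = 0.5) -> dict:
    """Per-image DC/JAC/BA for disc and cup, CDR error, optional AUC.

    Returns the summary dict; optionally writes the per-image CSV and the
    JSON summary.
    """
    model = (model_or_checkpoint if isinstance(model_or_checkpoint, EARDS)
             else load_checkpoint(model_or_checkpoint))
    model.eval()
    pairs = _resolve_pairs(dataset)
    if not pairs:
        raise ConfigurationError("empty evaluation dataset")
    rows, records, labels = [], [], []
    with T.no_grad():
        for i, (img, msk, lab) in enumerate(pairs):
            prob = model(_to_input(img)).data
            _, disc, cup = predict_masks(prob)
            rdisc, rcup = M.structure_masks(msk)
            row = {"index": i}
            for name, pm, rm in (("disc", disc, rdisc), ("cup", cup, rcup)):
                c = M.confusion_counts(pm, rm)
                row[f"dc_{name}"] = M.dice_coefficient(c)
                row[f"jac_{name}"] = M.jaccard(c)
                row[f"ba_{name}"] = M.balanced_accuracy(c)
            cdr_ref = M.cdr(rcup, rdisc).value if rdisc.any() else 0.0
            cdr_pred = (M.cdr(cup, disc).value if disc.any() else 0.0)
            row["cdr_pred"], row["cdr_ref"] = cdr_pred, cdr_ref
            rows.append(row)
            records.append(M.CDRRecord(cdr_pred=cdr_pred, cdr_ref=cdr_ref))
            labels.append(lab)
    summary = {
        "n_images": len(rows),
        "mean_dc_disc": float(np.mean([r["dc_disc"] for r in rows])),
        "mean_jac_disc": float(np.mean([r["jac_disc"] for r in rows])),
        "mean_ba_disc": float(np.mean([r["ba_disc"] for r in rows])),
        "mean_dc_cup": float(np.mean([r["dc_cup"] for r in rows])),
        "mean_jac_cup": float(np.mean([r["jac_cup"] for r in rows])),
        "mean_ba_cup": float(np.mean([r["ba_cup"] for r in rows])),
        "cdr_error": M.cdr_error(records),
    }
    if all(l is not None for l in labels) and len(set(labels)) > 1:
        rep = M.screen(records, labels, threshold=screen_threshold)
        summary["auc"] = rep.auc
    if csv_path:
        import csv as _csv
        with open(csv_path, "w", newline="") as fh:
            w = _csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            w.writeheader()
            w.writerows(rows)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def predict(model_or_checkpoint, image_paths, out_dir) -> list[Path]:
    """Write predicted label masks (indexed PNG) and per-structure binary
    masks for each readable input image; unreadable files are reported and
    skipped."""
    model = (model_or_checkpoint if isinstance(model_or_checkpoint, EARDS)
             else load_checkpoint(model_or_checkpoint))
    model.eval()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for p in map(Path, image_paths):
        try:
            img = D.load_image(p)
        except Exception as exc:       # per-file robustness
            print(f"skipping {p}: {exc}")
            continue
        with T.no_grad():
            prob = model(_to_input(img)).data
        label, disc, cup = predict_masks(prob)
        base = out_dir / p.stem
        D.save_mask(f"{base}_mask.png", label)
        D.save_mask(f"{base}_disc.png", (disc * RIM_CODE).astype(np.uint8))
        D.save_mask(f"{base}_cup.png", (cup * CUP_CODE).astype(np.uint8))
        written.append(Path(f"{base}_mask.png"))
    return written


RIM_CODE, CUP_CODE = D.RIM, D.CUP
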