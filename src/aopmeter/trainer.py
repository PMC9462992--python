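"""Two-stage training of the multitask network.

Stage 1 optimizes the shared encoder together with the segmentation and
heatmap decoders on standard-plane images only, under the uncertainty-
weighted combination of Dice, shape-constrained and heatmap-MSE losses.
Stage 2 loads the stage-1 encoder, freezes it (by default) and trains only
the classification head with cross-entropy on standard + nonstandard images.

Optimization is adaptive-moment (Adam) from lr 1e-4 with a step schedule
(x0.1 every 20 epochs), batch size 2.  Model selection: lowest validation
total loss in stage 1, highest validation accuracy in stage 2.  A per-epoch
CSV log (epoch, lr, loss components, validation metric) is written next to
the checkpoint when an output directory is given.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dataio, losses
from .autodiff import Adam, Parameter, StepLR, Tensor
from .dataio import Sample
from .losses import LossWeights
from .mtunet import MTUnet, NetworkOutput, save_checkpoint, load_checkpoint

__all__ = ["TrainConfig", "train_stage1", "train_stage2", "predict", "PredictResult"]


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 1e-4
    step_size: int = 20
    gamma: float = 0.1
    epochs: int = 200
    batch_size: int = 2
    seed: int = 0
    freeze_encoder_stage2: bool = True
    augment: bool = True
    rotation_range: tuple[float, float] = (-30.0, 30.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    heatmap_sigma: float = dataio.DEFAULT_SIGMA
    slf_classes: tuple[int, ...] = (2,)     # convex prior on the fetal head
    slf_triplets: int = 256
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.lr0 <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


class NonFiniteLossError(RuntimeError):
    pass


def _stack_images(batch: list[Sample]) -> np.ndarray:
    return np.stack([s.image for s in batch])[:, None].astype(np.float32)


def _stage1_losses(model: MTUnet, batch: list[Sample], cfg: TrainConfig,
                   rng: np.random.Generator, s1, s2):
    out = model.forward(_stack_images(batch))
    labels = np.stack([s.mask for s in batch])
    l_d = losses.dice_loss_masks(labels, out.seg_probs)
    slf_terms = []
    for bi, s in enumerate(batch):
        for c in cfg.slf_classes:
            p_map = out.seg_probs.narrow(0, bi, 1).narrow(1, c, 1).reshape(
                *s.mask.shape)
            slf_terms.append(losses.shape_constrained_loss(
                s.mask, p_map, class_id=c, n_triplets=cfg.slf_triplets, rng=rng))
    l_sc = slf_terms[0] if len(slf_terms) == 1 else None
    if l_sc is None:
        acc = Tensor(np.float32(0.0))
        for t in slf_terms:
            acc = acc + (t if isinstance(t, Tensor) else Tensor(np.float32(t)))
        l_sc = acc * Tensor(np.float32(1.0 / len(slf_terms)))
    elif not isinstance(l_sc, Tensor):
        l_sc = Tensor(np.float32(l_sc))
    hm_true = np.stack([s.heatmaps for s in batch])
    l_mse = losses.mse_heatmap_loss(out.heatmap_preds, hm_true, cfg.weights.delta)
    total = losses.total_loss(l_d, l_sc, l_mse, cfg.weights, s1, s2)
    return total, l_d, l_sc, l_mse


def _check_finite(value: float, what: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise NonFiniteLossError(f"non-finite {what} at epoch {epoch}: {value}")


def _write_log(path: Path | None, rows: list[dict]) -> None:
    if path is None or not rows:
        return
    with open(path, "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=list(rows[0].keys()))
        w.writeheader()
        w.writerows(rows)


def _set_requires_grad(params, flag: bool) -> None:
    for p in params:
        p.requires_grad = flag


def train_stage1(model: MTUnet, train_set: list[Sample], val_set: list[Sample],
                 config: TrainConfig, out_dir=None):
    """Stage 1: encoder + Task2 + Task3 on standard planes only.

    Returns ``(checkpoint_path_or_None, history)``; the model is left at the
    best-validation weights.
    """
    train_set = [s for s in train_set if s.class_label == 1]
    val_set = [s for s in val_set if s.class_label == 1]
    if not train_set:
        raise ValueError("stage 1 needs standard-plane training samples")
    rng = np.random.default_rng(config.seed)
    s1 = Parameter(np.float32(0.0))
    s2 = Parameter(np.float32(0.0))
    params = (model.encoder_parameters() + model.task2_parameters()
              + model.task3_parameters() + [s1, s2])
    opt = Adam(params, lr=config.lr0)
    sched = StepLR(opt, config.step_size, config.gamma)
    history: list[dict] = []
    best = (np.inf, None)
    for epoch in range(config.epochs):
        sched.set_epoch(epoch)
        model.train()
        order = rng.permutation(len(train_set))
        comps = np.zeros(4)
        nb = 0
        for lo in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[lo:lo + config.batch_size]]
            if config.augment:
                batch = [dataio.augment(s, rng, config.rotation_range,
                                        config.scale_range, config.heatmap_sigma)
                         for s in batch]
            total, l_d, l_sc, l_mse = _stage1_losses(model, batch, config, rng, s1, s2)
            _check_finite(total.item(), "training loss", epoch)
            opt.zero_grad()
            total.backward()
            opt.step()
            comps += (total.item(), l_d.item(), l_sc.item(), l_mse.item())
            nb += 1
        comps /= max(nb, 1)
        val = _validate_stage1(model, val_set, config, s1, s2)
        _check_finite(val, "validation loss", epoch)
        history.append({"epoch": epoch, "lr": sched.lr_at(epoch),
                        "loss_total": comps[0], "loss_dice": comps[1],
                        "loss_slf": comps[2], "loss_mse": comps[3],
                        "val_loss": val})
        if val < best[0]:
            best = (val, _snapshot(model))
    if best[1] is not None:
        _restore(model, best[1])
    ckpt = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt = out_dir / "stage1.npz"
        save_checkpoint(ckpt, model, extra={"stage": 1, "best_val": best[0]},
                        rng_state=rng.bit_generator.state)
        _write_log(out_dir / "stage1_log.csv", history)
    return ckpt, history


def _validate_stage1(model, val_set, config, s1, s2) -> float:
    if not val_set:
        return 0.0
    model.eval()
    rng = np.random.default_rng(config.seed + 1)  # fixed eval triplet draw
    vals = []
    for lo in range(0, len(val_set), config.batch_size):
        batch = val_set[lo:lo + config.batch_size]
        total, *_ = _stage1_losses(model, batch, config, rng,
                                   s1.detach(), s2.detach())
        vals.append(total.item())
        total.release()
    return float(np.mean(vals))


def train_stage2(model: MTUnet | None, checkpoint, train_set: list[Sample],
                 val_set: list[Sample], config: TrainConfig, out_dir=None):
    """Stage 2: classification head on standard + nonstandard planes.

    ``checkpoint`` is a stage-1 archive path (or None to reuse ``model``
    as-is).  The encoder is frozen unless ``freeze_encoder_stage2=False``;
    Task2/Task3 weights are never touched.
    """
    if checkpoint is not None:
        model, _meta = load_checkpoint(checkpoint)
    if model is None:
        raise ValueError("need a model or a stage-1 checkpoint")
    if not train_set:
        raise ValueError("stage 2 needs training samples")
    rng = np.random.default_rng(config.seed + 2)
    head_params = model.task1_parameters()
    frozen = model.encoder_parameters() + model.task2_parameters() + model.task3_parameters()
    train_params = list(head_params)
    if not config.freeze_encoder_stage2:
        train_params += model.encoder_parameters()
        frozen = model.task2_parameters() + model.task3_parameters()
    _set_requires_grad(frozen, False)
    opt = Adam(train_params, lr=config.lr0)
    sched = StepLR(opt, config.step_size, config.gamma)
    history: list[dict] = []
    best = (-np.inf, None)
    # with a frozen encoder the bottleneck features of every image are
    # constant, so they are computed once and the head trains on the cache
    cache_train = cache_val = None
    if config.freeze_encoder_stage2:
        model.eval()
        cache_train = _encode_all(model, train_set)
        cache_val = _encode_all(model, val_set) if val_set else None
    try:
        for epoch in range(config.epochs):
            sched.set_epoch(epoch)
            # frozen parts keep their batch statistics: only the head trains
            model.eval()
            for m in model.task1_modules():
                m.train()
            if not config.freeze_encoder_stage2:
                for m in model.encoder_modules():
                    m.train()
            order = rng.permutation(len(train_set))
            tot, nb, ncorrect = 0.0, 0, 0
            for lo in range(0, len(order), config.batch_size):
                idx = order[lo:lo + config.batch_size]
                batch = [train_set[i] for i in idx]
                if cache_train is not None:
                    probs = model.classify_from_bottleneck(Tensor(cache_train[idx]))
                else:
                    probs = model.classify(_stack_images(batch))
                y = np.array([s.class_label for s in batch], dtype=np.float32)
                loss = losses.cross_entropy(y, probs.narrow(1, 1, 1).reshape(-1))
                _check_finite(loss.item(), "training loss", epoch)
                opt.zero_grad()
                loss.backward()
                opt.step()
                tot += loss.item()
                nb += 1
                ncorrect += int((probs.data.argmax(axis=1) == y).sum())
            model.eval()
            if val_set:
                val_acc = (_accuracy_cached(model, cache_val, val_set)
                           if cache_val is not None
                           else _accuracy(model, val_set, config))
            else:
                val_acc = ncorrect / len(train_set)
            history.append({"epoch": epoch, "lr": sched.lr_at(epoch),
                            "loss_ce": tot / max(nb, 1),
                            "train_acc": ncorrect / len(train_set),
                            "val_acc": val_acc})
            if val_acc > best[0]:
                best = (val_acc, _snapshot(model))
    finally:
        _set_requires_grad(frozen, True)
    if best[1] is not None:
        _restore(model, best[1])
    ckpt = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt = out_dir / "stage2.npz"
        save_checkpoint(ckpt, model, extra={"stage": 2, "best_val_acc": best[0]},
                        rng_state=rng.bit_generator.state)
        _write_log(out_dir / "stage2_log.csv", history)
    return model, ckpt, history


def _encode_all(model, samples, chunk: int = 8) -> np.ndarray:
    feats = []
    for lo in range(0, len(samples), chunk):
        t = model.encode_bottleneck(_stack_images(samples[lo:lo + chunk]))
        feats.append(t.data)
        t.release()
    return np.concatenate(feats)


def _accuracy_cached(model, feats, samples) -> float:
    probs = model.classify_from_bottleneck(Tensor(feats))
    probs.release()
    pred = probs.data.argmax(axis=1)
    return float(np.mean([int(p) == s.class_label for p, s in zip(pred, samples)]))


def _accuracy(model, samples, config) -> float:
    correct = 0
    for lo in range(0, len(samples), max(config.batch_size, 8)):
        batch = samples[lo:lo + max(config.batch_size, 8)]
        probs_t = model.classify(_stack_images(batch))
        probs = probs_t.data
        probs_t.release()
        pred = probs.argmax(axis=1)
        correct += int(sum(int(p) == s.class_label for p, s in zip(pred, batch)))
    return correct / len(samples)


def _snapshot(model) -> dict:
    state = {f"p/{k}": p.data.copy() for k, p in model.named_parameters()}
    state.update({f"b/{k}": v.copy() for k, v in model.named_buffers()})
    return state


def _restore(model, state) -> None:
    for k, p in model.named_parameters():
        p.data[...] = state[f"p/{k}"]
    for k, v in model.named_buffers():
        v[...] = state[f"b/{k}"]


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictResult:
    is_standard: bool
    class_probs: tuple[float, float]
    seg_mask: np.ndarray                    # (H', W') argmax labels
    endpoints: tuple | None                 # ((xl, yl), (xr, yr)) original coords
    endpoint_failure: str = ""


def predict(model: MTUnet, image: np.ndarray,
            spatial_map: dataio.SpatialMap | None = None) -> PredictResult:
    """Eval-mode forward pass + hard decisions for one preprocessed image.

    ``image`` is (H', W') in [-1, 1]; ``spatial_map`` maps endpoint
    predictions back to original coordinates (identity if None).
    """
    model.eval()
    out = model.forward(image[None, None].astype(np.float32))
    out.class_probs.release()
    probs = out.class_probs.data[0]
    seg = out.seg_probs.data[0].argmax(axis=0).astype(np.uint8)
    smap = spatial_map or dataio.SpatialMap(1.0, 1.0)
    endpoints, failure = None, ""
    try:
        left, right = dataio.extract_endpoints(out.heatmap_preds.data[0], smap)
        endpoints = (left, right)
    except dataio.DetectionError as exc:
        failure = str(exc)
    return PredictResult(is_standard=bool(probs[1] >= probs[0]),
                         class_probs=(float(probs[0]), float(probs[1])),
                         seg_mask=seg, endpoints=endpoints,
                         endpoint_failure=failure)
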