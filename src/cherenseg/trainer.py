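"""Two-stage transfer-learning trainer.

The model is pretrained on the data-rich source domain (fundus-like vessel
patches) and then fine-tuned — all parameters trainable, no freezing — on
the small target domain (Cherenkov-like patches).  Each stage runs
mini-batch RMSProp with on-the-fly augmentation of the training split,
evaluates the compound Dice + cross-entropy loss on the untouched
validation split every epoch, and returns the checkpoint with the minimum
validation loss.  The pre-update (epoch-0) validation loss is recorded as
well, so a warm start that fine-tuning never improves on remains
selectable.

Full-scale defaults: batch 24, learning rate 1e-5, 400 pretraining epochs
with 1e-8 L2 weight decay, 100 fine-tuning epochs with no decay.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from .augment import AugmentPolicy, augment_arrays
from .metrics import dice_score
from .objective import LossConfig, seg_loss, seg_loss_grad
from .patchify import TRAIN, VAL, PatchSet
from .segnet import NetworkConfig, SegModel, _sigmoid, binarize, build_model

log = logging.getLogger("cherenseg.trainer")

PRETRAIN = "pretrain"
FINETUNE = "finetune"


@dataclass
class TrainConfig:
    batch_size: int = 24
    lr: float = 1e-5
    weight_decay: float = 1e-8        # L2 decay; pretraining default
    epochs: int = 400
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-8
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentPolicy | None = field(default_factory=AugmentPolicy)
    seed: int = 0
    stage: str = PRETRAIN

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0 or self.lr < 0:
            raise ValueError("batch size, epochs and learning rate must be >= 0")


def finetune_config(**kw) -> TrainConfig:
    kw.setdefault("epochs", 100)
    kw.setdefault("weight_decay", 0.0)
    kw.setdefault("stage", FINETUNE)
    return TrainConfig(**kw)


@dataclass
class TrainHistory:
    """Loss traces and the selected checkpoint.

    ``val_loss`` has epochs + 1 entries — index 0 is the warm start,
    evaluated before any update; ``train_loss`` has one entry per epoch.
    ``selected_epoch`` indexes ``val_loss`` (0 = the initial weights).
    """

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    selected_epoch: int | None = None
    wall_times: list[float] = field(default_factory=list)

    @property
    def selected_val_loss(self) -> float:
        return self.val_loss[self.selected_epoch]


class RMSProp:
    """Root-mean-square propagation with L2 weight decay."""

    def __init__(self, model: SegModel, lr: float, rho: float = 0.9,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.model, self.lr, self.rho, self.eps = model, lr, rho, eps
        self.weight_decay = weight_decay
        self.sq = {name: np.zeros_like(layer.params[p])
                   for name, layer, p in model.parameters()}

    def step(self) -> None:
        for name, layer, p in self.model.parameters():
            g = layer.grads[p]
            if self.weight_decay:
                g = g + self.weight_decay * layer.params[p]
            self.sq[name] = self.rho * self.sq[name] + (1.0 - self.rho) * g**2
            layer.params[p] -= self.lr * g / (np.sqrt(self.sq[name]) + self.eps)


def _stack(patches) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.image for p in patches])[:, None].astype(np.float64)
    y = np.stack([p.mask for p in patches])[:, None].astype(np.float64)
    return x, y


def _eval_loss(model: SegModel, x: np.ndarray, y: np.ndarray,
               loss_cfg: LossConfig, batch_size: int) -> float:
    total, n = 0.0, x.shape[0]
    for i in range(0, n, batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        p = _sigmoid(model.forward(xb, train=False))
        total += seg_loss(p, yb, loss_cfg) * xb.shape[0]
    return total / n


def train_stage(
    model: SegModel,
    data: PatchSet,
    cfg: TrainConfig,
    val_eval_fn=None,
) -> tuple[SegModel, TrainHistory]:
    """One optimization stage on a split PatchSet.

    Augmentation is redrawn per epoch on the training split only; the
    validation split is evaluated untouched in inference mode.  Returns the
    model loaded with the minimum-validation-loss checkpoint plus the full
    history.  ``val_eval_fn(model) -> float`` may replace the internal
    validation evaluation (used for testing model selection in isolation).
    """
    if cfg.epochs == 0:
        return model, TrainHistory()
    train_patches = data.subset(TRAIN)
    val_patches = data.subset(VAL)
    if not train_patches:
        raise ValueError("patch set has an empty training split")
    if not val_patches and val_eval_fn is None:
        raise ValueError(
            "patch set has an empty validation split; re-split with a "
            "different seed or more patches"
        )
    x_tr, y_tr = _stack(train_patches)
    if val_patches:
        x_va, y_va = _stack(val_patches)
    evaluate = (
        val_eval_fn
        if val_eval_fn is not None
        else lambda m: _eval_loss(m, x_va, y_va, cfg.loss, cfg.batch_size)
    )

    rng = np.random.default_rng(cfg.seed)
    opt = RMSProp(model, cfg.lr, cfg.rmsprop_rho, cfg.rmsprop_eps, cfg.weight_decay)
    hist = TrainHistory()
    v0 = float(evaluate(model))
    hist.val_loss.append(v0)
    best_val, best_state, best_epoch = v0, model.state_dict(), 0
    n = x_tr.shape[0]
    for epoch in range(1, cfg.epochs + 1):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        loss_sum = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb = x_tr[idx].copy()
            yb = y_tr[idx].copy()
            if cfg.augment is not None:
                for j in range(xb.shape[0]):
                    img, msk = augment_arrays(xb[j, 0], yb[j, 0], cfg.augment, rng)
                    xb[j, 0], yb[j, 0] = img, msk
            model.zero_grads()
            p = _sigmoid(model.forward(xb, train=True))
            loss = seg_loss(p, yb, cfg.loss)
            dlogits = seg_loss_grad(p, yb, cfg.loss) * p * (1.0 - p)
            model.backward(dlogits)
            opt.step()
            loss_sum += loss * xb.shape[0]
        train_loss = loss_sum / n
        val_loss = float(evaluate(model))
        hist.train_loss.append(train_loss)
        hist.val_loss.append(val_loss)
        hist.wall_times.append(time.perf_counter() - t0)
        if val_loss < best_val:
            best_val, best_state, best_epoch = val_loss, model.state_dict(), epoch
        log.info(
            "stage=%s epoch=%d train_loss=%.5f val_loss=%.5f lr=%.2e seed=%d",
            cfg.stage, epoch, train_loss, val_loss, cfg.lr, cfg.seed,
        )
    hist.selected_epoch = best_epoch
    model.load_state_dict(best_state)
    model.provenance = {
        "stage": cfg.stage,
        "epoch": best_epoch,
        "val_loss": best_val,
        "seed": cfg.seed,
    }
    return model, hist


def transfer_pipeline(
    source: PatchSet,
    target: PatchSet,
    cfg_pre: TrainConfig,
    cfg_ft: TrainConfig,
    net_cfg: NetworkConfig | None = None,
    seed: int = 0,
    pretrain: bool = True,
) -> tuple[SegModel, TrainHistory, TrainHistory]:
    """Pretrain on the source domain, then fine-tune every parameter on the
    target domain, starting from the selected pretraining checkpoint.  With
    ``pretrain=False`` the pipeline reduces to scratch training on the
    target (the ablation baseline)."""
    model = build_model(net_cfg, seed=seed)
    if pretrain:
        model, hist_pre = train_stage(model, source, cfg_pre)
    else:
        hist_pre = TrainHistory()
    model, hist_ft = train_stage(model, target, cfg_ft)
    return model, hist_pre, hist_ft


def joint_training(
    source: PatchSet,
    target: PatchSet,
    cfg: TrainConfig,
    mix: float = 0.5,
    net_cfg: NetworkConfig | None = None,
    seed: int = 0,
) -> tuple[SegModel, TrainHistory]:
    """Experimental single-stage mode: each step optimizes
    (1 - mix) * loss(source batch) + mix * loss(target batch).

    The mixing weight is a plain convex combination; this mode is off by
    default and provided for exploration only.
    """
    if not (0.0 <= mix <= 1.0):
        raise ValueError("mix must be in [0, 1]")
    model = build_model(net_cfg, seed=seed)
    xs, ys = _stack(source.subset(TRAIN))
    xt, yt = _stack(target.subset(TRAIN))
    xv, yv = _stack(target.subset(VAL))
    rng = np.random.default_rng(cfg.seed)
    opt = RMSProp(model, cfg.lr, cfg.rmsprop_rho, cfg.rmsprop_eps, cfg.weight_decay)
    hist = TrainHistory()
    hist.val_loss.append(_eval_loss(model, xv, yv, cfg.loss, cfg.batch_size))
    best_val, best_state, best_epoch = hist.val_loss[0], model.state_dict(), 0
    half = max(cfg.batch_size // 2, 1)
    for epoch in range(1, cfg.epochs + 1):
        losses = []
        for _ in range(max(xs.shape[0] // half, 1)):
            i_s = rng.integers(0, xs.shape[0], half)
            i_t = rng.integers(0, xt.shape[0], half)
            model.zero_grads()
            loss = 0.0
            for xb, yb, w in ((xs[i_s], ys[i_s], 1.0 - mix), (xt[i_t], yt[i_t], mix)):
                if w == 0.0:
                    continue
                p = _sigmoid(model.forward(xb, train=True))
                loss += w * seg_loss(p, yb, cfg.loss)
                model.backward(w * seg_loss_grad(p, yb, cfg.loss) * p * (1.0 - p))
            opt.step()
            losses.append(loss)
        hist.train_loss.append(float(np.mean(losses)))
        val = _eval_loss(model, xv, yv, cfg.loss, cfg.batch_size)
        hist.val_loss.append(val)
        if val < best_val:
            best_val, best_state, best_epoch = val, model.state_dict(), epoch
    hist.selected_epoch = best_epoch
    model.load_state_dict(best_state)
    return model, hist


# ---------------------------------------------------------------------------
# scaled two-domain benchmark
# ---------------------------------------------------------------------------


def _benchmark_patchsets(seed: int, patch: int, n_source: int, n_target: int):
    """Phantom patch sets for the scaled benchmark: high-contrast source
    images and low-SNR beam-limited target images, tiled into 2 x 2 grids
    of small patches and retention-filtered (which keeps roughly three
    quarters of them, as with real fundus patches)."""
    from . import phantom
    from .patchify import PatchSet as PS
    from .patchify import extract_patches, retention_filter

    rng = np.random.default_rng(seed)
    # denser trees than the full-scale defaults: at 64 px patches a sparse
    # tree rarely clears the 5 % labeled-area retention threshold
    grow = dict(shape=(2 * patch, 2 * patch), width_range=(3.0, 6.0),
                depth=5, branch_prob=0.7, n_steps=14, step=6.0)

    def make(spec_fn, need, tag):
        spec = spec_fn(**grow)
        patches = []
        i = 0
        while len(patches) < need:
            tree = phantom.sample_vessel_tree(spec, int(rng.integers(2**31)))
            ann = phantom.render_annotated(
                tree, spec, seed=int(rng.integers(2**31)), identifier=f"{tag}{i}"
            )
            tiled = extract_patches(ann, patch_size=patch)
            for p in tiled.patches:
                p.parent = ann.identifier
            patches.extend(retention_filter(tiled).patches)
            i += 1
        return PS(patches[:need])

    source = make(phantom.source_spec, n_source, tag="s")
    target = make(phantom.target_spec, n_target, tag="t")
    return source, target


def val_dice(model: SegModel, data: PatchSet, threshold: float = 0.5) -> float:
    """Mean Dice of binarized predictions over the validation split."""
    val = data.subset(VAL)
    x, y = _stack(val)
    probs = model.predict(x[:, 0])
    return float(
        np.mean([dice_score(binarize(p, threshold), m[0]) for p, m in zip(probs, y)])
    )


def transfer_benchmark(
    n_seeds: int = 5,
    base_seed: int = 0,
    patch: int = 64,
    n_source: int = 200,
    n_target: int = 20,
    epochs: int = 30,
    lr: float = 1e-3,
) -> list[dict]:
    """Head-to-head transfer vs scratch at reduced scale.

    Per seed: 200 source patches / 20 target patches of 64 x 64 px, a
    2-level 8-filter network, 30 pretraining + 30 fine-tuning epochs, and
    an identically-seeded scratch model trained 30 epochs on the target
    alone.  Reports the selected-checkpoint validation Dice of both.
    """
    net_cfg = NetworkConfig(init_filters=8, levels=2, blocks_per_level=(1, 2))
    results = []
    for s in range(n_seeds):
        seed = base_seed + s
        source, target = _benchmark_patchsets(seed, patch, n_source, n_target)
        source = replace_split(source, seed)
        target = replace_split(target, seed)
        cfg_pre = TrainConfig(epochs=epochs, lr=lr, seed=seed, stage=PRETRAIN)
        cfg_ft = finetune_config(epochs=epochs, lr=lr, seed=seed)
        ft_model, _, _ = transfer_pipeline(
            source, target, cfg_pre, cfg_ft, net_cfg, seed=seed
        )
        sc_model, _, _ = transfer_pipeline(
            source, target, cfg_pre, cfg_ft, net_cfg, seed=seed, pretrain=False
        )
        results.append(
            {
                "seed": seed,
                "finetuned_dice": val_dice(ft_model, target),
                "scratch_dice": val_dice(sc_model, target),
            }
        )
    return results


def replace_split(ps: PatchSet, seed: int) -> PatchSet:
    from .patchify import split_patches

    return split_patches(PatchSet(list(ps.patches)), seed=seed)


# ---------------------------------------------------------------------------
# structured config file
# ---------------------------------------------------------------------------


def default_config() -> dict:
    """Every pipeline block with its full-scale default hyperparameters."""
    return {
        "phantom": {"domain": "source", "shape": [448, 448], "noise_sigma": 0.02},
        "patchify": {"grid": 6, "threshold": 0.05, "train_fraction": 0.9,
                     "patch_size": 224},
        "augment": {"flip_prob": 0.33, "rot_prob": 0.33,
                    "angles": [90, 180, 270], "noise_prob": 0.5,
                    "noise_max": 0.25},
        "network": {"init_filters": 32, "kernel": 3, "levels": 4,
                    "blocks_per_level": [1, 2, 2, 4], "decoder_blocks": 1},
        "loss": {"lambda_dice": 1.0, "lambda_ce": 0.1, "eps": 1e-5,
                 "delta": 1e-7},
        "train": {"batch_size": 24, "lr": 1e-5, "weight_decay": 1e-8,
                  "epochs_pretrain": 400, "epochs_finetune": 100, "seed": 0},
    }


def load_config(path: str | None = None) -> dict:
    cfg = default_config()
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for block, vals in user.items():
            cfg.setdefault(block, {}).update(vals)
    return cfg


def configs_from_dict(cfg: dict, stage: str = PRETRAIN):
    """Materialize NetworkConfig / TrainConfig / AugmentPolicy from the
    structured config dictionary."""
    net = NetworkConfig(
        **{**cfg["network"],
           "blocks_per_level": tuple(cfg["network"]["blocks_per_level"])}
    )
    aug = AugmentPolicy(**{**cfg["augment"], "angles": tuple(cfg["augment"]["angles"])})
    t = cfg["train"]
    epochs = t["epochs_pretrain"] if stage == PRETRAIN else t["epochs_finetune"]
    wd = t["weight_decay"] if stage == PRETRAIN else 0.0
    train = TrainConfig(
        batch_size=t["batch_size"], lr=t["lr"], weight_decay=wd, epochs=epochs,
        loss=LossConfig(**cfg["loss"]), augment=aug, seed=t["seed"], stage=stage,
    )
    return net, train
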