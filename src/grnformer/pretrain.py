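"""Joint pretraining: denoising + bottleneck autoencoding + classification.

One training step runs a single corrupted encoder pass and reuses its outputs
everywhere: the cell's counts are ZIP-downsampled, a context of genes is
sampled from the corrupted profile, and the encoder forward produces gene
output embeddings (decoded to ZINB parameters and scored against the *true*
counts — the denoising loss), class placeholder outputs (hierarchical
classification loss + contrastive disentanglement over each cell's embedding
set), and the embeddings that drive a second, expression-free decoder pass
whose ZINB reconstruction of the true profile is the bottleneck loss.  The
four losses are summed without scaling.

Optimization is decoupled-weight-decay Adam with linear warmup, gradient-norm
clipping, plateau LR decay, early stopping on consecutive validation-loss
increases, and optional stochastic weight averaging.  Class imbalance is
handled by weighted sampling with replacement: a cell in a joint-label group
of size c is drawn with weight 50 / (c + 50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from .encoding import TokenBatch, sample_context
from .losses import (
    DownsampleConfig,
    contrastive_loss,
    downsample,
    hierarchical_ce_batch,
    mse_loss,
    nb_nll,
    zinb_nll,
)
from .model import Model, ZINBParams
from .synthetic import CountMatrix

__all__ = [
    "TrainConfig",
    "group_sampler",
    "bottleneck_pass",
    "total_loss",
    "train",
    "PlateauScheduler",
]


@dataclass
class TrainConfig:
    steps: int = 2000
    lr: float = 1e-4
    weight_decay: float = 0.01
    swa_lr: float = 0.03
    swa: bool = False
    grad_clip: float = 100.0
    warmup_steps: int = 500
    batch_size: int = 64
    lr_decay_factor: float = 0.6
    lr_patience: int = 1
    early_stop_patience: int = 3
    val_fraction: float = 0.02
    val_interval: int = 100
    sampler_factor: float = 50.0
    seed: int = 0
    downsample: DownsampleConfig = field(default_factory=DownsampleConfig)
    tasks: tuple[str, ...] = (
        "denoising", "bottleneck", "classification", "contrastive"
    )

    def __post_init__(self) -> None:
        if min(self.lr, self.grad_clip, self.batch_size, self.steps) <= 0:
            raise ValueError("training scales must be positive")

    @classmethod
    def toy(cls, steps: int = 2000, seed: int = 0) -> "TrainConfig":
        """Desk-scale preset: smaller batches, a faster LR and shorter warmup
        suited to the few-thousand-step runs used throughout the test suite."""
        return cls(
            steps=steps, lr=3e-3, warmup_steps=100, batch_size=4,
            val_interval=200, seed=seed,
        )


# ---------------------------------------------------------------------------
# weighted group sampler
# ---------------------------------------------------------------------------

def group_sampler(
    cell_labels: dict[str, np.ndarray],
    factor: float = 50.0,
    rng: np.random.Generator | None = None,
    label_keys: tuple[str, ...] | None = None,
):
    """Per-cell sampling weights factor/(c+factor) from joint label groups.

    The group of a cell is the tuple of its labels across all annotated
    classes; ``c`` is the group's cell count.  Returns ``(weights, draw)``
    where ``draw(n)`` samples n indices with replacement proportionally to
    the weights.
    """
    keys = label_keys if label_keys is not None else sorted(cell_labels)
    if not keys or len(next(iter(cell_labels.values()))) == 0:
        raise ValueError("empty dataset")
    groups = list(zip(*(np.asarray(cell_labels[k], dtype=str) for k in keys)))
    counts: dict[tuple, int] = {}
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
    weights = np.array([factor / (counts[g] + factor) for g in groups])
    probs = weights / weights.sum()
    rng = rng if rng is not None else np.random.default_rng()

    def draw(n: int) -> np.ndarray:
        return rng.choice(len(groups), size=n, replace=True, p=probs)

    return weights, draw


# ---------------------------------------------------------------------------
# loss assembly
# ---------------------------------------------------------------------------

def _make_batch(
    data: CountMatrix,
    cell_idx: np.ndarray,
    model: Model,
    context_size: int,
    ds_cfg: DownsampleConfig | None,
    rng: np.random.Generator,
) -> TokenBatch:
    """Corrupt each cell, sample its context from the corrupted profile, and
    keep the true counts at the same positions as the prediction target."""
    idx_rows, val_rows, tgt_rows, totals = [], [], [], []
    for ci in cell_idx:
        true_row = data.counts[ci]
        noisy_row = (
            downsample(true_row, ds_cfg, rng) if ds_cfg is not None else true_row
        )
        gi, gv = sample_context(noisy_row, context_size, rng)
        idx_rows.append(gi)
        val_rows.append(gv)
        tgt_rows.append(true_row[gi])
        totals.append(true_row.sum())
    return TokenBatch(
        gene_indices=np.stack(idx_rows),
        values=np.stack(val_rows).astype(float),
        totals=np.asarray(totals, dtype=float),
        placeholder_ids=model.config.placeholder_ids,
        target_values=np.stack(tgt_rows).astype(float),
    )


def bottleneck_pass(
    model: Model,
    batch: TokenBatch,
    encoder_placeholders: dict,
    params: dict | None = None,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> ZINBParams:
    """Decoder half of the autoencoder: same gene positions, no expression
    stream, placeholder positions carrying the encoder's output embeddings
    (the total-count position included)."""
    out = model.forward(
        batch,
        params=params,
        train=train,
        rng=rng,
        include_expression=False,
        placeholder_override=dict(encoder_placeholders),
    )
    return model.decode_expression(out.gene_embeddings, params=params, validate=False)


def _reconstruction(x, zp, mode: str):
    if mode == "zinb":
        return zinb_nll(x, zp)
    if mode == "nb":
        return nb_nll(x, zp)
    if mode == "mse":
        # single decoded value: the raw log-mean channel
        return mse_loss(anp.log2(1.0 + zp.mu), x)
    raise ValueError(f"unknown loss mode {mode!r}")


def total_loss(
    model: Model,
    batch: TokenBatch,
    labels: dict[str, np.ndarray],
    cfg: TrainConfig,
    params: dict | None = None,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Sum of the enabled task losses (unweighted) plus a component log."""
    params = model.params if params is None else params
    enc = model.forward(batch, params=params, train=train, rng=rng)
    mode = model.config.loss_mode
    components: dict = {}

    if "denoising" in cfg.tasks:
        zp = model.decode_expression(enc.gene_embeddings, params=params,
                                     validate=False)
        components["denoising"] = _reconstruction(batch.target_values, zp, mode)

    if "classification" in cfg.tasks:
        logits = model.class_logits(enc.placeholder_embeddings, params)
        cls_total = 0.0
        for cls in model.config.classes:
            cls_total = cls_total + hierarchical_ce_batch(
                logits[cls], labels.get(cls, [None] * batch.n_cells),
                model.ontologies[cls],
            )
        components["classification"] = cls_total

    if "contrastive" in cfg.tasks:
        # per-cell disentangled embedding set: default + class placeholders
        names = ["default"] + list(model.config.classes)
        stacked = anp.stack(
            [enc.placeholder_embeddings[n] for n in names], axis=1
        )  # (B, n_emb, d)
        con = 0.0
        for i in range(batch.n_cells):
            con = con + contrastive_loss(
                stacked[i], sign=model.config.contrastive_sign
            )
        components["contrastive"] = con / batch.n_cells

    if "bottleneck" in cfg.tasks:
        override = {
            name: enc.placeholder_embeddings[name]
            for name in ("total_count", "default") + model.config.classes
        }
        zp = bottleneck_pass(model, batch, override, params=params,
                             train=train, rng=rng)
        components["bottleneck"] = _reconstruction(batch.target_values, zp, mode)

    total = 0.0
    for name, v in components.items():
        val = v._value if hasattr(v, "_value") else v
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite loss component {name!r}")
        total = total + v
    return total, components


# ---------------------------------------------------------------------------
# optimizer machinery
# ---------------------------------------------------------------------------

def _tree_map(f, *trees):
    t0 = trees[0]
    if isinstance(t0, dict):
        return {k: _tree_map(f, *(t[k] for t in trees)) for k in t0}
    if isinstance(t0, list):
        return [_tree_map(f, *(t[i] for t in trees)) for i in range(len(t0))]
    return f(*trees)


def _tree_reduce_sumsq(tree) -> float:
    total = 0.0
    if isinstance(tree, dict):
        for v in tree.values():
            total += _tree_reduce_sumsq(v)
    elif isinstance(tree, list):
        for v in tree:
            total += _tree_reduce_sumsq(v)
    else:
        total += float(np.sum(np.asarray(tree) ** 2))
    return total


class _AdamW:
    """Decoupled-weight-decay Adam over a parameter pytree."""

    def __init__(self, params, lr, weight_decay, betas=(0.9, 0.999), eps=1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = _tree_map(lambda p: np.zeros_like(np.asarray(p, dtype=float)), params)
        self.v = _tree_map(lambda p: np.zeros_like(np.asarray(p, dtype=float)), params)

    def step(self, params, grads, lr_scale: float = 1.0):
        self.t += 1
        lr = self.lr * lr_scale
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        self.m = _tree_map(lambda m, g: self.b1 * m + (1 - self.b1) * g, self.m, grads)
        self.v = _tree_map(lambda v, g: self.b2 * v + (1 - self.b2) * g * g, self.v, grads)

        def upd(p, m, v):
            mhat = m / b1t
            vhat = v / b2t
            return p - lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)

        return _tree_map(upd, params, self.m, self.v)


class PlateauScheduler:
    """Plateau LR decay plus early stop on consecutive validation increases.

    ``update(val_loss)`` returns the current LR multiplier; ``should_stop``
    flips after ``early_stop_patience`` consecutive increases.
    """

    def __init__(self, factor: float = 0.6, patience: int = 1,
                 early_stop_patience: int = 3):
        self.factor = factor
        self.patience = patience
        self.early_stop_patience = early_stop_patience
        self.best = np.inf
        self.prev = np.inf
        self.bad_evals = 0
        self.consecutive_increases = 0
        self.multiplier = 1.0
        self.should_stop = False

    def update(self, val_loss: float) -> float:
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.bad_evals = 0
        else:
            self.bad_evals += 1
            if self.bad_evals > self.patience:
                self.multiplier *= self.factor
                self.bad_evals = 0
        if val_loss > self.prev + 1e-12:
            self.consecutive_increases += 1
        else:
            self.consecutive_increases = 0
        if self.consecutive_increases >= self.early_stop_patience:
            self.should_stop = True
        self.prev = val_loss
        return self.multiplier


def _warmup_scale(step: int, warmup: int) -> float:
    return min(1.0, (step + 1) / max(1, warmup))


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def train(
    model: Model,
    data: CountMatrix,
    cfg: TrainConfig,
    context_size: int | None = None,
) -> list[dict]:
    """Train the model in place; returns the metrics log (one dict per step).

    Deterministic given ``cfg.seed``: the train/validation split, the sampler,
    context sampling, corruption and dropout all derive from it.
    """
    rng = np.random.default_rng(cfg.seed)
    context_size = (
        min(model.config.context_size, data.n_genes)
        if context_size is None
        else context_size
    )

    n = data.n_cells
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    train_data = data.subset_cells(train_idx)
    val_data = data.subset_cells(np.sort(val_idx))

    label_keys = [k for k in model.config.classes if k in data.cell_labels]
    _, draw = group_sampler(
        {k: train_data.cell_labels[k] for k in label_keys} if label_keys
        else {"all": np.zeros(train_data.n_cells, dtype=str)},
        factor=cfg.sampler_factor,
        rng=rng,
    )

    # fixed validation batch, deterministic context sampling
    val_rng = np.random.default_rng([cfg.seed, 7])
    val_batch = _make_batch(
        val_data,
        np.arange(min(val_data.n_cells, max(cfg.batch_size, 8))),
        model, context_size, cfg.downsample, val_rng,
    )
    val_labels = {
        k: val_data.cell_labels[k][: val_batch.n_cells] for k in label_keys
    }

    opt = _AdamW(model.params, cfg.lr, cfg.weight_decay)
    sched = PlateauScheduler(
        cfg.lr_decay_factor, cfg.lr_patience, cfg.early_stop_patience
    )
    swa_sum = None
    swa_count = 0
    log: list[dict] = []

    def loss_fn(params, batch, labels, step_rng, train_mode):
        total, comps = total_loss(
            model, batch, labels, cfg, params=params, train=train_mode,
            rng=step_rng,
        )
        return total

    vag = value_and_grad(loss_fn)

    for step in range(cfg.steps):
        cell_idx = draw(cfg.batch_size)
        batch = _make_batch(
            train_data, cell_idx, model, context_size, cfg.downsample, rng
        )
        labels = {k: train_data.cell_labels[k][cell_idx] for k in label_keys}
        step_rng = np.random.default_rng([cfg.seed, 1, step])
        try:
            value, grads = vag(model.params, batch, labels, step_rng, True)
        except FloatingPointError as err:
            raise FloatingPointError(f"divergence at step {step}: {err}") from err
        if not np.isfinite(value):
            raise FloatingPointError(f"divergence at step {step}: loss={value}")

        gnorm = np.sqrt(_tree_reduce_sumsq(grads))
        if gnorm > cfg.grad_clip:
            scale = cfg.grad_clip / gnorm
            grads = _tree_map(lambda g: g * scale, grads)

        in_swa = cfg.swa and step >= cfg.steps // 2
        lr_scale = (
            (cfg.swa_lr / cfg.lr) if in_swa
            else _warmup_scale(step, cfg.warmup_steps) * sched.multiplier
        )
        model.params = opt.step(model.params, grads, lr_scale=lr_scale)

        if in_swa and (step % cfg.val_interval == 0):
            swa_sum = (
                _tree_map(lambda p: np.array(p, dtype=float), model.params)
                if swa_sum is None
                else _tree_map(lambda s, p: s + p, swa_sum, model.params)
            )
            swa_count += 1

        entry = {"step": step, "loss": float(value), "lr_scale": lr_scale,
                 "grad_norm": float(gnorm)}
        if (step + 1) % cfg.val_interval == 0 or step == cfg.steps - 1:
            vloss, _ = total_loss(
                model, val_batch, val_labels, cfg, params=model.params,
                train=False,
            )
            vloss = float(vloss)
            entry["val_loss"] = vloss
            if not in_swa:
                sched.update(vloss)
        log.append(entry)
        if sched.should_stop:
            break

    if cfg.swa and swa_count > 0:
        model.params = _tree_map(lambda s: s / swa_count, swa_sum)
    return log
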