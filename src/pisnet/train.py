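"""Seeded training and evaluation harness.

Optimiser configuration: Adam (first-moment coefficient 0.9), learning rate
1e-4 decayed by cosine annealing to 1e-5 over the configured epochs, batch
size 8, 400 epochs for the full-scale recipe (desk-scale runs shrink epochs
and widths via the config).  The validation split doubles as the test split
(no third split is held out); the best-validation checkpoint is retained.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
import numpy as np

from . import nn
from .autodiff import Tensor
from .data import split_samples, to_batch
from .losses import (LossWeights, combined_loss, evaluate_batch,
                     summarize, write_report)
from .model import ModelConfig, build_model, predict, save_checkpoint
from .nn import Adam, cosine_annealing_lr


@dataclass(frozen=True)
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    learning_rate: float = 1e-4
    min_learning_rate: float = 1e-5
    beta1: float = 0.9
    batch_size: int = 8
    epochs: int = 400
    seed: int = 0
    split_ratio: float = 0.8
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.min_learning_rate >= self.learning_rate:
            raise ValueError("min_learning_rate must be < learning_rate")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class TrainResult:
    model: object
    history: list                 # per-epoch dicts
    best_epoch: int
    best_val_dice: float


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train(cfg: TrainConfig, train_samples, val_samples=None,
          checkpoint_path=None, log_fn=None):
    """Train a model from a config; returns the best-validation model.

    `train_samples`/`val_samples` are SegmentationSample lists; when
    `val_samples` is None an internal seeded 8:2 split of `train_samples`
    is used.  Non-finite loss aborts with a diagnostic.
    """
    if val_samples is None:
        train_samples, val_samples = split_samples(
            train_samples, cfg.split_ratio, cfg.seed)
    nn.seed_all(cfg.seed)
    model = build_model(cfg.model)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1)
    rng = np.random.default_rng(cfg.seed + 1)

    x_tr, y_tr = to_batch(train_samples, cfg.model.in_channels)
    x_va, y_va = to_batch(val_samples, cfg.model.in_channels)

    history, best = [], (-1, -math.inf, None)
    for epoch in range(cfg.epochs):
        opt.lr = cosine_annealing_lr(epoch, cfg.epochs,
                                     cfg.learning_rate, cfg.min_learning_rate)
        model.train()
        epoch_losses = []
        for idx in _batches(len(train_samples), cfg.batch_size, rng):
            xb = Tensor(x_tr[idx])
            yb = Tensor(y_tr[idx])
            logits = model(xb)
            probs = logits.sigmoid()
            loss = combined_loss(probs, yb, cfg.loss_weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        val_probs = predict(model, x_va)
        rows = evaluate_batch(val_probs[:, 0], y_va[:, 0],
                              ids=[s.id for s in val_samples])
        stats = summarize(rows)
        record = {"epoch": epoch, "lr": opt.lr,
                  "train_loss": float(np.mean(epoch_losses)),
                  "val_iou": stats["mean_iou"], "val_dice": stats["mean_dice"]}
        history.append(record)
        if log_fn:
            log_fn(record)
        if stats["mean_dice"] > best[1]:
            best = (epoch, stats["mean_dice"], model.state_dict())

    best_epoch, best_dice, best_state = best
    model.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model,
                        extra={"best_epoch": best_epoch,
                               "best_val_dice": best_dice,
                               "seed": cfg.seed})
    return TrainResult(model=model, history=history,
                       best_epoch=best_epoch, best_val_dice=best_dice)


def train_steps(cfg: TrainConfig, samples, n_steps, batch_size=None):
    """Step-budgeted training on a fixed set (the overfit smoke recipe).

    Cycles deterministic batches for exactly `n_steps` optimiser steps with
    the cosine schedule stretched over the step budget; returns the model
    and the per-step loss curve.
    """
    batch_size = batch_size or cfg.batch_size
    nn.seed_all(cfg.seed)
    model = build_model(cfg.model)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1)
    x, y = to_batch(samples, cfg.model.in_channels)
    n = len(samples)
    rng = np.random.default_rng(cfg.seed + 1)
    order = rng.permutation(n)
    curve = []
    pos = 0
    for step in range(n_steps):
        opt.lr = cosine_annealing_lr(step, n_steps,
                                     cfg.learning_rate, cfg.min_learning_rate)
        if pos + batch_size > n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos:pos + batch_size]
        pos += batch_size
        model.train()
        logits = model(Tensor(x[idx]))
        loss = combined_loss(logits.sigmoid(), Tensor(y[idx]))
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        curve.append(float(loss.data))
    return model, curve


def evaluate(model, samples, csv_path=None, json_path=None, batch_size=8):
    """Per-image and mean IoU/Dice for a sample list; optional CSV/JSON."""
    in_channels = model.cfg.in_channels
    rows = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        x, y = to_batch(chunk, in_channels)
        probs = predict(model, x)
        rows.extend(evaluate_batch(probs[:, 0], y[:, 0],
                                   ids=[s.id for s in chunk]))
    if csv_path is not None:
        write_report(rows, csv_path, json_path)
    return rows, summarize(rows)


def write_history(history, path):
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["epoch", "lr", "train_loss", "val_iou", "val_dice"])
        writer.writeheader()
        writer.writerows(history)
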