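"""Three-phase training: prior initialization, dynamic inference, fine-tuning.

Phase 1 is implicit in construction (ULM activities anchor the embedding and
the GRN layer starts at the signed prior); phase 2 is :func:`fit`, which runs
the alpha / gamma / prior-mask schedules; phase 3 is
:func:`finetune_celltypes`, which clones the global model per cell-type and
continues training on that subset at reduced learning rate.
"""

from __future__ import annotations

import copy
import json
import logging
import math
import warnings
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from autograd import grad

from .io_prior import ExpressionMatrix, PriorNetwork, DataError
from .model import (
    LossBreakdown, ModelConfig, RegVAE, WeightedGRN,
    alpha_step, blend_weights, mask_factor,
)
from .ulm import TFActivityMatrix, ulm_activities

logger = logging.getLogger(__name__)

CHECKPOINT_SCHEMA = 1


@dataclass
class TrainConfig:
    val_fraction: float = 0.15
    learning_rate: float = 1e-3
    lr_patience: int = 10
    lr_factor: float = 0.5
    batch_size: int = 128
    max_epochs: int = 100
    early_stop_patience: int = 25
    grad_clip: float = 5.0
    min_cells: int = 20           # fine-tuning group size guard
    finetune_lr_scale: float = 0.1
    finetune_epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")


@dataclass
class TrainedModel:
    model: RegVAE
    train_config: TrainConfig
    tf_ids: list[str]
    gene_ids: list[str]
    history: list[tuple[LossBreakdown, LossBreakdown]]
    best_epoch: int
    final_alpha: float
    prior_weights: Optional[np.ndarray] = None  # for the ULM anchor at inference

    @property
    def grn(self) -> WeightedGRN:
        return WeightedGRN(self.tf_ids, self.gene_ids,
                           self.model.params["grn_W"].copy(), "global")


@dataclass
class CellTypeGRNSet:
    grns: dict[str, WeightedGRN]
    activities: dict[str, TFActivityMatrix]

    def contexts(self) -> list[str]:
        return sorted(self.grns)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, clip: float) -> None:
        norm = math.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
        scale = clip / norm if (clip > 0 and norm > clip) else 1.0
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k] * scale
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] = params[k] - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_train_val(n_cells: int, val_fraction: float, seed: int):
    """Deterministic disjoint train/validation index split."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")
    n_val = int(round(n_cells * val_fraction))
    if n_cells < 2 or n_val < 1 or n_val >= n_cells:
        raise ValueError(f"cannot split {n_cells} cells at fraction {val_fraction}")
    perm = np.random.default_rng(seed).permutation(n_cells)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _run_epochs(model, X, E_ulm, train_idx, val_idx, train_cfg, *,
                alpha, alpha_schedule, gamma_schedule, blend_schedule,
                W_prior, rng, lr):
    """Shared epoch loop for global fit and per-cell-type fine-tuning."""
    params = model.params
    opt = _Adam(params, lr)
    loss_grad = grad(model.batch_loss)
    history: list[tuple[LossBreakdown, LossBreakdown]] = []
    best = (math.inf, -1, None)  # (val_total, epoch, params copy)
    since_best = 0
    since_lr_drop = 0
    n_epochs = len(gamma_schedule)

    for epoch in range(n_epochs):
        gamma = gamma_schedule[epoch]
        order = rng.permutation(len(train_idx))
        for start in range(0, len(order), train_cfg.batch_size):
            batch = train_idx[order[start:start + train_cfg.batch_size]]
            xb = X[batch]
            eb = E_ulm[batch]
            noise = rng.standard_normal((len(batch), model.config.latent_dim))
            grads = loss_grad(params, xb, eb, alpha, gamma, noise)
            if any(not np.all(np.isfinite(g)) for g in grads.values()):
                raise FloatingPointError(f"non-finite gradient at epoch {epoch}")
            opt.step(params, grads, train_cfg.grad_clip)

        if blend_schedule:
            m = mask_factor(epoch + 1, n_epochs)
            params["grn_W"] = blend_weights(W_prior, params["grn_W"], m)

        tr = model.loss_breakdown(params, X[train_idx], E_ulm[train_idx], alpha, gamma)
        va = model.loss_breakdown(params, X[val_idx], E_ulm[val_idx], alpha, gamma)
        if not (math.isfinite(tr.total) and math.isfinite(va.total)):
            logger.warning("non-finite loss at epoch %d; stopping with last finite state", epoch)
            break
        history.append((tr, va))

        if va.total < best[0] - 1e-12:
            best = (va.total, epoch, copy.deepcopy(params))
            since_best = 0
            since_lr_drop = 0
        else:
            since_best += 1
            since_lr_drop += 1
            if since_lr_drop >= train_cfg.lr_patience:
                opt.lr *= train_cfg.lr_factor
                since_lr_drop = 0
            if since_best >= train_cfg.early_stop_patience:
                break

        if alpha_schedule:
            alpha = alpha_step(alpha, model.config.delta_alpha, model.config.alpha_max)

    if best[2] is not None:
        model.params = best[2]
    return history, best[1], alpha


def fit(expr: ExpressionMatrix, prior: PriorNetwork, e_ulm: TFActivityMatrix,
        model_cfg: ModelConfig, train_cfg: TrainConfig) -> TrainedModel:
    """Global (phase 1+2) training run; returns the best-validation checkpoint."""
    if expr.layer != "lognorm":
        raise DataError("fit expects log-normalized expression")
    if list(expr.gene_ids) != list(prior.gene_ids):
        raise DataError("expression and prior are not gene-aligned")
    if list(e_ulm.tf_ids) != list(prior.tf_ids):
        raise DataError("ULM activities and prior are not TF-aligned")

    rng = np.random.default_rng(model_cfg.seed)
    model = RegVAE(expr.n_genes, prior.n_tfs, model_cfg, prior=prior, rng=rng)
    train_idx, val_idx = split_train_val(expr.n_cells, train_cfg.val_fraction,
                                         train_cfg.seed)
    T = train_cfg.max_epochs
    gamma_schedule = np.linspace(model_cfg.gamma_start, model_cfg.gamma_end, T)
    history, best_epoch, final_alpha = _run_epochs(
        model, expr.values, e_ulm.values, train_idx, val_idx, train_cfg,
        alpha=model_cfg.alpha_start, alpha_schedule=True,
        gamma_schedule=gamma_schedule, blend_schedule=True,
        W_prior=prior.dense(), rng=rng, lr=train_cfg.learning_rate,
    )
    return TrainedModel(model=model, train_config=train_cfg,
                        tf_ids=list(prior.tf_ids), gene_ids=list(expr.gene_ids),
                        history=history, best_epoch=best_epoch,
                        final_alpha=final_alpha, prior_weights=prior.dense())


def finetune_celltypes(trained: TrainedModel, expr: ExpressionMatrix,
                       labels, e_ulm: TFActivityMatrix,
                       train_cfg: Optional[TrainConfig] = None) -> CellTypeGRNSet:
    """Phase 3: clone the global model per label and continue training.

    Groups smaller than ``train_cfg.min_cells`` are skipped with a warning.
    The ULM anchor is the global matrix restricted to each subset; alpha stays
    at its final (data-driven) value and the prior blend is no longer applied.
    """
    train_cfg = train_cfg or trained.train_config
    labels = np.asarray(labels)
    if len(labels) != expr.n_cells:
        raise ValueError("labels length does not match the number of cells")

    grns: dict[str, WeightedGRN] = {}
    acts: dict[str, TFActivityMatrix] = {}
    for label in sorted(set(map(str, labels))):
        idx = np.flatnonzero(labels.astype(str) == label)
        if len(idx) < train_cfg.min_cells:
            warnings.warn(f"cell type {label!r} has {len(idx)} cells "
                          f"(< {train_cfg.min_cells}); skipped")
            continue
        sub = expr.subset(cell_idx=idx)
        sub_ulm = e_ulm.values[idx]
        clone = copy.deepcopy(trained.model)
        # crc32, not hash(): str hashing is salted per interpreter run
        rng = np.random.default_rng(
            (train_cfg.seed + zlib.crc32(label.encode())) % (2**32)
        )
        tr_idx, va_idx = split_train_val(len(idx), train_cfg.val_fraction,
                                         train_cfg.seed)
        gamma = np.full(train_cfg.finetune_epochs, clone.config.gamma_end)
        _run_epochs(
            clone, sub.values, sub_ulm, tr_idx, va_idx, train_cfg,
            alpha=trained.final_alpha, alpha_schedule=False,
            gamma_schedule=gamma, blend_schedule=False, W_prior=None,
            rng=rng, lr=train_cfg.learning_rate * train_cfg.finetune_lr_scale,
        )
        grns[label] = WeightedGRN(trained.tf_ids, trained.gene_ids,
                                  clone.params["grn_W"].copy(), label)
        sub_model = TrainedModel(clone, train_cfg, trained.tf_ids,
                                 trained.gene_ids, [], -1, trained.final_alpha,
                                 prior_weights=trained.prior_weights)
        acts[label] = infer_activities(sub_model, sub)
    return CellTypeGRNSet(grns=grns, activities=acts)


def infer_activities(trained: TrainedModel, expr: ExpressionMatrix) -> TFActivityMatrix:
    """Deterministic (noise-free) per-cell TF activities.

    Uses the mean decoder output (z = mu); when the final alpha is below 1
    the reported activities are the blend (1-alpha) * ULM + alpha * decoder,
    with the ULM anchor recomputed on the supplied expression from the stored
    prior network.
    """
    if list(expr.gene_ids) != list(trained.gene_ids):
        missing = sorted(set(trained.gene_ids) - set(expr.gene_ids))[:10]
        raise DataError(f"gene set mismatch; missing from input: {missing}")
    model = trained.model
    mu, _ = model.encode(model.params, expr.values)
    e_dec = np.asarray(model.decode(model.params, np.asarray(mu)))
    alpha = trained.final_alpha
    if alpha < 1.0 and trained.prior_weights is not None:
        from scipy import sparse

        prior = PriorNetwork(list(trained.tf_ids), list(trained.gene_ids),
                             sparse.csr_matrix(trained.prior_weights))
        e_ulm = ulm_activities(expr, prior).values
        values = (1.0 - alpha) * e_ulm + alpha * e_dec
        source = "blended"
    else:
        values, source = e_dec, "model"
    return TFActivityMatrix(values, list(expr.cell_ids),
                            list(trained.tf_ids), source=source)


# ---------------------------------------------------------------------------
# export / checkpointing
# ---------------------------------------------------------------------------

def export_grn(grn: WeightedGRN, path, dense_csv: Optional[str] = None) -> None:
    """Write a GRN as long-format TSV (tf, gene, weight, context); zeros omitted."""
    tf_idx, gene_idx = np.nonzero(grn.weights)
    df = pd.DataFrame({
        "tf": [grn.tf_ids[i] for i in tf_idx],
        "gene": [grn.gene_ids[j] for j in gene_idx],
        "weight": grn.weights[tf_idx, gene_idx],
        "context": grn.context,
    })
    df.to_csv(path, sep="\t", index=False)
    if dense_csv is not None:
        pd.DataFrame(grn.weights, index=grn.tf_ids,
                     columns=grn.gene_ids).to_csv(dense_csv)


def import_grn(path, tf_ids=None, gene_ids=None) -> WeightedGRN:
    """Read a long-format GRN TSV back; identifier order optionally pinned."""
    df = pd.read_csv(path, sep="\t")
    tf_ids = list(tf_ids) if tf_ids is not None else list(pd.unique(df["tf"]))
    gene_ids = list(gene_ids) if gene_ids is not None else list(pd.unique(df["gene"]))
    tf_pos = {t: i for i, t in enumerate(tf_ids)}
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    W = np.zeros((len(tf_ids), len(gene_ids)))
    for tf, gene, w in zip(df["tf"], df["gene"], df["weight"]):
        W[tf_pos[str(tf)], gene_pos[str(gene)]] = w
    context = str(df["context"].iloc[0]) if "context" in df and len(df) else "global"
    return WeightedGRN(tf_ids, gene_ids, W, context)


def save_checkpoint(trained: TrainedModel, path) -> None:
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "model_config": asdict(trained.model.config),
        "train_config": asdict(trained.train_config),
        "tf_ids": trained.tf_ids,
        "gene_ids": trained.gene_ids,
        "best_epoch": trained.best_epoch,
        "final_alpha": trained.final_alpha,
    }
    arrays = {f"param/{k}": v for k, v in trained.model.params.items()}
    if trained.prior_weights is not None:
        arrays["prior_weights"] = trained.prior_weights
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise DataError(f"unsupported checkpoint schema {meta['schema']}")
        params = {k[len("param/"):]: data[k] for k in data.files
                  if k.startswith("param/")}
        prior_w = data["prior_weights"] if "prior_weights" in data.files else None
    mc = meta["model_config"]
    mc["encoder_widths"] = tuple(mc["encoder_widths"])
    mc["decoder_widths"] = tuple(mc["decoder_widths"])
    model_cfg = ModelConfig(**mc)
    model = RegVAE(len(meta["gene_ids"]), len(meta["tf_ids"]), model_cfg)
    model.params = params
    return TrainedModel(model=model, train_config=TrainConfig(**meta["train_config"]),
                        tf_ids=meta["tf_ids"], gene_ids=meta["gene_ids"],
                        history=[], best_epoch=meta["best_epoch"],
                        final_alpha=meta["final_alpha"], prior_weights=prior_w)
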