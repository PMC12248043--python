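"""Model core: encoder, reparameterization, TF-embedding decoder, GRN readout.

The network is a variational autoencoder whose decoder ends in an
interpretable linear layer: a TF x gene weight matrix ``W_grn`` mapping the
inferred TF activity embedding to reconstructed expression.  ``W_grn`` is
initialized from a signed prior network and relaxed over training by a
scheduled blend; TF activities are anchored to prior-driven ULM estimates by
a scheduled mixing coefficient alpha.

Implemented on HIPS ``autograd`` (numpy autodiff) so training runs on a plain
CPU scientific stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import autograd.numpy as anp
import numpy as np

from .io_prior import PriorNetwork

__all__ = [
    "ModelConfig", "ForwardState", "WeightedGRN", "LossBreakdown",
    "RegVAE", "kl_divergence", "grn_sparsity_loss", "total_loss",
    "alpha_step", "mask_factor", "blend_weights",
]


@dataclass
class ModelConfig:
    latent_dim: int = 64
    encoder_widths: tuple[int, ...] = (512, 256)
    decoder_widths: tuple[int, ...] = (256,)
    alpha_start: float = 0.0
    alpha_max: float = 0.9   # keep a small ULM anchor at the data-driven end
    delta_alpha: float = 0.02
    gamma_start: float = 0.0
    gamma_end: float = 1e-4
    epochs: int = 100
    seed: int = 0
    gene_bias: bool = False
    grn_init_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_start <= self.alpha_max <= 1.0):
            raise ValueError("need 0 <= alpha_start <= alpha_max <= 1")
        if self.delta_alpha <= 0:
            raise ValueError("delta_alpha must be > 0")
        if not 1 <= len(self.encoder_widths) <= 3:
            raise ValueError("encoder takes 1-3 hidden layers")
        if not 1 <= len(self.decoder_widths) <= 2:
            raise ValueError("decoder takes 1-2 hidden layers")
        if self.gamma_start < 0 or self.gamma_end < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class ForwardState:
    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray
    e_dec: np.ndarray
    e_hat: np.ndarray
    x_hat: np.ndarray


@dataclass
class WeightedGRN:
    """A real-valued TF x gene weight matrix, global or per cell type."""

    tf_ids: list[str]
    gene_ids: list[str]
    weights: np.ndarray
    context: str = "global"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValueError("GRN weight shape does not match identifier lists")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("GRN weights contain non-finite values")


@dataclass
class LossBreakdown:
    recon: float
    kl: float
    grn_l1: float

    @property
    def elbo(self) -> float:
        return self.recon + self.kl

    @property
    def total(self) -> float:
        return self.elbo + self.grn_l1


# ---------------------------------------------------------------------------
# schedule and loss primitives
# ---------------------------------------------------------------------------

def kl_divergence(mu, sigma) -> float:
    """KL( N(mu, diag(sigma^2)) || N(0, I) ), summed over dimensions.

    For batched input (2-D) the per-cell KLs are averaged.
    """
    mu = anp.atleast_2d(anp.asarray(mu, dtype=float))
    sigma = anp.atleast_2d(anp.asarray(sigma, dtype=float))
    if anp.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    per_cell = -0.5 * anp.sum(1.0 + 2.0 * anp.log(sigma) - mu**2 - sigma**2, axis=1)
    return float(anp.mean(per_cell))


def grn_sparsity_loss(W, gamma: float) -> float:
    """L1 sparsity penalty gamma * sum |W| over all GRN entries."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    weights = W.weights if isinstance(W, WeightedGRN) else W
    return float(gamma * np.sum(np.abs(weights)))


def total_loss(state: ForwardState, x, W, gamma: float) -> LossBreakdown:
    """Gaussian reconstruction NLL (MSE) + KL + L1 penalty, as a breakdown."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.atleast_2d(state.x_hat)
    recon = float(np.mean(np.sum((x - x_hat) ** 2, axis=1)))
    kl = kl_divergence(state.mu, state.sigma)
    l1 = grn_sparsity_loss(W, gamma)
    return LossBreakdown(recon=recon, kl=kl, grn_l1=l1)


def alpha_step(alpha: float, delta_alpha: float, alpha_max: float) -> float:
    """One step of the increasing, clipped alpha schedule."""
    return min(alpha_max, alpha + delta_alpha)


def mask_factor(t: float, T: float) -> float:
    """Decreasing logistic prior-mask schedule: ~1 at t=0, 0.5 at T/2, ~0 at T."""
    if T <= 0:
        raise ValueError("T must be > 0")
    return 1.0 / (1.0 + math.exp((t - T / 2.0) / (T / 20.0)))


def blend_weights(W_prior, W_t, m: float):
    """Elementwise blend m * W_prior + (1 - m) * W_t."""
    wp = W_prior.weights if isinstance(W_prior, (WeightedGRN,)) else W_prior
    if hasattr(wp, "todense"):
        wp = np.asarray(wp.todense())
    wt = W_t.weights if isinstance(W_t, WeightedGRN) else W_t
    wp = np.asarray(wp, dtype=float)
    wt = np.asarray(wt, dtype=float)
    if wp.shape != wt.shape:
        raise ValueError(f"shape mismatch {wp.shape} vs {wt.shape}")
    blended = m * wp + (1.0 - m) * wt
    if isinstance(W_t, WeightedGRN):
        return WeightedGRN(W_t.tf_ids, W_t.gene_ids, blended, W_t.context)
    return blended


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _relu(x):
    return anp.maximum(x, 0.0)


def _linear(params, name, x):
    return x @ params[f"{name}_W"] + params[f"{name}_b"]


class RegVAE:
    """VAE with a prior-initialized linear GRN readout layer.

    Parameters live in a flat dict of numpy arrays so that ``autograd`` can
    differentiate the batch loss directly; the class only holds structure
    (layer names and sizes) plus the current parameter values.
    """

    def __init__(self, n_genes: int, n_tfs: int, config: ModelConfig,
                 prior: Optional[PriorNetwork] = None,
                 rng: Optional[np.random.Generator] = None):
        self.n_genes = n_genes
        self.n_tfs = n_tfs
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.params = self._init_params(rng, prior)

    def _init_params(self, rng, prior) -> dict:
        cfg = self.config
        params: dict[str, np.ndarray] = {}

        def glorot(fan_in, fan_out):
            s = math.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-s, s, size=(fan_in, fan_out))

        d = self.n_genes
        for i, width in enumerate(cfg.encoder_widths):
            params[f"enc{i}_W"] = glorot(d, width)
            params[f"enc{i}_b"] = np.zeros(width)
            d = width
        params["mu_W"] = glorot(d, cfg.latent_dim)
        params["mu_b"] = np.zeros(cfg.latent_dim)
        params["logvar_W"] = glorot(d, cfg.latent_dim)
        params["logvar_b"] = np.zeros(cfg.latent_dim)

        d = cfg.latent_dim
        for i, width in enumerate(cfg.decoder_widths):
            params[f"dec{i}_W"] = glorot(d, width)
            params[f"dec{i}_b"] = np.zeros(width)
            d = width
        params["etf_W"] = glorot(d, self.n_tfs)
        params["etf_b"] = np.zeros(self.n_tfs)

        if prior is not None:
            W0 = prior.dense().astype(np.float64)
        else:
            W0 = glorot(self.n_tfs, self.n_genes)
        if cfg.grn_init_jitter > 0:
            W0 = W0 + rng.normal(0.0, cfg.grn_init_jitter, size=W0.shape)
        params["grn_W"] = W0
        if cfg.gene_bias:
            params["gene_b"] = np.zeros(self.n_genes)
        return params

    # -- forward pieces, written against autograd.numpy ---------------------

    def encode(self, params, x):
        h = x
        for i in range(len(self.config.encoder_widths)):
            h = _relu(_linear(params, f"enc{i}", h))
        mu = _linear(params, "mu", h)
        logvar = anp.clip(_linear(params, "logvar", h), -10.0, 10.0)
        return mu, logvar

    def decode(self, params, z):
        h = z
        for i in range(len(self.config.decoder_widths)):
            h = _relu(_linear(params, f"dec{i}", h))
        return _linear(params, "etf", h)  # linear output: activities may be < 0

    def reconstruct(self, params, e_hat):
        x_hat = e_hat @ params["grn_W"]
        if self.config.gene_bias:
            x_hat = x_hat + params["gene_b"]
        return x_hat

    def forward(self, x, e_ulm, alpha: float,
                W: Optional[WeightedGRN] = None,
                noise: Optional[np.ndarray] = None,
                params: Optional[dict] = None) -> ForwardState:
        """Deterministic-or-sampled forward pass returning all intermediates.

        ``noise=None`` gives the deterministic pass (z = mu).  ``W`` overrides
        the stored GRN weights (used when probing alternative readouts).
        """
        params = dict(params if params is not None else self.params)
        if W is not None:
            params["grn_W"] = np.asarray(W.weights, dtype=float)
        x = np.atleast_2d(np.asarray(x, dtype=float))
        e_ulm = np.atleast_2d(np.asarray(e_ulm, dtype=float))
        if x.shape[1] != self.n_genes:
            raise ValueError(f"x has {x.shape[1]} genes, model expects {self.n_genes}")
        if e_ulm.shape[1] != self.n_tfs:
            raise ValueError(f"e_ulm has {e_ulm.shape[1]} TFs, model expects {self.n_tfs}")
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        mu, logvar = self.encode(params, x)
        sigma = anp.exp(0.5 * logvar)
        z = mu if noise is None else mu + sigma * np.atleast_2d(noise)
        e_dec = self.decode(params, z)
        e_hat = (1.0 - alpha) * e_ulm + alpha * e_dec
        x_hat = self.reconstruct(params, e_hat)
        return ForwardState(mu=np.asarray(mu), sigma=np.asarray(sigma),
                           z=np.asarray(z), e_dec=np.asarray(e_dec),
                           e_hat=np.asarray(e_hat), x_hat=np.asarray(x_hat))

    def batch_loss(self, params, x, e_ulm, alpha, gamma, noise):
        """Differentiable scalar loss (autograd path used by the trainer)."""
        mu, logvar = self.encode(params, x)
        sigma = anp.exp(0.5 * logvar)
        z = mu if noise is None else mu + sigma * noise
        e_dec = self.decode(params, z)
        e_hat = (1.0 - alpha) * e_ulm + alpha * e_dec
        x_hat = e_hat @ params["grn_W"]
        if self.config.gene_bias:
            x_hat = x_hat + params["gene_b"]
        recon = anp.mean(anp.sum((x - x_hat) ** 2, axis=1))
        kl = anp.mean(-0.5 * anp.sum(1.0 + logvar - mu**2 - anp.exp(logvar), axis=1))
        l1 = gamma * anp.sum(anp.abs(params["grn_W"]))
        return recon + kl + l1

    def loss_breakdown(self, params, x, e_ulm, alpha, gamma) -> LossBreakdown:
        """Deterministic (z = mu) loss terms for logging/validation."""
        mu, logvar = self.encode(params, x)
        sigma = np.exp(0.5 * np.asarray(logvar))
        e_dec = self.decode(params, np.asarray(mu))
        e_hat = (1.0 - alpha) * e_ulm + alpha * np.asarray(e_dec)
        x_hat = e_hat @ params["grn_W"]
        if self.config.gene_bias:
            x_hat = x_hat + params["gene_b"]
        recon = float(np.mean(np.sum((x - x_hat) ** 2, axis=1)))
        kl = kl_divergence(np.asarray(mu), sigma)
        l1 = grn_sparsity_loss(params["grn_W"], gamma)
        return LossBreakdown(recon=recon, kl=kl, grn_l1=l1)
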