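"""Learning: joint optimization of network weights and per-sequence
adaptive posterior variables by free-energy descent through time.

Training is full-batch by default: every epoch unrolls all sequences,
draws fresh reparameterization noise, backpropagates the batch-mean
objective through the whole sequence length (no truncation) and applies
one Adam update to all weights and to the per-sequence adaptive
variables (A_mu, A_sigma) that parameterize each sequence's posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (NetworkParams, LayerSpec, init_params, unroll,
                   free_energy_from_cache, backward, FreeEnergyBreakdown,
                   StructuralError)
from .synthetic_data import TrajectoryData

__all__ = ["TrainConfig", "TrainResult", "TrainingDivergedError",
           "Adam", "train", "prior_generate"]


class TrainingDivergedError(RuntimeError):
    """Objective became non-finite; carries the last finite diagnostics."""

    def __init__(self, epoch: int, breakdown: FreeEnergyBreakdown | None):
        self.epoch = epoch
        self.breakdown = breakdown
        super().__init__(f"non-finite free energy at epoch {epoch}")


@dataclass
class TrainConfig:
    """Optimization settings.  ``w_train`` overrides the per-layer
    meta-prior for the whole run (the layer specs' ``w`` otherwise);
    ``n_samples`` averages gradients over several reparameterization
    draws per epoch (one-sample training by default)."""

    epochs: int = 150_000
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    w_train: Sequence[float] | None = None
    checkpoint_every: int = 0
    log_every: int = 100
    batch_size: int | None = None
    n_samples: int = 1
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


class Adam:
    """Minimal Adam over a dict of named arrays (in-place updates)."""

    def __init__(self, arrays: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, arrays: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in arrays.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainResult:
    params: NetworkParams
    Amu: np.ndarray
    Asig: np.ndarray
    history: pd.DataFrame


def _stack_targets(corpus: Sequence[TrajectoryData]) -> np.ndarray:
    if not corpus:
        raise StructuralError("corpus is empty")
    lengths = {tr.values.shape[0] for tr in corpus}
    dims = {tr.values.shape[1] for tr in corpus}
    if len(lengths) != 1 or len(dims) != 1:
        raise StructuralError("all sequences must share length and dimensionality")
    return np.stack([tr.values for tr in corpus], axis=2)  # (T, RX, B)


def train(corpus: Sequence[TrajectoryData], specs: Sequence[LayerSpec],
          cfg: TrainConfig, params: NetworkParams | None = None,
          callback=None) -> TrainResult:
    """Minimize the batch-mean free energy over the corpus.

    Returns the optimized weights, the per-sequence adaptive variables
    and a loss history with complexity and accuracy reported separately.
    Fully reproducible under ``cfg.seed``.
    """
    targets = _stack_targets(corpus)
    T, rx, B = targets.shape
    if params is None:
        params = init_params(specs, rx=rx, seed=cfg.seed)
    if cfg.w_train is not None:
        params.w = np.asarray(cfg.w_train, dtype=float)
    L = params.n_layers
    nzm = params.Wzd.shape[2]
    Amu = np.zeros((T, L, nzm, B))
    Asig = np.zeros((T, L, nzm, B))
    rng = np.random.default_rng(cfg.seed)

    arrays = dict(params.trainable())
    arrays["Amu"] = Amu
    arrays["Asig"] = Asig
    opt = Adam(arrays, cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps)

    rows = []
    last_fe = None
    for epoch in range(cfg.epochs):
        if cfg.batch_size is not None and cfg.batch_size < B:
            idx = np.sort(rng.choice(B, cfg.batch_size, replace=False))
        else:
            idx = None
        tgt = targets if idx is None else targets[:, :, idx]
        amu = Amu if idx is None else np.ascontiguousarray(Amu[:, :, :, idx])
        asig = Asig if idx is None else np.ascontiguousarray(Asig[:, :, :, idx])
        b = tgt.shape[2]

        grads_sum = None
        fe = None
        for _ in range(cfg.n_samples):
            eps = rng.standard_normal((T, L, nzm, b))
            cache = unroll(params, T, b, Amu=amu, Asig=asig, eps=eps,
                           posterior=True, unit_prior_t1=True)
            fe = free_energy_from_cache(cache, tgt, params)
            g = backward(params, cache, tgt)
            if grads_sum is None:
                grads_sum = g
            else:
                for k in grads_sum:
                    grads_sum[k] += g[k]
        if cfg.n_samples > 1:
            for k in grads_sum:
                grads_sum[k] /= cfg.n_samples
        if not np.isfinite(fe.total):
            raise TrainingDivergedError(epoch, last_fe)
        last_fe = fe

        if idx is not None:
            gAmu = np.zeros_like(Amu)
            gAsig = np.zeros_like(Asig)
            gAmu[:, :, :, idx] = grads_sum["Amu"]
            gAsig[:, :, :, idx] = grads_sum["Asig"]
            grads_sum["Amu"] = gAmu
            grads_sum["Asig"] = gAsig
        opt.step(arrays, grads_sum)

        if epoch % cfg.log_every == 0 or epoch == cfg.epochs - 1:
            row = {"epoch": epoch, "accuracy": fe.accuracy, "total": fe.total}
            for l in range(L):
                row[f"complexity_l{l + 1}"] = fe.complexity_per_layer[l]
            rows.append(row)
            if callback is not None:
                callback(epoch, fe)
    history = pd.DataFrame(rows)
    return TrainResult(params=params, Amu=Amu, Asig=Asig, history=history)


def prior_generate(params: NetworkParams, steps: int, seed: int = 0):
    """Closed-loop generative rollout: z is sampled from the learned
    prior at every step (unit Gaussian at the very first step), no
    observations are consumed.

    Returns the output trajectory (steps, R_X) and the deterministic-unit
    traces per layer (steps, L, ndm) for inspection.
    """
    if steps == 0:
        return np.zeros((0, params.rx)), np.zeros((0, params.n_layers, params.Wdd.shape[1]))
    rng = np.random.default_rng(seed)
    cache = unroll(params, steps, 1, posterior=False, unit_prior_t1=True, rng=rng)
    return cache.xbar[:, :, 0], cache.d[1:, :, :, 0]
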