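"""Online perception by error regression in a sliding window.

After training, the network perceives a target stream one sample at a
time.  All weights stay frozen; only the adaptive posterior variables
(A_mu, A_sigma) of the steps inside a sliding window are re-optimized by
a few Adam epochs of free-energy descent per sensory step.  The window
is anchored to the deterministic state just before its first step; when
it slides, the oldest step is folded into the anchor using its posterior
mean.  The controller consumes ``er_sum``, the average per-step
normalized squared reconstruction error over a recent sub-window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NetworkParams, unroll, backward, kl_unit, ContractError
from .training import Adam
from . import controller as ctl

__all__ = ["InferenceConfig", "WindowState", "PerceptStepRecord",
           "new_window_state", "perceive_step", "average_reconstruction_error",
           "perceive"]


@dataclass
class InferenceConfig:
    """Sliding-window settings: window length, error-monitoring length
    (both in time steps), and the per-step inner optimization budget."""

    window_len: int = 400
    error_window: int = 300
    inner_epochs: int = 30
    inner_lr: float = 0.05
    controller_every: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.error_window <= self.window_len:
            raise ValueError("need 0 < error_window <= window_len")
        if self.inner_epochs < 1:
            raise ValueError("inner_epochs must be >= 1")


@dataclass
class WindowState:
    """Mutable inference-window bookkeeping.  ``Amu``/``Asig`` and the
    target buffer cover exactly the min(t, window_len) most recent steps;
    the anchor is the deterministic state preceding the window.
    ``error_history`` is the trailing buffer of newest-step prediction
    errors as they were experienced, feeding ``er_sum``."""

    Amu: np.ndarray
    Asig: np.ndarray
    target_buffer: np.ndarray
    anchor_h: np.ndarray
    anchor_d: np.ndarray
    anchor_is_initial: bool
    t: int
    rng: np.random.Generator
    error_history: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.target_buffer.shape[0]


@dataclass
class PerceptStepRecord:
    """Outcome of one sensory step.

    ``errors`` are the current window's per-step normalized squared
    reconstruction errors (diagnostic); ``error_history`` is the trailing
    buffer of errors each step produced when it was newest, which is what
    ``er_sum`` averages — past errors are not rewritten when the window
    later re-optimizes."""

    t: int
    xbar: np.ndarray
    errors: np.ndarray
    error_history: np.ndarray
    kl: np.ndarray
    er_sum: float
    w: np.ndarray


def new_window_state(params: NetworkParams, cfg: InferenceConfig) -> WindowState:
    L, ndm = params.n_layers, params.Wdd.shape[1]
    nzm = params.Wzd.shape[2]
    return WindowState(
        Amu=np.zeros((0, L, nzm, 1)), Asig=np.zeros((0, L, nzm, 1)),
        target_buffer=np.zeros((0, params.rx, 1)),
        anchor_h=np.zeros((L, ndm, 1)), anchor_d=np.zeros((L, ndm, 1)),
        anchor_is_initial=True, t=0,
        rng=np.random.default_rng(cfg.seed))


def _advance_anchor(state: WindowState, params: NetworkParams) -> None:
    """Fold the oldest window step into the anchor deterministically
    (z at its posterior mean)."""
    L, nzm = params.n_layers, params.Wzd.shape[2]
    eps0 = np.zeros((1, L, nzm, 1))
    cache = unroll(params, 1, 1, Amu=np.ascontiguousarray(state.Amu[:1]),
                   Asig=np.ascontiguousarray(state.Asig[:1]), eps=eps0,
                   h0=state.anchor_h, d0=state.anchor_d,
                   posterior=True, unit_prior_t1=state.anchor_is_initial)
    state.anchor_h = np.ascontiguousarray(cache.h[1])
    state.anchor_d = np.ascontiguousarray(cache.d[1])
    state.anchor_is_initial = False
    state.Amu = state.Amu[1:]
    state.Asig = state.Asig[1:]
    state.target_buffer = state.target_buffer[1:]


def perceive_step(state: WindowState, observation: np.ndarray,
                  params: NetworkParams, w_current: np.ndarray,
                  cfg: InferenceConfig) -> tuple[WindowState, PerceptStepRecord]:
    """Consume one observation: slide the window, warm-start the new
    step's adaptive variables at zero, run ``inner_epochs`` Adam steps on
    all A in the window under the supplied meta-prior, and report the
    window reconstruction and error statistics."""
    L, nzm = params.n_layers, params.Wzd.shape[2]
    obs = np.asarray(observation, dtype=float).reshape(1, params.rx, 1)
    state.t += 1
    state.target_buffer = np.concatenate([state.target_buffer, obs], axis=0)
    state.Amu = np.concatenate([state.Amu, np.zeros((1, L, nzm, 1))], axis=0)
    state.Asig = np.concatenate([state.Asig, np.zeros((1, L, nzm, 1))], axis=0)
    if state.n > cfg.window_len:
        _advance_anchor(state, params)

    n = state.n
    w_current = np.asarray(w_current, dtype=float)
    arrays = {"Amu": state.Amu, "Asig": state.Asig}
    opt = Adam(arrays, cfg.inner_lr)
    for _ in range(cfg.inner_epochs):
        eps = state.rng.standard_normal((n, L, nzm, 1))
        cache = unroll(params, n, 1, Amu=state.Amu, Asig=state.Asig, eps=eps,
                       h0=state.anchor_h, d0=state.anchor_d,
                       posterior=True, unit_prior_t1=state.anchor_is_initial)
        g = backward(params, cache, state.target_buffer, w=w_current)
        if not (np.all(np.isfinite(g["Amu"])) and np.all(np.isfinite(g["Asig"]))):
            raise RuntimeError(f"non-finite inner gradient at t={state.t}")
        opt.step(arrays, {"Amu": g["Amu"], "Asig": g["Asig"]})

    # deterministic reporting pass (z at posterior means)
    cache = unroll(params, n, 1, Amu=state.Amu, Asig=state.Asig,
                   eps=np.zeros((n, L, nzm, 1)),
                   h0=state.anchor_h, d0=state.anchor_d,
                   posterior=True, unit_prior_t1=state.anchor_is_initial)
    xbar = cache.xbar[:, :, 0]
    errors = ((state.target_buffer[:, :, 0] - xbar) ** 2).sum(axis=1) / params.rx
    kl = np.zeros((n, L))
    for l in range(L):
        m = params.nz[l]
        if m > 0:
            kl[:, l] = kl_unit(cache.muq[:, l, :m, 0], cache.sigq[:, l, :m, 0],
                               cache.mup[:, l, :m, 0], cache.sigp[:, l, :m, 0]).sum(axis=1)
    state.error_history.append(float(errors[-1]))
    if len(state.error_history) > cfg.error_window:
        del state.error_history[:-cfg.error_window]
    hist = np.array(state.error_history)
    rec = PerceptStepRecord(t=state.t, xbar=xbar, errors=errors,
                            error_history=hist, kl=kl,
                            er_sum=float(hist.mean()), w=w_current.copy())
    return state, rec


def average_reconstruction_error(record: PerceptStepRecord, error_window: int) -> float:
    """er_sum: mean newest-step normalized squared error over the most
    recent ``error_window`` steps (all steps if fewer exist)."""
    hist = record.error_history
    if hist.size == 0:
        raise ContractError("record holds no errors")
    return float(hist[-min(error_window, hist.size):].mean())


def perceive(params: NetworkParams, target: np.ndarray, cfg: InferenceConfig,
             ctrl_cfg: "ctl.ControllerConfig | None" = None,
             fixed_w=None, initial_regime: str = ctl.FS,
             progress: bool = False):
    """Full perception loop over a target stream (T, R_X).

    With ``ctrl_cfg`` the meta-prior switches autonomously (the
    controller sleeps until ``error_window`` observations exist);
    ``fixed_w`` pins the meta-prior instead.  Returns a per-step log
    DataFrame, the controller state (or None) and the number of
    controller ticks.
    """
    target = np.asarray(target, dtype=float)
    if fixed_w is None and ctrl_cfg is None:
        fixed_w = params.w
    state = new_window_state(params, cfg)
    ctrl_state = None
    if ctrl_cfg is not None:
        ctrl_state = ctl.ControllerState.init(ctrl_cfg, regime=initial_regime)
        w_current = ctrl_state.current_w(ctrl_cfg)
    else:
        w_current = np.asarray(fixed_w, dtype=float)
    it = range(target.shape[0])
    if progress:
        from tqdm import tqdm
        it = tqdm(it)
    rows = []
    ticks = 0
    for t in it:
        state, rec = perceive_step(state, target[t], params, w_current, cfg)
        row = {"t": state.t, "x": target[t, 0], "y": target[t, 1],
               "xbar": rec.xbar[-1, 0], "ybar": rec.xbar[-1, 1],
               "err": rec.errors[-1], "er_sum": rec.er_sum,
               "regime": ctrl_state.regime if ctrl_state else ""}
        for l in range(params.n_layers):
            row[f"kl_l{l + 1}"] = rec.kl[-1, l]
            row[f"kl_win_l{l + 1}"] = rec.kl[:, l].mean()
            row[f"w_l{l + 1}"] = w_current[l]
        rows.append(row)
        if (ctrl_state is not None and state.t >= cfg.error_window
                and state.t % cfg.controller_every == 0):
            ctrl_state, w_current = ctl.step(ctrl_state, rec.er_sum, ctrl_cfg, state.t)
            ticks += 1
    return pd.DataFrame(rows), ctrl_state, ticks
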