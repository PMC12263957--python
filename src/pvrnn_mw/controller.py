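"""Error-driven meta-prior switching between focus and mind-wandering.

A two-state machine modulates the per-layer complexity weight ``w``.
In the focus state (FS, low ``w``) the posterior tracks the senses; once
the recent average reconstruction error ``er_sum`` falls near a lower
threshold, the machine flips, with a sigmoid probability, to the
mind-wandering state (MW, high ``w``) in which top-down generation
dominates and the error drifts upward.  Crossing an upper threshold
makes the reverse flip likely.  A temperature parameter sets how sharp
(deterministic) or soft (random) the threshold behavior is:

    P(FS -> MW) = sigmoid(-(er_sum - Thr_L) / Temp)
    P(MW -> FS) = sigmoid( (er_sum - Thr_H) / Temp)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["ControllerConfig", "ControllerState", "Transition",
           "transition_probability", "step", "controller_step"]

FS = "FS"
MW = "MW"


@dataclass
class ControllerConfig:
    w_low: tuple[float, ...] = (0.01, 0.01)
    w_high: tuple[float, ...] = (100.0, 100.0)
    thr_low: float = 0.15
    thr_high: float = 0.40
    temperature: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not self.thr_low < self.thr_high:
            raise ValueError("thr_low must be < thr_high")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not all(lo < hi for lo, hi in zip(self.w_low, self.w_high)):
            raise ValueError("w_low must be < w_high elementwise")


@dataclass
class Transition:
    t: int
    src: str
    dst: str
    er_sum: float
    p: float


@dataclass
class ControllerState:
    regime: str = FS
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    transition_log: list[Transition] = field(default_factory=list)

    @classmethod
    def init(cls, cfg: ControllerConfig, regime: str = FS) -> "ControllerState":
        return cls(regime=regime, rng=np.random.default_rng(cfg.seed))

    def current_w(self, cfg: ControllerConfig) -> np.ndarray:
        return np.asarray(cfg.w_low if self.regime == FS else cfg.w_high, dtype=float)


def transition_probability(regime: str, er_sum: float, cfg: ControllerConfig) -> float:
    """Probability of leaving ``regime`` given the current average error.
    Exactly 0.5 at the regime's threshold; approaches a hard step as the
    temperature goes to zero and a coin flip as it grows."""
    if regime == FS:
        return float(expit(-(er_sum - cfg.thr_low) / cfg.temperature))
    if regime == MW:
        return float(expit((er_sum - cfg.thr_high) / cfg.temperature))
    raise ValueError(f"unknown regime {regime!r}")


def step(state: ControllerState, er_sum: float, cfg: ControllerConfig,
         t: int) -> tuple[ControllerState, np.ndarray]:
    """One controller tick: draw u ~ U(0,1), flip the regime iff
    u < P(leave), log any flip, and return the meta-prior vector for the
    (possibly new) regime."""
    p = transition_probability(state.regime, er_sum, cfg)
    if state.rng.random() < p:
        dst = MW if state.regime == FS else FS
        state.transition_log.append(Transition(t=t, src=state.regime, dst=dst,
                                               er_sum=float(er_sum), p=p))
        state.regime = dst
    return state, state.current_w(cfg)


controller_step = step
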