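"""Evaluation tooling: cycle categorization, transition statistics and
the temperature-sweep experiment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chisquare

from .core import NetworkParams, ContractError
from .synthetic_data import CyclicPattern
from .online_inference import InferenceConfig, perceive
from .controller import ControllerConfig, FS

__all__ = ["CycleLabelSeries", "SweepResult", "categorize_cycles",
           "transition_stats", "destination_uniformity_pvalue",
           "temperature_sweep"]


@dataclass
class CycleLabelSeries:
    """One template label per completed period of an output stream, with
    the phase-aligned distance of each cycle to every template."""

    labels: np.ndarray
    match_scores: np.ndarray  # (n_cycles, n_templates), best-shift distances


def categorize_cycles(output: np.ndarray, templates: list[CyclicPattern]) -> CycleLabelSeries:
    """Assign each consecutive period-length segment of ``output`` to the
    nearest template, minimizing mean Euclidean distance over all cyclic
    phase shifts (generated streams are phase-locked; generative rollouts
    are not)."""
    output = np.asarray(output, dtype=float)
    period = templates[0].period
    if output.shape[0] < period:
        raise ContractError("output shorter than one period")
    n_cycles = output.shape[0] // period
    K = len(templates)
    # (K, period, period, 2): every cyclic shift of every template
    shifted = np.stack([
        np.stack([np.roll(tp.points, s, axis=0) for s in range(period)])
        for tp in templates])
    labels = np.empty(n_cycles, dtype=np.int64)
    scores = np.empty((n_cycles, K))
    for c in range(n_cycles):
        seg = output[c * period:(c + 1) * period]
        dist = np.linalg.norm(shifted - seg[None, None], axis=3).mean(axis=2)
        scores[c] = dist.min(axis=1)
        labels[c] = int(scores[c].argmin())
    return CycleLabelSeries(labels=labels, match_scores=scores)


def transition_stats(series: CycleLabelSeries):
    """Empirical stay probability, switch probability and the
    destination-count matrix over consecutive cycle labels."""
    labels = np.asarray(series.labels if isinstance(series, CycleLabelSeries) else series)
    if labels.size < 2:
        raise ContractError("need at least two cycles")
    k = int(labels.max()) + 1
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in zip(labels[:-1], labels[1:]):
        counts[a, b] += 1
    n = labels.size - 1
    p_stay = float(np.trace(counts)) / n
    return p_stay, 1.0 - p_stay, counts


def destination_uniformity_pvalue(counts: np.ndarray) -> float:
    """Chi-square p-value for uniformity of switch destinations (the
    off-diagonal counts, pooled by destination rank within each row)."""
    counts = np.asarray(counts)
    k = counts.shape[0]
    pooled = np.zeros(k - 1, dtype=np.int64)
    for a in range(k):
        dests = [counts[a, b] for b in range(k) if b != a]
        pooled += np.array(dests)
    if pooled.sum() == 0:
        return 1.0
    return float(chisquare(pooled).pvalue)


@dataclass
class SweepResult:
    temperatures: np.ndarray
    transitions_per_1000: list[np.ndarray]  # per temperature, one entry per run

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean() for c in self.transitions_per_1000])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.std(ddof=1) if c.size > 1 else 0.0
                         for c in self.transitions_per_1000])


def temperature_sweep(params: NetworkParams, target: np.ndarray,
                      temps, n_runs: int, inf_cfg: InferenceConfig,
                      ctrl_cfg: ControllerConfig, seed: int = 0) -> SweepResult:
    """Run the full perceive+controller loop ``n_runs`` times per
    temperature with distinct seeds and count FS->MW transitions,
    normalized per 1,000 controller-active steps."""
    temps = np.asarray(temps, dtype=float)
    results = []
    for i, temp in enumerate(temps):
        rates = []
        for r in range(n_runs):
            run_seed = int(np.random.SeedSequence([seed, i, r]).generate_state(1)[0] % (2 ** 31))
            icfg = InferenceConfig(window_len=inf_cfg.window_len,
                                   error_window=inf_cfg.error_window,
                                   inner_epochs=inf_cfg.inner_epochs,
                                   inner_lr=inf_cfg.inner_lr,
                                   controller_every=inf_cfg.controller_every,
                                   seed=run_seed)
            ccfg = ControllerConfig(w_low=ctrl_cfg.w_low, w_high=ctrl_cfg.w_high,
                                    thr_low=ctrl_cfg.thr_low, thr_high=ctrl_cfg.thr_high,
                                    temperature=float(temp), seed=run_seed + 1)
            _, ctrl_state, ticks = perceive(params, target, icfg, ctrl_cfg=ccfg,
                                            initial_regime=FS)
            n_fs_mw = sum(1 for tr in ctrl_state.transition_log if tr.src == FS)
            rates.append(1000.0 * n_fs_mw / max(ticks, 1))
        results.append(np.array(rates))
    return SweepResult(temperatures=temps, transitions_per_1000=results)
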