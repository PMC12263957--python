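"""Markov-switching cyclic pattern generator.

Training and test streams for the network are 2-D time series built by
chaining cycles of a small repertoire of closed curves.  After each
completed cycle the active pattern either repeats (probability ``p_stay``)
or switches to one of the other ``K - 1`` patterns chosen uniformly.
Sparse Gaussian perturbations are added at randomly spaced time points to
mimic sensor jitter without destroying the cyclic structure.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CyclicPattern",
    "GeneratorSpec",
    "TrajectoryData",
    "make_default_patterns",
    "generate_trajectory",
    "add_sparse_noise",
    "make_training_corpus",
    "write_trajectory",
    "read_trajectory",
    "write_corpus",
]


class InvalidSpecError(ValueError):
    """Raised when generator parameters violate their contracts."""


@dataclass(frozen=True)
class CyclicPattern:
    """One period of a closed 2-D curve.

    ``points`` has shape (period, 2) and all coordinates lie in (-1, 1) so
    that a tanh readout can represent them.
    """

    points: np.ndarray
    id: int

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidSpecError("pattern points must be (period, 2)")
        if np.max(np.abs(pts)) >= 1.0:
            raise InvalidSpecError("pattern coordinates must lie within (-1, 1)")

    @property
    def period(self) -> int:
        return self.points.shape[0]


@dataclass
class GeneratorSpec:
    """Full description of the switching-pattern source.

    ``p_stay`` is the probability that the same pattern repeats after a
    completed cycle; switching mass is split equally over the other
    patterns.  Noise points are spaced by rounded draws from
    Normal(noise_interval_mean, noise_interval_sd), clamped to >= 1 step,
    and perturb both coordinates by Normal(0, noise_sd).
    """

    patterns: Sequence[CyclicPattern] = field(default_factory=lambda: make_default_patterns(4, 30, 0))
    p_stay: float = 0.2727
    noise_interval_mean: float = 1.0
    noise_interval_sd: float = 10.0
    noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_stay <= 1.0:
            raise InvalidSpecError("p_stay must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if len(self.patterns) < 1:
            raise InvalidSpecError("at least one pattern required")
        periods = {p.period for p in self.patterns}
        if len(periods) != 1:
            raise InvalidSpecError("all patterns must share one period")

    @property
    def k(self) -> int:
        return len(self.patterns)

    @property
    def period(self) -> int:
        return self.patterns[0].period


@dataclass
class TrajectoryData:
    """A generated stream: values (T, 2), per-step pattern labels (T,),
    and the indices at which a pattern period completes."""

    values: np.ndarray
    labels: np.ndarray
    cycle_boundaries: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# pattern repertoire
# ---------------------------------------------------------------------------

def _shape_circle(theta, radius, direction=1.0, phase=0.0):
    a = direction * theta + phase
    return np.stack([radius * np.cos(a), radius * np.sin(a)], axis=1)


def _shape_eight(theta, amp):
    # Lissajous 1:2 figure-eight
    return np.stack([amp * np.sin(theta), amp * np.sin(2 * theta)], axis=1)


def _shape_ellipse(theta, ax, ay, direction=1.0):
    a = direction * theta
    return np.stack([ax * np.cos(a), ay * np.sin(a)], axis=1)


def make_default_patterns(k: int, period: int = 30, seed: int = 0) -> list[CyclicPattern]:
    """Build ``k`` mutually distinguishable closed curves sampled at
    ``period`` points.

    The first four are fixed shapes (large circle, counter-rotating small
    circle, figure-eight, flat ellipse); further patterns are circles with
    seeded random phase and graded radii.  Pairwise mean distances are far
    above the generator's nominal noise scale.
    """
    if k < 2:
        raise InvalidSpecError("need at least k=2 patterns")
    if period < 4:
        raise InvalidSpecError("period must be >= 4")
    theta = 2 * np.pi * np.arange(period) / period
    shapes = [
        _shape_circle(theta, 0.8),
        _shape_circle(theta, 0.35, direction=-1.0),
        _shape_eight(theta, 0.7),
        _shape_ellipse(theta, 0.85, 0.25, direction=-1.0),
    ]
    rng = np.random.default_rng(seed)
    while len(shapes) < k:
        r = 0.15 + 0.75 * (len(shapes) - 3) / max(k - 3, 1)
        shapes.append(_shape_circle(theta, min(r, 0.9), direction=(-1.0) ** len(shapes),
                                    phase=rng.uniform(0, 2 * np.pi)))
    return [CyclicPattern(points=s, id=i) for i, s in enumerate(shapes[:k])]


# ---------------------------------------------------------------------------
# trajectory assembly
# ---------------------------------------------------------------------------

def _markov_labels(spec: GeneratorSpec, n_cycles: int, rng: np.random.Generator) -> np.ndarray:
    k = spec.k
    labels = np.empty(n_cycles, dtype=np.int64)
    labels[0] = rng.integers(k)
    for c in range(1, n_cycles):
        if k == 1 or rng.random() < spec.p_stay:
            labels[c] = labels[c - 1]
        else:
            others = [i for i in range(k) if i != labels[c - 1]]
            labels[c] = others[rng.integers(k - 1)]
    return labels


def generate_trajectory(spec: GeneratorSpec, n_cycles: int, *, with_noise: bool = True,
                        rng: np.random.Generator | None = None) -> TrajectoryData:
    """Chain ``n_cycles`` pattern periods under the Markov stay/switch rule.

    The initial pattern is uniform over the repertoire.  Deterministic
    given ``spec.seed`` (or an explicit ``rng``).
    """
    if n_cycles < 1:
        raise InvalidSpecError("n_cycles must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    period = spec.period
    cyc_labels = _markov_labels(spec, n_cycles, rng)
    values = np.concatenate([spec.patterns[c].points for c in cyc_labels], axis=0)
    labels = np.repeat(cyc_labels, period)
    boundaries = period * np.arange(1, n_cycles + 1)
    traj = TrajectoryData(values=values, labels=labels, cycle_boundaries=boundaries)
    if with_noise:
        traj = add_sparse_noise(traj, spec, rng=rng)
    return traj


def add_sparse_noise(traj: TrajectoryData, spec: GeneratorSpec, *,
                     rng: np.random.Generator | None = None) -> TrajectoryData:
    """Perturb isolated points of the stream.

    Gap lengths between perturbed indices are drawn from
    Normal(noise_interval_mean, noise_interval_sd), rounded to the nearest
    integer and clamped to a minimum of one step; at each selected index
    both coordinates receive independent Normal(0, noise_sd) offsets.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    values = traj.values.copy()
    T = values.shape[0]
    i = max(1, int(round(rng.normal(spec.noise_interval_mean, spec.noise_interval_sd))))
    while i < T:
        values[i] += rng.normal(0.0, spec.noise_sd, size=2)
        i += max(1, int(round(rng.normal(spec.noise_interval_mean, spec.noise_interval_sd))))
    return TrajectoryData(values=values, labels=traj.labels.copy(),
                          cycle_boundaries=traj.cycle_boundaries.copy())


def make_training_corpus(spec: GeneratorSpec, n_seqs: int, steps: int) -> list[TrajectoryData]:
    """Independent trajectories with per-sequence seeds derived from
    ``spec.seed``; ``steps`` must be a whole number of periods."""
    if steps % spec.period != 0:
        raise InvalidSpecError("steps must be a multiple of the pattern period")
    if n_seqs < 1:
        raise InvalidSpecError("n_seqs must be >= 1")
    n_cycles = steps // spec.period
    out = []
    for i in range(n_seqs):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        out.append(generate_trajectory(spec, n_cycles, rng=rng))
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def write_trajectory(traj: TrajectoryData, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "x", "y", "label"])
        for t in range(traj.n_steps):
            w.writerow([t, f"{traj.values[t, 0]:.10g}", f"{traj.values[t, 1]:.10g}",
                        int(traj.labels[t])])


def read_trajectory(path: str | Path, period: int = 30) -> TrajectoryData:
    arr = np.genfromtxt(path, delimiter=",", names=True)
    values = np.stack([arr["x"], arr["y"]], axis=1)
    labels = arr["label"].astype(np.int64)
    T = values.shape[0]
    boundaries = period * np.arange(1, T // period + 1)
    return TrajectoryData(values=values, labels=labels, cycle_boundaries=boundaries)


def write_corpus(corpus: list[TrajectoryData], spec: GeneratorSpec, out_dir: str | Path) -> Path:
    """Write one CSV per sequence plus a JSON manifest recording the spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, traj in enumerate(corpus):
        name = f"seq_{i:04d}.csv"
        write_trajectory(traj, out_dir / name)
        files.append(name)
    meta = asdict(spec)
    meta["patterns"] = [{"id": p.id, "points": p.points.tolist()} for p in spec.patterns]
    manifest = {"files": files, "generator": meta}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir / "manifest.json"


def read_corpus(manifest_path: str | Path) -> tuple[list[TrajectoryData], GeneratorSpec]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    meta = manifest["generator"]
    patterns = [CyclicPattern(points=np.asarray(p["points"]), id=p["id"])
                for p in meta.pop("patterns")]
    spec = GeneratorSpec(patterns=patterns, **meta)
    corpus = [read_trajectory(manifest_path.parent / f, period=spec.period)
              for f in manifest["files"]]
    return corpus, spec
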