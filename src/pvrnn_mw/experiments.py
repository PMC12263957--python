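"""The reference study protocol at desk scale.

The full-size protocol (200 sequences of 3,000 steps, 60+30 d-units,
150,000 epochs) is far beyond a single-CPU session, so the package
defines one fixed scaled-down protocol used by the test suite and the
results script: two cyclic patterns (the repertoire's large circle and
counter-rotating small circle), the same stay probability and noise
statistics as the full protocol, a proportionally smaller network, and a
training budget at which prior generation reliably reproduces the
corpus switching statistics.  Perception keeps the full-size window
lengths (400 / 300) so that transition counts per 1,000 steps remain on
the same time scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import GeneratorSpec, make_default_patterns, make_training_corpus
from .core import LayerSpec
from .training import TrainConfig, TrainResult, train
from .online_inference import InferenceConfig

__all__ = ["ScaledProtocol", "default_protocol", "train_scaled_model",
           "pattern_stream"]


@dataclass(frozen=True)
class ScaledProtocol:
    """Frozen constants of the desk-scale study.

    ``pattern_ids`` select from the default repertoire the two most
    separated shapes (large circle, figure-eight; mean squared
    separation ~0.57 per dimension) so that a full top-down deviation
    drives the normalized error well past the controller's upper
    threshold, as in the full-size study."""

    pattern_ids: tuple = (0, 2)
    period: int = 30
    p_stay: float = 0.2727
    n_seqs: int = 20
    steps: int = 300
    layer_sizes: tuple = ((32, 4, 3.0), (16, 2, 5.0))  # (n_d, n_z, tau) per layer
    w_train: tuple = (0.1, 0.1)
    epochs: int = 8000
    learning_rate: float = 1e-3
    inner_epochs: int = 15
    inner_lr: float = 0.05

    @property
    def k(self) -> int:
        return len(self.pattern_ids)

    def patterns(self):
        repertoire = make_default_patterns(4, self.period, 0)
        return [repertoire[i] for i in self.pattern_ids]

    def generator_spec(self, seed: int) -> GeneratorSpec:
        return GeneratorSpec(patterns=self.patterns(),
                             p_stay=self.p_stay, seed=seed)

    def layer_specs(self) -> list[LayerSpec]:
        return [LayerSpec(nd, nz, tau, w)
                for (nd, nz, tau), w in zip(self.layer_sizes, self.w_train)]

    def train_config(self, seed: int, epochs: int | None = None) -> TrainConfig:
        return TrainConfig(epochs=self.epochs if epochs is None else epochs,
                           learning_rate=self.learning_rate, seed=seed,
                           log_every=200)

    def inference_config(self, seed: int) -> InferenceConfig:
        return InferenceConfig(inner_epochs=self.inner_epochs,
                               inner_lr=self.inner_lr, seed=seed)


def default_protocol() -> ScaledProtocol:
    return ScaledProtocol()


def train_scaled_model(seed: int, epochs: int | None = None,
                       protocol: ScaledProtocol | None = None) -> TrainResult:
    """Generate the scaled corpus and train the scaled network, all
    seeded from ``seed``."""
    proto = protocol or default_protocol()
    spec = proto.generator_spec(seed)
    corpus = make_training_corpus(spec, proto.n_seqs, proto.steps)
    return train(corpus, proto.layer_specs(), proto.train_config(seed, epochs))


def pattern_stream(pattern_id: int, n_steps: int,
                   protocol: ScaledProtocol | None = None) -> np.ndarray:
    """A noiseless perception target: one trained pattern tiled."""
    proto = protocol or default_protocol()
    pats = proto.patterns()
    reps = int(np.ceil(n_steps / proto.period))
    return np.tile(pats[pattern_id].points, (reps, 1))[:n_steps]
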