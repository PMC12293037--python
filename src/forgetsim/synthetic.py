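"""Synthetic trial-record generator for the forgetting experiment.

Emulates the paired-associate design: each participant studies word pairs,
takes an initial test, and is retested after a retention interval of 2, 20
or 80 intervening trials (10 analyzed pairs per condition, 99 participants
by default). Initial strengths are drawn directly as

    strength = mu0 + participant_effect + item_noise

(participant_effect ~ N(0, participant_sd), item_noise ~ N(0, item_sd));
the learning phase is not simulated mechanistically because no learning
model is specified by the design. A test is correct when the item's current
strength exceeds the threshold, optionally perturbed by a lapse probability
(failure despite being above threshold) and a guess probability (success
despite being below); both default to 0 so that correctness is a pure
threshold read-out. Final-test strength is the initial strength minus the
decrement d(interval) of the configured forgetting function. Blank final
responses are injected at ``blank_prob`` and are always scored incorrect.

The default configuration calibrates the threshold to the 33rd percentile
of the initial-strength distribution, so about a third of items fail the
initial test and are excluded by the analysis pipeline — the hallmark of
the experimental data this generator emulates. Fillers and the practice
phase are not generated; only the 30 analyzed pairs per participant.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forgetting import ForgettingFunction, PowerForgetting, forgetting_from_dict

__all__ = [
    "GeneratorConfig",
    "generate",
    "write_trials",
    "default_config",
    "default_concave_config",
    "null_config",
    "threshold_for_initial_accuracy",
]


def threshold_for_initial_accuracy(
    mu0: float, participant_sd: float, item_sd: float, accuracy: float
) -> float:
    """Threshold placing P(strength > theta) at ``accuracy`` for the marginal normal."""
    if not 0 < accuracy < 1:
        raise ValueError("accuracy must be in (0, 1)")
    sigma = float(np.hypot(participant_sd, item_sd))
    return float(mu0 + sigma * stats.norm.ppf(1.0 - accuracy))


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic experiment.

    ``decrement`` is any ForgettingFunction; only its decrement d(t) is used
    (its own intercept is irrelevant here). Probabilities: ``lapse`` is the
    chance an above-threshold item is missed on a test, ``guess`` the chance
    a below-threshold item is answered correctly, ``blank_prob`` the chance
    the final response is left blank (blanks score incorrect). All default
    to 0 to keep the threshold read-out exact.
    """

    n_participants: int = 99
    items_per_condition: int = 10
    intervals: tuple = (2, 20, 80)
    mu0: float = 2.0
    participant_sd: float = 0.4
    item_sd: float = 0.6
    threshold: Optional[float] = None  # None -> 33rd percentile (67% initial accuracy)
    decrement: ForgettingFunction = dataclasses.field(
        default_factory=lambda: PowerForgetting(0.0, 0.05, 0.5)
    )
    lapse: float = 0.0
    guess: float = 0.0
    blank_prob: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_participants < 1 or self.items_per_condition < 1:
            raise ValueError("counts must be >= 1")
        for name in ("lapse", "guess", "blank_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.participant_sd < 0 or self.item_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if len(self.intervals) < 2:
            raise ValueError("need at least 2 interval conditions")

    @property
    def effective_threshold(self) -> float:
        if self.threshold is not None:
            return float(self.threshold)
        return threshold_for_initial_accuracy(
            self.mu0, self.participant_sd, self.item_sd, 2.0 / 3.0
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intervals"] = list(self.intervals)
        d["decrement"] = self.decrement.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "decrement" in d and isinstance(d["decrement"], dict):
            d["decrement"] = forgetting_from_dict(d["decrement"])
        if "intervals" in d:
            d["intervals"] = tuple(d["intervals"])
        return cls(**d)


def default_config() -> GeneratorConfig:
    """Experiment-emulation defaults: ~67% initial accuracy (33% item exclusion)."""
    return GeneratorConfig()


def default_concave_config() -> GeneratorConfig:
    """A parameter set under which the analyzed curve comes out concave.

    High initial strength and a small strength SD put the threshold ~1.6 SD
    below the mean (about 5% of items fail the initial test), and the power
    decrement is scaled so the bulk of the distribution crosses the threshold
    during the *second* retention interval. Group means then decrease across
    (2, 20, 80), per-interval forgetting accelerates, and the slope
    difference is large relative to its between-participant spread — the
    concave regime of the model at high recall.
    """
    return GeneratorConfig(
        participant_sd=0.25,
        item_sd=0.25,
        threshold=2.0 - 1.645 * float(np.hypot(0.25, 0.25)),
        decrement=PowerForgetting(0.0, 0.017, 0.87),
    )


def null_config() -> GeneratorConfig:
    """Zero-forgetting scenario for type-I calibration of the pipeline.

    The decrement is identically zero and a 0.5 lapse rate makes every
    analyzed final-test outcome an independent fair coin, so the two
    per-participant slopes differ only by symmetric noise and the Wilcoxon
    p-value should reject at the nominal rate.
    """
    return GeneratorConfig(
        decrement=PowerForgetting(0.0, 0.0, 0.5),
        lapse=0.5,
    )


def generate(
    config: GeneratorConfig, seed: Optional[int] = None, with_latent: bool = False
):
    """Generate schema-valid trial records; deterministic given the seed.

    ``seed`` overrides ``config.seed``. With ``with_latent=True`` also
    returns a dict of latent arrays (strengths, assignments) for diagnostics.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    P = config.n_participants
    conds = [int(i) for i in config.intervals]
    I = config.items_per_condition * len(conds)
    theta = config.effective_threshold

    u = rng.normal(0.0, config.participant_sd, size=P)
    e = rng.normal(0.0, config.item_sd, size=(P, I))
    strength = config.mu0 + u[:, None] + e

    base_assignment = np.repeat(conds, config.items_per_condition)
    assignment = np.stack([rng.permutation(base_assignment) for _ in range(P)])

    flip_initial = rng.random(size=(P, I))
    flip_final = rng.random(size=(P, I))
    blank_draw = rng.random(size=(P, I))

    decr = {c: float(config.decrement.decrement_at(float(c))) for c in conds}
    d = np.vectorize(decr.get)(assignment)

    above0 = strength > theta
    initial_correct = np.where(above0, flip_initial >= config.lapse, flip_initial < config.guess)
    final_strength = strength - d
    above1 = final_strength > theta
    final_hit = np.where(above1, flip_final >= config.lapse, flip_final < config.guess)
    final_blank = blank_draw < config.blank_prob
    final_correct = final_hit & ~final_blank

    pid = np.repeat([f"p{k + 1:03d}" for k in range(P)], I)
    iid = np.tile([f"it{k + 1:02d}" for k in range(I)], P)
    records = pd.DataFrame(
        {
            "participant_id": pid,
            "item_id": iid,
            "interval": assignment.ravel(),
            "initial_correct": initial_correct.ravel().astype(int),
            "final_blank": final_blank.ravel().astype(int),
            "final_correct": final_correct.ravel().astype(int),
            "did_before": np.zeros(P * I, dtype=int),
        }
    )
    if with_latent:
        return records, {
            "strength": strength,
            "final_strength": final_strength,
            "assignment": assignment,
            "threshold": theta,
            "participant_effect": u,
        }
    return records


def write_trials(records: pd.DataFrame, path) -> None:
    """Write trial records in the canonical CSV dialect (booleans as 0/1)."""
    records.to_csv(path, index=False)
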