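"""Distributions of memory strength relative to a recall threshold.

Memory strength is a unitless latent scalar: an item is retrieved on a test
exactly when its strength lies *strictly above* a recall threshold ``theta``.
The empirically observed recall rate is therefore the survival function of the
strength distribution evaluated at the threshold, ``P(S > theta)``.

Four families are supported:

``Normal``
    Gaussian strengths, the canonical illustration of the model.
``Uniform``
    Rectangular strengths; the large-spread limit in which the observed
    forgetting curve tracks the item forgetting curve.
``Mixture``
    Weighted mixture of any valid components; a two-component normal mixture
    models the bifurcated distribution produced by testing without feedback.
``Empirical``
    A finite list of strengths with mass 1/n per point (step-function cdf).

The strength scale is arbitrary. Package defaults put the threshold at 0 and
initial strengths at Normal(mean=2, sd=1), which places the population in the
high-recall regime.
"""

from __future__ import annotations

import abc
import dataclasses
import math
from typing import Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "StrengthDistribution",
    "Normal",
    "Uniform",
    "Mixture",
    "Empirical",
    "Threshold",
    "recall_fraction",
    "distribution_from_dict",
]

DEFAULT_THRESHOLD = 0.0
DEFAULT_INITIAL_MEAN = 2.0
DEFAULT_INITIAL_SD = 1.0


@dataclasses.dataclass(frozen=True)
class Threshold:
    """Recall threshold on the strength scale. Items with strength > theta recall."""

    theta: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta):
            raise ValueError("threshold must be finite")


ThresholdLike = Union[Threshold, float, int]


def as_theta(thr: ThresholdLike) -> float:
    """Coerce a Threshold or bare number to the float threshold value."""
    if isinstance(thr, Threshold):
        return thr.theta
    theta = float(thr)
    if not math.isfinite(theta):
        raise ValueError("threshold must be finite")
    return theta


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class StrengthDistribution(abc.ABC):
    """A univariate distribution of memory strengths."""

    family: str

    @abc.abstractmethod
    def cdf(self, x):
        """P(strength <= x), vectorised over ``x``."""

    @abc.abstractmethod
    def sample(self, n: int, seed=None) -> np.ndarray:
        """``n`` independent draws; deterministic given an integer seed."""

    @abc.abstractmethod
    def shift(self, delta: float) -> "StrengthDistribution":
        """Distribution of (strength + delta); negative delta models forgetting."""

    @abc.abstractmethod
    def to_dict(self) -> dict:
        """JSON-serialisable spec ``{"family": ..., "params": {...}}``."""

    def recall_fraction(self, thr: ThresholdLike = DEFAULT_THRESHOLD) -> float:
        """P(strength > theta): the fraction of items that would be recalled.

        Strict inequality: an item sitting exactly at the threshold counts as
        forgotten. This convention is applied consistently package-wide.
        """
        return float(1.0 - self.cdf(as_theta(thr)))

    @staticmethod
    def _check_n(n: int) -> int:
        n = int(n)
        if n < 1:
            raise ValueError("sample size n must be >= 1")
        return n


class Normal(StrengthDistribution):
    family = "normal"

    def __init__(self, mean: float = DEFAULT_INITIAL_MEAN, sd: float = DEFAULT_INITIAL_SD):
        mean, sd = float(mean), float(sd)
        if not (math.isfinite(mean) and math.isfinite(sd)):
            raise ValueError("normal parameters must be finite")
        if sd <= 0:
            raise ValueError(f"normal sd must be > 0, got {sd}")
        self.mean = mean
        self.sd = sd

    def cdf(self, x):
        return stats.norm.cdf(x, loc=self.mean, scale=self.sd)

    def sample(self, n, seed=None):
        n = self._check_n(n)
        return _rng(seed).normal(self.mean, self.sd, size=n)

    def shift(self, delta):
        return Normal(self.mean + float(delta), self.sd)

    def to_dict(self):
        return {"family": "normal", "params": {"mean": self.mean, "sd": self.sd}}

    def __repr__(self):
        return f"Normal(mean={self.mean!r}, sd={self.sd!r})"


class Uniform(StrengthDistribution):
    family = "uniform"

    def __init__(self, lower: float, upper: float):
        lower, upper = float(lower), float(upper)
        if not (math.isfinite(lower) and math.isfinite(upper)):
            raise ValueError("uniform bounds must be finite")
        if lower >= upper:
            raise ValueError(f"uniform requires lower < upper, got [{lower}, {upper}]")
        self.lower = lower
        self.upper = upper

    def cdf(self, x):
        return stats.uniform.cdf(x, loc=self.lower, scale=self.upper - self.lower)

    def sample(self, n, seed=None):
        n = self._check_n(n)
        return _rng(seed).uniform(self.lower, self.upper, size=n)

    def shift(self, delta):
        d = float(delta)
        return Uniform(self.lower + d, self.upper + d)

    def to_dict(self):
        return {"family": "uniform", "params": {"lower": self.lower, "upper": self.upper}}

    def __repr__(self):
        return f"Uniform({self.lower!r}, {self.upper!r})"


class Mixture(StrengthDistribution):
    """Weighted mixture of strength distributions.

    ``components`` is a sequence of ``(weight, StrengthDistribution)`` pairs with
    positive weights summing to 1 (within 1e-9). A two-component normal mixture
    with well-separated means is the bifurcated case produced by retrieval
    practice without feedback.
    """

    family = "mixture"

    _WEIGHT_TOL = 1e-9

    def __init__(self, components: Sequence[tuple]):
        components = [(float(w), c) for w, c in components]
        if not components:
            raise ValueError("mixture needs at least one component")
        for w, c in components:
            if not (math.isfinite(w) and w > 0):
                raise ValueError(f"mixture weights must be positive, got {w}")
            if not isinstance(c, StrengthDistribution):
                raise TypeError("mixture components must be StrengthDistribution")
        total = sum(w for w, _ in components)
        if abs(total - 1.0) > self._WEIGHT_TOL:
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        self.components = components

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, c in self.components:
            out = out + w * np.asarray(c.cdf(x), dtype=float)
        return out if out.ndim else float(out)

    def sample(self, n, seed=None):
        n = self._check_n(n)
        rng = _rng(seed)
        weights = np.array([w for w, _ in self.components])
        idx = rng.choice(len(self.components), size=n, p=weights / weights.sum())
        out = np.empty(n)
        for k, (_, comp) in enumerate(self.components):
            mask = idx == k
            if mask.any():
                out[mask] = comp.sample(int(mask.sum()), seed=rng)
        return out

    def shift(self, delta):
        return Mixture([(w, c.shift(delta)) for w, c in self.components])

    def to_dict(self):
        return {
            "family": "mixture",
            "params": {
                "components": [
                    {"weight": w, "component": c.to_dict()} for w, c in self.components
                ]
            },
        }

    def __repr__(self):
        return f"Mixture({self.components!r})"


class Empirical(StrengthDistribution):
    """Finite set of strengths, mass 1/n per point; cdf is the right-continuous step function."""

    family = "empirical"

    def __init__(self, values: Sequence[float]):
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("empirical distribution needs a non-empty 1-d value list")
        if not np.all(np.isfinite(values)):
            raise ValueError("empirical values must be finite")
        self.values = np.sort(values)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self.values, x, side="right") / self.values.size
        return out if out.ndim else float(out)

    def sample(self, n, seed=None):
        n = self._check_n(n)
        return _rng(seed).choice(self.values, size=n, replace=True)

    def shift(self, delta):
        return Empirical(self.values + float(delta))

    def to_dict(self):
        return {"family": "empirical", "params": {"values": self.values.tolist()}}

    def __repr__(self):
        return f"Empirical(n={self.values.size})"


def recall_fraction(dist: StrengthDistribution, thr: ThresholdLike = DEFAULT_THRESHOLD) -> float:
    """Fraction of the strength distribution strictly above the threshold."""
    return dist.recall_fraction(thr)


def distribution_from_dict(spec: dict) -> StrengthDistribution:
    """Rebuild a distribution from its ``{"family": ..., "params": {...}}`` spec."""
    if not isinstance(spec, dict) or "family" not in spec:
        raise ValueError("distribution spec must be a dict with a 'family' key")
    family = spec["family"]
    params = spec.get("params", {})
    if family == "normal":
        return Normal(**params)
    if family == "uniform":
        return Uniform(**params)
    if family == "empirical":
        return Empirical(params["values"])
    if family == "mixture":
        comps = [
            (c["weight"], distribution_from_dict(c["component"]))
            for c in params["components"]
        ]
        return Mixture(comps)
    raise ValueError(f"unknown distribution family: {family!r}")
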