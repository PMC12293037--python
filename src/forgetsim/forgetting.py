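"""Item-level forgetting trajectories.

A forgetting function describes how a *single* item's latent strength f(t)
declines with time t >= 0 (time in abstract units; the experiment analysis
uses intervening trials as the unit). Three families:

linear        f(t) = s - r*t
exponential   f(t) = s - a**t        (a > 1, so strength decreases)
power         f(t) = s - a * t**b   (a >= 0, b > 0)

Note the exponential family's literal form has f(0) = s - 1, not s: the a**t
term is 1 at t = 0. The shared-shift engine therefore works with the
*decrement* d(t) = f(0) - f(t), which starts at 0 for every family
(linear r*t; power a*t**b; exponential a**t - 1).

Strength is not clamped at zero: observed forgetting arises from threshold
crossings, not from a floor on the latent scale.
"""

from __future__ import annotations

import abc
import math

import numpy as np

__all__ = [
    "ForgettingFunction",
    "LinearForgetting",
    "ExponentialForgetting",
    "PowerForgetting",
    "forgetting_from_dict",
]


def _check_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("time t must be finite and >= 0")
    return t


class ForgettingFunction(abc.ABC):
    """Latent strength trajectory of one item."""

    family: str
    s: float

    @abc.abstractmethod
    def decrement_at(self, t):
        """Cumulative strength lost by time t: d(t) = f(0) - f(t), d(0) = 0."""

    @abc.abstractmethod
    def to_dict(self) -> dict: ...

    def __eq__(self, other) -> bool:
        if not isinstance(other, ForgettingFunction):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __hash__(self) -> int:
        return hash(repr(self.to_dict()))

    def strength_at(self, t):
        """f(t); vectorised over t. May go arbitrarily negative."""
        t = _check_times(t)
        out = self.initial_strength - self.decrement_at(t)
        return out if np.ndim(out) else float(out)

    @property
    def initial_strength(self) -> float:
        """f(0): s for linear/power, s - 1 for the exponential family."""
        return self.s

    def time_to_reach(self, level: float) -> float:
        """Smallest t >= 0 with f(t) <= level (closed form per family).

        Returns ``math.inf`` when the trajectory never reaches ``level``
        (e.g. a linear function with rate 0).
        """
        level = float(level)
        f0 = self.initial_strength
        if level > f0:
            raise ValueError(f"level {level} exceeds initial strength {f0}")
        if level == f0:
            return 0.0
        return self._inverse(level)

    @abc.abstractmethod
    def _inverse(self, level: float) -> float:
        """Solve f(t) = level for level strictly below f(0)."""


class LinearForgetting(ForgettingFunction):
    """f(t) = s - r*t with rate r >= 0 per unit time."""

    family = "linear"

    def __init__(self, s: float, rate: float):
        s, rate = float(s), float(rate)
        if not (math.isfinite(s) and math.isfinite(rate)):
            raise ValueError("parameters must be finite")
        if rate < 0:
            raise ValueError(f"linear rate must be >= 0, got {rate}")
        self.s = s
        self.rate = rate

    def decrement_at(self, t):
        t = _check_times(t)
        out = self.rate * t
        return out if out.ndim else float(out)

    def _inverse(self, level):
        if self.rate == 0:
            return math.inf
        return (self.s - level) / self.rate

    def to_dict(self):
        return {"family": "linear", "s": self.s, "params": {"rate": self.rate}}

    def __repr__(self):
        return f"LinearForgetting(s={self.s!r}, rate={self.rate!r})"


class ExponentialForgetting(ForgettingFunction):
    """f(t) = s - a**t, base a > 1 so that strength decreases over time.

    Bases in (0, 1) would make f *increase* with time under this form and are
    rejected; remembering-with-time is outside this model.
    """

    family = "exponential"

    def __init__(self, s: float, base: float):
        s, base = float(s), float(base)
        if not (math.isfinite(s) and math.isfinite(base)):
            raise ValueError("parameters must be finite")
        if base <= 1:
            raise ValueError(
                f"exponential base must be > 1 (got {base}): with f(t) = s - a**t a "
                "base <= 1 gives non-decreasing strength, which is not forgetting"
            )
        self.s = s
        self.base = base

    @property
    def initial_strength(self):
        return self.s - 1.0

    def decrement_at(self, t):
        t = _check_times(t)
        out = np.power(self.base, t) - 1.0
        return out if out.ndim else float(out)

    def _inverse(self, level):
        # f(t) = s - a**t <= level  <=>  a**t >= s - level
        return math.log(self.s - level) / math.log(self.base)

    def to_dict(self):
        return {"family": "exponential", "s": self.s, "params": {"base": self.base}}

    def __repr__(self):
        return f"ExponentialForgetting(s={self.s!r}, base={self.base!r})"


class PowerForgetting(ForgettingFunction):
    """f(t) = s - a * t**b with scale a >= 0, exponent b > 0.

    With b < 1 the decrement decelerates: loss is fast at first and slower
    later, the classic retention-function shape.
    """

    family = "power"

    def __init__(self, s: float, scale: float, exponent: float):
        s, scale, exponent = float(s), float(scale), float(exponent)
        if not all(map(math.isfinite, (s, scale, exponent))):
            raise ValueError("parameters must be finite")
        if scale < 0:
            raise ValueError(f"power scale must be >= 0, got {scale}")
        if exponent <= 0:
            raise ValueError(f"power exponent must be > 0, got {exponent}")
        self.s = s
        self.scale = scale
        self.exponent = exponent

    def decrement_at(self, t):
        t = _check_times(t)
        out = self.scale * np.power(t, self.exponent)
        return out if out.ndim else float(out)

    def _inverse(self, level):
        if self.scale == 0:
            return math.inf
        return ((self.s - level) / self.scale) ** (1.0 / self.exponent)

    def to_dict(self):
        return {
            "family": "power",
            "s": self.s,
            "params": {"scale": self.scale, "exponent": self.exponent},
        }

    def __repr__(self):
        return (
            f"PowerForgetting(s={self.s!r}, scale={self.scale!r}, "
            f"exponent={self.exponent!r})"
        )


def forgetting_from_dict(spec: dict) -> ForgettingFunction:
    """Rebuild a forgetting function from ``{"family": ..., "s": ..., "params": {...}}``."""
    if not isinstance(spec, dict) or "family" not in spec:
        raise ValueError("forgetting spec must be a dict with a 'family' key")
    family, s, params = spec["family"], spec.get("s", 0.0), spec.get("params", {})
    if family == "linear":
        return LinearForgetting(s, **params)
    if family == "exponential":
        return ExponentialForgetting(s, **params)
    if family == "power":
        return PowerForgetting(s, **params)
    raise ValueError(f"unknown forgetting family: {family!r}")
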