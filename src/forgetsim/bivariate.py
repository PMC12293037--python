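"""Bivariate retrieval/storage model: heterogeneous per-item forgetting.

Each item carries two latent quantities: its current *retrieval strength*
(what a recall test probes) and a *storage strength* that governs how fast
retrieval strength is lost — durable items forget slowly. The two are
positively correlated (rho), so strong items also tend to be durable.

Operationally the sampler draws a latent standard bivariate normal
(z_retrieval, z_storage) with correlation rho, maps z_retrieval to the
initial strength s_i = s_mean + s_sd * z_retrieval, and maps storage
monotonically to the forgetting scale parameter via a log-linear link

    a_i = a_base * exp(-kappa * z_storage)          (power family)
    a_i = 1 + a_base * exp(-kappa * z_storage)      (exponential family)

kappa > 0 controls the spread of forgetting rates; the log-linear form keeps
every a_i in its valid range while preserving "more storage -> slower
forgetting". The power exponent can also vary per item (lognormal around
b_mean with log-sd b_sd), but is held fixed by default.

Two consequences of rate heterogeneity are exposed here and tested:

- the strength distribution *morphs*: it grows wider and more negatively
  skewed over time, because weak items (which are also fast-forgetting) race
  leftward while durable items barely move;
- the aggregate observed curve of pure-exponential items is typically fit
  better by a power form than by an exponential one.

This model is flexible enough to fit many curve shapes, so a good fit is not
evidence for it; the package deliberately ships no fit-to-real-data API.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .forgetting import ExponentialForgetting, PowerForgetting

__all__ = [
    "PopulationSpec",
    "ItemPopulation",
    "sample_population",
    "distribution_summary",
    "DistributionSummary",
]


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """Population-level parameters for a heterogeneous item sample.

    Attributes
    ----------
    family : {"power", "exponential"}
        Per-item forgetting family.
    s_mean, s_sd : float
        Mean and SD of initial retrieval strength (unitless scale).
    rho : float
        Correlation between latent retrieval and storage strengths, |rho| <= 1.
    a_base : float
        Baseline forgetting scale: the value of a_i (power) or a_i - 1
        (exponential) for an item of average storage strength.
    kappa : float
        Storage-to-rate link strength (>= 0); 0 gives identical rates.
    b_mean, b_sd : float
        Power exponent: per-item b_i = b_mean * exp(b_sd * z) with independent
        standard-normal z. b_sd defaults to 0 (no exponent spread).
    """

    family: str = "power"
    s_mean: float = 2.0
    s_sd: float = 1.0
    rho: float = 0.6
    a_base: float = 0.25
    kappa: float = 0.5
    b_mean: float = 0.5
    b_sd: float = 0.0

    def __post_init__(self):
        if self.family not in ("power", "exponential"):
            raise ValueError(f"unknown forgetting family {self.family!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")
        if self.s_sd < 0 or self.kappa < 0 or self.b_sd < 0:
            raise ValueError("s_sd, kappa and b_sd must be >= 0")
        if self.a_base <= 0:
            raise ValueError("a_base must be > 0")
        if self.b_mean <= 0:
            raise ValueError("b_mean must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class ItemPopulation:
    """A finite sample of items with per-item initial strengths and rates."""

    spec: PopulationSpec
    s: np.ndarray          # initial retrieval strengths
    storage: np.ndarray    # latent storage z-scores
    a: np.ndarray          # per-item forgetting scale (valid for the family)
    b: Optional[np.ndarray]  # per-item power exponents (None for exponential)
    seed: Optional[int] = None

    def __post_init__(self):
        fam = self.spec.family
        if fam == "exponential":
            if np.any(self.a <= 1):
                raise ValueError("exponential items need base a_i > 1")
        else:
            if np.any(self.a < 0):
                raise ValueError("power items need scale a_i >= 0")
            if self.b is None or np.any(self.b <= 0):
                raise ValueError("power items need exponents b_i > 0")

    @property
    def n(self) -> int:
        return self.s.size

    def decrements_at(self, times) -> np.ndarray:
        """Per-item decrement matrix d_i(t), shape (n, len(times))."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(t < 0):
            raise ValueError("time t must be >= 0")
        if self.spec.family == "power":
            tb = np.where(t[None, :] > 0, np.power(np.maximum(t, 1e-300)[None, :], self.b[:, None]), 0.0)
            return self.a[:, None] * tb
        return np.power(self.a[:, None], t[None, :]) - 1.0

    def strengths_at(self, times) -> np.ndarray:
        """Per-item strengths s_i - d_i(t), shape (n, len(times))."""
        return self.s[:, None] - self.decrements_at(times)

    def evolve(self, t: float) -> np.ndarray:
        """Strengths of every item at a single time t."""
        return self.strengths_at([float(t)])[:, 0]

    def item_function(self, i: int):
        """The i-th item's forgetting function as a ForgettingFunction object."""
        if self.spec.family == "power":
            return PowerForgetting(float(self.s[i]), float(self.a[i]), float(self.b[i]))
        # exponential: align initial strength, ItemPopulation treats s_i as f(0)
        return ExponentialForgetting(float(self.s[i]) + 1.0, float(self.a[i]))

    def to_frame(self, times: Sequence[float]):
        """Long-format evolved strengths: columns item_id, t, strength."""
        import pandas as pd

        t = np.asarray(times, dtype=float)
        strengths = self.strengths_at(t)
        return pd.DataFrame(
            {
                "item_id": np.repeat(np.arange(self.n), t.size),
                "t": np.tile(t, self.n),
                "strength": strengths.ravel(),
            }
        )


def sample_population(spec: PopulationSpec, n: int, seed=None) -> ItemPopulation:
    """Draw ``n`` items from the bivariate population; deterministic given seed.

    With rho = 0 and kappa = b_sd = 0 the population reduces exactly to the
    homogeneous model (every item shares a_base and b_mean).
    """
    n = int(n)
    if n < 1:
        raise ValueError("population size n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z_r = rng.standard_normal(n)
    z_extra = rng.standard_normal(n)
    # correlated storage z-score: rho*z_r + sqrt(1-rho^2)*independent noise
    z_s = spec.rho * z_r + math.sqrt(max(0.0, 1.0 - spec.rho**2)) * z_extra
    s = spec.s_mean + spec.s_sd * z_r
    rate_scale = spec.a_base * np.exp(-spec.kappa * z_s)
    if spec.family == "power":
        a = rate_scale
        b = spec.b_mean * np.exp(spec.b_sd * rng.standard_normal(n))
    else:
        a = 1.0 + rate_scale
        b = None
    return ItemPopulation(spec=spec, s=s, storage=z_s, a=a, b=b,
                          seed=seed if isinstance(seed, int) else None)


class DistributionSummary(NamedTuple):
    mean: float
    sd: float
    skewness: float


def distribution_summary(strengths) -> DistributionSummary:
    """Sample mean, SD (n-1 denominator) and adjusted Fisher-Pearson skewness."""
    x = np.asarray(strengths, dtype=float)
    if x.size < 3:
        raise ValueError("distribution summary needs at least 3 values")
    return DistributionSummary(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        skewness=float(stats.skew(x, bias=False)),
    )
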