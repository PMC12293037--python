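"""Observed forgetting curves and their shape diagnostics.

The empirically observed forgetting curve is the fraction of items whose
strength exceeds the recall threshold at each time point. Under the
homogeneous-shift assumption (every item loses the same decrement d(t)) the
curve is available in closed form:

    p(t) = 1 - F(theta + d(t))

where F is the cdf of the initial strength distribution. The Monte Carlo
route simulates a finite item sample and counts threshold survivors; it also
covers heterogeneous populations in which each item carries its own
forgetting parameters (see :mod:`forgetsim.bivariate`).

Shape diagnostics classify a curve as convex ("left side of a smile",
decelerating loss), linear, or concave ("right side of a frown",
accelerating loss) from slope changes across adjacent intervals, and
:func:`fit_observed` fits power/exponential aggregate forms to an observed
curve, which is how the averaging artifact (a mixture of exponential items
looking like a power curve) is demonstrated.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .distributions import StrengthDistribution, ThresholdLike, as_theta
from .forgetting import ForgettingFunction

__all__ = [
    "ObservedCurve",
    "ShapeReport",
    "RegimeComparison",
    "analytic_observed",
    "monte_carlo_observed",
    "classify_shape",
    "fit_observed",
    "FitResult",
    "regime_comparison",
]

#: Default tolerance for calling a slope change "linear" (p per time unit).
DEFAULT_SHAPE_EPSILON = 1e-4


@dataclasses.dataclass(frozen=True)
class ObservedCurve:
    """Fraction recalled over time, with optional Monte Carlo standard errors."""

    times: np.ndarray
    p: np.ndarray
    se: Optional[np.ndarray] = None
    n_items: Optional[int] = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if times.ndim != 1 or times.shape != p.shape:
            raise ValueError("times and p must be 1-d arrays of equal length")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any((p < -1e-12) | (p > 1 + 1e-12)):
            raise ValueError("p values must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "p", np.clip(p, 0.0, 1.0))
        if self.se is not None:
            se = np.asarray(self.se, dtype=float)
            if se.shape != p.shape:
                raise ValueError("se must match p in shape")
            object.__setattr__(self, "se", se)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "p": self.p,
                "se": self.se if self.se is not None else np.full_like(self.p, np.nan),
                "n_items": self.n_items if self.n_items is not None else np.nan,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservedCurve":
        import pandas as pd

        df = pd.read_csv(path)
        for col in ("time", "p"):
            if col not in df.columns:
                raise ValueError(f"curve CSV missing required column {col!r}")
        se = df["se"].to_numpy() if "se" in df and df["se"].notna().all() else None
        n_items = None
        if "n_items" in df and df["n_items"].notna().all():
            n_items = int(df["n_items"].iloc[0])
        return cls(df["time"].to_numpy(), df["p"].to_numpy(), se=se, n_items=n_items)


def analytic_observed(
    dist: StrengthDistribution,
    fn: ForgettingFunction,
    thr: ThresholdLike,
    times: Sequence[float],
) -> ObservedCurve:
    """Closed-form observed curve under the homogeneous-shift assumption.

    Every item's strength at time t is its initial strength minus the shared
    decrement d(t), so p(t) = 1 - F(theta + d(t)), exact up to cdf accuracy.
    """
    times = np.asarray(times, dtype=float)
    theta = as_theta(thr)
    d = np.asarray(fn.decrement_at(times), dtype=float)
    p = 1.0 - np.asarray(dist.cdf(theta + d), dtype=float)
    return ObservedCurve(times=times, p=p)


def monte_carlo_observed(
    model,
    thr: ThresholdLike,
    times: Sequence[float],
    n_items: Optional[int] = None,
    seed=None,
) -> ObservedCurve:
    """Simulated observed curve from a finite item sample.

    ``model`` is either a ``(StrengthDistribution, ForgettingFunction)`` pair
    (homogeneous: initial strengths sampled, shared decrement applied) or any
    object with a ``strengths_at(times) -> (n_items, n_times)`` method such as
    :class:`forgetsim.bivariate.ItemPopulation`. Items are evaluated on the
    supplied grid only — no event-driven crossing detection — so grid
    resolution is the caller's responsibility.
    """
    times = np.asarray(times, dtype=float)
    theta = as_theta(thr)
    if isinstance(model, tuple):
        dist, fn = model
        if n_items is None or int(n_items) < 1:
            raise ValueError("homogeneous Monte Carlo requires n_items >= 1")
        s0 = dist.sample(int(n_items), seed=seed)
        strengths = s0[:, None] - np.asarray(fn.decrement_at(times), dtype=float)[None, :]
    else:
        strengths = np.asarray(model.strengths_at(times), dtype=float)
        if n_items is not None and int(n_items) != strengths.shape[0]:
            raise ValueError("n_items disagrees with the population size")
    n = strengths.shape[0]
    p = np.mean(strengths > theta, axis=0)
    se = np.sqrt(p * (1.0 - p) / n)
    return ObservedCurve(times=times, p=p, se=se, n_items=n)


@dataclasses.dataclass(frozen=True)
class ShapeReport:
    """Slope/curvature summary of an observed curve.

    ``second_differences`` are changes in adjacent interval slopes,
    (p[k+1]-p[k])/(t[k+1]-t[k]) - (p[k]-p[k-1])/(t[k]-t[k-1]), in units of
    p per time unit; divided first differences make the measure meaningful on
    unequally spaced grids such as the experiment's (2, 20, 80). An interior
    point is concave when its slope change is below -epsilon, convex above
    +epsilon, linear otherwise.
    """

    times: np.ndarray
    slopes: np.ndarray
    second_differences: np.ndarray
    point_labels: tuple
    overall: str
    r_squared: float
    epsilon: float

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "slopes": self.slopes.tolist(),
            "second_differences": self.second_differences.tolist(),
            "point_labels": list(self.point_labels),
            "overall": self.overall,
            "r_squared": self.r_squared,
            "epsilon": self.epsilon,
        }


def _label(sd: float, epsilon: float) -> str:
    if sd < -epsilon:
        return "concave"
    if sd > epsilon:
        return "convex"
    return "linear"


def classify_shape(curve: ObservedCurve, epsilon: float = DEFAULT_SHAPE_EPSILON) -> ShapeReport:
    """Classify an observed curve as convex / linear / concave / mixed.

    Overall label: majority vote over interior points; if both concave and
    convex labels occur, or the vote ties, the overall label is "mixed".
    Requires >= 3 strictly increasing time points.
    """
    t, p = curve.times, curve.p
    if t.size < 3:
        raise ValueError("shape classification needs at least 3 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("shape classification needs strictly increasing times")
    slopes = np.diff(p) / np.diff(t)
    second = np.diff(slopes)
    labels = tuple(_label(sd, epsilon) for sd in second)

    counts = {lab: labels.count(lab) for lab in ("concave", "convex", "linear")}
    if counts["concave"] and counts["convex"]:
        overall = "mixed"
    else:
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        overall = winners[0] if len(winners) == 1 else "mixed"

    # linearity index: R^2 of the straight-line fit p ~ t
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0
    else:
        coeffs = np.polyfit(t, p, 1)
        resid = p - np.polyval(coeffs, t)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot

    return ShapeReport(
        times=t,
        slopes=slopes,
        second_differences=second,
        point_labels=labels,
        overall=overall,
        r_squared=r2,
        epsilon=float(epsilon),
    )


@dataclasses.dataclass(frozen=True)
class FitResult:
    family: str
    params: dict
    sse: float
    constant_input: bool = False

    def predict(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return _predict(self.family, self.params, times)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "sse": self.sse,
            "constant_input": self.constant_input,
        }


def _predict(family: str, params: dict, t: np.ndarray) -> np.ndarray:
    if family == "power":
        # t**b at t=0 is 0 for every b > 0
        tb = np.where(t > 0, np.power(np.maximum(t, 1e-300), params["b"]), 0.0)
        raw = params["c"] - params["a"] * tb
    elif family == "exponential":
        raw = params["c"] - np.exp(params["lam"] * t)  # a**t with a = exp(lam)
    else:
        raise ValueError(f"unknown fit family {family!r}")
    return np.clip(raw, 0.0, 1.0)


def _fit_family(family: str, t: np.ndarray, p: np.ndarray, seed: int) -> FitResult:
    """Multi-start bounded least squares on the clipped curve forms."""
    rng = np.random.default_rng(seed)
    p0, p_end = float(p[0]), float(p[-1])
    t_end = max(float(t[-1]), 1.0)
    starts = []
    if family == "power":
        # p(t) = clip(c - a * t**b)
        for b0 in (0.25, 0.5, 0.8, 1.0, 1.5):
            a0 = max((p0 - p_end) / t_end**b0, 1e-6)
            starts.append((p0, a0, b0))
        for _ in range(3):
            starts.append((p0 + rng.uniform(-0.05, 0.05), rng.uniform(1e-4, 0.5), rng.uniform(0.2, 1.8)))
        bounds = ([-0.5, 0.0, 1e-3], [2.0, 50.0, 4.0])
        names = ("c", "a", "b")
    else:
        # p(t) = clip(c - a**t), parameterised by lam = ln a > 0, c may exceed 1
        for lam0 in (0.005, 0.02, 0.05, 0.1, 0.3, 1.0):
            starts.append((p0 + 1.0, lam0))
        for _ in range(3):
            starts.append((p0 + 1.0 + rng.uniform(-0.1, 0.1), rng.uniform(1e-3, 1.5)))
        bounds = ([0.0, 1e-6], [3.0, 5.0])
        names = ("c", "lam")

    def residuals(x):
        return _predict(family, dict(zip(names, x)), t) - p

    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), bounds[0], bounds[1])
        try:
            res = optimize.least_squares(residuals, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        raise RuntimeError("curve fitting failed from every start")
    sse, x = best
    params = dict(zip(names, (float(v) for v in x)))
    if family == "exponential":
        params["a"] = float(np.exp(params["lam"]))
    return FitResult(family=family, params=params, sse=sse)


def fit_observed(
    times: Sequence[float],
    p: Sequence[float],
    family: str,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of an aggregate curve form to observed recall fractions.

    Families (on the p scale, clipped to [0, 1]):

    - ``"power"``:       p(t) = c - a * t**b
    - ``"exponential"``: p(t) = c - a**t (the intercept c may exceed 1 so the
      clipped curve can start near ceiling; a > 1 is enforced via a = e**lam)

    The optimiser is a seeded multi-start grid with bounded local refinement
    (scipy ``least_squares``). Fitting operates on observed recall fractions,
    not latent strengths — the strengths are unobservable in a recall test.
    Constant input returns the constant fit flagged ``constant_input``.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.size < 3 or t.shape != p.shape:
        raise ValueError("need >= 3 matching time/p points")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if family not in ("power", "exponential"):
        raise ValueError(f"unknown fit family {family!r}")
    if np.allclose(p, p[0]):
        const = float(p[0])
        if family == "power":
            params = {"c": const, "a": 0.0, "b": 1.0}
        else:
            params = {"c": const + 1.0, "lam": 0.0, "a": 1.0}
        return FitResult(family=family, params=params, sse=0.0, constant_input=True)
    return _fit_family(family, t, p, seed)


# ---------------------------------------------------------------------------
# Regime diagnostics: observed curvature vs item-trajectory curvature
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RegimeComparison:
    """Mean |slope change| of observed vs item curves, split by recall regime."""

    observed_high: float
    item_high: float
    observed_low: float
    item_low: float
    n_high: int
    n_low: int

    @property
    def flatter_at_high_recall(self) -> bool:
        return self.observed_high < self.item_high

    @property
    def curvier_at_low_recall(self) -> bool:
        return self.observed_low > self.item_low

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _mean_abs_second_diff(t: np.ndarray, y: np.ndarray) -> float:
    slopes = np.diff(y) / np.diff(t)
    return float(np.mean(np.abs(np.diff(slopes))))


def regime_comparison(
    dist: StrengthDistribution,
    fn: ForgettingFunction,
    thr: ThresholdLike,
    times: Sequence[float],
    high: float = 0.6,
    low: float = 0.3,
) -> RegimeComparison:
    """Compare observed-curve curvature with item-curve curvature by regime.

    At high recall (p > ``high``) the distribution's pull opposes the item
    curve's convexity, flattening the observed curve; at low recall
    (p < ``low``) the two effects compound and the observed curve is curvier
    than the item trajectory. Curvature is the mean absolute slope change on
    the restricted time window, computed for the analytic observed curve and
    for the item strength trajectory on the same window.
    """
    times = np.asarray(times, dtype=float)
    curve = analytic_observed(dist, fn, thr, times)
    strength = np.asarray(fn.strength_at(times), dtype=float)

    def window(mask: np.ndarray) -> tuple:
        idx = np.flatnonzero(mask)
        if idx.size < 3:
            raise ValueError("regime window has fewer than 3 time points")
        tw = times[idx[0] : idx[-1] + 1]
        return (
            _mean_abs_second_diff(tw, curve.p[idx[0] : idx[-1] + 1]),
            _mean_abs_second_diff(tw, strength[idx[0] : idx[-1] + 1]),
            idx.size,
        )

    obs_hi, item_hi, n_hi = window(curve.p > high)
    obs_lo, item_lo, n_lo = window(curve.p < low)
    return RegimeComparison(
        observed_high=obs_hi,
        item_high=item_hi,
        observed_low=obs_lo,
        item_low=item_lo,
        n_high=n_hi,
        n_low=n_lo,
    )
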