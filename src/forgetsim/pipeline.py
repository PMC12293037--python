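"""Analysis pipeline for the paired-associate forgetting experiment.

Trial records describe one participant x item observation: the item's
retention-interval condition (2, 20 or 80 intervening trials between the
initial and final test), whether the initial test was answered correctly,
and the final-test outcome (correct / blank). The pipeline applies the
pre-registration-style exclusions, keeps only items answered correctly on
the initial test, computes per-participant recall proportions by condition,
converts them to forgetting-per-unit-time slopes, and compares the two
interval slopes with a Wilcoxon signed-rank test (the slope differences are
generally non-normal, which a Shapiro-Wilk check documents).

Slope scale: percentage points per intervening item. With percent scores
P1, P2, P3 at intervals (2, 20, 80):

    slope1 = (P2 - P1) / (20 - 2)      slope2 = (P3 - P2) / (80 - 20)

Slopes are signed (negative when forgetting). Proportion inputs in [0, 1]
are multiplied by 100 first.

Wilcoxon conventions (documented because the literature varies):
W = sum of ranks of positive differences; zero differences are dropped;
ties receive midranks; the p-value is exact (tie-aware null distribution by
rank convolution) for n <= 25 and a normal approximation with continuity
and tie correction otherwise; the matched-pairs rank-biserial effect size is
(R+ - R-) / (R+ + R-).
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curves import DEFAULT_SHAPE_EPSILON, ObservedCurve, ShapeReport, classify_shape

__all__ = [
    "REQUIRED_COLUMNS",
    "DESIGN_INTERVALS",
    "validate_records",
    "apply_participant_exclusions",
    "filter_initially_correct",
    "condition_means",
    "forgetting_slopes",
    "interval_drops",
    "paired_wilcoxon",
    "WilcoxonResult",
    "normality_check",
    "analyze_experiment",
    "SlopeStats",
    "ExperimentReport",
    "read_trials",
]

REQUIRED_COLUMNS = (
    "participant_id",
    "item_id",
    "interval",
    "initial_correct",
    "final_blank",
    "final_correct",
    "did_before",
)

DESIGN_INTERVALS = (2, 20, 80)

_BOOL_COLUMNS = ("initial_correct", "final_blank", "final_correct", "did_before")


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV (booleans as 0/1) and validate it."""
    return validate_records(pd.read_csv(path))


def validate_records(records: pd.DataFrame, intervals: Sequence[int] = DESIGN_INTERVALS) -> pd.DataFrame:
    """Schema-check trial records; raises ValueError naming offending rows."""
    if not isinstance(records, pd.DataFrame):
        raise TypeError("records must be a pandas DataFrame")
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"trial records missing required columns: {missing}")
    df = records.copy()
    problems = []

    bad_interval = ~df["interval"].isin(list(intervals))
    if bad_interval.any():
        rows = df.index[bad_interval].tolist()[:20]
        problems.append(f"interval not in {tuple(intervals)} at rows {rows}")

    for col in _BOOL_COLUMNS:
        vals = df[col]
        ok = vals.isin([0, 1, True, False])
        if not ok.all():
            rows = df.index[~ok].tolist()[:20]
            problems.append(f"column {col!r} must be boolean 0/1, bad rows {rows}")

    if not problems:
        for col in _BOOL_COLUMNS:
            df[col] = df[col].astype(bool)
        contradictory = df["final_correct"] & df["final_blank"]
        if contradictory.any():
            rows = df.index[contradictory].tolist()[:20]
            problems.append(f"final_correct with final_blank at rows {rows}")

    if problems:
        raise ValueError("malformed trial records: " + "; ".join(problems))
    df["interval"] = df["interval"].astype(int)
    return df


def apply_participant_exclusions(
    records: pd.DataFrame, intervals: Sequence[int] = DESIGN_INTERVALS
) -> tuple:
    """Drop participants per the exclusion rules; returns (records, report).

    Rules, applied to the full design trials of each participant:
    (a) reported having done the experiment before;
    (b) left more than half of their final-test answers blank;
    (c) answered zero items correctly on the initial test in at least one
        interval condition (such participants would have no analyzable data
        in that condition once items are filtered on initial accuracy).

    The report counts exclusions per reason (a participant can trip several
    rules; each rule counts everyone who trips it).
    """
    df = validate_records(records, intervals)
    by_p = df.groupby("participant_id", sort=False)

    did_before = by_p["did_before"].any()
    blank_frac = by_p["final_blank"].mean()
    # participants x intervals with at least one initially-correct item
    cover = (
        df[df["initial_correct"]]
        .groupby("participant_id", sort=False)["interval"]
        .agg(lambda s: set(s.unique()))
        .reindex(did_before.index)
    )
    full = set(int(i) for i in intervals)
    no_data = cover.map(lambda s: not isinstance(s, set) or not full.issubset(s))

    excluded = did_before | (blank_frac > 0.5) | no_data
    report = {
        "did_before": int(did_before.sum()),
        "blank_over_half": int((blank_frac > 0.5).sum()),
        "zero_correct_in_condition": int(no_data.sum()),
        "n_excluded": int(excluded.sum()),
        "n_retained": int((~excluded).sum()),
    }
    keep = excluded.index[~excluded]
    return df[df["participant_id"].isin(keep)].copy(), report


def filter_initially_correct(records: pd.DataFrame) -> tuple:
    """Keep only items answered correctly on the initial test.

    Returns (filtered_records, exclusion_rate); the rate is NaN for empty
    input. Never changes the set of participants, only items.
    """
    total = len(records)
    if total == 0:
        return records.copy(), float("nan")
    kept = records[records["initial_correct"].astype(bool)].copy()
    return kept, (total - len(kept)) / total


def condition_means(records: pd.DataFrame, intervals: Sequence[int] = DESIGN_INTERVALS) -> pd.DataFrame:
    """Per-participant proportion of final-test correct answers by interval.

    Returns a wide table (participants x intervals); cells without items are
    NaN (upstream exclusions prevent this for the design intervals).
    """
    table = (
        records.groupby(["participant_id", "interval"], sort=True)["final_correct"]
        .mean()
        .unstack("interval")
        .reindex(columns=sorted(int(i) for i in intervals))
    )
    return table


class Slopes(NamedTuple):
    slope1: float
    slope2: float


def _to_percent(p, percent: bool) -> float:
    p = float(p)
    lo, hi = (0.0, 100.0) if percent else (0.0, 1.0)
    if not lo <= p <= hi:
        raise ValueError(f"score {p} outside [{lo}, {hi}]")
    return p if percent else 100.0 * p


def forgetting_slopes(
    p1, p2, p3, intervals: Sequence[float] = DESIGN_INTERVALS, percent: bool = False
) -> Slopes:
    """Forgetting per unit of time for the two retention intervals.

    Signed slopes in percentage points per intervening item; pass
    ``percent=True`` when inputs are already on the 0-100 scale. With the
    intervals (2, 20, 80) the divisors are 18 and 60.
    """
    t1, t2, t3 = (float(t) for t in intervals)
    P1, P2, P3 = (_to_percent(p, percent) for p in (p1, p2, p3))
    return Slopes((P2 - P1) / (t2 - t1), (P3 - P2) / (t3 - t2))


def interval_drops(
    p1, p2, p3, percent: bool = False
) -> tuple:
    """Amount forgotten per interval (percentage points): (P1-P2, P2-P3)."""
    P1, P2, P3 = (_to_percent(p, percent) for p in (p1, p2, p3))
    return (P1 - P2, P2 - P3)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


class WilcoxonResult(NamedTuple):
    statistic: float      # W = sum of ranks of positive differences
    p_value: float        # two-sided
    rank_biserial: float  # (R+ - R-) / (R+ + R-)
    n: int                # nonzero differences used
    method: str           # "exact" or "normal"


_EXACT_LIMIT = 25


def _exact_two_sided_p(ranks: np.ndarray, w: float) -> float:
    """Tie-aware exact null of W by convolution over sign assignments.

    Ranks are midranks, so doubling makes them integers; the null assigns
    each rank to the positive sum independently with probability 1/2.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_wilcoxon(x, y) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples (x vs y), differences x - y.

    Zero differences are dropped (Wilcoxon's original convention); ties among
    |d| get midranks. Exact p for n <= 25, otherwise a normal approximation
    with tie correction and a 0.5 continuity correction. Requires at least 5
    nonzero differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError(
            f"only {n} nonzero differences; need >= 5 (consult exact tables for smaller n)"
        )
    ranks = stats.rankdata(np.abs(d))
    r_pos = float(ranks[d > 0].sum())
    r_neg = float(ranks[d < 0].sum())
    rb = (r_pos - r_neg) / (r_pos + r_neg)

    if n <= _EXACT_LIMIT:
        p = _exact_two_sided_p(ranks, r_pos)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        sd = math.sqrt(var)
        z = (r_pos - mean - 0.5 * np.sign(r_pos - mean)) / sd if sd > 0 else 0.0
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "normal"
    return WilcoxonResult(statistic=r_pos, p_value=p, rank_biserial=rb, n=n, method=method)


def normality_check(diffs) -> tuple:
    """Shapiro-Wilk statistic and p for the paired differences (3 <= n <= 5000)."""
    d = np.asarray(diffs, dtype=float)
    if not 3 <= d.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.allclose(d, d[0]):
        raise ValueError("constant input: normality test is degenerate")
    stat, p = stats.shapiro(d)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# End-to-end analysis
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SlopeStats:
    """Per-participant slopes and the paired-test summary."""

    participant_ids: tuple
    slope1: np.ndarray
    slope2: np.ndarray
    slope1_mean: float
    slope1_sd: float
    slope2_mean: float
    slope2_sd: float
    shapiro_statistic: float
    shapiro_p: float
    wilcoxon: WilcoxonResult
    n_analyzed: int
    exclusions: dict
    item_exclusion_rate: float

    def to_dict(self) -> dict:
        return {
            "n_analyzed": self.n_analyzed,
            "slope1": {"mean": self.slope1_mean, "sd": self.slope1_sd},
            "slope2": {"mean": self.slope2_mean, "sd": self.slope2_sd},
            "shapiro": {"statistic": self.shapiro_statistic, "p": self.shapiro_p},
            "wilcoxon": {
                "W": self.wilcoxon.statistic,
                "p": self.wilcoxon.p_value,
                "rank_biserial": self.wilcoxon.rank_biserial,
                "n": self.wilcoxon.n,
                "method": self.wilcoxon.method,
            },
            "exclusions": dict(self.exclusions),
            "item_exclusion_rate": self.item_exclusion_rate,
        }


@dataclasses.dataclass(frozen=True)
class ExperimentReport:
    slope_stats: SlopeStats
    shape: ShapeReport
    group_means: dict  # interval -> mean proportion final correct
    alpha: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "group_means": {str(k): v for k, v in self.group_means.items()},
            "slopes": self.slope_stats.to_dict(),
            "shape": self.shape.to_dict(),
            "alpha": self.alpha,
            "significant": self.significant,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def analyze_experiment(
    records: pd.DataFrame,
    intervals: Sequence[int] = DESIGN_INTERVALS,
    epsilon: float = DEFAULT_SHAPE_EPSILON,
    alpha: float = 0.05,
) -> ExperimentReport:
    """Full analysis: exclusions -> item filter -> condition means -> slopes
    -> Shapiro-Wilk -> Wilcoxon (slope1 vs slope2) -> shape of group means.

    The Wilcoxon pairs are the two per-participant slopes; the difference
    slope1 - slope2 is positive when forgetting accelerates (the second-
    interval slope is more negative), so a positive rank-biserial correlation
    indicates concave observed forgetting.
    """
    try:
        df = validate_records(records, intervals)
    except ValueError as err:
        raise ValueError(f"[validate] {err}") from err
    df, exclusion_report = apply_participant_exclusions(df, intervals)
    if exclusion_report["n_retained"] == 0:
        raise ValueError("[exclusions] no participants remain after exclusions")
    df, item_rate = filter_initially_correct(df)
    means = condition_means(df, intervals)
    means = means.dropna()
    if len(means) < 5:
        raise ValueError("[slopes] fewer than 5 participants with data in all conditions")

    cols = sorted(int(i) for i in intervals)
    slopes = np.array(
        [forgetting_slopes(*row, intervals=cols) for row in means[cols].to_numpy()]
    )
    slope1, slope2 = slopes[:, 0], slopes[:, 1]
    diffs = slope1 - slope2
    try:
        sh_stat, sh_p = normality_check(diffs)
    except ValueError:
        sh_stat, sh_p = float("nan"), float("nan")
    wres = paired_wilcoxon(slope1, slope2)

    group = means[cols].mean(axis=0)
    shape = classify_shape(
        ObservedCurve(times=np.asarray(cols, dtype=float), p=group.to_numpy()),
        epsilon=epsilon,
    )
    slope_stats = SlopeStats(
        participant_ids=tuple(means.index),
        slope1=slope1,
        slope2=slope2,
        slope1_mean=float(slope1.mean()),
        slope1_sd=float(slope1.std(ddof=1)),
        slope2_mean=float(slope2.mean()),
        slope2_sd=float(slope2.std(ddof=1)),
        shapiro_statistic=sh_stat,
        shapiro_p=sh_p,
        wilcoxon=wres,
        n_analyzed=len(means),
        exclusions=exclusion_report,
        item_exclusion_rate=float(item_rate),
    )
    return ExperimentReport(
        slope_stats=slope_stats,
        shape=shape,
        group_means={int(k): float(v) for k, v in group.items()},
        alpha=float(alpha),
        significant=bool(wres.p_value < alpha),
    )
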