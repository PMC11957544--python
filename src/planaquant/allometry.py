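"""Downstream quantitative summaries of count tables.

Ratios, allometric scaling fits with an optional breakpoint, classical
two-sample comparisons, and regeneration time-courses — the statistics
layer that turns per-animal censuses into the numbers a comparative
study reports (e.g. the neuron fraction of body cells, or the
two-regime scaling of neuron number with total cell number).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ScalingFit:
    """Piecewise-linear least-squares fit of y against x.

    ``slopes``/``intercepts`` are per segment in x order; ``breakpoint``
    is the x value separating the two segments (None for a single
    line).  ``breakpoint_supported`` is False when a requested
    two-segment fit improved the residual sum of squares by less than
    ``tol`` relative to the single line, i.e. no breakpoint is
    supported by the data.
    """

    slopes: tuple[float, ...]
    intercepts: tuple[float, ...]
    breakpoint: float | None
    residual_sd: float
    n: int
    breakpoint_supported: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.breakpoint is None or not self.breakpoint_supported:
            return self.intercepts[0] + self.slopes[0] * x
        lo = self.intercepts[0] + self.slopes[0] * x
        hi = self.intercepts[1] + self.slopes[1] * x
        return np.where(x <= self.breakpoint, lo, hi)


def neuron_cell_ratio(
    table: pd.DataFrame,
    neuron_col: str = "neurons",
    cell_col: str = "cells",
    group_col: str | None = None,
) -> pd.DataFrame:
    """Per-sample neuron/cell ratios with group mean ± SEM summaries.

    With no grouping column all samples form one group ("all").  Zero
    cell counts raise.
    """
    cells = table[cell_col].to_numpy(dtype=float)
    if np.any(cells <= 0):
        raise ValueError("cell counts must be positive")
    ratios = table[neuron_col].to_numpy(dtype=float) / cells
    groups = table[group_col] if group_col else pd.Series(["all"] * len(table))
    out = (
        pd.DataFrame({"group": groups.to_numpy(), "ratio": ratios})
        .groupby("group", sort=True)["ratio"]
        .agg(mean="mean", sem=lambda v: float(stats.sem(v)) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return out


def _line_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted LS slope, intercept, weighted RSS via the normal equations."""
    A = np.stack([x, np.ones_like(x)], axis=1) * w[:, None]
    coef, *_ = np.linalg.lstsq(A, y * w, rcond=None)
    resid = y * w - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def _stick_fit(x: np.ndarray, y: np.ndarray, bp: float, w: np.ndarray):
    """Continuous broken-stick y = a + b·x + c·(x-bp)+, weighted LS."""
    h = np.maximum(x - bp, 0.0)
    A = np.stack([np.ones_like(x), x, h], axis=1) * w[:, None]
    coef, *_ = np.linalg.lstsq(A, y * w, rcond=None)
    resid = y * w - A @ coef
    return coef, float(resid @ resid)


def fit_scaling(
    table: pd.DataFrame,
    segments: int = 1,
    x_col: str = "cells",
    y_col: str = "neurons",
    min_points_per_segment: int = 5,
    tol: float = 0.5,
    weights: str | None = "relative",
) -> ScalingFit:
    """Least-squares scaling fit with 1 or 2 segments.

    ``weights="relative"`` (default) weights residuals by 1/x, matching
    the constant-coefficient-of-variation errors typical of count data —
    unweighted least squares on such data lets the largest animals
    dominate and favours spurious splits.  ``weights=None`` gives plain
    OLS.

    For ``segments=2`` a continuous broken-stick
    ``y = a + b·x + c·(x - bp)+`` is fit with the breakpoint chosen by
    exhaustive grid search over observed x values (at least
    ``min_points_per_segment`` points per side), minimizing the
    (weighted) residual sum of squares.  If the best broken stick
    reduces RSS by less than the fraction ``tol`` versus the single
    line, no breakpoint is supported and the single line is returned.
    """
    x = table[x_col].to_numpy(dtype=float)
    y = table[y_col].to_numpy(dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    if n < segments * min_points_per_segment:
        raise ValueError(f"need at least {segments * min_points_per_segment} points, have {n}")
    w = 1.0 / x if weights == "relative" else np.ones_like(x)
    s1, i1, rss1 = _line_fit(x, y, w)
    sd1 = float(np.std(y - (i1 + s1 * x), ddof=min(2, n - 1)))
    if segments == 1:
        return ScalingFit((s1,), (i1,), None, sd1, n)
    if segments != 2:
        raise ValueError("segments must be 1 or 2")

    best = None
    for bp in x[min_points_per_segment : n - min_points_per_segment + 1]:
        coef, rss = _stick_fit(x, y, float(bp), w)
        if best is None or rss < best[1]:
            best = (float(bp), rss, coef)
    bp, rss2, (a, b, c) = best
    improvement = (rss1 - rss2) / rss1 if rss1 > 0 else 0.0
    if improvement < tol:
        return ScalingFit((s1,), (i1,), None, sd1, n, breakpoint_supported=False)
    slopes = (float(b), float(b + c))
    intercepts = (float(a), float(a - c * bp))
    resid = y - np.where(x <= bp, intercepts[0] + slopes[0] * x, intercepts[1] + slopes[1] * x)
    sd = float(np.std(resid, ddof=min(4, n - 1)))
    return ScalingFit(slopes, intercepts, bp, sd, n)


def compare_groups(a, b) -> dict:
    """Two-tailed unpaired Student's t-test (pooled variance).

    Returns ``{"t", "p", "stars", "df"}`` with the conventional star
    annotation (*p<0.05, **p<0.01, ***p<0.001, else "ns").  Degenerate
    zero-variance input: equal means give p = 1 by convention; unequal
    means raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0, "stars": "ns", "df": df}
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"
    return {"t": float(t), "p": float(p), "stars": stars, "df": df}


def regeneration_timecourse(
    tables: dict,
    value_col: str = "count",
    plateau_fraction: float = 0.10,
) -> pd.DataFrame:
    """Per-day summaries of a regeneration series with phase annotation.

    ``tables`` maps day label -> DataFrame (or array-like) of per-animal
    counts.  Days are sorted numerically; per-day mean ± SEM are
    computed, the day-to-day slope of the mean is evaluated, and each
    day is annotated ``"increase"`` until the slope first falls below
    ``plateau_fraction`` of the maximal earlier slope and stays there —
    from that day on the phase is ``"plateau"``.  A series whose slope
    never drops (strictly linear growth) reports no plateau; a constant
    series plateaus from day 0.
    """
    if len(tables) < 3:
        raise ValueError("need at least 3 time points")
    days = sorted(tables, key=float)
    rows = []
    for d in days:
        v = tables[d]
        v = v[value_col].to_numpy(dtype=float) if isinstance(v, pd.DataFrame) else np.asarray(v, float)
        rows.append(
            {"day": float(d), "mean": float(v.mean()),
             "sem": float(stats.sem(v)) if len(v) > 1 else 0.0, "n": len(v)}
        )
    out = pd.DataFrame(rows)
    means = out["mean"].to_numpy()
    dts = np.diff(out["day"].to_numpy())
    slopes = np.diff(means) / dts
    max_slope = float(slopes.max()) if len(slopes) else 0.0
    plateau_start = None
    if max_slope <= 0:
        plateau_start = 0
    else:
        for i in range(len(slopes)):
            if np.all(slopes[i:] < plateau_fraction * max_slope):
                plateau_start = i + 1
                break
    phases = []
    for i in range(len(out)):
        phases.append("plateau" if plateau_start is not None and i >= plateau_start else "increase")
    if plateau_start == 0:
        phases = ["plateau"] * len(out)
    out["phase"] = phases
    out.attrs["plateau_onset_day"] = (
        float(out["day"].iloc[plateau_start]) if plateau_start is not None else None
    )
    return out
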