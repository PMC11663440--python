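"""Cohort-level ontogenetic analysis.

Individuals are binned into five age-defined locomotor stages (carried
infant -> climbing/suspensory infant -> transitional -> independent juvenile
-> near-adult adolescent, covering ages 0-13 years in chimpanzees), the four
size-independent section parameters (Imax/Imin, Ix/Iy, medullary index,
porosity index) are summarized per stage with Tukey box-plot statistics, and
their ontogenetic trajectories are smoothed with LOESS (local linear
regression, tricube weights, span 0.7).  No inter-stage hypothesis testing
is performed: desk-scale cohorts of this kind are too small for meaningful
group comparisons, and trends are meant to be read from the smooths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREND_PARAMETERS = ("imax_imin_ratio", "ix_iy_ratio", "medullary_index", "porosity_index")

#: Half-open age intervals [low, high) in years for the five locomotor stages.
STAGE_BINS: tuple[tuple[int, float, float, str], ...] = (
    (1, 0.0, 5.0 / 12.0, "carried infant (0-4.9 months)"),
    (2, 5.0 / 12.0, 3.0, "early independent locomotion (5 months-2.9 years)"),
    (3, 3.0, 5.0, "increasing quadrupedalism (3-4.9 years)"),
    (4, 5.0, 10.0, "independent juvenile (5-9.9 years)"),
    (5, 10.0, 13.0, "near-adult adolescent (10-13 years)"),
)


def assign_stage(age_years: float) -> int:
    """Locomotor stage (1-5) for an age in [0, 13) years.

    The printed stage definitions leave gaps (e.g. "2.9 / 3"); the intervals
    here are half-open [low, high) so the bins are exhaustive and disjoint.
    """
    for stage_id, low, high, _ in STAGE_BINS:
        if low <= age_years < high:
            return stage_id
    raise ValueError(f"age {age_years} outside the staged range [0, 13) years")


# ---------------------------------------------------------------------------
# LOESS


@dataclass(frozen=True)
class TrendFit:
    """LOESS trend on a uniform age grid with pointwise 95% half-widths."""

    grid: np.ndarray
    fitted: np.ndarray
    ci_half_width: np.ndarray
    span: float


def loess_trend(
    ages, values, span: float = 0.7, n_grid: int = 100, degree: int = 2
) -> TrendFit:
    """LOESS: locally weighted polynomial regression with tricube weights.

    At each grid point the ``span`` fraction of nearest neighbours is
    weighted by the tricube kernel on distance scaled to the furthest
    neighbour, and a weighted polynomial of the given ``degree`` is fitted;
    the smooth is the collection of local predictions over a uniform grid
    spanning the observed ages.  Pointwise 95% intervals use the local
    linear-combination variance with a residual-based scale estimate.

    The default is local quadratic (degree 2), matching R's ``loess`` as
    used by ``ggplot2::geom_smooth`` — with wide spans a local quadratic can
    represent interior extrema of an ontogenetic trajectory that a local
    line flattens into its boundary trend.  ``degree=1`` gives classic local
    linear smoothing.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ages and values must be equal-length 1D arrays")
    n = x.size
    if n < 8:
        raise ValueError("LOESS needs at least 8 points")
    if np.ptp(x) == 0:
        raise ValueError("ages must not all be equal")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    k = max(int(np.ceil(span * n)), degree + 2)
    if k > n:
        raise ValueError(f"span window ({k}) exceeds the number of points ({n})")

    grid = np.linspace(x.min(), x.max(), n_grid)
    fitted = np.empty(n_grid)
    lsq = np.empty(n_grid)  # sum of squared weights of the linear combination
    for j, x0 in enumerate(grid):
        fitted[j], lsq[j] = _local_poly(x, y, x0, k, degree)

    # residual scale from leave-nothing-out fits at the data points
    resid = np.array([y[i] - _local_poly(x, y, x[i], k, degree)[0] for i in range(n)])
    dof = max(n - (degree + 1), 1)
    sigma = float(np.sqrt(np.sum(resid**2) / dof))
    return TrendFit(grid=grid, fitted=fitted, ci_half_width=1.96 * sigma * np.sqrt(lsq),
                    span=span)


def _local_poly(x, y, x0, k, degree):
    d = np.abs(x - x0)
    d_k = np.partition(d, k - 1)[k - 1]
    if d_k == 0:
        # duplicated abscissae fill the whole window: average them
        w = (d == 0).astype(float)
        l_vec = w / w.sum()
        return float(np.dot(l_vec, y)), float(np.dot(l_vec, l_vec))
    u = np.clip(d / d_k, 0.0, 1.0)
    w = (1.0 - u**3) ** 3
    xc = x - x0
    design = np.vander(xc, degree + 1, increasing=True)  # [1, xc, xc^2 ...]
    wd = design * w[:, None]
    gram = design.T @ wd
    try:
        # prediction at x0 is the intercept of the weighted fit in centred
        # coords: e0' (X'WX)^-1 X'W y = l' y
        l_vec = wd @ np.linalg.solve(gram, np.eye(degree + 1)[:, 0])
    except np.linalg.LinAlgError:
        l_vec = w / w.sum()  # degenerate design: weighted mean
    return float(np.dot(l_vec, y)), float(np.dot(l_vec, l_vec))


# ---------------------------------------------------------------------------
# stage summaries


@dataclass(frozen=True)
class StageSummary:
    """Tukey box-plot statistics for one locomotor stage."""

    stage_id: int
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple = field(default_factory=tuple)


def stage_summaries(ages, values) -> list[StageSummary]:
    """Per-stage n, mean, median, quartiles (linear interpolation), whiskers
    at the last observations within 1.5x IQR of the quartiles, and outliers
    beyond the whiskers.  Stages with no observations are omitted."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    stages = np.array([assign_stage(a) for a in ages])
    out = []
    for stage_id, *_ in STAGE_BINS:
        v = np.sort(values[stages == stage_id])
        if v.size == 0:
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        outliers = tuple(float(o) for o in v[(v < lo_fence) | (v > hi_fence)])
        out.append(
            StageSummary(
                stage_id=stage_id, n=int(v.size), mean=float(v.mean()),
                median=float(med), q1=float(q1), q3=float(q3),
                whisker_low=float(inside.min()), whisker_high=float(inside.max()),
                outliers=outliers,
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort orchestration


@dataclass(frozen=True)
class CohortResults:
    """Tidy per-(specimen, fraction) table plus per-(fraction, parameter)
    trend fits and stage summaries."""

    table: pd.DataFrame
    trends: dict
    summaries: dict


def run_cohort_analysis(
    metadata: pd.DataFrame,
    records: pd.DataFrame,
    fractions=(0.35, 0.5, 0.65),
    span: float = 0.7,
    parameters=TREND_PARAMETERS,
) -> CohortResults:
    """Join cohort metadata with per-section geometry and derive trends.

    ``metadata`` needs columns (specimen_id, age_years, ...); ``records``
    needs (specimen_id, fraction) plus the parameter columns.  Every specimen
    must have a record at every requested fraction.  Output rows are sorted
    by (specimen_id, fraction) so results are invariant to input order.
    """
    missing = []
    for sid in metadata["specimen_id"]:
        have = set(records.loc[records["specimen_id"] == sid, "fraction"].round(6))
        lack = [f for f in fractions if round(f, 6) not in have]
        if lack:
            missing.append(f"{sid}: missing fractions {lack}")
    if missing:
        raise ValueError("incomplete section records — " + "; ".join(missing))

    table = records.merge(
        metadata[[c for c in metadata.columns if c not in records.columns or c == "specimen_id"]],
        on="specimen_id",
        how="inner",
    )
    table = table[table["fraction"].round(6).isin([round(f, 6) for f in fractions])]
    table = table.sort_values(["specimen_id", "fraction"], kind="mergesort").reset_index(drop=True)
    table["stage"] = [assign_stage(a) for a in table["age_years"]]

    trends, summaries = {}, {}
    for frac in fractions:
        sub = table[table["fraction"].round(6) == round(frac, 6)]
        for param in parameters:
            if param not in sub.columns:
                continue
            key = (frac, param)
            if len(sub) >= 8:
                trends[key] = loess_trend(sub["age_years"].to_numpy(),
                                          sub[param].to_numpy(), span=span)
            summaries[key] = stage_summaries(sub["age_years"].to_numpy(),
                                             sub[param].to_numpy())
    return CohortResults(table=table, trends=trends, summaries=summaries)
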