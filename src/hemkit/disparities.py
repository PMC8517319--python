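"""Between-group disparity gaps in survey-weighted mean health.

A disparity here is the difference in weighted mean coded health between
an advantaged and a disadvantaged group in a given survey year:

* ``black_white``  — white non-Latinx minus Black non-Latinx;
* ``latinx_white`` — white non-Latinx minus Latinx;
* ``income``       — ≥400% FPL minus <150% FPL (middle category excluded).

A positive gap means the advantaged group is healthier, so a narrowing
disparity shows up as a negative slope over time.  Standard errors use
the same stratified between-PSU linearization as the equity metric,
applied jointly to both group means so within-PSU covariance is kept;
the income contrast is computed per income-imputation replicate and
pooled with Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CombinationError, ConfigurationError, EstimationError
from .hem import _Z975, _count_imputations

__all__ = ["CONTRASTS", "DisparityEstimate", "compute_disparity", "disparity_series", "scenario_gap"]

#: contrast -> (column kind, advantaged level, disadvantaged level)
CONTRASTS = {
    "black_white": ("race_ethnicity", "white_nl", "black_nl"),
    "latinx_white": ("race_ethnicity", "white_nl", "latinx"),
    "income": ("income", "ge400", "lt150"),
}


@dataclass(frozen=True)
class DisparityEstimate:
    """A year's advantaged-minus-disadvantaged gap in weighted mean health."""

    year: int
    measure: str
    contrast: str
    gap: float
    se: float
    ci_low: float
    ci_high: float
    n_advantaged: int
    n_disadvantaged: int


def _gap_and_se(
    df: pd.DataFrame, measure: str, mask_a: pd.Series, mask_b: pd.Series,
    single_psu: str = "error",
) -> tuple[float, float, int, int]:
    """Weighted mean difference A − B with joint linearized design SE.

    Both group means are linearized on the full frame (u_i = 0 for records
    in neither group), so within-PSU covariance between the groups is kept
    and the design structure survives subgroup restriction.
    """
    from .hem import _stratified_psu_variance

    mask_a = (mask_a & df[measure].notna()).to_numpy()
    mask_b = (mask_b & df[measure].notna()).to_numpy()
    if not mask_a.any() or not mask_b.any():
        raise EstimationError("empty contrast group")
    w = df["weight"].to_numpy(float)
    y = df[measure].to_numpy(float)
    wa, wb = w[mask_a], w[mask_b]
    mean_a = float(np.sum(wa * y[mask_a]) / wa.sum())
    mean_b = float(np.sum(wb * y[mask_b]) / wb.sum())

    # influence values: u_i = w_i(y_i − ȳ_A)/W_A for A, minus the analogue for B
    u = np.zeros(len(df))
    u[mask_a] = wa * (y[mask_a] - mean_a) / wa.sum()
    u[mask_b] = -wb * (y[mask_b] - mean_b) / wb.sum()
    var = _stratified_psu_variance(df, u, single_psu=single_psu)
    return mean_a - mean_b, float(np.sqrt(var)), int(mask_a.sum()), int(mask_b.sum())


def compute_disparity(
    df: pd.DataFrame,
    measure: str,
    contrast: str,
    year: int | None = None,
    n_imputations: int | None = None,
) -> DisparityEstimate:
    """Disparity gap for one year's coded records.

    Race contrasts are a single computation (race is observed); the income
    contrast is recomputed under each income imputation and pooled with
    Rubin's rules.
    """
    if contrast not in CONTRASTS:
        raise ConfigurationError(f"unknown contrast: {contrast!r}")
    kind, adv, dis = CONTRASTS[contrast]
    coded = df[measure].notna()
    if not coded.any():
        raise EstimationError(f"no coded values for {measure}")
    if year is None:
        years = df.loc[coded, "year"].unique()
        year = int(years[0]) if len(years) == 1 else -1

    if kind == "race_ethnicity":
        gap, se, n_a, n_b = _gap_and_se(
            df, measure, df[kind] == adv, df[kind] == dis
        )
        return _finish(year, measure, contrast, gap, se, n_a, n_b)

    m = n_imputations or _count_imputations(df)
    gaps, ses, n_as, n_bs = [], [], [], []
    for i in range(1, m + 1):
        col = df[f"income_imp{i}"]
        gap, se, n_a, n_b = _gap_and_se(df, measure, col == adv, col == dis)
        gaps.append(gap)
        ses.append(se)
        n_as.append(n_a)
        n_bs.append(n_b)
    if m == 1:
        return _finish(year, measure, contrast, gaps[0], ses[0], n_as[0], n_bs[0])
    q = np.array(gaps)
    within = float(np.mean(np.array(ses) ** 2))
    between = float(np.sum((q - q.mean()) ** 2) / (m - 1))
    se = float(np.sqrt(within + (1 + 1 / m) * between))
    return _finish(
        year, measure, contrast, float(q.mean()), se,
        int(round(np.mean(n_as))), int(round(np.mean(n_bs))),
    )


def _finish(year, measure, contrast, gap, se, n_a, n_b) -> DisparityEstimate:
    return DisparityEstimate(
        year=year,
        measure=measure,
        contrast=contrast,
        gap=gap,
        se=se,
        ci_low=gap - _Z975 * se,
        ci_high=gap + _Z975 * se,
        n_advantaged=n_a,
        n_disadvantaged=n_b,
    )


def disparity_series(
    df: pd.DataFrame,
    measure: str,
    contrast: str,
    n_imputations: int | None = None,
) -> list[DisparityEstimate]:
    """Annual disparity estimates over all years with coded data."""
    out = []
    for year, sub in df.groupby("year", sort=True):
        if sub[measure].notna().sum() == 0:
            continue
        out.append(
            compute_disparity(sub, measure, contrast, year=int(year), n_imputations=n_imputations)
        )
    return out


def scenario_gap(privileged: Sequence[float], nonprivileged: Sequence[float]) -> float:
    """Privileged-minus-non-privileged difference in sample means (equal weights)."""
    p, n = np.asarray(privileged, float), np.asarray(nonprivileged, float)
    if p.size == 0 or n.size == 0:
        raise EstimationError("empty scenario group")
    return float(p.mean() - n.mean())
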