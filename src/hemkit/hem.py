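"""The benchmark-relative Health Equity Metric (HEM).

The metric summarizes how far a population falls short of a benchmark
("health potential") level of health ȳ*.  Each individual contributes a
convexly weighted relative deficit

    d_i = max{(ȳ* − y_i)/ȳ*, 0},        c_i = (β · d_i)^α,

and the metric is the rescaled complement of the (survey-weighted) mean
contribution

    HEM = rescale × (1 − Σ w_i c_i / Σ w_i).

With equal weights this reduces to the plain 1/N sum.  Individuals at or
above the benchmark contribute 0 (the same maximum contribution to the
metric), so HEM = rescale exactly for a population with no deficits; the
attainable range is rescale × (1 − β^α) .. rescale.  Defaults are
α = 2.5, β = 2 and rescale = 1000, under which larger deficits are
weighted more than proportionally — concentrating a fixed total deficit
on fewer people lowers the metric, which is what distinguishes it from a
group-mean disparity gap.

The benchmark is the survey-weighted median health of the most socially
privileged identifiable subgroup (white, non-Latinx boys in households
at ≥400% of the federal poverty line), or alternatively the weighted
90th percentile of the whole population.  Standard errors come from
stratified between-PSU linearization of the weighted mean contribution
(benchmark treated as fixed), and income-imputation replicates are
combined with Rubin's rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CombinationError, ConfigurationError, EstimationError

__all__ = [
    "BenchmarkSpec",
    "HEMParams",
    "HEMEstimate",
    "weighted_median",
    "weighted_quantile",
    "is_privileged",
    "compute_benchmark",
    "deficit_contributions",
    "hem_point",
    "compute_hem",
    "estimate_variance",
    "combine_imputations",
    "compute_hem_mi",
    "hem_series",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class HEMParams:
    """Scale parameters of the metric: deficit exponent α, scale β, rescale."""

    alpha: float = 2.5
    beta: float = 2.0
    rescale: float = 1000.0

    def __post_init__(self):
        if not self.alpha > 1:
            raise ConfigurationError(f"alpha must exceed 1, got {self.alpha}")
        if not self.beta > 0:
            raise ConfigurationError(f"beta must be positive, got {self.beta}")

    @property
    def floor(self) -> float:
        """Lower end of the attainable range, rescale × (1 − β^α)."""
        return self.rescale * (1.0 - self.beta**self.alpha)


@dataclass(frozen=True)
class BenchmarkSpec:
    """How the benchmark level of health ȳ* is operationalized.

    ``privileged_median`` uses the weighted median among records matching
    ``privileged_predicate`` (default: white non-Latinx boys, income
    ≥400% FPL); ``population_p90`` uses the weighted 90th percentile of
    everyone.  ``min_cell_size`` triggers a small-cell warning.
    """

    mode: str = "privileged_median"
    per_year: bool = True
    min_cell_size: int = 50
    privileged_predicate: Callable[[pd.DataFrame, str], pd.Series] | None = None

    def __post_init__(self):
        if self.mode not in ("privileged_median", "population_p90"):
            raise ConfigurationError(f"unknown benchmark mode: {self.mode!r}")


@dataclass(frozen=True)
class HEMEstimate:
    """A survey year's HEM with design-based uncertainty."""

    year: int
    measure: str
    value: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    benchmark: float


def weighted_median(values: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Smallest value at which cumulative normalized weight reaches 1/2.

    This lower weighted median (no interpolation) is well defined on the
    discrete coded scales and agrees with the unweighted median of the
    record set expanded by integer weights.
    """
    return weighted_quantile(values, 0.5, weights)


def weighted_quantile(
    values: Sequence[float], q: float, weights: Sequence[float] | None = None
) -> float:
    """Smallest value at which cumulative normalized weight reaches q."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EstimationError("cannot take a quantile of an empty set")
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise EstimationError("weights must be nonnegative with positive total")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order]) / w.sum()
    idx = int(np.searchsorted(cum, q - 1e-12))
    return float(v[order][min(idx, v.size - 1)])


def is_privileged(df: pd.DataFrame, income_col: str = "income_imp1") -> pd.Series:
    """Mask for the most privileged cell: white non-Latinx boys, ≥400% FPL."""
    return (
        (df["sex"] == "male")
        & (df["race_ethnicity"] == "white_nl")
        & (df[income_col] == "ge400")
    )


def compute_benchmark(
    df: pd.DataFrame,
    measure: str,
    spec: BenchmarkSpec | None = None,
    income_col: str = "income_imp1",
    domain: pd.Series | None = None,
) -> float:
    """Benchmark ȳ* for one year's records (coded column ``measure``)."""
    spec = spec or BenchmarkSpec()
    sub = df.loc[_domain_mask(df, measure, domain)]
    if sub.empty:
        raise EstimationError(f"no coded values for {measure}")
    if spec.mode == "population_p90":
        return weighted_quantile(sub[measure], 0.9, sub["weight"])
    pred = spec.privileged_predicate or is_privileged
    priv = sub.loc[pred(sub, income_col)]
    if priv.empty:
        raise EstimationError(f"empty privileged subgroup for {measure}")
    if len(priv) < spec.min_cell_size:
        warnings.warn(
            f"privileged cell for {measure} has only {len(priv)} records "
            f"(< {spec.min_cell_size}); benchmark may be unstable",
            stacklevel=2,
        )
    return weighted_median(priv[measure], priv["weight"])


def deficit_contributions(
    values: np.ndarray, benchmark: float, params: HEMParams
) -> np.ndarray:
    """Per-individual convex deficit contributions c_i = (β·d_i)^α."""
    if benchmark <= 0:
        raise EstimationError(f"benchmark must be positive, got {benchmark}")
    d = np.maximum((benchmark - np.asarray(values, dtype=float)) / benchmark, 0.0)
    return (params.beta * d) ** params.alpha


def hem_point(
    values: Sequence[float],
    benchmark: float,
    params: HEMParams | None = None,
    weights: Sequence[float] | None = None,
) -> float:
    """HEM point value (rescaled) for raw coded values and weights."""
    params = params or HEMParams()
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EstimationError("empty population")
    c = deficit_contributions(v, benchmark, params)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    return float(params.rescale * (1.0 - np.sum(w * c) / np.sum(w)))


def _stratified_psu_variance(
    df: pd.DataFrame, z: np.ndarray, single_psu: str = "error"
) -> float:
    """Between-PSU variance of a linearized total: Σ_h n_h/(n_h−1) Σ_k (Z_hk − Z̄_h)².

    ``z`` is the linearized value per record of ``df`` (zero outside the
    estimation domain, so subgroup estimates keep the full design
    structure).  ``single_psu`` controls strata with one PSU: ``"error"``
    raises, ``"center"`` scores the lone PSU against the grand mean of
    PSU totals.
    """
    psu_tot = (
        pd.DataFrame({"stratum": df["stratum"].to_numpy(), "psu": df["psu"].to_numpy(), "z": z})
        .groupby(["stratum", "psu"], sort=True)["z"]
        .sum()
    )
    var = 0.0
    grand_mean = float(psu_tot.mean())
    for _, ztots in psu_tot.groupby(level="stratum", sort=True):
        n_h = len(ztots)
        if n_h < 2:
            if single_psu == "center":
                var += float(((ztots - grand_mean) ** 2).sum())
                continue
            raise EstimationError(
                "stratum with a single PSU; pass single_psu='center' to "
                "score it against the grand mean"
            )
        var += n_h / (n_h - 1) * float(((ztots - ztots.mean()) ** 2).sum())
    return var


def _domain_mask(df: pd.DataFrame, measure: str, domain: pd.Series | None) -> np.ndarray:
    mask = df[measure].notna()
    if domain is not None:
        mask &= domain.reindex(df.index, fill_value=False)
    return mask.to_numpy()


def estimate_variance(
    df: pd.DataFrame,
    measure: str,
    benchmark: float,
    params: HEMParams | None = None,
    single_psu: str = "error",
    domain: pd.Series | None = None,
) -> float:
    """Design-based SE of the HEM via stratified between-PSU linearization.

    The HEM is an affine transform of the weighted mean contribution
    θ = Σw c/Σw, so SE(HEM) = rescale × SE(θ) with the benchmark treated
    as fixed.  θ is linearized as z_i = w_i (c_i − θ)/Σw over the
    estimation domain (records with a coded value, optionally restricted
    further by ``domain``); records outside contribute z_i = 0 but their
    PSUs stay in the design, as in standard survey domain estimation.
    """
    params = params or HEMParams()
    mask = _domain_mask(df, measure, domain)
    if not mask.any():
        raise EstimationError(f"no coded values for {measure}")
    w = df["weight"].to_numpy(dtype=float)
    c = np.zeros(len(df))
    c[mask] = deficit_contributions(df[measure].to_numpy()[mask], benchmark, params)
    wsum = float(w[mask].sum())
    theta = float(np.sum(w[mask] * c[mask]) / wsum)
    z = np.where(mask, w * (c - theta), 0.0) / wsum
    var = _stratified_psu_variance(df, z, single_psu=single_psu)
    return float(params.rescale * np.sqrt(var))


def compute_hem(
    df: pd.DataFrame,
    measure: str,
    benchmark: float,
    params: HEMParams | None = None,
    year: int | None = None,
    single_psu: str = "error",
    domain: pd.Series | None = None,
) -> HEMEstimate:
    """HEM estimate with design-based SE for one year's coded records.

    ``domain`` optionally restricts estimation to a subgroup (e.g. an age
    band) while keeping the full design structure for the variance.
    """
    params = params or HEMParams()
    mask = _domain_mask(df, measure, domain)
    if not mask.any():
        raise EstimationError(f"no coded values for {measure}")
    sub = df.loc[mask]
    value = hem_point(sub[measure], benchmark, params, sub["weight"])
    se = estimate_variance(df, measure, benchmark, params, single_psu=single_psu, domain=domain)
    if year is None:
        years = sub["year"].unique()
        year = int(years[0]) if len(years) == 1 else -1
    return HEMEstimate(
        year=year,
        measure=measure,
        value=value,
        se=se,
        ci_low=value - _Z975 * se,
        ci_high=value + _Z975 * se,
        n=int(len(sub)),
        benchmark=float(benchmark),
    )


def combine_imputations(per_imputation: Sequence[HEMEstimate]) -> HEMEstimate:
    """Pool estimates over imputation replicates with Rubin's rules.

    Point = mean of points; total variance = within + (1 + 1/m) × between,
    where between = Σ(q − q̄)²/(m − 1).  CI from a normal approximation.
    """
    if len(per_imputation) == 0:
        raise CombinationError("no estimates to combine")
    first = per_imputation[0]
    if any(e.year != first.year or e.measure != first.measure for e in per_imputation):
        raise CombinationError("mismatched year/measure across imputations")
    m = len(per_imputation)
    if m == 1:
        return first
    q = np.array([e.value for e in per_imputation])
    within = float(np.mean([e.se**2 for e in per_imputation]))
    between = float(np.sum((q - q.mean()) ** 2) / (m - 1))
    total = within + (1 + 1 / m) * between
    point = float(q.mean())
    se = float(np.sqrt(total))
    return replace(
        first,
        value=point,
        se=se,
        ci_low=point - _Z975 * se,
        ci_high=point + _Z975 * se,
        benchmark=float(np.mean([e.benchmark for e in per_imputation])),
    )


def compute_hem_mi(
    df: pd.DataFrame,
    measure: str,
    spec: BenchmarkSpec | None = None,
    params: HEMParams | None = None,
    n_imputations: int | None = None,
    year: int | None = None,
    single_psu: str = "error",
    domain: pd.Series | None = None,
) -> HEMEstimate:
    """HEM for one year, re-deriving the benchmark under each income imputation.

    Only the benchmark depends on the imputed income category (the
    privileged cell is income-defined), so each replicate recomputes
    ȳ* and the full estimate before Rubin's rules pooling.
    """
    spec = spec or BenchmarkSpec()
    m = n_imputations or _count_imputations(df)
    estimates = []
    for i in range(1, m + 1):
        bench = compute_benchmark(
            df, measure, spec, income_col=f"income_imp{i}", domain=domain
        )
        estimates.append(
            compute_hem(
                df, measure, bench, params, year=year, single_psu=single_psu, domain=domain
            )
        )
    return combine_imputations(estimates)


def _count_imputations(df: pd.DataFrame) -> int:
    m = sum(1 for c in df.columns if c.startswith("income_imp"))
    if m == 0:
        raise EstimationError("no income_imp* columns in microdata")
    return m


def hem_series(
    df: pd.DataFrame,
    measure: str,
    spec: BenchmarkSpec | None = None,
    params: HEMParams | None = None,
    n_imputations: int | None = None,
    single_psu: str = "error",
    domain: pd.Series | None = None,
) -> list[HEMEstimate]:
    """Annual HEM estimates over all years present.

    With ``spec.per_year`` (default) the benchmark is recomputed within
    each survey year; otherwise a single pooled benchmark per imputation
    is reused across years.  ``domain`` restricts estimation to a
    subgroup while keeping the full design for the variance.
    """
    spec = spec or BenchmarkSpec()
    m = n_imputations or _count_imputations(df)
    pooled = None
    if not spec.per_year:
        pooled = [
            compute_benchmark(df, measure, spec, income_col=f"income_imp{i}", domain=domain)
            for i in range(1, m + 1)
        ]
    out = []
    for year, sub in df.groupby("year", sort=True):
        sub_domain = None if domain is None else domain.loc[sub.index]
        if not _domain_mask(sub, measure, sub_domain).any():
            continue
        if pooled is None:
            est = compute_hem_mi(
                sub, measure, spec, params,
                n_imputations=m, year=int(year), single_psu=single_psu, domain=sub_domain,
            )
        else:
            per_imp = [
                compute_hem(
                    sub, measure, b, params,
                    year=int(year), single_psu=single_psu, domain=sub_domain,
                )
                for b in pooled
            ]
            est = combine_imputations(per_imp)
        out.append(est)
    return out
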