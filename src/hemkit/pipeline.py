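"""End-to-end orchestration: code measures, estimate annual equity and
disparities (overall and by age band or region), run trend inference, and
emit tidy result tables plus a run manifest.

Output layout is one tidy CSV per artifact type (``hem.csv``,
``disparities.csv``, ``trends.csv``, ``describe.csv``) plus a
``manifest.json`` recording the seed, all parameters, and the package
version; a bundle can be regenerated exactly from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .disparities import CONTRASTS, disparity_series
from .exceptions import ConfigurationError, EstimationError
from .hem import BenchmarkSpec, HEMParams, hem_series, is_privileged
from .measures import MEASURES, MEASURE_NAMES, code_dataframe
from .synthetic_data import (
    INCOME_LEVELS,
    RACE_LEVELS,
    REGION_LEVELS,
    SEX_LEVELS,
    PopulationConfig,
    generate_population,
    read_microdata,
)
from .trends import AnnualSeries, TrendResult, simulate_trend

__all__ = [
    "AGE_BANDS",
    "AnalysisConfig",
    "ResultBundle",
    "run_analysis",
    "describe_population",
    "config_from_manifest",
]

logger = logging.getLogger("hemkit")

#: The four age bands used for age-stratified analyses.
AGE_BANDS: Mapping[str, tuple[int, int]] = {
    "0-3": (0, 3),
    "4-7": (4, 7),
    "8-12": (8, 12),
    "13-17": (13, 17),
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to run (and exactly re-run) a full analysis."""

    population: PopulationConfig | None = field(default_factory=PopulationConfig)
    input_path: str | None = None
    measures: tuple[str, ...] = MEASURE_NAMES
    benchmark: BenchmarkSpec = field(default_factory=BenchmarkSpec)
    params: HEMParams = field(default_factory=HEMParams)
    strata: str = "age_groups"
    age_bands: tuple[str, ...] = tuple(AGE_BANDS)
    contrasts: tuple[str, ...] = tuple(CONTRASTS)
    n_reps: int = 10_000
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.population is None and self.input_path is None:
            raise ConfigurationError("need either a population config or an input path")
        if self.strata not in ("none", "age_groups", "regions"):
            raise ConfigurationError(f"unknown strata mode: {self.strata!r}")
        for m in self.measures:
            if m not in MEASURES:
                raise ConfigurationError(f"unknown measure: {m!r}")
        for c in self.contrasts:
            if c not in CONTRASTS:
                raise ConfigurationError(f"unknown contrast: {c!r}")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        for band in self.age_bands:
            if band not in AGE_BANDS:
                raise ConfigurationError(f"unknown age band: {band!r}")
        if self.strata == "age_groups":
            for m in self.measures:
                if not self._compatible_bands(m, self.age_bands):
                    raise ConfigurationError(
                        f"measure {m!r} is valid for ages {MEASURES[m].valid_ages}, "
                        "compatible with none of the requested age bands"
                    )

    @staticmethod
    def _compatible_bands(measure: str, bands: Sequence[str]) -> list[str]:
        lo, hi = MEASURES[measure].valid_ages
        return [
            label
            for label in bands
            if max(lo, AGE_BANDS[label][0]) <= min(hi, AGE_BANDS[label][1])
        ]


@dataclass
class ResultBundle:
    """Tidy result tables plus the manifest that reproduces them."""

    hem: pd.DataFrame
    disparities: pd.DataFrame
    trends: pd.DataFrame
    describe: pd.DataFrame
    manifest: dict


def _strata_masks(
    df: pd.DataFrame, mode: str, measure: str, bands: Sequence[str] = tuple(AGE_BANDS)
) -> list[tuple[str, pd.Series]]:
    out: list[tuple[str, pd.Series]] = [("all", pd.Series(True, index=df.index))]
    if mode == "age_groups":
        for label in AnalysisConfig._compatible_bands(measure, bands):
            blo, bhi = AGE_BANDS[label]
            out.append((label, df["age"].between(blo, bhi)))
    elif mode == "regions":
        for region in REGION_LEVELS:
            out.append((region, df["region"] == region))
    return out


def _series_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def run_analysis(config: AnalysisConfig) -> ResultBundle:
    """Run the full analysis described by ``config``.

    For every measure × stratum: annual equity estimates (income
    imputations pooled) and a Monte Carlo trend; for every measure ×
    contrast on the whole population: annual disparity gaps and their
    trends.  Deterministic for a fixed config.
    """
    config.validate()
    if config.input_path is not None:
        df_raw = read_microdata(config.input_path)
        logger.info("read %d records from %s", len(df_raw), config.input_path)
    else:
        df_raw = generate_population(config.population)
        logger.info("generated %d records", len(df_raw))
    df = code_dataframe(df_raw, config.measures)
    for m in config.measures:
        logger.info("coded %s: %d/%d records", m, int(df[m].notna().sum()), len(df))

    hem_rows, trend_rows, disp_rows = [], [], []
    series_idx = 0
    for measure in config.measures:
        for label, mask in _strata_masks(df, config.strata, measure, config.age_bands):
            try:
                estimates = hem_series(
                    df, measure, config.benchmark, config.params,
                    domain=None if label == "all" else mask,
                )
            except EstimationError as err:
                logger.warning("skipping %s / %s: %s", measure, label, err)
                continue
            for e in estimates:
                hem_rows.append(
                    {
                        "year": e.year, "measure": e.measure, "stratum": label,
                        "estimate": e.value, "se": e.se, "ci_low": e.ci_low,
                        "ci_high": e.ci_high, "n": e.n, "benchmark": e.benchmark,
                    }
                )
            trend_rows.extend(
                _trend_row(estimates, measure, label, "hem", config, series_idx)
            )
            series_idx += 1
        for contrast in config.contrasts:
            estimates = disparity_series(df, measure, contrast)
            for e in estimates:
                disp_rows.append(
                    {
                        "year": e.year, "measure": e.measure, "stratum": "all",
                        "contrast": e.contrast, "estimate": e.gap, "se": e.se,
                        "ci_low": e.ci_low, "ci_high": e.ci_high,
                        "n_advantaged": e.n_advantaged,
                        "n_disadvantaged": e.n_disadvantaged,
                    }
                )
            trend_rows.extend(
                _trend_row(estimates, measure, contrast, "disparity", config, series_idx)
            )
            series_idx += 1

    bundle = ResultBundle(
        hem=pd.DataFrame(hem_rows),
        disparities=pd.DataFrame(disp_rows),
        trends=pd.DataFrame(trend_rows),
        describe=describe_population(df),
        manifest=_manifest(config),
    )
    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _trend_row(estimates, measure, label, kind, config, series_idx) -> list[dict]:
    years = {e.year for e in estimates}
    if len(years) < 3:
        logger.warning("too few years for %s trend on %s / %s", kind, measure, label)
        return []
    series = AnnualSeries.from_estimates(estimates, measure=measure, stratum=label)
    res: TrendResult = simulate_trend(
        series, n_reps=config.n_reps, seed=_series_seed(config.seed, series_idx)
    )
    return [
        {
            "kind": kind, "measure": measure, "stratum": label,
            "median_slope": res.median_slope, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "n_reps": res.n_reps,
            "significant": res.significant, "seed": res.seed,
        }
    ]


def describe_population(df: pd.DataFrame) -> pd.DataFrame:
    """Weighted composition and measure means — the Table-1-style summary.

    Returns tidy rows (dimension, level, statistic, value, se): weighted
    shares by age band, sex, race/ethnicity, income category (averaged
    over imputations) and the privileged share, plus weighted means with
    design-based SEs for each coded measure present.
    """
    if df.empty:
        raise EstimationError("empty population")
    w = df["weight"].to_numpy(float)
    rows = []

    def share(mask: np.ndarray) -> float:
        return float(np.sum(w * mask) / w.sum())

    for label, (lo, hi) in AGE_BANDS.items():
        rows.append(("age_band", label, "share", share(df["age"].between(lo, hi).to_numpy()), np.nan))
    for sex in SEX_LEVELS:
        rows.append(("sex", sex, "share", share((df["sex"] == sex).to_numpy()), np.nan))
    for race in RACE_LEVELS:
        rows.append(
            ("race_ethnicity", race, "share", share((df["race_ethnicity"] == race).to_numpy()), np.nan)
        )
    imp_cols = [c for c in df.columns if c.startswith("income_imp")]
    for inc in INCOME_LEVELS:
        shares = [share((df[c] == inc).to_numpy()) for c in imp_cols]
        rows.append(("income", inc, "share", float(np.mean(shares)), np.nan))
    priv = [share(is_privileged(df, c).to_numpy()) for c in imp_cols]
    rows.append(("privileged", "privileged", "share", float(np.mean(priv)), np.nan))

    for measure in MEASURE_NAMES:
        if measure not in df.columns or df[measure].notna().sum() == 0:
            continue
        mean, se = _weighted_mean_se(df, measure)
        rows.append(("measure_mean", measure, "mean", mean, se))

    return pd.DataFrame(rows, columns=["dimension", "level", "statistic", "value", "se"])


def _weighted_mean_se(df: pd.DataFrame, measure: str) -> tuple[float, float]:
    """Design-based weighted mean and SE via between-PSU linearization
    (records without a coded value stay in the design with zero influence)."""
    from .hem import _stratified_psu_variance

    mask = df[measure].notna().to_numpy()
    wv = df["weight"].to_numpy(float)
    yv = df[measure].to_numpy(float)
    wsum = float(wv[mask].sum())
    mean = float(np.sum(wv[mask] * yv[mask]) / wsum)
    z = np.where(mask, wv * (np.nan_to_num(yv) - mean), 0.0) / wsum
    var = _stratified_psu_variance(df, z, single_psu="center")
    return mean, float(np.sqrt(var))


# ---------------------------------------------------------------------------
# manifest round-trip


def _manifest(config: AnalysisConfig) -> dict:
    pop = None
    if config.population is not None:
        pop = dataclasses.asdict(config.population)
        pop["years"] = list(config.population.years)
        pop["n_per_year"] = (
            list(config.population.n_per_year)
            if isinstance(config.population.n_per_year, (tuple, list))
            else config.population.n_per_year
        )
        pop["group_proportions"] = {
            "|".join(cell): float(p)
            for cell, p in config.population.group_proportions.items()
        }
        pop["health_model"] = {k: dict(v) for k, v in config.population.health_model.items()}
        pop["trend"] = {k: dict(v) for k, v in config.population.trend.items()}
    return {
        "package": "hemkit",
        "version": __version__,
        "seed": config.seed,
        "n_reps": config.n_reps,
        "strata": config.strata,
        "age_bands": list(config.age_bands),
        "measures": list(config.measures),
        "contrasts": list(config.contrasts),
        "benchmark": {
            "mode": config.benchmark.mode,
            "per_year": config.benchmark.per_year,
            "min_cell_size": config.benchmark.min_cell_size,
        },
        "params": {
            "alpha": config.params.alpha,
            "beta": config.params.beta,
            "rescale": config.params.rescale,
        },
        "population": pop,
        "input_path": config.input_path,
    }


def config_from_manifest(manifest: Mapping) -> AnalysisConfig:
    """Rebuild the exact :class:`AnalysisConfig` recorded in a manifest."""
    pop = None
    if manifest.get("population") is not None:
        p = dict(manifest["population"])
        p["years"] = tuple(p["years"])
        npy = p["n_per_year"]
        p["n_per_year"] = tuple(npy) if isinstance(npy, list) else int(npy)
        p["group_proportions"] = {
            tuple(k.split("|")): float(v) for k, v in p["group_proportions"].items()
        }
        pop = PopulationConfig(**p)
    return AnalysisConfig(
        population=pop,
        input_path=manifest.get("input_path"),
        measures=tuple(manifest["measures"]),
        benchmark=BenchmarkSpec(**manifest["benchmark"]),
        params=HEMParams(**manifest["params"]),
        strata=manifest["strata"],
        age_bands=tuple(manifest.get("age_bands", tuple(AGE_BANDS))),
        contrasts=tuple(manifest["contrasts"]),
        n_reps=int(manifest["n_reps"]),
        seed=int(manifest["seed"]),
    )


def _write_bundle(bundle: ResultBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.hem.to_csv(out_dir / "hem.csv", index=False)
    bundle.disparities.to_csv(out_dir / "disparities.csv", index=False)
    bundle.trends.to_csv(out_dir / "trends.csv", index=False)
    bundle.describe.to_csv(out_dir / "describe.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    logger.info("wrote result bundle to %s", out_dir)
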