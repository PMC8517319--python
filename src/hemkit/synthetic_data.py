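"""NHIS-like synthetic child microdata and the illustrative scenario populations.

Two generators live here:

* :func:`generate_population` draws repeated cross-sections of sampled
  children (one row per child) with the structural features the downstream
  estimators need: demographic composition similar to published NHIS
  sample-child descriptives, income/race gradients in each health measure,
  complex-design fields (weights, strata, PSUs), several income-imputation
  replicates, and optional linear time trends in group means.  Raw survey
  responses are produced (categories, item points), so the coding step is
  exercised for real.

* :func:`generate_scenario` draws the four two-group illustration
  populations (privileged mean 60, non-privileged mean 40 on a 0–100
  scale) in which the between-group mean difference is constant at 20
  while the within-group distributions concentrate health deficits more
  and more — the construction that separates a disparity gap from the
  equity metric.

All randomness flows from a single integer seed via
``numpy.random.default_rng``; identical configs give identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .measures import (
    GENERAL_HEALTH_WEIGHTS,
    MEASURES,
    MEASURE_NAMES,
    MHI_N_ITEMS,
    SDQ_N_ITEMS,
)

__all__ = [
    "RACE_LEVELS",
    "SEX_LEVELS",
    "INCOME_LEVELS",
    "REGION_LEVELS",
    "PopulationConfig",
    "ScenarioSpec",
    "default_group_proportions",
    "default_health_model",
    "generate_population",
    "generate_scenario",
    "embed_known_trend",
    "write_microdata",
    "read_microdata",
    "config_to_yaml",
    "config_from_yaml",
]

RACE_LEVELS = ("white_nl", "black_nl", "latinx", "other_nl")
SEX_LEVELS = ("male", "female")
INCOME_LEVELS = ("lt150", "mid150_399", "ge400")
REGION_LEVELS = ("northeast", "midwest", "south", "west")

# Age-band shares approximating the published sample-child composition.
AGE_BAND_SHARES = {(0, 3): 0.22, (4, 7): 0.225, (8, 12): 0.28, (13, 17): 0.275}
REGION_SHARES = (0.17, 0.21, 0.38, 0.24)

_RACE_SHARES = {"white_nl": 0.58, "black_nl": 0.15, "latinx": 0.21, "other_nl": 0.06}
_MALE_SHARE = 0.51
# Income category given race/ethnicity: the correlation is what puts the
# privileged cell (white non-Latinx boys, >=400% FPL) near 11% of children.
_INCOME_GIVEN_RACE = {
    "white_nl": (0.20, 0.42, 0.38),
    "black_nl": (0.45, 0.40, 0.15),
    "latinx": (0.45, 0.41, 0.14),
    "other_nl": (0.30, 0.42, 0.28),
}


def default_group_proportions() -> dict[tuple[str, str, str], float]:
    """Joint (race, sex, income) cell probabilities; privileged cell ≈ 0.112."""
    props = {}
    for race, p_race in _RACE_SHARES.items():
        for sex, p_sex in zip(SEX_LEVELS, (_MALE_SHARE, 1 - _MALE_SHARE)):
            for inc, p_inc in zip(INCOME_LEVELS, _INCOME_GIVEN_RACE[race]):
                props[(race, sex, inc)] = p_race * p_sex * p_inc
    return props


def default_health_model() -> dict[str, dict]:
    """Per-measure latent-mean model on each coded (higher-is-better) scale.

    ``latent = baseline + income_offset + race_offset + trend*(year - y0) + noise``
    is discretized onto the measure's raw response scale.  Baselines and
    gradient sizes are set so that coded population means land near the
    published sample-child averages (general health ≈ 0.94, school-loss
    days ≈ 36.5, SDQ ≈ 8.2, emotional difficulties ≈ 2.7, toddler MHI
    ≈ 6.7, toddler depression ≈ 1.9) with the advantaged cells healthier.
    """
    return {
        "general_health": {
            "baseline": 0.958,
            "income_offsets": {"lt150": -0.025, "mid150_399": 0.0, "ge400": 0.03},
            "race_offsets": {"white_nl": 0.0, "black_nl": -0.018, "latinx": -0.012, "other_nl": -0.006},
            "noise_sd": 0.08,
        },
        "school_days": {
            "baseline": 37.9,
            "income_offsets": {"lt150": -1.6, "mid150_399": 0.0, "ge400": 1.2},
            "race_offsets": {"white_nl": 0.0, "black_nl": -0.8, "latinx": -0.6, "other_nl": -0.3},
            "noise_sd": 5.5,
        },
        "sdq": {
            "baseline": 8.6,
            "income_offsets": {"lt150": -0.5, "mid150_399": 0.0, "ge400": 0.35},
            "race_offsets": {"white_nl": 0.0, "black_nl": -0.25, "latinx": -0.15, "other_nl": -0.1},
            "noise_sd": 1.8,
        },
        "emotional_difficulties": {
            "baseline": 2.88,
            "income_offsets": {"lt150": -0.12, "mid150_399": 0.0, "ge400": 0.08},
            "race_offsets": {"white_nl": 0.0, "black_nl": -0.05, "latinx": -0.03, "other_nl": -0.02},
            "noise_sd": 0.55,
        },
        "toddler_mhi": {
            "baseline": 7.0,
            "income_offsets": {"lt150": -0.4, "mid150_399": 0.0, "ge400": 0.3},
            "race_offsets": {"white_nl": 0.0, "black_nl": -0.2, "latinx": -0.12, "other_nl": -0.08},
            "noise_sd": 1.5,
        },
        "toddler_depression": {
            "baseline": 1.95,
            "income_offsets": {"lt150": -0.12, "mid150_399": 0.0, "ge400": 0.08},
            "race_offsets": {"white_nl": 0.0, "black_nl": -0.05, "latinx": -0.03, "other_nl": -0.02},
            "noise_sd": 0.6,
        },
    }


@dataclass(frozen=True)
class PopulationConfig:
    """Full parameterization of the synthetic repeated cross-section.

    ``n_per_year`` is either a fixed integer or an inclusive (low, high)
    range from which each year's sample size is drawn uniformly.
    ``trend`` maps measure name -> {selector: additive change per year in
    the latent group mean}, with selectors ``"all"``, ``"income:<cat>"``
    or ``"race:<cat>"``.
    """

    years: tuple[int, ...] = tuple(range(1997, 2019))
    n_per_year: int | tuple[int, int] = (8000, 14000)
    group_proportions: Mapping[tuple[str, str, str], float] = field(
        default_factory=default_group_proportions
    )
    health_model: Mapping[str, Mapping] = field(default_factory=default_health_model)
    trend: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    n_strata: int = 50
    psus_per_stratum: int = 2
    weight_sigma: float = 0.5
    n_imputations: int = 5
    income_missing_rate: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        total = float(sum(self.group_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"group proportions sum to {total}, not 1")
        if any(p < 0 for p in self.group_proportions.values()):
            raise ConfigurationError("negative group proportion")
        lo, hi = self._n_range()
        if lo < 1 or hi < lo:
            raise ConfigurationError(f"invalid n_per_year: {self.n_per_year!r}")
        if self.n_imputations < 1:
            raise ConfigurationError("n_imputations must be >= 1")
        if not 0 <= self.income_missing_rate <= 1:
            raise ConfigurationError("income_missing_rate must be in [0, 1]")
        if self.n_strata < 1 or self.psus_per_stratum < 1:
            raise ConfigurationError("need at least one stratum and one PSU")
        for name, model in self.health_model.items():
            if name not in MEASURES:
                raise ConfigurationError(f"unknown measure in health model: {name}")
            if model["noise_sd"] < 0:
                raise ConfigurationError(f"negative noise scale for {name}")
        for name in self.trend:
            if name not in MEASURES:
                raise ConfigurationError(f"unknown measure in trend spec: {name}")

    def _n_range(self) -> tuple[int, int]:
        if isinstance(self.n_per_year, (tuple, list)):
            return int(self.n_per_year[0]), int(self.n_per_year[1])
        return int(self.n_per_year), int(self.n_per_year)


# ---------------------------------------------------------------------------
# latent-to-raw response discretization


def _group_latent(config: PopulationConfig, measure: str, race, income, year) -> np.ndarray:
    model = config.health_model[measure]
    latent = np.full(len(race), float(model["baseline"]))
    latent += np.array([model["income_offsets"][c] for c in income])
    latent += np.array([model["race_offsets"][c] for c in race])
    slopes = config.trend.get(measure, {})
    dy = year - config.years[0]
    if dy and slopes:
        latent += _trend_shift(slopes, race, income) * dy
    return latent


def _trend_shift(slopes: Mapping[str, float], race, income) -> np.ndarray:
    shift = np.full(len(race), float(slopes.get("all", 0.0)))
    for sel, slope in slopes.items():
        if sel == "all":
            continue
        kind, _, cat = sel.partition(":")
        if kind == "income":
            shift += np.where(np.asarray(income) == cat, slope, 0.0)
        elif kind == "race":
            shift += np.where(np.asarray(race) == cat, slope, 0.0)
        else:
            raise ConfigurationError(f"unknown trend selector: {sel!r}")
    return shift


_GH_VALUES = np.array(sorted(GENERAL_HEALTH_WEIGHTS.values()))
_GH_LABELS = [
    name for name, _ in sorted(GENERAL_HEALTH_WEIGHTS.items(), key=lambda kv: kv[1])
]
_GH_MIDPOINTS = (_GH_VALUES[1:] + _GH_VALUES[:-1]) / 2


def _split_items(total: np.ndarray, n_items: int) -> list[np.ndarray]:
    """Deterministically split integer totals into n_items points in 0..2."""
    return [np.clip(total - 2 * k, 0, 2) for k in range(n_items)]


def _responses_for_measure(measure: str, latent: np.ndarray) -> dict[str, np.ndarray]:
    """Discretize latent coded-scale health onto raw survey responses."""
    if measure == "general_health":
        idx = np.searchsorted(_GH_MIDPOINTS, latent)
        return {"general_health_raw": np.array(_GH_LABELS, dtype=object)[idx]}
    if measure == "school_days":
        days = np.clip(np.rint(40.0 - latent), 0, 40).astype(int)
        return {"school_days_raw": days}
    if measure == "sdq":
        total = np.clip(np.rint(10.0 - latent), 0, 10).astype(int)
        items = _split_items(total, SDQ_N_ITEMS)
        return {f"sdq_item{i + 1}": items[i] for i in range(SDQ_N_ITEMS)}
    if measure == "emotional_difficulties":
        coded = np.clip(np.rint(latent), 0, 3).astype(int)
        labels = np.array(["severe", "definite", "minor", "no"], dtype=object)
        return {"emotional_difficulties_raw": labels[coded]}
    if measure == "toddler_mhi":
        total = np.clip(np.rint(8.0 - latent), 0, 8).astype(int)
        items = _split_items(total, MHI_N_ITEMS)
        return {f"mhi_item{i + 1}": items[i] for i in range(MHI_N_ITEMS)}
    if measure == "toddler_depression":
        coded = np.clip(np.rint(latent), 1, 3).astype(int)
        labels = np.array(["", "often true", "sometimes true", "not true"], dtype=object)
        return {"toddler_depression_raw": labels[coded]}
    raise ConfigurationError(f"unknown measure: {measure}")


def _draw_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    bands = list(AGE_BAND_SHARES)
    probs = np.array(list(AGE_BAND_SHARES.values()))
    idx = rng.choice(len(bands), size=n, p=probs / probs.sum())
    lows = np.array([b[0] for b in bands])[idx]
    highs = np.array([b[1] for b in bands])[idx]
    return lows + rng.integers(0, highs - lows + 1)


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw the full repeated cross-section as one microdata frame.

    One row per sampled child with columns: ``year, age, sex,
    race_ethnicity, region, income_true, income_missing,
    income_imp1..income_impM, weight, stratum, psu`` plus the raw response
    columns of every measure the child is eligible for (NaN elsewhere).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells = sorted(config.group_proportions)  # canonical order: draws do not depend on dict order
    cell_probs = np.array([config.group_proportions[c] for c in cells], dtype=float)
    cell_probs = cell_probs / cell_probs.sum()
    income_given_race = _income_given_race_table(config)
    lo, hi = config._n_range()

    frames = []
    for year in config.years:
        n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        cell_idx = rng.choice(len(cells), size=n, p=cell_probs)
        race = np.array([cells[i][0] for i in cell_idx], dtype=object)
        sex = np.array([cells[i][1] for i in cell_idx], dtype=object)
        income = np.array([cells[i][2] for i in cell_idx], dtype=object)
        age = _draw_ages(rng, n)
        region = rng.choice(np.array(REGION_LEVELS, dtype=object), size=n, p=REGION_SHARES)

        weight = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)
        weight = weight / weight.mean()
        stratum = rng.integers(0, config.n_strata, size=n)
        psu = rng.integers(0, config.psus_per_stratum, size=n)

        cols: dict[str, np.ndarray] = {
            "year": np.full(n, year),
            "age": age,
            "sex": sex,
            "race_ethnicity": race,
            "region": region,
            "income_true": income,
            "weight": weight,
            "stratum": stratum,
            "psu": psu,
        }

        missing = rng.random(n) < config.income_missing_rate
        cols["income_missing"] = missing
        for m in range(1, config.n_imputations + 1):
            imp = income.copy()
            if missing.any():
                imp[missing] = _draw_income_conditional(
                    rng, race[missing], income_given_race
                )
            cols[f"income_imp{m}"] = imp

        for measure, mdef in MEASURES.items():
            if measure not in config.health_model:
                continue
            eligible = (
                (age >= mdef.valid_ages[0])
                & (age <= mdef.valid_ages[1])
                & mdef.is_available(year)
            )
            latent = _group_latent(config, measure, race, income, year)
            noise_sd = config.health_model[measure]["noise_sd"]
            if noise_sd > 0:
                latent = latent + rng.normal(0.0, noise_sd, size=n)
            responses = _responses_for_measure(measure, latent)
            for col, vals in responses.items():
                arr = np.array(vals, dtype=object)
                arr[~eligible] = np.nan
                cols[col] = arr

        frames.append(pd.DataFrame(cols))

    df = pd.concat(frames, ignore_index=True)
    return df


def _income_given_race_table(config: PopulationConfig) -> dict[str, np.ndarray]:
    """Income-category distribution by race implied by the joint cell table."""
    table = {}
    for race in RACE_LEVELS:
        probs = np.array(
            [
                sum(
                    p
                    for (r, s, inc2), p in config.group_proportions.items()
                    if r == race and inc2 == inc
                )
                for inc in INCOME_LEVELS
            ]
        )
        total = probs.sum()
        table[race] = probs / total if total > 0 else np.full(3, 1 / 3)
    return table


def _draw_income_conditional(rng, race: np.ndarray, table) -> np.ndarray:
    out = np.empty(len(race), dtype=object)
    levels = np.array(INCOME_LEVELS, dtype=object)
    for r in RACE_LEVELS:
        mask = race == r
        if mask.any():
            out[mask] = rng.choice(levels, size=mask.sum(), p=table[r])
    return out


# ---------------------------------------------------------------------------
# illustrative two-group scenarios


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the four two-group illustration populations.

    ``components`` holds, per group, a list of (mixture weight, location,
    spread) normal components on the 0–100 health scale.  The default
    constructions hold both group means fixed (privileged 60,
    non-privileged 40) while concentrating deficits:

    1. both groups unimodal, spread 8;
    2. non-privileged spread doubled to 16;
    3. both spreads doubled to 16;
    4. each group an equal-weight mixture at ±12 about its mean, spread 4.
    """

    scenario_id: int
    n_privileged: int = 100_000
    n_nonprivileged: int = 100_000
    mean_privileged: float = 60.0
    mean_nonprivileged: float = 40.0
    components: Mapping[str, Sequence[tuple[float, float, float]]] | None = None
    seed: int = 0

    def resolved_components(self) -> dict[str, list[tuple[float, float, float]]]:
        if self.components is not None:
            comps = {g: list(c) for g, c in self.components.items()}
        else:
            mp, mn = self.mean_privileged, self.mean_nonprivileged
            if self.scenario_id == 1:
                comps = {"privileged": [(1.0, mp, 8.0)], "nonprivileged": [(1.0, mn, 8.0)]}
            elif self.scenario_id == 2:
                comps = {"privileged": [(1.0, mp, 8.0)], "nonprivileged": [(1.0, mn, 16.0)]}
            elif self.scenario_id == 3:
                comps = {"privileged": [(1.0, mp, 16.0)], "nonprivileged": [(1.0, mn, 16.0)]}
            elif self.scenario_id == 4:
                comps = {
                    "privileged": [(0.5, mp - 12.0, 4.0), (0.5, mp + 12.0, 4.0)],
                    "nonprivileged": [(0.5, mn - 12.0, 4.0), (0.5, mn + 12.0, 4.0)],
                }
            else:
                raise ConfigurationError(f"scenario_id must be 1..4, got {self.scenario_id}")
        self._validate(comps)
        return comps

    def _validate(self, comps) -> None:
        for group, target in (
            ("privileged", self.mean_privileged),
            ("nonprivileged", self.mean_nonprivileged),
        ):
            clist = comps[group]
            wsum = float(sum(w for w, _, _ in clist))
            if abs(wsum - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{group} mixture weights sum to {wsum}, not 1"
                )
            implied = sum(w * loc for w, loc, _ in clist)
            if abs(implied - target) > 1e-9:
                raise ConfigurationError(
                    f"{group} implied mean {implied} != configured {target}"
                )
            if any(sd < 0 for _, _, sd in clist):
                raise ConfigurationError("negative component spread")


def generate_scenario(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (privileged, non-privileged) health values for one scenario."""
    comps = spec.resolved_components()
    rng = np.random.default_rng(spec.seed)
    out = []
    for group, n in (
        ("privileged", spec.n_privileged),
        ("nonprivileged", spec.n_nonprivileged),
    ):
        clist = comps[group]
        weights = np.array([w for w, _, _ in clist])
        idx = rng.choice(len(clist), size=n, p=weights / weights.sum())
        locs = np.array([loc for _, loc, _ in clist])[idx]
        sds = np.array([sd for _, _, sd in clist])[idx]
        out.append(locs + sds * rng.standard_normal(n))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# known-trend embedding


def embed_known_trend(
    config: PopulationConfig, slope_spec: Mapping[str, Mapping[str, float]]
) -> PopulationConfig:
    """Return a config whose latent group means follow the given lines.

    ``slope_spec`` maps measure -> {selector: change per year}; selectors
    as in :class:`PopulationConfig.trend`.  Raises if a slope would push
    any affected group's latent mean outside the measure's coded range
    over the configured years.  Latent means are allowed to drift up to
    10% of the scale width past either end: responses cluster at the
    boundary category there (e.g. zero school-loss days), which is
    representable; beyond that the configured line is not.
    """
    span = config.years[-1] - config.years[0]
    for measure, slopes in slope_spec.items():
        if measure not in config.health_model:
            raise ConfigurationError(f"no health model for measure {measure!r}")
        model = config.health_model[measure]
        lo, hi = MEASURES[measure].value_range
        margin = 0.1 * (hi - lo)
        lo, hi = lo - margin, hi + margin
        for inc in INCOME_LEVELS:
            for race in RACE_LEVELS:
                base = (
                    model["baseline"]
                    + model["income_offsets"][inc]
                    + model["race_offsets"][race]
                )
                shift = float(
                    _trend_shift(slopes, np.array([race]), np.array([inc]))[0]
                )
                end = base + shift * span
                if not lo <= end <= hi:
                    raise ConfigurationError(
                        f"trend on {measure} pushes ({race}, {inc}) mean to "
                        f"{end:.3f}, outside [{lo}, {hi}]"
                    )
    merged = dict(config.trend)
    for measure, slopes in slope_spec.items():
        combined = dict(merged.get(measure, {}))
        for sel, slope in slopes.items():
            combined[sel] = combined.get(sel, 0.0) + slope
        merged[measure] = combined
    return dataclasses.replace(config, trend=merged)


# ---------------------------------------------------------------------------
# I/O


def write_microdata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_microdata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["income_missing"] = df["income_missing"].astype(bool)
    return df


def config_to_yaml(config: PopulationConfig, path) -> None:
    """Serialize a population config as a flat YAML document."""
    payload = dataclasses.asdict(config)
    payload["years"] = list(config.years)
    payload["n_per_year"] = (
        list(config.n_per_year)
        if isinstance(config.n_per_year, (tuple, list))
        else config.n_per_year
    )
    payload["group_proportions"] = {
        "|".join(cell): float(p) for cell, p in config.group_proportions.items()
    }
    payload["health_model"] = {k: dict(v) for k, v in config.health_model.items()}
    payload["trend"] = {k: dict(v) for k, v in config.trend.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def config_from_yaml(path) -> PopulationConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    payload["years"] = tuple(payload["years"])
    npy = payload["n_per_year"]
    payload["n_per_year"] = tuple(npy) if isinstance(npy, list) else int(npy)
    payload["group_proportions"] = {
        tuple(key.split("|")): float(p)
        for key, p in payload["group_proportions"].items()
    }
    return PopulationConfig(**payload)
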