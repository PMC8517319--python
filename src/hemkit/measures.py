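"""Coding of the six child-health measures.

Each measure is transformed from its raw survey response onto a
semi-continuous scale on which *higher values always mean better health*
(reverse-coding where the instrument scores difficulties):

``general_health``
    Parent-reported 5-level general health status, reweighted with the
    Van Doorslaer–Jones health weights so the categorical report behaves
    like a semi-continuous utility (0.983 = excellent ... 0.401 = poor).
``school_days``
    Days of school missed in the past year due to illness/injury
    (ages 5–17), top-coded at 40 and reversed: value = 40 − min(days, 40).
``sdq``
    Abbreviated Strengths and Difficulties Questionnaire (ages 4–17),
    five 3-level items scored 0/1/2 and summed to 0–10, then reversed
    (10 − raw).  As printed on the instrument all five prompts are scored
    identically; ``flip_strength_items`` optionally reverse-scores the
    positively-worded prompts before summing.
``emotional_difficulties``
    Single 4-level report of difficulties with emotions/concentration/
    behaviour, coded 3 = no difficulties ... 0 = severe difficulties.
``toddler_mhi``
    Four-item toddler mental-health indicator (ages 2–3), items scored
    0/1/2, summed to 0–8 and reversed (8 − raw).
``toddler_depression``
    Single 3-level item (ages 2–3) reversed so "not true" (best) = 3 and
    "often true" (worst) = 1.

The module exposes scalar coders for each measure, a registry of
:class:`MeasureDefinition` objects describing coding maps, valid ages and
unavailable survey years, and :func:`code_dataframe` to code microdata in
bulk (records missing any item of a multi-item scale are excluded from
that measure, i.e. coded as NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import CodingError

__all__ = [
    "MEASURE_NAMES",
    "MEASURES",
    "MeasureDefinition",
    "GENERAL_HEALTH_WEIGHTS",
    "recode_general_health",
    "code_school_days",
    "score_sdq",
    "score_emotional_difficulties",
    "score_toddler_mhi",
    "score_toddler_depression",
    "code_dataframe",
    "write_registry",
]

#: Van Doorslaer–Jones health weights for parent-reported general health.
GENERAL_HEALTH_WEIGHTS: Mapping[str, float] = {
    "excellent": 0.983,
    "very good": 0.931,
    "good": 0.841,
    "fair": 0.707,
    "poor": 0.401,
}

EMOTIONAL_DIFFICULTIES_CODES: Mapping[str, int] = {
    "no": 3,
    "minor": 2,
    "definite": 1,
    "severe": 0,
}

TODDLER_DEPRESSION_CODES: Mapping[str, int] = {
    "not true": 3,
    "sometimes true": 2,
    "often true": 1,
}

#: 3-level item points shared by the SDQ and toddler-MHI scales.
ITEM_POINTS: Mapping[str, int] = {
    "not true": 0,
    "somewhat true": 1,
    "sometimes true": 1,
    "certainly true": 2,
    "often true": 2,
}

SDQ_N_ITEMS = 5
MHI_N_ITEMS = 4
SCHOOL_DAYS_TOP_CODE = 40
#: SDQ item indices whose prompts are positively worded (strengths):
#: gets along with adults/peers, good attention span, generally well-behaved.
SDQ_STRENGTH_ITEMS = (0, 1, 3)


@dataclass(frozen=True)
class MeasureDefinition:
    """Coding metadata for one health measure.

    Parameters
    ----------
    name : measure identifier used as the coded column name.
    valid_ages : inclusive (low, high) age range of respondents.
    unavailable_years : survey years in which the item was not fielded.
    coding : raw response -> numeric points (item points for summed scales).
    value_range : inclusive range of the coded, reverse-coded value.
    discrete_values : the exact attainable coded values, when the scale is
        a small finite set; ``None`` for effectively continuous scales.
    top_code : cap applied to the raw response before reversal.
    n_items : number of summed items (1 for single-item measures).
    raw_columns : microdata columns holding the raw response(s).
    """

    name: str
    valid_ages: tuple[int, int]
    coding: Mapping[str, float]
    value_range: tuple[float, float]
    raw_columns: tuple[str, ...]
    unavailable_years: frozenset[int] = frozenset()
    discrete_values: tuple[float, ...] | None = None
    top_code: int | None = None
    n_items: int = 1

    def is_available(self, year: int) -> bool:
        return year not in self.unavailable_years

    def valid_for_age(self, age: int) -> bool:
        lo, hi = self.valid_ages
        return lo <= age <= hi


MEASURES: Mapping[str, MeasureDefinition] = {
    "general_health": MeasureDefinition(
        name="general_health",
        valid_ages=(0, 17),
        coding=GENERAL_HEALTH_WEIGHTS,
        value_range=(0.401, 0.983),
        discrete_values=tuple(sorted(GENERAL_HEALTH_WEIGHTS.values())),
        raw_columns=("general_health_raw",),
    ),
    "school_days": MeasureDefinition(
        name="school_days",
        valid_ages=(5, 17),
        coding={},  # numeric raw response; see top_code + reversal
        value_range=(0.0, 40.0),
        top_code=SCHOOL_DAYS_TOP_CODE,
        raw_columns=("school_days_raw",),
    ),
    "sdq": MeasureDefinition(
        name="sdq",
        valid_ages=(4, 17),
        unavailable_years=frozenset({1997, 2009}),
        coding={"not true": 0, "somewhat true": 1, "certainly true": 2},
        value_range=(0.0, 10.0),
        n_items=SDQ_N_ITEMS,
        raw_columns=tuple(f"sdq_item{i + 1}" for i in range(SDQ_N_ITEMS)),
    ),
    "emotional_difficulties": MeasureDefinition(
        name="emotional_difficulties",
        valid_ages=(4, 17),
        unavailable_years=frozenset({1997}),
        coding=EMOTIONAL_DIFFICULTIES_CODES,
        value_range=(0.0, 3.0),
        discrete_values=(0.0, 1.0, 2.0, 3.0),
        raw_columns=("emotional_difficulties_raw",),
    ),
    "toddler_mhi": MeasureDefinition(
        name="toddler_mhi",
        valid_ages=(2, 3),
        coding={"not true": 0, "sometimes true": 1, "often true": 2},
        value_range=(0.0, 8.0),
        n_items=MHI_N_ITEMS,
        raw_columns=tuple(f"mhi_item{i + 1}" for i in range(MHI_N_ITEMS)),
    ),
    "toddler_depression": MeasureDefinition(
        name="toddler_depression",
        valid_ages=(2, 3),
        coding=TODDLER_DEPRESSION_CODES,
        value_range=(1.0, 3.0),
        discrete_values=(1.0, 2.0, 3.0),
        raw_columns=("toddler_depression_raw",),
    ),
}

MEASURE_NAMES: tuple[str, ...] = tuple(MEASURES)


def recode_general_health(category: str) -> float:
    """Map a 5-level general-health report to its Van Doorslaer–Jones weight."""
    try:
        return GENERAL_HEALTH_WEIGHTS[str(category).strip().lower()]
    except KeyError:
        raise CodingError(f"unknown general-health category: {category!r}") from None


def code_school_days(days_missed: float) -> float:
    """Reverse-code school-loss days: 40 − min(days, 40); higher = fewer missed."""
    days = float(days_missed)
    if not np.isfinite(days) or days < 0:
        raise CodingError(f"days missed must be a nonnegative number, got {days_missed!r}")
    return float(SCHOOL_DAYS_TOP_CODE - min(days, SCHOOL_DAYS_TOP_CODE))


def _item_points(response, n_items: int, what: str) -> int:
    if isinstance(response, str):
        try:
            return ITEM_POINTS[response.strip().lower()]
        except KeyError:
            raise CodingError(f"unknown {what} item response: {response!r}") from None
    if response is None or (isinstance(response, float) and np.isnan(response)):
        raise CodingError(f"missing {what} item")
    pts = int(response)
    if pts != response or not 0 <= pts <= 2:
        raise CodingError(f"{what} item points must be integers in 0..2, got {response!r}")
    return pts


def score_sdq(item_responses: Sequence, flip_strength_items: bool = False) -> float:
    """Score the abbreviated SDQ: 10 − (sum of five 0/1/2 items).

    As printed, all five prompts are scored identically.  With
    ``flip_strength_items`` the three positively-worded prompts are
    reverse-scored (2 − points) before summing.
    """
    if len(item_responses) != SDQ_N_ITEMS:
        raise CodingError(f"SDQ requires {SDQ_N_ITEMS} items, got {len(item_responses)}")
    pts = [_item_points(r, SDQ_N_ITEMS, "SDQ") for r in item_responses]
    if flip_strength_items:
        pts = [2 - p if i in SDQ_STRENGTH_ITEMS else p for i, p in enumerate(pts)]
    return float(10 - sum(pts))


def score_emotional_difficulties(response: str) -> float:
    """Code the 4-level emotional-difficulties report (3 = none ... 0 = severe)."""
    key = str(response).strip().lower()
    if key in EMOTIONAL_DIFFICULTIES_CODES:
        return float(EMOTIONAL_DIFFICULTIES_CODES[key])
    # tolerate the fuller phrasings, e.g. "yes, minor difficulties"; check the
    # severity words before "no", which is a substring of "minor"
    for level in ("severe", "definite", "minor", "no"):
        if level in key:
            return float(EMOTIONAL_DIFFICULTIES_CODES[level])
    raise CodingError(f"unknown emotional-difficulties level: {response!r}")


def score_toddler_mhi(item_responses: Sequence) -> float:
    """Score the toddler mental-health indicator: 8 − (sum of four 0/1/2 items)."""
    if len(item_responses) != MHI_N_ITEMS:
        raise CodingError(f"toddler MHI requires {MHI_N_ITEMS} items, got {len(item_responses)}")
    return float(8 - sum(_item_points(r, MHI_N_ITEMS, "toddler MHI") for r in item_responses))


def score_toddler_depression(response: str) -> float:
    """Code toddler depression reverse-scored: not true = 3 ... often true = 1."""
    try:
        return float(TODDLER_DEPRESSION_CODES[str(response).strip().lower()])
    except KeyError:
        raise CodingError(f"unknown toddler-depression level: {response!r}") from None


def _code_column(raw: pd.Series, mapping: Mapping[str, float]) -> pd.Series:
    coded = raw.map(mapping)
    bad = raw.notna() & coded.isna()
    if bad.any():
        raise CodingError(f"unmappable responses in {raw.name!r}: {raw[bad].unique()[:5]}")
    return coded.astype(float)


def code_dataframe(
    df: pd.DataFrame,
    measures: Sequence[str] | None = None,
    flip_sdq_strength_items: bool = False,
) -> pd.DataFrame:
    """Add coded measure columns to a microdata frame.

    A record is coded for a measure only when its age is in the measure's
    valid range, the survey year fielded the item, and every raw item is
    present; otherwise the coded value is NaN (complete-case per measure).
    Returns a copy; raw columns are retained.
    """
    out = df.copy()
    for name in measures or MEASURE_NAMES:
        mdef = MEASURES[name]
        eligible = out["age"].between(*mdef.valid_ages) & ~out["year"].isin(
            list(mdef.unavailable_years)
        )
        if name == "school_days":
            raw = pd.to_numeric(out["school_days_raw"], errors="coerce")
            if (raw.dropna() < 0).any():
                raise CodingError("negative school-loss days")
            coded = SCHOOL_DAYS_TOP_CODE - raw.clip(upper=SCHOOL_DAYS_TOP_CODE)
        elif mdef.n_items > 1:
            items = out[list(mdef.raw_columns)].apply(pd.to_numeric, errors="coerce")
            legal = items.isin([0, 1, 2]) | items.isna()
            if not legal.all().all():
                raise CodingError(f"{name} item points outside 0..2")
            if name == "sdq" and flip_sdq_strength_items:
                for i in SDQ_STRENGTH_ITEMS:
                    col = mdef.raw_columns[i]
                    items[col] = 2 - items[col]
            raw_sum = items.sum(axis=1, skipna=False)  # NaN if any item missing
            coded = mdef.value_range[1] - raw_sum
        else:
            norm = out[mdef.raw_columns[0]].astype("string").str.strip().str.lower()
            coded = _code_column(norm, dict(mdef.coding))
        out[name] = coded.where(eligible)
    return out


def write_registry(path) -> None:
    """Dump the measure registry (coding maps, ages, years) as YAML for audit."""
    payload = {}
    for name, m in MEASURES.items():
        payload[name] = {
            "valid_ages": list(m.valid_ages),
            "unavailable_years": sorted(m.unavailable_years),
            "coding": dict(m.coding),
            "value_range": list(m.value_range),
            "top_code": m.top_code,
            "n_items": m.n_items,
            "raw_columns": list(m.raw_columns),
            "direction": "higher_is_better",
        }
    payload["school_days"]["transform"] = "value = 40 - min(days_missed, 40)"
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
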