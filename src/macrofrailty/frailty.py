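"""Frailty-index construction at every aggregation level.

The frailty index of an individual is the fraction of a fixed list of N
age-related health conditions (deficits) that the individual has.  Averaged
over a population cell, the index equals the arithmetic mean of the N
condition prevalence rates in that cell — a rearrangement of the double sum
over individuals and conditions.  This module builds:

* the micro index for a single deficit vector,
* the cell index d_ac for (country, period, sex, age-group) cells,
* unweighted "period life-cycle" aggregates (the deficits of a hypothetical
  person facing one period's age-specific rates, ages 20–94),
* population-weighted aggregates, in particular the workforce index
  (ages 20–64, weighted by the population shares of the age groups).

All panels are long-format :class:`pandas.DataFrame` objects; see
:mod:`macrofrailty.io` for the on-disk schemas.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError

#: Closed five-year age groups used throughout, ages 20 to 94.
AGE_GROUPS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(20, 95, 5)
)

#: Working-age subset, 20–24 through 60–64.
WORKING_AGE_GROUPS: tuple[str, ...] = AGE_GROUPS[:9]

#: Old-age complement of the working ages, 65–69 through 90–94.
OLD_AGE_GROUPS: tuple[str, ...] = AGE_GROUPS[9:]

SEXES: tuple[str, ...] = ("female", "male")

CELL_KEYS = ["country", "period", "sex", "age_group"]


def age_group_position(label: str) -> int:
    """0-based index of a five-year age-group label (``"20-24"`` -> 0).

    The linear age coordinate in the age-gradient regression is this index,
    so the slope is per five-year group and dividing by 5 annualizes it.
    """
    try:
        return AGE_GROUPS.index(label)
    except ValueError:
        raise ValidationError(
            f"unknown age-group label {label!r}; expected one of "
            f"{AGE_GROUPS[0]}..{AGE_GROUPS[-1]}"
        ) from None


def age_range(age_lo: str, age_hi: str) -> tuple[str, ...]:
    """Contiguous run of age-group labels from ``age_lo`` to ``age_hi``."""
    lo, hi = age_group_position(age_lo), age_group_position(age_hi)
    if lo > hi:
        raise ValidationError(f"age range {age_lo}..{age_hi} is reversed")
    return AGE_GROUPS[lo : hi + 1]


def micro_frailty(flags: Iterable[int]) -> float:
    """Frailty index of one individual: the fraction of deficits present.

    Parameters
    ----------
    flags
        Binary indicators, one per potential deficit (length N >= 1).
    """
    arr = np.asarray(list(flags) if not isinstance(flags, np.ndarray) else flags)
    if arr.size == 0:
        raise DomainError("deficit vector is empty; need N >= 1 deficits")
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("deficit indicators must be 0 or 1")
    return float(arr.mean())


def age_group_index(cell_prevalences: Sequence[float], n_conditions: int | None = None) -> float:
    """Cell frailty index: the mean of the N condition prevalence rates.

    ``n_conditions`` declares the expected item set size; supplying fewer or
    more rates is an error — the index is never silently renormalized over
    an incomplete condition set, because the item list must stay fixed from
    one computation to the next.
    """
    rates = np.asarray(cell_prevalences, dtype=float)
    if rates.size == 0:
        raise ValidationError("no prevalence rates supplied")
    if n_conditions is not None and rates.size != n_conditions:
        raise ValidationError(
            f"expected {n_conditions} conditions, got {rates.size}; the "
            "deficit item set is fixed and is not renormalized"
        )
    if ((rates < 0) | (rates > 1)).any():
        raise ValidationError("prevalence rates must lie in [0, 1]")
    return float(rates.mean())


def build_frailty_panel(prevalence: pd.DataFrame) -> pd.DataFrame:
    """Collapse a prevalence panel to cell frailty indices.

    Every (country, period, sex, age_group) cell must carry the identical
    condition set; a cell missing conditions raises rather than averaging
    over what is present.

    Returns a frailty panel with columns ``country, period, sex, age_group,
    frailty``.
    """
    conditions = frozenset(prevalence["condition"].unique())
    n = len(conditions)
    counts = prevalence.groupby(CELL_KEYS, sort=False, observed=True)["condition"].nunique()
    bad = counts[counts != n]
    if len(bad):
        raise ValidationError(
            f"{len(bad)} cells do not carry the full {n}-condition set; "
            f"first offender: {bad.index[0]}"
        )
    if prevalence.duplicated(CELL_KEYS + ["condition"]).any():
        dup = prevalence[prevalence.duplicated(CELL_KEYS + ["condition"])].iloc[0]
        raise ValidationError(f"duplicate prevalence key: {tuple(dup[CELL_KEYS + ['condition']])}")
    out = (
        prevalence.groupby(CELL_KEYS, sort=True, observed=True)["prevalence"]
        .mean()
        .rename("frailty")
        .reset_index()
    )
    return out


def _check_range_complete(df: pd.DataFrame, groups: Sequence[str]) -> None:
    got = df.groupby(["country", "period", "sex"], observed=True)["age_group"].apply(set)
    want = set(groups)
    gaps = got[got.apply(lambda s: not want.issubset(s))]
    if len(gaps):
        key = gaps.index[0]
        missing = sorted(want - gaps.iloc[0], key=age_group_position)
        raise ValidationError(
            f"age groups missing in range for {key}: {missing}"
        )


def _combine_sexes(cells: pd.DataFrame) -> pd.DataFrame:
    """Both-sex cell index: population-weighted mean of the sex indices.

    Weighting by head counts reproduces the index computed from pooled
    both-sex prevalence, since prevalence x count = affected persons.
    """
    g = cells.groupby(["country", "period", "age_group"], observed=True)

    def pool(sub: pd.DataFrame) -> float:
        return float(np.average(sub["frailty"], weights=sub["count"]))

    pooled = g.apply(pool, include_groups=False).rename("frailty")
    counts = g["count"].sum()
    return pd.concat([pooled, counts], axis=1).reset_index()


def aggregate_index(
    frailty: pd.DataFrame,
    pop: pd.DataFrame | None,
    age_lo: str = "20-24",
    age_hi: str = "90-94",
    weighted: bool = True,
    combine_sexes: bool = True,
) -> pd.DataFrame:
    """Aggregate cell indices over an age range, per country-period.

    ``weighted=True`` weights age groups by their population share (the
    index of the average person alive); ``weighted=False`` is the simple
    mean across age groups (period life-cycle deficits — each age counts
    equally regardless of the population pyramid).  Population counts are
    required whenever weights or sex pooling are requested.

    Returns columns ``country, period, frailty`` (plus ``sex`` when
    ``combine_sexes=False``).
    """
    groups = age_range(age_lo, age_hi)
    sub = frailty[frailty["age_group"].isin(groups)].copy()
    if sub.empty:
        raise ValidationError(f"no cells in age range {age_lo}..{age_hi}")
    _check_range_complete(sub, groups)

    need_pop = weighted or combine_sexes
    if need_pop:
        if pop is None:
            raise ValidationError("population counts required for weighted or sex-pooled aggregation")
        sub = sub.merge(pop, on=CELL_KEYS, how="left", validate="one_to_one")
        if sub["count"].isna().any():
            miss = sub[sub["count"].isna()].iloc[0]
            raise ValidationError(f"population count missing for cell {tuple(miss[CELL_KEYS])}")

    if combine_sexes:
        sub = _combine_sexes(sub)
        keys = ["country", "period"]
    else:
        keys = ["country", "period", "sex"]

    if weighted:
        agg = sub.groupby(keys, observed=True).apply(
            lambda s: float(np.average(s["frailty"], weights=s["count"])),
            include_groups=False,
        )
    else:
        agg = sub.groupby(keys, observed=True)["frailty"].mean()
    return agg.rename("frailty").reset_index()


def workforce_index(frailty: pd.DataFrame, pop: pd.DataFrame) -> pd.DataFrame:
    """Workforce frailty index: weighted both-sex aggregate over ages 20–64.

    The workforce ages through two channels — deficits rising within each
    age group, and population mass shifting toward older (more frail)
    groups; the population-share weights capture the second channel.
    """
    return aggregate_index(
        frailty, pop, WORKING_AGE_GROUPS[0], WORKING_AGE_GROUPS[-1],
        weighted=True, combine_sexes=True,
    )
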