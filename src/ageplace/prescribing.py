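"""Apportion practice-level prescriptions to small areas.

GP prescribing ledgers record monthly item counts per practice, not per
patient address. To express prescribing as an area rate, each
practice-month's items are split across areas in proportion to where
that practice's registered patients live, then summed per area and
divided by the 50+ population and the number of years covered. The
resulting rates are *not* age-standardised: they describe the local
treatment environment, not prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CHEMICAL_CLASSES = ("AChEI", "Memantine")

_KEY = ["practice_id", "year", "month"]


def registration_proportions(registration: pd.DataFrame) -> pd.DataFrame:
    """Per practice-month, the share of registered patients in each area.

    Parameters
    ----------
    registration:
        Long table with columns ``practice_id, year, month, area_id,
        patients`` (non-negative integer counts).

    Returns
    -------
    DataFrame with columns ``practice_id, year, month, area_id, share``.
    Shares within each (practice, year, month) sum to 1; practice-months
    whose total registered count is zero emit no rows.
    """
    if registration.empty:
        raise ValueError("registration table is empty")
    if (registration["patients"] < 0).any():
        bad = registration.loc[registration["patients"] < 0]
        raise ValueError(
            f"negative patient counts for {len(bad)} registration rows"
        )
    reg = registration.groupby(_KEY + ["area_id"], as_index=False)["patients"].sum()
    totals = reg.groupby(_KEY)["patients"].transform("sum")
    reg = reg.loc[totals > 0].copy()
    reg["share"] = reg["patients"] / totals.loc[reg.index]
    return reg[_KEY + ["area_id", "share"]]


def _fallback_shares(shares: pd.DataFrame, ledger_months: pd.DataFrame) -> pd.DataFrame:
    """Fill practice-months missing from the share table.

    A ledger month with no registration snapshot borrows the nearest
    *earlier* month's shares for that practice (registration extracts
    can lag prescribing extracts). Months with no earlier snapshot stay
    missing and are reported by :func:`allocate_items`.
    """
    have = shares[_KEY].drop_duplicates()
    need = ledger_months.merge(have, on=_KEY, how="left", indicator=True)
    missing = need.loc[need["_merge"] == "left_only", _KEY]
    if missing.empty:
        return shares
    shares = shares.copy()
    shares["_t"] = shares["year"] * 12 + shares["month"]
    fills = []
    for practice_id, year, month in missing.itertuples(index=False):
        t = year * 12 + month
        prior = shares.loc[
            (shares["practice_id"] == practice_id) & (shares["_t"] < t)
        ]
        if prior.empty:
            continue
        src = prior.loc[prior["_t"] == prior["_t"].max()].copy()
        src["year"], src["month"] = year, month
        fills.append(src)
    out = pd.concat([shares] + fills, ignore_index=True) if fills else shares
    return out.drop(columns="_t")


def allocate_items(
    ledger: pd.DataFrame,
    shares: pd.DataFrame,
    chemical_class: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allocate a class's ledger items to areas via registration shares.

    Returns ``(allocated, unallocated)``: ``allocated`` has columns
    ``area_id, year, month, items`` with fractional items; ``unallocated``
    lists practice-months that had items but no registration shares (they
    are reported, never silently dropped). Allocation is conservative:
    for every practice-month with shares the allocated items sum to the
    ledger count.
    """
    if chemical_class not in CHEMICAL_CLASSES:
        raise ValueError(
            f"unknown chemical_class {chemical_class!r}; "
            f"expected one of {CHEMICAL_CLASSES}"
        )
    led = ledger.loc[ledger["chemical_class"] == chemical_class]
    led = led.groupby(_KEY, as_index=False)["items"].sum()
    if led.empty:
        empty = pd.DataFrame(columns=["area_id", "year", "month", "items"])
        return empty, pd.DataFrame(columns=_KEY + ["items"])
    shares = _fallback_shares(shares, led[_KEY])
    merged = led.merge(shares, on=_KEY, how="left")
    unmatched = merged.loc[merged["share"].isna() & (merged["items"] > 0), _KEY + ["items"]]
    unallocated = unmatched.drop_duplicates(_KEY).reset_index(drop=True)
    ok = merged.dropna(subset=["share"]).copy()
    ok["items"] = ok["items"] * ok["share"]
    allocated = (
        ok.groupby(["area_id", "year", "month"], as_index=False)["items"].sum()
    )
    return allocated, unallocated


@dataclass
class AreaRateTable:
    """Per-area prescribing rates, items per person (50+) per year."""

    table: pd.DataFrame  # area_id, chemical_class, rate, missing flag


def annual_rate(
    allocated: pd.DataFrame,
    population: pd.DataFrame,
    n_years: float,
    chemical_class: str = "AChEI",
) -> pd.DataFrame:
    """Convert allocated monthly items to annual per-person (50+) rates.

    ``rate = total allocated items / (pop_50_plus * n_years)``. Areas
    with no allocated items get rate 0; areas with ``pop_50_plus == 0``
    get a flagged missing rate (NaN), never infinity. Allocated area ids
    absent from the population table raise an error listing offenders.
    """
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    pop = population.set_index("area_id")["pop_50_plus"]
    totals = allocated.groupby("area_id")["items"].sum()
    unknown = totals.index.difference(pop.index)
    if len(unknown) > 0:
        raise ValueError(
            f"allocated items for area ids not in population table: "
            f"{sorted(unknown)[:10]}"
        )
    items = totals.reindex(pop.index, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = items / (pop * n_years)
    out = pd.DataFrame(
        {
            "area_id": pop.index,
            "chemical_class": chemical_class,
            "rate": np.where(pop > 0, rate, np.nan),
            "missing": pop.to_numpy() == 0,
        }
    ).reset_index(drop=True)
    return out


def area_rates(
    ledger: pd.DataFrame,
    registration: pd.DataFrame,
    population: pd.DataFrame,
    n_years: float = 5.0,
    classes: tuple[str, ...] = CHEMICAL_CLASSES,
) -> pd.DataFrame:
    """End-to-end: ledger + registration -> per-area annual rates per class."""
    shares = registration_proportions(registration)
    frames = []
    for cls in classes:
        allocated, _ = allocate_items(ledger, shares, cls)
        frames.append(annual_rate(allocated, population, n_years, cls))
    return pd.concat(frames, ignore_index=True)
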