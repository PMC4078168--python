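"""Deer-browsing susceptibility index (DBSI).

For each species and year, DBSI is the fraction of the species' summed
percent cover found inside exclosures::

    DBSI = sum(C_e) / (sum(C_e) + sum(C_c))

where ``C_e`` and ``C_c`` are the species' percent covers in the exclosure
and control plots of that year.  DBSI = 1 means the species occurred only
inside exclosures (browse-susceptible), DBSI = 0 only outside; a
species-year with zero cover in both treatments is undefined (0/0) and is
excluded from the across-year mean rather than coerced to a value.

A rarity filter excludes species too sparse to score reliably: by default
a species must have positive cover in at least ``plot_threshold`` distinct
plots (either treatment) in each of at least ``year_threshold`` years.
Both thresholds are configurable because published descriptions of such
filters vary between "more than two plots" and "more than one exclosure"
readings.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .diversity import CoverPanel

logger = logging.getLogger(__name__)

__all__ = ["rarity_filter", "dbsi_per_year", "mean_dbsi"]


def rarity_filter(
    panel: CoverPanel,
    plot_threshold: int = 2,
    year_threshold: int = 2,
    treatments: Iterable[str] | None = None,
) -> set[str]:
    """Species with >= ``plot_threshold`` occupied plots in >= ``year_threshold`` years.

    A plot counts when the species has cover > 0 there; ``treatments``
    restricts which plots are counted (default: both).
    """
    cover = panel.cover
    if treatments is not None:
        treatments = set(treatments)
        keep_plots = [p for p in panel.plot_ids() if panel.treatment_of(p) in treatments]
        cover = cover[cover["plot_id"].isin(keep_plots)]
    occupied = cover[cover["cover"] > 0]
    plots_per_year = (
        occupied.groupby(["species", "year"])["plot_id"].nunique().reset_index()
    )
    good_years = plots_per_year[plots_per_year["plot_id"] >= plot_threshold]
    year_counts = good_years.groupby("species")["year"].nunique()
    return set(year_counts.index[year_counts >= year_threshold])


def dbsi_per_year(panel: CoverPanel, species: str, year: int) -> float:
    """DBSI of one species in one year; NaN when the species is absent
    from both treatments that year (the 0/0 case)."""
    sel = panel.cover[
        (panel.cover["year"] == int(year)) & (panel.cover["species"] == species)
    ]
    ex_plots = set(panel.plot_ids("exclosure"))
    c_e = float(sel.loc[sel["plot_id"].isin(ex_plots), "cover"].sum())
    c_c = float(sel.loc[~sel["plot_id"].isin(ex_plots), "cover"].sum())
    if c_e + c_c == 0:
        return float("nan")
    return c_e / (c_e + c_c)


def mean_dbsi(
    panel: CoverPanel,
    plot_threshold: int = 2,
    year_threshold: int = 2,
    treatments: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-species per-year DBSI plus the across-year mean.

    One row per species carrying the rarity-filter flag, each year's DBSI
    (NaN where undefined), the unweighted mean over defined years and the
    number of defined years.  Species with no defined year are omitted
    (logged); rows are sorted ascending by mean DBSI, least to most
    susceptible.
    """
    included = rarity_filter(panel, plot_threshold, year_threshold, treatments)
    years = panel.years
    rows = []
    for sp in panel.species:
        per_year = {yr: dbsi_per_year(panel, sp, yr) for yr in years}
        defined = [v for v in per_year.values() if np.isfinite(v)]
        if not defined:
            logger.info("species %r has no defined DBSI year; omitted", sp)
            continue
        row = {"species": sp, "included": sp in included}
        row.update({f"dbsi_{yr}": per_year[yr] for yr in years})
        row["mean_dbsi"] = float(np.mean(defined))
        row["n_years_defined"] = len(defined)
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values(
        ["mean_dbsi", "species"], kind="mergesort"
    ).reset_index(drop=True)
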