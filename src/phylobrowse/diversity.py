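"""Line-intercept cover, species richness and Shannon–Wiener diversity.

The sampling design mirrored here is the classic paired-exclosure survey:
each site holds one fenced (exclosure) plot and one adjacent unfenced
(control) plot, each sampled by three 5 m (500 cm) line-intercept
transects.  Percent cover of species *i* in a plot is
``100 * (sum of intercepted centimetres) / 1500``; because several species
can overhang the same tape segment at different heights, the per-plot total
over species may exceed 100 %.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

logger = logging.getLogger(__name__)

TREATMENTS = ("exclosure", "control")

__all__ = [
    "TREATMENTS",
    "CoverError",
    "TransectRecord",
    "CoverPanel",
    "compute_cover",
    "pooled_cover",
    "species_richness",
    "shannon_index",
    "read_transect_csv",
    "write_transect_csv",
]


class CoverError(ValueError):
    """Raised for invalid transect records or cover tables."""


@dataclass(frozen=True)
class TransectRecord:
    """One intercepted stretch of tape: a species occurrence on a transect."""

    plot_id: str
    site_id: str
    treatment: str
    year: int
    transect_id: int
    species: str
    intercept_cm: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise CoverError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if int(self.intercept_cm) != self.intercept_cm or self.intercept_cm < 1:
            raise CoverError(
                f"intercept_cm must be a positive integer (cm), got {self.intercept_cm!r}"
            )


def compute_cover(
    records: Sequence[TransectRecord],
    transect_total_cm: int = 1500,
    transect_cm: int = 500,
) -> dict[str, float]:
    """Percent cover per species for one plot in one year.

    ``cover_i = 100 * (sum of intercepted cm over all occurrences and
    transects) / transect_total_cm``.  Multiple occurrences of a species on
    one transect are summed; a species' total on a single transect may not
    exceed the transect length.
    """
    if not records:
        return {}
    keys = {(r.plot_id, r.year) for r in records}
    if len(keys) > 1:
        raise CoverError(f"records span multiple plot/year combinations: {sorted(keys)}")
    per_transect: dict[tuple[int, str], int] = {}
    totals: dict[str, int] = {}
    for r in records:
        per_transect[(r.transect_id, r.species)] = (
            per_transect.get((r.transect_id, r.species), 0) + r.intercept_cm
        )
        totals[r.species] = totals.get(r.species, 0) + r.intercept_cm
    for (tid, sp), s in per_transect.items():
        if s > transect_cm:
            raise CoverError(
                f"species {sp!r} covers {s} cm on transect {tid}, "
                f"exceeding the {transect_cm} cm transect length"
            )
    return {sp: 100.0 * s / transect_total_cm for sp, s in sorted(totals.items())}


def species_richness(cover: Mapping[str, float] | pd.Series) -> int:
    """Number of species with positive cover."""
    values = cover.values if isinstance(cover, pd.Series) else cover.values()
    return int(sum(1 for v in values if v > 0))


def shannon_index(cover: Mapping[str, float] | pd.Series) -> float:
    """Shannon–Wiener diversity H' in nats, with cover as abundance.

    ``p_i = cover_i / sum(cover)`` over species with positive cover;
    ``H' = -sum p_i ln p_i``.  Undefined (raises) when all covers are zero.
    """
    values = np.asarray(
        list(cover.values) if isinstance(cover, pd.Series) else list(cover.values()),
        dtype=float,
    )
    values = values[values > 0]
    if values.size == 0:
        raise CoverError("Shannon index undefined: no species with positive cover")
    return float(_shannon_entropy(values))  # normalises and uses natural log


class CoverPanel:
    """Plot x species x year percent cover with plot metadata.

    Parameters
    ----------
    cover : DataFrame with columns ``plot_id, year, species, cover``
        Long-format percent cover (0-100 per species); absent combinations
        mean zero cover.  Duplicate (plot, year, species) rows are summed.
    plots : DataFrame with columns ``plot_id, site_id, treatment``
        One row per plot; ``treatment`` in ``{"exclosure", "control"}``.
        Paired plots share a ``site_id``.
    """

    def __init__(self, cover: pd.DataFrame, plots: pd.DataFrame) -> None:
        cover = pd.DataFrame(cover).copy()
        plots = pd.DataFrame(plots).copy()
        for col in ("plot_id", "year", "species", "cover"):
            if col not in cover.columns:
                raise CoverError(f"cover table missing column {col!r}")
        for col in ("plot_id", "site_id", "treatment"):
            if col not in plots.columns:
                raise CoverError(f"plot table missing column {col!r}")
        bad = set(plots["treatment"]) - set(TREATMENTS)
        if bad:
            raise CoverError(f"unknown treatments: {sorted(bad)}")
        if plots["plot_id"].duplicated().any():
            raise CoverError("duplicate plot_id in plot metadata")
        unknown = set(cover["plot_id"]) - set(plots["plot_id"])
        if unknown:
            raise CoverError(f"cover rows reference unknown plots: {sorted(unknown)}")
        cover["year"] = cover["year"].astype(int)
        cover["cover"] = cover["cover"].astype(float)
        cover = (
            cover.groupby(["plot_id", "year", "species"], as_index=False)["cover"].sum()
        )
        if (cover["cover"] < 0).any():
            raise CoverError("negative cover value")
        if (cover["cover"] > 100 + 1e-9).any():
            offender = cover.loc[cover["cover"] > 100 + 1e-9].iloc[0]
            raise CoverError(
                f"per-species cover exceeds 100 %: {offender['species']!r} in plot "
                f"{offender['plot_id']!r}, year {int(offender['year'])}"
            )
        self.cover = cover
        self.plots = plots.set_index("plot_id")

    # ------------------------------------------------------------------ #

    @property
    def years(self) -> list[int]:
        return sorted(self.cover["year"].unique().tolist())

    @property
    def species(self) -> list[str]:
        return sorted(self.cover["species"].unique().tolist())

    def plot_ids(self, treatment: str | None = None) -> list[str]:
        if treatment is None:
            return sorted(self.plots.index.tolist())
        if treatment not in TREATMENTS:
            raise CoverError(f"unknown treatment {treatment!r}")
        return sorted(self.plots.index[self.plots["treatment"] == treatment].tolist())

    def treatment_of(self, plot_id: str) -> str:
        return str(self.plots.loc[plot_id, "treatment"])

    def site_of(self, plot_id: str) -> str:
        return str(self.plots.loc[plot_id, "site_id"])

    def plot_cover(self, plot_id: str, year: int) -> pd.Series:
        """Percent cover per recorded species in one plot-year."""
        sel = self.cover[(self.cover["plot_id"] == plot_id) & (self.cover["year"] == int(year))]
        return sel.set_index("species")["cover"].sort_index()

    def pooled_cover(
        self, treatment: str, year: int, expected_n_plots: int | None = None
    ) -> pd.Series:
        """Treatment-level percent cover: mean over the treatment's plots.

        Summing intercepted centimetres across the four plots and dividing
        by the pooled tape length (6000 cm) is identical to averaging the
        four per-plot covers, which is what is computed here.
        """
        plots = self.plot_ids(treatment)
        if not plots:
            raise CoverError(f"no plots with treatment {treatment!r}")
        if expected_n_plots is not None and len(plots) != expected_n_plots:
            raise CoverError(
                f"treatment {treatment!r} has plots {plots}, expected {expected_n_plots}"
            )
        sel = self.cover[(self.cover["plot_id"].isin(plots)) & (self.cover["year"] == int(year))]
        pooled = sel.groupby("species")["cover"].sum() / len(plots)
        return pooled.reindex(self.species, fill_value=0.0).sort_index()

    def species_present(self, treatment: str, year: int) -> list[str]:
        pooled = self.pooled_cover(treatment, year)
        return sorted(pooled.index[pooled > 0].tolist())

    def with_swapped_treatments(self) -> "CoverPanel":
        """A copy with exclosure and control labels exchanged."""
        plots = self.plots.reset_index().copy()
        plots["treatment"] = plots["treatment"].map(
            {"exclosure": "control", "control": "exclosure"}
        )
        return CoverPanel(self.cover.copy(), plots)

    # ------------------------------------------------------------------ #
    # construction and I/O

    @classmethod
    def from_transect_records(
        cls,
        records: Sequence[TransectRecord],
        transect_total_cm: int = 1500,
        transect_cm: int = 500,
    ) -> "CoverPanel":
        if not records:
            raise CoverError("no transect records")
        groups: dict[tuple[str, int], list[TransectRecord]] = {}
        meta: dict[str, tuple[str, str]] = {}
        for r in records:
            groups.setdefault((r.plot_id, r.year), []).append(r)
            prev = meta.get(r.plot_id)
            if prev is not None and prev != (r.site_id, r.treatment):
                raise CoverError(f"inconsistent metadata for plot {r.plot_id!r}")
            meta[r.plot_id] = (r.site_id, r.treatment)
        rows = []
        for (plot_id, year), recs in sorted(groups.items()):
            for sp, cov in compute_cover(recs, transect_total_cm, transect_cm).items():
                rows.append(
                    {"plot_id": plot_id, "year": year, "species": sp, "cover": cov}
                )
        plots = pd.DataFrame(
            [
                {"plot_id": p, "site_id": s, "treatment": t}
                for p, (s, t) in sorted(meta.items())
            ]
        )
        return cls(pd.DataFrame(rows), plots)

    def cover_matrix(self, year: int) -> pd.DataFrame:
        """Wide plot x species percent-cover matrix for one year."""
        sel = self.cover[self.cover["year"] == int(year)]
        mat = sel.pivot_table(
            index="plot_id", columns="species", values="cover", fill_value=0.0
        )
        return mat.reindex(index=self.plot_ids(), columns=self.species, fill_value=0.0)

    def to_csv(self, path) -> None:
        out = self.cover.merge(
            self.plots.reset_index(), on="plot_id", how="left"
        )[["plot_id", "site_id", "treatment", "year", "species", "cover"]]
        out.sort_values(["plot_id", "year", "species"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CoverPanel":
        df = pd.read_csv(path)
        for col in ("plot_id", "site_id", "treatment", "year", "species", "cover"):
            if col not in df.columns:
                raise CoverError(f"cover CSV missing column {col!r}")
        plots = df[["plot_id", "site_id", "treatment"]].drop_duplicates()
        return cls(df[["plot_id", "year", "species", "cover"]], plots)


def pooled_cover(panel: CoverPanel, treatment: str, year: int, **kwargs) -> pd.Series:
    """Functional alias for :meth:`CoverPanel.pooled_cover`."""
    return panel.pooled_cover(treatment, year, **kwargs)


_TRANSECT_COLUMNS = [
    "plot_id", "site_id", "treatment", "year", "transect_id", "species", "intercept_cm",
]


def read_transect_csv(path) -> list[TransectRecord]:
    df = pd.read_csv(path)
    for col in _TRANSECT_COLUMNS:
        if col not in df.columns:
            raise CoverError(f"transect CSV missing column {col!r}")
    return [
        TransectRecord(
            plot_id=str(r.plot_id),
            site_id=str(r.site_id),
            treatment=str(r.treatment),
            year=int(r.year),
            transect_id=int(r.transect_id),
            species=str(r.species),
            intercept_cm=int(r.intercept_cm),
        )
        for r in df.itertuples(index=False)
    ]


def write_transect_csv(records: Sequence[TransectRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records], columns=_TRANSECT_COLUMNS).to_csv(
        path, index=False
    )
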