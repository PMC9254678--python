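"""Assemblage-level metabolic demand from visual-census data.

Each census record is a species x length count on a belt transect of known
area.  Individual SMR (grid median) and AMRfield (grid mean) come from the
per-cm species estimate grid; transect totals are summed and divided by
transect area (g O2 m-2 d-1), and a site is summarized as the mean +/- SD
of its transect densities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._exceptions import InputError

__all__ = ["individual_rates", "site_totals", "relative_abundance"]

_CENSUS_COLS = ("site", "transect", "area_m2", "species_id", "total_length_cm", "count")


def _check_census(census: pd.DataFrame):
    missing = set(_CENSUS_COLS) - set(census.columns)
    if missing:
        raise InputError(f"census table missing columns {sorted(missing)}")
    if len(census) == 0:
        raise InputError("census table is empty")
    if (census["area_m2"] <= 0).any():
        raise InputError("transect areas must be positive")
    if (census["count"] < 1).any():
        raise InputError("census counts must be >= 1")


def _grid_lookup(estimates: pd.DataFrame):
    return {
        (r.species_id, int(r.length_cm)): (r.smr_med, r.amr_field_mean)
        for r in estimates.itertuples(index=False)
    }


def individual_rates(
    record, estimates: pd.DataFrame
) -> tuple[float, float]:
    """(SMR, AMRfield) in g O2 d-1 for one census record's fish.

    ``record`` is a mapping/row with ``species_id`` and ``total_length_cm``;
    the length is rounded half-up to the nearest cm of the estimate grid.
    """
    sp = record["species_id"]
    length = int(np.floor(float(record["total_length_cm"]) + 0.5))
    sub = estimates[estimates["species_id"] == sp]
    if sub.empty:
        raise InputError(f"species {sp!r} absent from the estimate grid ({record})")
    row = sub[sub["length_cm"] == length]
    if row.empty:
        raise InputError(
            f"length {length} cm outside the {sp!r} estimate grid ({record})"
        )
    return float(row["smr_med"].iloc[0]), float(row["amr_field_mean"].iloc[0])


def site_totals(census: pd.DataFrame, estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-site areal SMR and AMRfield: transect densities sum(count x
    rate)/area, then mean +/- SD across the site's transects.

    Returns one row per site with ``smr_total``/``amr_total`` (means),
    their SDs, the ``amr_smr_ratio`` of the site means, and the transect
    count.
    """
    _check_census(census)
    grid = _grid_lookup(estimates)

    def rates(row):
        length = int(np.floor(float(row["total_length_cm"]) + 0.5))
        key = (row["species_id"], length)
        if key not in grid:
            raise InputError(
                f"species/length {key} absent from the estimate grid "
                f"(site {row['site']}, transect {row['transect']})"
            )
        return grid[key]

    work = census.copy()
    pairs = work.apply(rates, axis=1, result_type="expand")
    work["smr_sum"] = pairs[0] * work["count"]
    work["amr_sum"] = pairs[1] * work["count"]
    per_transect = (
        work.groupby(["site", "transect"], sort=True)
        .agg(
            smr=("smr_sum", "sum"),
            amr=("amr_sum", "sum"),
            area=("area_m2", "first"),
        )
        .reset_index()
    )
    per_transect["smr_density"] = per_transect["smr"] / per_transect["area"]
    per_transect["amr_density"] = per_transect["amr"] / per_transect["area"]
    out = (
        per_transect.groupby("site", sort=True)
        .agg(
            smr_total=("smr_density", "mean"),
            smr_total_sd=("smr_density", lambda s: float(np.std(s, ddof=0))),
            amr_total=("amr_density", "mean"),
            amr_total_sd=("amr_density", lambda s: float(np.std(s, ddof=0))),
            n_transects=("transect", "nunique"),
        )
        .reset_index()
    )
    out["amr_smr_ratio"] = out["amr_total"] / out["smr_total"]
    return out


def relative_abundance(census: pd.DataFrame) -> pd.DataFrame:
    """Per-site species shares of total counts (summed across transects);
    shares sum to 1 within each site."""
    _check_census(census)
    counts = (
        census.groupby(["site", "species_id"], sort=True)["count"].sum().reset_index()
    )
    totals = counts.groupby("site")["count"].transform("sum")
    counts["share"] = counts["count"] / totals
    return counts
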