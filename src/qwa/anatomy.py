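"""Tracheid-level anatomy: trait formulas, sectorization, earlywood/latewood
classification and annual aggregation.

The cell table (one row per tracheid, ROXAS-style CSV dialect) is turned
into (i) per tree x year x ring-part {EW, LW} trait records and (ii)
100-sector intra-annual profiles.  Traits follow the standard quantitative
wood anatomy definitions:

* mean hydraulic diameter  DH = sum(d^5) / sum(d^4)  over conduit
  diameters d (equivalent-circle diameter of the lumen), the conduit size
  weighted by its contribution to hydraulic conductance;
* cell wall thickness      CWT = (radial + tangential wall) / 2;
* anatomical density       AD  = wall area / (wall area + lumen area).

Earlywood/latewood is split by Mork's index m = 4 * (single radial wall) /
(radial lumen diameter), latewood iff m >= 1, applied per tangential sector
by majority vote of its cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "cell_hydraulic_diameter",
    "mean_hydraulic_diameter",
    "cell_cwt",
    "anatomical_density",
    "morks_index",
    "morks_classify",
    "assign_sectors",
    "filter_outliers",
    "filter_ring_outliers",
    "classify_cells",
    "aggregate_annual",
    "build_sector_profiles",
    "FilterLog",
]

TRAITS = ("DH", "CWT", "AD")


def cell_hydraulic_diameter(lumen_area):
    """Equivalent-circle diameter d = 2 sqrt(A / pi) of a lumen area (um^2)."""
    lumen_area = np.asarray(lumen_area, dtype=float)
    if np.any(lumen_area <= 0):
        raise ValueError("lumen area must be positive")
    return 2.0 * np.sqrt(lumen_area / np.pi)


def mean_hydraulic_diameter(diameters) -> float:
    """Hydraulically weighted mean conduit diameter, sum(d^5)/sum(d^4)."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        return float("nan")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    return float(np.sum(d**5) / np.sum(d**4))


def cell_cwt(cwt_rad, cwt_tan):
    """Mean of radial and tangential single-wall thickness (um)."""
    cwt_rad = np.asarray(cwt_rad, dtype=float)
    cwt_tan = np.asarray(cwt_tan, dtype=float)
    if np.any(cwt_rad < 0) or np.any(cwt_tan < 0):
        raise ValueError("wall thickness must be >= 0")
    return (cwt_rad + cwt_tan) / 2.0


def anatomical_density(cwa, lumen_area):
    """Wall-area fraction of the cell, cwa / (cwa + lumen), in [0, 1]."""
    cwa = np.asarray(cwa, dtype=float)
    lumen_area = np.asarray(lumen_area, dtype=float)
    if np.any(cwa < 0) or np.any(lumen_area < 0):
        raise ValueError("areas must be >= 0")
    total = cwa + lumen_area
    if np.any(total == 0):
        raise ValueError("cell with zero wall and zero lumen area")
    return cwa / total


def morks_index(cwt_rad, lumen_diam_rad):
    """Mork's index m = 4 * cwt_rad / lumen_diam_rad (== 2 * double wall / lumen)."""
    cwt_rad = np.asarray(cwt_rad, dtype=float)
    lumen_diam_rad = np.asarray(lumen_diam_rad, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(lumen_diam_rad > 0, 4.0 * cwt_rad / np.where(lumen_diam_rad > 0, lumen_diam_rad, 1.0), np.inf)


def morks_classify(cwt_rad, lumen_diam_rad):
    """Latewood iff Mork's index >= 1 (wall-only cells classify latewood)."""
    m = morks_index(cwt_rad, lumen_diam_rad)
    return np.where(m >= 1.0, "LW", "EW")


def assign_sectors(rel_pos, n_sectors: int = 100):
    """Tangential sector 1..n from the relative radial position in [0, 1)."""
    rel_pos = np.asarray(rel_pos, dtype=float)
    if np.any((rel_pos < 0) | (rel_pos >= 1)):
        raise ValueError("rel_pos must lie in [0, 1)")
    return np.floor(rel_pos * n_sectors).astype(int) + 1


@dataclass
class FilterLog:
    n_in: int
    n_removed: int
    mode: str
    warnings: list[str]


def filter_outliers(values, mode: str = "tukey") -> tuple[np.ndarray, FilterLog]:
    """Quartile-based outlier removal within one ring part.

    ``tukey`` keeps x in [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (quartiles by linear
    interpolation, type 7).  ``literal`` implements the rule exactly
    as sometimes stated in field protocols -- remove x > 1.5*Q3 or
    x < 1.5*Q1 -- which is only coherent when 1.5*Q1 lies below the median;
    otherwise it falls back to Tukey fences with a warning.  Fewer than 4
    values pass through unfiltered.
    """
    x = np.asarray(values, dtype=float)
    notes: list[str] = []
    if x.size < 4:
        notes.append("fewer than 4 values: passed through unfiltered")
        return x, FilterLog(x.size, 0, mode, notes)
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    if mode == "tukey":
        iqr = q3 - q1
        keep = (x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)
    elif mode == "literal":
        if 1.5 * q1 < q2:
            keep = (x >= 1.5 * q1) & (x <= 1.5 * q3)
        else:
            notes.append(
                "literal lower bound 1.5*Q1 above the median; fell back to Tukey fences"
            )
            iqr = q3 - q1
            keep = (x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)
    else:
        raise ValueError(f"unknown outlier mode {mode!r}")
    kept = x[keep]
    return kept, FilterLog(x.size, int(x.size - kept.size), mode, notes)


def _prepare(cells: pd.DataFrame, n_sectors: int = 100) -> pd.DataFrame:
    """Attach sector, per-cell traits and radial lumen diameter columns."""
    out = cells.copy()
    bad = (out["rel_pos"] < 0) | (out["rel_pos"] >= 1) | (out["lumen_area_um2"] <= 0)
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} cells with invalid position or lumen area")
        out = out[~bad].copy()
    out["sector"] = assign_sectors(out["rel_pos"].to_numpy(), n_sectors)
    out["d_um"] = cell_hydraulic_diameter(out["lumen_area_um2"].to_numpy())
    if "lumen_diam_rad_um" not in out.columns:
        # fall back on the equivalent-circle diameter for Mork's index
        out["lumen_diam_rad_um"] = out["d_um"]
    out["cwt_um"] = cell_cwt(out["cwt_rad_um"].to_numpy(), out["cwt_tan_um"].to_numpy())
    out["ad"] = anatomical_density(out["cwa_um2"].to_numpy(), out["lumen_area_um2"].to_numpy())
    return out


def classify_cells(cells: pd.DataFrame, n_sectors: int = 100, per_cell: bool = False) -> pd.DataFrame:
    """Sectorize and classify cells into EW/LW.

    Default is the sector-level rule: each sector takes the majority class
    of its cells (ties -> LW, consistent with the >= boundary of Mork's
    index).  ``per_cell=True`` keeps individual cell classes instead.
    """
    out = _prepare(cells, n_sectors)
    is_lw = morks_classify(out["cwt_rad_um"].to_numpy(), out["lumen_diam_rad_um"].to_numpy()) == "LW"
    if per_cell:
        out["part"] = np.where(is_lw, "LW", "EW")
        return out
    out["_is_lw"] = is_lw
    frac = out.groupby(["tree_id", "year", "sector"])["_is_lw"].transform("mean")
    out["part"] = np.where(frac >= 0.5, "LW", "EW")
    return out.drop(columns="_is_lw")


def filter_ring_outliers(
    cells: pd.DataFrame, value_col: str = "lumen_area_um2", mode: str = "tukey"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the quartile outlier rule separately within the EW and the LW
    cells of every ring; returns (kept cells, per-ring removal log)."""
    if mode not in ("tukey", "literal"):
        raise ValueError(f"unknown outlier mode {mode!r}")
    g = cells.groupby(["tree_id", "year", "part"])[value_col]
    q1 = g.transform("quantile", 0.25)
    q2 = g.transform("quantile", 0.50)
    q3 = g.transform("quantile", 0.75)
    count = g.transform("size")
    x = cells[value_col]
    iqr = q3 - q1
    keep_tukey = (x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)
    if mode == "literal":
        literal_ok = 1.5 * q1 < q2
        keep = np.where(literal_ok, (x >= 1.5 * q1) & (x <= 1.5 * q3), keep_tukey)
    else:
        keep = keep_tukey
    keep = pd.Series(keep, index=cells.index) | (count < 4)
    kept = cells[keep].reset_index(drop=True)
    log = (
        pd.DataFrame(
            {
                "tree_id": cells["tree_id"],
                "year": cells["year"],
                "part": cells["part"],
                "removed": ~keep,
            }
        )
        .groupby(["tree_id", "year", "part"], as_index=False)
        .agg(n_in=("removed", "size"), n_removed=("removed", "sum"))
    )
    return kept, log


def aggregate_annual(cells: pd.DataFrame, ring_widths: pd.DataFrame) -> pd.DataFrame:
    """Per tree x year x part records: median CWT and AD, DH over the part's
    cells, and part width as the part's sector fraction of the ring width.

    ``cells`` must already carry ``sector`` and ``part`` columns (see
    :func:`classify_cells`).  EW width + LW width equals ring width exactly,
    the split being the fraction of classified sectors in each part.
    """
    recs: list[dict] = []
    rw = ring_widths.set_index(["tree_id", "year"])["ring_width_mm"]
    for (tree, year), ring in cells.groupby(["tree_id", "year"], sort=True):
        sector_part = ring.drop_duplicates("sector").set_index("sector")["part"]
        n_sec = len(sector_part)
        width = float(rw.get((tree, year), np.nan))
        for part in ("EW", "LW"):
            sub = ring[ring["part"] == part]
            frac = float((sector_part == part).sum()) / n_sec if n_sec else 0.0
            if len(sub) == 0:
                recs.append({"tree_id": tree, "year": year, "part": part,
                             "dh": np.nan, "cwt": np.nan, "ad": np.nan,
                             "width_mm": width * frac, "n_cells": 0})
                continue
            recs.append({
                "tree_id": tree, "year": year, "part": part,
                "dh": mean_hydraulic_diameter(sub["d_um"].to_numpy()),
                "cwt": float(sub["cwt_um"].median()),
                "ad": float(sub["ad"].median()),
                "width_mm": width * frac,
                "n_cells": int(len(sub)),
            })
    out = pd.DataFrame(recs)
    if "group" in cells.columns:
        groups = cells.drop_duplicates("tree_id").set_index("tree_id")["group"]
        out["group"] = out["tree_id"].map(groups)
    return out


def build_sector_profiles(cells: pd.DataFrame, n_sectors: int = 100) -> pd.DataFrame:
    """Per tree x year x trait 100-sector median profiles (long format:
    tree_id, year, trait, sector, value; empty sectors are absent and are
    treated as missing downstream)."""
    needed = {"sector", "d_um", "cwt_um", "ad"}
    if not needed <= set(cells.columns):
        cells = _prepare(cells, n_sectors)
    med = (
        cells.groupby(["tree_id", "year", "sector"])[["d_um", "cwt_um", "ad"]]
        .median()
        .reset_index()
        .rename(columns={"d_um": "DH", "cwt_um": "CWT", "ad": "AD"})
    )
    long = med.melt(
        id_vars=["tree_id", "year", "sector"],
        value_vars=["DH", "CWT", "AD"],
        var_name="trait",
        value_name="value",
    )
    if "group" in cells.columns:
        groups = cells.drop_duplicates("tree_id").set_index("tree_id")["group"]
        long["group"] = long["tree_id"].map(groups)
    return long


def profiles_to_wide(profiles: pd.DataFrame, n_sectors: int = 100) -> pd.DataFrame:
    """Pivot long sector profiles to one row per tree x year x trait with
    sector_001..sector_100 columns (missing sectors -> NaN)."""
    wide = profiles.pivot_table(
        index=["tree_id", "year", "trait"], columns="sector", values="value"
    )
    wide = wide.reindex(columns=range(1, n_sectors + 1))
    wide.columns = [f"sector_{c:03d}" for c in wide.columns]
    return wide.reset_index()
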