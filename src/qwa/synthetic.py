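"""Synthetic study generator: cell tables, ring widths, stands and monthly climate.

Emulates the study design of a two-site Scots pine admixture experiment:
nine trees in pure and nine in mixed forest per site, ~60 years of monthly
climate with plantable drought events, and tracheid-level anatomy with an
earlywood->latewood gradient plus configurable, group-specific drought
effects on anatomical density.  Every downstream stage of the pipeline can
therefore be exercised against known ground truth.

All randomness flows from a single root seed through named substreams
(climate, trees), so identical configurations produce byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClimateParams",
    "DroughtEvent",
    "EffectSpec",
    "OntogeneticSpec",
    "SyntheticConfig",
    "StandPlot",
    "STUDY_STANDS",
    "stand_table",
    "sdi_group_means",
    "generate_climate",
    "generate_cells",
    "generate_dataset",
    "quadratic_mean_dbh",
    "reineke_sdi",
]

# Monthly normals emulating a warm-summer humid continental site
# (mean annual temperature ~8.3 degC, annual precipitation 565 mm).
_TEMP_NORMALS = (-2.2, -1.2, 2.8, 8.3, 13.8, 16.8, 18.8, 18.1, 13.3, 8.3, 3.3, -0.7)
_PREC_NORMALS = (30.0, 28.0, 32.0, 38.0, 55.0, 70.0, 85.0, 65.0, 45.0, 40.0, 40.0, 37.0)


@dataclass(frozen=True)
class ClimateParams:
    """Monthly climate normals and interannual variability.

    temp_sd_c is the interannual standard deviation of a monthly mean
    temperature (degC); prec_cv is the coefficient of variation of monthly
    precipitation (multiplicative lognormal noise, so totals stay >= 0).
    warming_trend_c_per_decade adds a linear trend to every month.
    """

    temp_normals_c: tuple[float, ...] = _TEMP_NORMALS
    prec_normals_mm: tuple[float, ...] = _PREC_NORMALS
    temp_sd_c: float = 1.5
    prec_cv: float = 0.35
    warming_trend_c_per_decade: float = 0.3
    latitude: float = 51.8

    def __post_init__(self) -> None:
        if len(self.temp_normals_c) != 12 or len(self.prec_normals_mm) != 12:
            raise ValueError("normals must have 12 monthly values")
        if any(p < 0 for p in self.prec_normals_mm):
            raise ValueError("precipitation normals must be >= 0")


@dataclass(frozen=True)
class DroughtEvent:
    """A planted drought: listed months of one year receive a negative
    water-balance anomaly of `anomaly_sd` interannual standard deviations
    (precipitation reduced, temperature raised)."""

    year: int
    months: tuple[int, ...]
    anomaly_sd: float = 2.5

    def __post_init__(self) -> None:
        if not self.months or any(m < 1 or m > 12 for m in self.months):
            raise ValueError("months must be within 1..12")
        if self.anomaly_sd <= 0:
            raise ValueError("anomaly_sd must be positive (it is a deficit magnitude)")


@dataclass(frozen=True)
class EffectSpec:
    """Per-group multipliers on expected earlywood anatomical density in a
    drought year (`during`) and in the following year (`after`)."""

    during: dict[str, float] = field(default_factory=lambda: {"pure": 1.0, "mixed": 1.0})
    after: dict[str, float] = field(default_factory=lambda: {"pure": 1.0, "mixed": 1.0})

    def __post_init__(self) -> None:
        for phase in (self.during, self.after):
            for group, mult in phase.items():
                if mult <= 0:
                    raise ValueError(f"effect multiplier for {group!r} must be > 0, got {mult}")


@dataclass(frozen=True)
class OntogeneticSpec:
    """Age trends: negative-exponential ring width (mm) and a mild juvenile
    enlargement of earlywood lumen diameter."""

    rw_juvenile_mm: float = 2.8
    rw_mature_mm: float = 1.2
    rw_decay_years: float = 25.0
    lumen_juvenile_frac: float = 0.85  # fraction of adult EW diameter in year 1
    lumen_maturation_years: float = 15.0


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_years: int = 62
    start_year: int = 1958
    trees_per_group: int = 9
    cells_per_ring: int = 300
    climate_params: ClimateParams = field(default_factory=ClimateParams)
    drought_spec: tuple[DroughtEvent, ...] = ()
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    ontogenetic_spec: OntogeneticSpec = field(default_factory=OntogeneticSpec)
    # anatomy gradient parameters (um): earlywood/latewood expected lumen
    # diameter and single-wall thickness, logistic transition location/rate
    lumen_diam_ew_um: float = 26.0
    lumen_diam_lw_um: float = 12.0
    cwt_ew_um: float = 3.2
    cwt_lw_um: float = 5.4
    transition_center: float = 0.65
    transition_rate: float = 12.0
    # noise (lognormal sigma)
    sigma_lumen: float = 0.18
    sigma_cwt: float = 0.10
    sigma_tree: float = 0.05
    sigma_ring_width: float = 0.15
    # climate coupling of ring width and earlywood lumen (per sd of the
    # Apr-Aug moisture proxy); set to 0 for a climate-free null generator
    rw_climate_beta: float = 0.25
    lumen_climate_beta: float = 0.05

    def __post_init__(self) -> None:
        if self.n_years <= 0 or self.trees_per_group <= 0 or self.cells_per_ring <= 0:
            raise ValueError("counts must be positive")

    @property
    def years(self) -> range:
        return range(self.start_year, self.start_year + self.n_years)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent RNG substreams derived from one root seed."""
    root = np.random.SeedSequence(seed)
    climate_ss, trees_ss = root.spawn(2)
    return {
        "climate": np.random.default_rng(climate_ss),
        "trees": np.random.default_rng(trees_ss),
    }


# ---------------------------------------------------------------------------
# climate


def generate_climate(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate a monthly climate table (year, month, tmean_c, prec_mm).

    Temperature: normals + linear warming trend + Gaussian interannual
    noise.  Precipitation: normals times mean-one lognormal noise.  Planted
    droughts subtract ``anomaly_sd`` precipitation standard deviations
    (clipped at zero) and add a proportional warm anomaly in the listed
    months.
    """
    if config.n_years < 35:
        raise ValueError(
            "n_years must be >= 35: the 30-year spline cutoff and the SPEI "
            "calibration both need a multi-decadal record"
        )
    cp = config.climate_params
    rng = _substreams(config.seed)["climate"]
    years = np.repeat(np.fromiter(config.years, int), 12)
    months = np.tile(np.arange(1, 13), config.n_years)
    t_norm = np.asarray(cp.temp_normals_c)[months - 1]
    p_norm = np.asarray(cp.prec_normals_mm)[months - 1]

    trend = cp.warming_trend_c_per_decade * (years - config.start_year) / 10.0
    tmean = t_norm + trend + cp.temp_sd_c * rng.standard_normal(years.size)
    # mean-one lognormal multiplier, sd ~ prec_cv
    z = rng.standard_normal(years.size)
    prec = p_norm * np.exp(cp.prec_cv * z - 0.5 * cp.prec_cv**2)

    for event in config.drought_spec:
        for m in event.months:
            sel = (years == event.year) & (months == m)
            if not sel.any():
                raise ValueError(f"drought year {event.year} outside the simulated record")
            prec_sd = cp.prec_cv * p_norm[sel]
            prec[sel] = np.maximum(prec[sel] - event.anomaly_sd * prec_sd, 0.0)
            tmean[sel] = tmean[sel] + 0.6 * event.anomaly_sd * cp.temp_sd_c

    return pd.DataFrame(
        {"year": years, "month": months, "tmean_c": tmean, "prec_mm": np.maximum(prec, 0.0)}
    )


def _moisture_z(config: SyntheticConfig, climate: pd.DataFrame) -> pd.Series:
    """Standardized Apr-Aug moisture proxy per year: precipitation anomaly
    minus half the temperature anomaly (z-scores over the record)."""
    season = climate[climate["month"].between(4, 8)]
    p = season.groupby("year")["prec_mm"].sum()
    t = season.groupby("year")["tmean_c"].mean()
    zp = (p - p.mean()) / p.std(ddof=1) if p.std(ddof=1) > 0 else p * 0.0
    zt = (t - t.mean()) / t.std(ddof=1) if t.std(ddof=1) > 0 else t * 0.0
    return zp - 0.5 * zt


# ---------------------------------------------------------------------------
# cells


def _annulus_wall_area(d: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Wall area of an annulus of lumen diameter d and wall thickness t."""
    return np.pi * (d * t + t * t)


def _cwt_from_wall_area(d: np.ndarray, wall_area: np.ndarray) -> np.ndarray:
    """Invert the annulus model for the wall thickness giving `wall_area`."""
    return 0.5 * (-d + np.sqrt(d * d + 4.0 * wall_area / np.pi))


def generate_cells(
    config: SyntheticConfig, climate: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate tracheid tables and ring widths for both forest-type groups.

    Per ring, ``cells_per_ring`` cells are placed at jittered relative
    positions in [0, 1).  Expected lumen diameter decreases and expected
    wall thickness increases along the ring following a logistic
    earlywood->latewood transition; lognormal cell-to-cell noise is applied
    on top.  In drought years and the year after, the expected earlywood
    anatomical density is multiplied by the group's effect multiplier (wall
    thickness is back-solved from the scaled wall area, so the multiplier
    acts on AD exactly, capped at 0.95).
    """
    have_years = set(climate["year"])
    missing = [y for y in config.years if y not in have_years]
    if missing:
        raise ValueError(f"climate table does not cover simulated years {missing[:5]}")

    on = config.ontogenetic_spec
    rng = _substreams(config.seed)["trees"]
    moisture = _moisture_z(config, climate)
    drought_years = {e.year for e in config.drought_spec}
    after_years = {e.year + 1 for e in config.drought_spec}

    years = np.fromiter(config.years, int)
    ny, nc = config.n_years, config.cells_per_ring
    age = np.arange(1, ny + 1, dtype=float)

    cell_frames: list[pd.DataFrame] = []
    ring_frames: list[pd.DataFrame] = []
    for group in ("pure", "mixed"):
        for i in range(config.trees_per_group):
            tree_id = f"{'PU' if group == 'pure' else 'MX'}{i + 1:02d}"
            plot_id = f"{'PP' if group == 'pure' else 'MP'}{chr(ord('A') + i % 3)}"
            tree_eff = math.exp(config.sigma_tree * rng.standard_normal())

            mz = moisture.reindex(years).to_numpy()
            rw_trend = on.rw_mature_mm + (on.rw_juvenile_mm - on.rw_mature_mm) * np.exp(
                -age / on.rw_decay_years
            )
            rw = (
                rw_trend
                * np.maximum(1.0 + config.rw_climate_beta * mz, 0.1)
                * np.exp(config.sigma_ring_width * rng.standard_normal(ny))
            )

            # (year, cell) grids
            rel_pos = (np.arange(nc) + rng.random((ny, nc))) / nc
            s = 1.0 / (1.0 + np.exp(-config.transition_rate * (rel_pos - config.transition_center)))

            juvenile = on.lumen_juvenile_frac + (1 - on.lumen_juvenile_frac) * (
                1 - np.exp(-age / on.lumen_maturation_years)
            )
            d_ew = (
                config.lumen_diam_ew_um
                * tree_eff
                * juvenile
                * np.maximum(1.0 + config.lumen_climate_beta * mz, 0.1)
            )
            d_exp = d_ew[:, None] + (config.lumen_diam_lw_um * tree_eff - d_ew[:, None]) * s
            t_exp = config.cwt_ew_um + (config.cwt_lw_um - config.cwt_ew_um) * s

            # planted drought effect on expected EW anatomical density
            lumen_exp = np.pi * d_exp**2 / 4.0
            wall_exp = _annulus_wall_area(d_exp, t_exp)
            ad_exp = wall_exp / (wall_exp + lumen_exp)
            mult = np.ones(ny)
            for phase, phase_years in (("during", drought_years), ("after", after_years)):
                m = getattr(config.effect_spec, phase).get(group, 1.0)
                if m != 1.0:
                    mult[np.isin(years, list(phase_years))] *= m
            ew_mask = rel_pos < config.transition_center
            ad_target = np.clip(ad_exp * mult[:, None], 0.0, 0.95)
            wall_target = np.where(
                ew_mask, lumen_exp * ad_target / (1.0 - ad_target), wall_exp
            )
            t_eff = _cwt_from_wall_area(d_exp, wall_target)

            d_cell = d_exp * np.exp(
                config.sigma_lumen * rng.standard_normal((ny, nc)) - 0.5 * config.sigma_lumen**2
            )
            t_cell = t_eff * np.exp(
                config.sigma_cwt * rng.standard_normal((ny, nc)) - 0.5 * config.sigma_cwt**2
            )
            wall_split = 0.05 * rng.standard_normal((ny, nc))
            cwt_rad = t_cell * (1.0 + wall_split)
            cwt_tan = t_cell * (1.0 - wall_split)
            lumen = np.pi * d_cell**2 / 4.0
            cwa = _annulus_wall_area(d_cell, t_cell)

            cell_frames.append(
                pd.DataFrame(
                    {
                        "tree_id": tree_id,
                        "plot_id": plot_id,
                        "group": group,
                        "year": np.repeat(years, nc),
                        "rel_pos": rel_pos.ravel(),
                        "lumen_area_um2": lumen.ravel(),
                        "cwt_rad_um": np.maximum(cwt_rad, 0.0).ravel(),
                        "cwt_tan_um": np.maximum(cwt_tan, 0.0).ravel(),
                        "cwa_um2": cwa.ravel(),
                    }
                )
            )
            ring_frames.append(
                pd.DataFrame(
                    {"tree_id": tree_id, "group": group, "year": years, "ring_width_mm": rw}
                )
            )

    return (
        pd.concat(cell_frames, ignore_index=True),
        pd.concat(ring_frames, ignore_index=True),
    )


@dataclass(frozen=True)
class SyntheticDataset:
    cells: pd.DataFrame
    rings: pd.DataFrame
    climate: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "cells.csv", index=False)
        self.rings.to_csv(outdir / "ring_widths.csv", index=False)
        self.climate.to_csv(outdir / "climate.csv", index=False)
        (outdir / "ground_truth.json").write_text(json.dumps(self.truth, indent=2))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full synthetic bundle: climate, cells, rings and the ground truth."""
    climate = generate_climate(config)
    cells, rings = generate_cells(config, climate)
    truth = {
        "seed": config.seed,
        "drought_years": sorted({e.year for e in config.drought_spec}),
        "effect_spec": dataclasses.asdict(config.effect_spec),
        "rw_climate_beta": config.rw_climate_beta,
        "lumen_climate_beta": config.lumen_climate_beta,
    }
    return SyntheticDataset(cells, rings, climate, truth)


# ---------------------------------------------------------------------------
# stand descriptions


@dataclass(frozen=True)
class StandPlot:
    """One inventory plot: stem density, basal area, Reineke SDI, pine DBH."""

    plot_id: str
    site: str
    mixture: str  # "pure" | "mixed"
    stems_per_ha: float
    basal_area_m2_ha: float
    sdi: float
    dbh_mean_cm: float
    dbh_sd_cm: float

    def __post_init__(self) -> None:
        if self.stems_per_ha <= 0 or self.basal_area_m2_ha <= 0 or self.sdi <= 0:
            raise ValueError("stand attributes must be positive")


# Published inventory of the two study sites (all-species stem counts and
# basal areas; SDI as reported per plot).  Rogow (Poland): pine sown
# 1936/1944, mixed with Quercus petraea.  Palacio de Valdellorma (Spain):
# pine sown 1971-72, mixed with Quercus pyrenaica.
STUDY_STANDS: tuple[StandPlot, ...] = (
    StandPlot("MPA", "Rogow", "mixed", 610, 36, 696, 31.4, 4.28),
    StandPlot("MPB", "Rogow", "mixed", 655, 42, 790, 29.6, 6.58),
    StandPlot("MPC", "Rogow", "mixed", 505, 41, 737, 31.6, 5.81),
    StandPlot("PPD", "Rogow", "pure", 708, 43, 825, 30.6, 5.56),
    StandPlot("PPE", "Rogow", "pure", 458, 41, 721, 33.8, 5.44),
    StandPlot("PPF", "Rogow", "pure", 444, 38, 681, 34.3, 6.15),
    StandPlot("MPA", "Valdellorma", "mixed", 5580, 31, 935, 11.9, 4.5),
    StandPlot("MPB", "Valdellorma", "mixed", 4635, 32, 932, 12.5, 3.9),
    StandPlot("MPC", "Valdellorma", "mixed", 4370, 33, 938, 12.5, 4.7),
    StandPlot("PPD", "Valdellorma", "pure", 2200, 67, 1460, 19.4, 5.4),
    StandPlot("PPE", "Valdellorma", "pure", 2350, 69, 1510, 17.7, 4.3),
    StandPlot("PPF", "Valdellorma", "pure", 2025, 57, 1269, 18.2, 4.3),
)


def stand_table(stands: tuple[StandPlot, ...] = STUDY_STANDS) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in stands])


def sdi_group_means(stands: tuple[StandPlot, ...] = STUDY_STANDS) -> pd.DataFrame:
    """Mean Stand Density Index per site x forest type."""
    df = stand_table(stands)
    out = df.groupby(["site", "mixture"], as_index=False)["sdi"].mean()
    return out.rename(columns={"sdi": "sdi_mean"})


def quadratic_mean_dbh(stems_per_ha: float, basal_area_m2_ha: float) -> float:
    """Diameter (cm) of the tree of mean basal area, Dq = sqrt(40000 BA / (pi N))."""
    if stems_per_ha <= 0 or basal_area_m2_ha <= 0:
        raise ValueError("stems_per_ha and basal_area must be positive")
    return math.sqrt(40000.0 * basal_area_m2_ha / (math.pi * stems_per_ha))


def reineke_sdi(stems_per_ha: float, dq_cm: float) -> float:
    """Reineke Stand Density Index: N * (Dq / 25 cm)^1.605."""
    if stems_per_ha <= 0 or dq_cm <= 0:
        raise ValueError("stems_per_ha and dq must be positive")
    return stems_per_ha * (dq_cm / 25.0) ** 1.605
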