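"""Table readers/writers, run configuration and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anatomy, chronology, climate as climate_mod, intra_annual, synthetic

__all__ = [
    "read_cell_table",
    "read_ring_widths",
    "read_climate",
    "RunConfig",
    "RunReport",
    "run_pipeline",
]

CELL_COLUMNS = {
    "tree_id": str,
    "year": int,
    "rel_pos": float,
    "lumen_area_um2": float,
    "cwt_rad_um": float,
    "cwt_tan_um": float,
    "cwa_um2": float,
}
OPTIONAL_CELL_COLUMNS = ("plot_id", "group", "lumen_diam_rad_um")


def read_cell_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read and validate a cell table CSV (ROXAS-compatible column subset).

    Malformed rows (non-finite or out-of-domain values) are rejected with
    their count reported; unknown extra columns are ignored with a single
    warning.  Returns (cells, report dict).
    """
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table is missing required column(s): {', '.join(missing)}")
    known = set(CELL_COLUMNS) | set(OPTIONAL_CELL_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"ignoring unknown cell-table column(s): {', '.join(extra)}")
        df = df.drop(columns=extra)

    n_read = len(df)
    numeric = ["year", "rel_pos", "lumen_area_um2", "cwt_rad_um", "cwt_tan_um", "cwa_um2"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df[numeric].notna().all(axis=1)
        & (df["rel_pos"] >= 0)
        & (df["rel_pos"] < 1)
        & (df["lumen_area_um2"] > 0)
        & (df["cwt_rad_um"] >= 0)
        & (df["cwt_tan_um"] >= 0)
        & (df["cwa_um2"] >= 0)
    )
    bad_lines = (df.index[~ok] + 2).tolist()  # +2: header and 1-based lines
    if bad_lines:
        warnings.warn(f"rejected {len(bad_lines)} malformed cell row(s), e.g. lines {bad_lines[:5]}")
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise ValueError("cell table contains no valid rows")
    report = {"cells_read": n_read, "cells_rejected": len(bad_lines), "cells_kept": len(df)}
    return df, report


def read_ring_widths(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("tree_id", "year", "ring_width_mm"):
        if col not in df.columns:
            raise ValueError(f"ring-width table is missing column {col!r}")
    return df


def read_climate(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("year", "month", "tmean_c", "prec_mm"):
        if col not in df.columns:
            raise ValueError(f"climate table is missing column {col!r}")
    return df


@dataclass
class RunConfig:
    """Declarative configuration of one full pipeline run."""

    output_dir: str = "qwa_output"
    # either synthetic generation ...
    synthetic: bool = True
    synthetic_config: synthetic.SyntheticConfig = field(
        default_factory=lambda: synthetic.SyntheticConfig(
            drought_spec=_default_droughts(),
            effect_spec=synthetic.EffectSpec(after={"pure": 1.15, "mixed": 1.0}),
        )
    )
    # ... or file inputs
    cells_path: str | None = None
    ring_widths_path: str | None = None
    climate_path: str | None = None
    latitude: float = 51.8
    spline_cutoff: float = 30.0
    spei_scales: tuple[int, ...] = (3, 6)
    drought_threshold: float = -1.5
    outlier_mode: str = "tukey"
    ks_mode: str = "profile"
    n_boot_correlation: int = 1000
    n_boot_gini: int = 2000
    seed: int = 0
    traits: tuple[str, ...] = ("DH", "CWT", "AD")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn_raw = raw.pop("synthetic_config", None)
        cfg = cls(**raw)
        if syn_raw is not None:
            droughts = tuple(
                synthetic.DroughtEvent(d["year"], tuple(d["months"]), d.get("anomaly_sd", 2.5))
                for d in syn_raw.pop("drought_spec", [])
            )
            effect_raw = syn_raw.pop("effect_spec", None)
            effect = (
                synthetic.EffectSpec(**effect_raw) if effect_raw else synthetic.EffectSpec()
            )
            cfg.synthetic_config = synthetic.SyntheticConfig(
                drought_spec=droughts, effect_spec=effect, **syn_raw
            )
        for p in (cfg.cells_path, cfg.ring_widths_path, cfg.climate_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _default_droughts() -> tuple[synthetic.DroughtEvent, ...]:
    """Demo drought regime: six planted spring/summer droughts spread over
    the record, with month timing varying between events as real droughts
    do."""
    return (
        synthetic.DroughtEvent(1964, (4, 5, 6)),
        synthetic.DroughtEvent(1976, (5, 6, 7)),
        synthetic.DroughtEvent(1983, (6, 7, 8)),
        synthetic.DroughtEvent(1992, (4, 5, 6)),
        synthetic.DroughtEvent(2003, (5, 6, 7)),
        synthetic.DroughtEvent(2015, (4, 5, 6)),
    )


@dataclass
class RunReport:
    config_digest: str
    seed: int
    counts: dict
    drought_years: list[int]
    planted_drought_years: list[int]
    legacy_contrasts: list[dict]
    warnings: list[str]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis: ingest -> anatomy -> SPEI/droughts ->
    chronologies -> climate correlations -> intra-annual statistics.

    All stage outputs are written as CSV/JSON under ``config.output_dir``;
    reruns with the same configuration are reproducible (fixed seeds)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    counts: dict = {}
    planted: list[int] = []

    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")

        # --- ingest
        if config.synthetic:
            ds = synthetic.generate_dataset(config.synthetic_config)
            ds.write(outdir / "input")
            cells, rings, clim = ds.cells, ds.rings, ds.climate
            planted = ds.truth["drought_years"]
            counts["cells_read"] = counts["cells_kept"] = len(cells)
            counts["cells_rejected"] = 0
        else:
            cells, cell_report = read_cell_table(config.cells_path)
            counts.update(cell_report)
            rings = read_ring_widths(config.ring_widths_path)
            clim = read_climate(config.climate_path)
        counts["trees"] = cells["tree_id"].nunique()
        counts["years"] = cells["year"].nunique()

        # --- anatomy
        classified = anatomy.classify_cells(cells)
        filtered, filter_log = anatomy.filter_ring_outliers(classified, mode=config.outlier_mode)
        counts["cells_outlier_removed"] = int(filter_log["n_removed"].sum())
        counts["rings"] = int(filter_log.groupby(["tree_id", "year"]).ngroups)
        annual = anatomy.aggregate_annual(filtered, rings)
        annual.to_csv(outdir / "annual_traits.csv", index=False)
        profiles = anatomy.build_sector_profiles(filtered)
        anatomy.profiles_to_wide(profiles).to_csv(outdir / "sector_profiles.csv", index=False)

        # --- climate / droughts
        wb = climate_mod.water_balance(clim, latitude=config.latitude)
        spei_frames = []
        spei_by_scale = {}
        for scale in config.spei_scales:
            s = climate_mod.spei(wb, scale=scale)
            spei_by_scale[scale] = s
            f = s.values.copy()
            f["scale"] = scale
            spei_frames.append(f)
        pd.concat(spei_frames, ignore_index=True).to_csv(outdir / "spei.csv", index=False)
        calendar = climate_mod.flag_drought_years(
            spei_by_scale[3], threshold=config.drought_threshold
        )
        (outdir / "drought_calendar.json").write_text(
            json.dumps(
                {
                    "drought_years": calendar.sorted(),
                    "threshold": calendar.threshold,
                    "window_months": list(calendar.window_months),
                    "scale": calendar.scale,
                },
                indent=2,
            )
        )

        # --- chronologies and climate correlations
        groups = sorted(cells["group"].unique()) if "group" in cells.columns else [""]
        clim_idx = {
            "temperature": climate_mod.detrend_climate(clim, "tmean_c", config.spline_cutoff),
            "precipitation": climate_mod.detrend_climate(clim, "prec_mm", config.spline_cutoff),
        }
        spei6 = spei_by_scale.get(6)
        if spei6 is not None:
            # SPEI is already standardized; it enters the window directly
            clim_idx["SPEI6"] = spei6.values.rename(columns={"spei": "index"}).dropna()

        corr_rows = []
        chron_rows = []
        for group in groups:
            sub = annual[annual["group"] == group] if group else annual
            for trait_col, trait in (("dh", "DH"), ("cwt", "CWT"), ("ad", "AD")):
                for part in ("EW", "LW"):
                    part_df = sub[sub["part"] == part]
                    if part_df[trait_col].notna().sum() < 10:
                        continue
                    chron = chronology.build_chronology(
                        part_df, trait_col, trait=trait, part=part, cutoff=config.spline_cutoff
                    )
                    cdf = pd.DataFrame(
                        {
                            "group": group,
                            "trait": trait,
                            "part": part,
                            "year": chron.index.index,
                            "index": chron.index.to_numpy(),
                            "sample_depth": chron.sample_depth.to_numpy(),
                        }
                    )
                    chron_rows.append(cdf)
                    try:
                        cm = chronology.correlate_monthly(
                            chron,
                            clim_idx,
                            n_boot=config.n_boot_correlation,
                            seed=config.seed,
                        )
                        cm.insert(0, "group", group)
                        corr_rows.append(cm)
                    except ValueError as exc:
                        caught.append(f"correlation skipped for {group}/{trait}/{part}: {exc}")
        pd.concat(chron_rows, ignore_index=True).to_csv(outdir / "chronologies.csv", index=False)
        if corr_rows:
            pd.concat(corr_rows, ignore_index=True).to_csv(outdir / "correlations.csv", index=False)

        # --- intra-annual statistics
        norm = intra_annual.normalize_profiles(profiles)
        legacy_rows: list[dict] = []
        if calendar.drought_years:
            for trait in config.traits:
                _, contrasts = intra_annual.drought_phase_profiles(
                    norm, calendar, trait=trait, ks_mode=config.ks_mode, seed=config.seed
                )
                contrasts.to_csv(outdir / f"legacy_ks_{trait}.csv", index=False)
                legacy_rows.extend(contrasts.to_dict("records"))
            rwi_frames = []
            for tree, grp in rings.groupby("tree_id"):
                grp = grp.sort_values("year")
                idx = chronology.detrend_series(
                    grp["ring_width_mm"].to_numpy(dtype=float), config.spline_cutoff
                )
                rwi_frames.append(
                    pd.DataFrame(
                        {
                            "tree_id": tree,
                            "group": grp["group"].iloc[0] if "group" in grp.columns else "",
                            "year": grp["year"].to_numpy(),
                            "rwi": idx,
                        }
                    )
                )
            rwi = pd.concat(rwi_frames, ignore_index=True)
            gini_table = intra_annual.drought_vs_nondrought_gini(
                norm, calendar, rwi=rwi, n_boot=config.n_boot_gini, seed=config.seed
            )
            gini_table.to_csv(outdir / "gini_table.csv", index=False)

        for w in wlog:
            caught.append(str(w.message))

    report = RunReport(
        config_digest=config.digest(),
        seed=config.seed,
        counts=counts,
        drought_years=calendar.sorted(),
        planted_drought_years=planted,
        legacy_contrasts=legacy_rows,
        warnings=caught,
    )
    report.write(outdir / "run_report.json")
    return report
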