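"""Per-bin orchestration: screen -> bin -> Moran QC -> covariates ->
aggregate -> fit model set -> select -> predict.

Bins are analysed independently; a failure in one bin (for example too few
sites) is recorded in the run report and does not stop the others.
Re-running with an identical configuration and seeds reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chronology import (
    DEFAULT_TIME_BINS,
    CalibrationCurve,
    EXCLUDED,
    TimeBin,
    assign_time_bin,
    calibrate_radiocarbon,
    validate_bins,
)
from .glmm import (
    ModelSpec,
    aggregate_by_site,
    enumerate_model_set,
    fit_dispersion_model,
    fit_mean_model,
    predict_dispersion,
    predict_isoscape,
    select_best_model,
)
from .ingest import ScreeningConfig, read_samples, screen_samples, summarize_dataset
from .moran import (
    build_inverse_distance_weights,
    classify_and_filter,
    global_moran,
    jitter_coincident,
    local_moran,
)
from .rasters import build_covariate_table, select_time_step, DEFAULT_TIME_STEP_MAP

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report", "bin_samples"]


@dataclass
class PipelineConfig:
    """Everything a run needs; every random seed is explicit."""

    input_table: str | Path | None = None
    curve_path: str | Path | None = None
    raster_dir: str | Path | None = None
    out_dir: str | Path | None = None
    column_map: dict = field(default_factory=dict)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    bins: tuple[TimeBin, ...] = DEFAULT_TIME_BINS
    time_step_map: dict = field(default_factory=lambda: dict(DEFAULT_TIME_STEP_MAP))
    calibration_grid_step: float = 5.0
    jitter_magnitude: float = 0.1
    jitter_seed: int = 17
    moran_n_perm: int = 999
    moran_seed: int = 17
    moran_alpha: float = 0.05
    model_specs: list[ModelSpec] | None = None   # None -> the 12-model set
    fix_nu: float | None = None
    optimizer_seed: int = 42
    n_starts: int = 3
    grid_resolution: float = 0.5
    min_sites: int = 10
    taxon_filter: str | None = None
    use_covariates: bool = True

    def validate(self) -> None:
        validate_bins(self.bins)
        if self.raster_dir is not None and not Path(self.raster_dir).is_dir():
            raise FileNotFoundError(f"raster directory not found: {self.raster_dir}")
        if self.input_table is not None and not Path(self.input_table).exists():
            raise FileNotFoundError(f"input table not found: {self.input_table}")

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, (ScreeningConfig, TimeBin, ModelSpec)):
                return sorted(str(o).split())
            if isinstance(o, frozenset):
                return sorted(o)
            if isinstance(o, Path):
                return str(o)
            return str(o)

        blob = json.dumps(self.__dict__, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Stage counts and per-bin model tables; reconciles across stages."""

    n_input: int = 0
    exclusion_counts: dict = field(default_factory=dict)
    n_screened: int = 0
    n_bin_excluded: int = 0
    n_binned: int = 0
    outliers_removed: dict = field(default_factory=dict)
    sites_per_bin: dict = field(default_factory=dict)
    global_moran: dict = field(default_factory=dict)
    model_tables: dict = field(default_factory=dict)      # bin -> list of dict rows
    bin_errors: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    version: str = __version__
    config_hash: str = ""

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "counts": {
                "input": self.n_input,
                "excluded_by_rule": self.exclusion_counts,
                "screened": self.n_screened,
                "bin_excluded": self.n_bin_excluded,
                "binned": self.n_binned,
                "outliers_removed": self.outliers_removed,
                "sites_per_bin": self.sites_per_bin,
            },
            "global_moran": self.global_moran,
            "models": self.model_tables,
            "bin_errors": self.bin_errors,
            "summary": self.summary,
        }


def bin_samples(
    samples: pd.DataFrame,
    curve: CalibrationCurve,
    bins: tuple[TimeBin, ...] = DEFAULT_TIME_BINS,
    grid_step: float = 5.0,
) -> pd.DataFrame:
    """Calibrate direct dates and assign every sample a bin (or EXCLUDED)."""
    out = samples.copy()
    assigned = []
    medians = []
    for _, row in out.iterrows():
        if row["dating_basis"] == "context":
            assigned.append(
                assign_time_bin(
                    None,
                    bins,
                    dating_basis="context",
                    context_age_bin=row["context_age_bin"] if pd.notna(row["context_age_bin"]) else None,
                    context_secure=bool(row.get("context_secure", True)),
                )
            )
            medians.append(np.nan)
        elif pd.notna(row["c14_age"]) and pd.notna(row["c14_error"]):
            try:
                cal = calibrate_radiocarbon(row["c14_age"], row["c14_error"], curve, grid_step)
            except ValueError:
                assigned.append(EXCLUDED)
                medians.append(np.nan)
                continue
            assigned.append(assign_time_bin(cal.median_cal_bp, bins))
            medians.append(cal.median_cal_bp)
        else:
            assigned.append(EXCLUDED)
            medians.append(np.nan)
    out["median_cal_bp"] = medians
    out["bin"] = assigned
    return out


def _analyse_bin(cfg: PipelineConfig, binned: pd.DataFrame, tb: TimeBin,
                 rasters: dict | None, report: RunReport) -> None:
    sub = binned[binned["bin"] == tb.name].reset_index(drop=True)
    if cfg.taxon_filter:
        sub = sub[sub["taxon"] == cfg.taxon_filter].reset_index(drop=True)
    if len(sub) < max(cfg.min_sites, 4):
        raise ValueError(f"too few samples in bin {tb.name}: {len(sub)}")

    coords = sub[["longitude", "latitude"]].to_numpy(dtype=float)
    jit = jitter_coincident(coords, cfg.jitter_magnitude, cfg.jitter_seed)
    sub["longitude"], sub["latitude"] = jit[:, 0], jit[:, 1]

    W = build_inverse_distance_weights(jit)
    vals = sub["d15N"].to_numpy(dtype=float)
    lm = local_moran(vals, W, cfg.moran_n_perm, cfg.moran_seed)
    gm = global_moran(vals, W)
    report.global_moran[tb.name] = {"I": gm.I, "z": gm.z_score, "p": gm.p_value}
    labels, keep = classify_and_filter(lm, vals, cfg.moran_alpha)
    report.outliers_removed[tb.name] = int(len(sub) - len(keep))
    sub = sub.iloc[keep].reset_index(drop=True)

    agg = aggregate_by_site(sub, bin_name=tb.name)
    report.sites_per_bin[tb.name] = int(len(agg))
    if len(agg) < cfg.min_sites:
        raise ValueError(f"too few sites in bin {tb.name}: {len(agg)}")

    covtab = None
    if rasters is not None and cfg.use_covariates:
        site_df = agg[["site_id", "lon", "lat"]]
        covtab = build_covariate_table(site_df, [tb.name], rasters, cfg.time_step_map)
        covtab = covtab.drop(columns=["bin"])

    try:
        disp = fit_dispersion_model(agg, seed=cfg.optimizer_seed, fix_nu=cfg.fix_nu,
                                    n_starts=cfg.n_starts)
        phi = predict_dispersion(disp, agg)
    except ValueError:
        phi = pd.Series(
            np.full(len(agg), np.nanmean(agg["var_d15N"].to_numpy()) or 1.0),
            index=agg["site_id"].to_numpy(),
        )

    specs = cfg.model_specs if cfg.model_specs is not None else enumerate_model_set()
    if covtab is None:
        specs = [s for s in specs if not s.fixed_effects]
    fits = []
    for spec in specs:
        try:
            fit = fit_mean_model(
                agg, covtab, spec, phi_hat=phi, fix_nu=cfg.fix_nu,
                n_starts=cfg.n_starts, seed=cfg.optimizer_seed,
                min_sites=cfg.min_sites,
            )
            fits.append(fit)
        except (ValueError, RuntimeError) as e:
            report.model_tables.setdefault(tb.name, []).append(
                {"model": spec.label(), "caic": None, "error": str(e)}
            )
    ranked = select_best_model(fits)
    report.model_tables.setdefault(tb.name, [])
    for _, r in ranked.iterrows():
        report.model_tables[tb.name].append(
            {"model": r["model"], "caic": float(r["caic"]),
             "delta_caic": float(r["delta_caic"]), "converged": bool(r["converged"])}
        )
    best = ranked.iloc[0]["fit"]
    surf = predict_isoscape(
        best,
        rasters,
        time_step=select_time_step(tb.name, cfg.time_step_map) if rasters else None,
        resolution=cfg.grid_resolution,
        bin_name=tb.name,
    )
    if cfg.out_dir is not None:
        outd = Path(cfg.out_dir)
        outd.mkdir(parents=True, exist_ok=True)
        surf.to_dataframe().to_csv(outd / f"isoscape_{tb.name}.csv", index=False)
        agg.to_csv(outd / f"aggregates_{tb.name}.csv", index=False)


def run_pipeline(
    cfg: PipelineConfig,
    samples: pd.DataFrame | None = None,
    curve: CalibrationCurve | None = None,
    rasters: dict | None = None,
) -> RunReport:
    """Execute the full pipeline; in-memory inputs may replace file paths."""
    cfg.validate()
    report = RunReport(config_hash=cfg.config_hash())

    if samples is None:
        samples = read_samples(cfg.input_table, column_map=cfg.column_map)
    if curve is None:
        if cfg.curve_path is None:
            raise ValueError("no calibration curve given")
        curve = CalibrationCurve.from_file(cfg.curve_path)
    if rasters is None and cfg.raster_dir is not None:
        from .rasters import ClimateRaster

        rasters = {}
        for f in sorted(Path(cfg.raster_dir).glob("*.nc")):
            ras = ClimateRaster.read_netcdf(f)
            rasters[(ras.variable, ras.time_step)] = ras

    report.n_input = len(samples)
    screened = screen_samples(samples, cfg.screening)
    report.exclusion_counts = screened.exclusion_counts
    report.n_screened = screened.n_retained

    binned = bin_samples(screened.samples, curve, cfg.bins, cfg.calibration_grid_step)
    kept = binned[binned["bin"] != EXCLUDED].reset_index(drop=True)
    report.n_bin_excluded = int(len(binned) - len(kept))
    report.n_binned = int(len(kept))
    report.summary = summarize_dataset(kept)

    for tb in cfg.bins:
        try:
            _analyse_bin(cfg, kept, tb, rasters, report)
        except Exception as e:  # per-bin isolation
            report.bin_errors[tb.name] = str(e)

    if cfg.out_dir is not None:
        write_report(report, Path(cfg.out_dir) / "report.json", "json")
        write_report(report, Path(cfg.out_dir) / "report.md", "markdown")
    return report


def write_report(report: RunReport, path: str | Path, fmt: str = "json") -> Path:
    """Serialize the run report as JSON or a readable markdown summary."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    elif fmt == "markdown":
        lines = [
            "# Isoscape pipeline run",
            "",
            f"- version: {report.version}",
            f"- config hash: {report.config_hash}",
            f"- input rows: {report.n_input}; screened: {report.n_screened}; "
            f"binned: {report.n_binned}",
            "",
            "## Exclusions",
        ]
        for rule, cnt in report.exclusion_counts.items():
            lines.append(f"- {rule}: {cnt}")
        lines += ["", "## Models (cAIC per bin)", ""]
        bins = list(report.model_tables)
        models: dict[str, dict] = {}
        for b in bins:
            for row in report.model_tables[b]:
                models.setdefault(row["model"], {})[b] = row.get("caic")
        header = "| Model | " + " | ".join(bins) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (len(bins) + 1))
        for m, per_bin in models.items():
            cells = [
                f"{per_bin[b]:.1f}" if isinstance(per_bin.get(b), float) else "-"
                for b in bins
            ]
            lines.append("| " + m + " | " + " | ".join(cells) + " |")
        if report.bin_errors:
            lines += ["", "## Skipped bins", ""]
            for b, err in report.bin_errors.items():
                lines.append(f"- {b}: {err}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path
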