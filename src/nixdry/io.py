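"""File I/O, run configuration and the end-to-end pipeline.

The on-disk trajectory schema is a plain CSV with header
``steeping_time_h,time_min,replicate,moisture_pct`` (extra columns such as
``clipped`` are carried through).  ``run_pipeline`` ties the stages
simulate -> fit -> diffusivity -> isolines together and emits a JSON report
plus CSV grid/isoline exports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .diffusion import GrainGeometry
from .fitting import fit_all_st, fits_to_table, v0_series
from .isolines import (build_param_surface, default_axes, extract_isoline,
                       grid_to_csv, isolines_to_csv, moisture_grid, rate_grid)
from .model import MoistureSeries
from .synthetic import (ExperimentDesign, NoiseModel, dataset_to_series,
                        generate_trajectories, write_dataset)

logger = logging.getLogger("nixdry")

REQUIRED_COLUMNS = ["steeping_time_h", "time_min", "replicate", "moisture_pct"]


def _round10(x: float) -> float:
    """Serialize floats at 10 significant digits for round-trip fidelity."""
    return float(f"{float(x):.10g}")


def read_trajectories(path) -> Dict[float, MoistureSeries]:
    """Read and validate a trajectory CSV into per-ST series.

    Malformed rows (non-numeric cells, out-of-range moisture, duplicate
    (ST, time, replicate) keys) are reported with their file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: header-only file, empty dataset", stacklevel=2)
        return {}
    # line numbers: header is line 1, first data row line 2
    for col in REQUIRED_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(
                f"{path}: non-numeric or missing value in column "
                f"'{col}' at line {line}")
        df[col] = numeric
    out_of_range = (df["moisture_pct"] < 0) | (df["moisture_pct"] > 100)
    if out_of_range.any():
        line = int(df.index[out_of_range][0]) + 2
        raise ValueError(f"{path}: moisture outside [0, 100] at line {line}")
    dup = df.duplicated(subset=["steeping_time_h", "time_min", "replicate"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(
            f"{path}: duplicate (steeping_time_h, time_min, replicate) key "
            f"at line {line}")
    return dataset_to_series(df)


@dataclass
class RunConfig:
    """Configuration for one pipeline run (CLI flags override file values)."""

    input_csv: Optional[str] = None       # if None, simulate
    output_dir: str = "nixdry_out"
    seed: int = 0
    replicates: int = 5
    noise_sd_t0: float = 0.993
    noise_sd_tmax: float = 0.181
    interpolation: str = "linear"
    st_step_h: float = 0.1
    t_step_min: float = 10.0
    t_max_min: float = 2600.0
    n_levels: int = 14
    radius_m: float = 0.0049
    average_replicates: bool = True
    verbosity: int = 1

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Flat ``key = value`` config file; keyword overrides win."""
        values = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{i}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{i}: unknown config key '{key}'")
            values[key] = val
        cfg = cls()
        for key, val in values.items():
            current = getattr(cfg, key)
            if isinstance(current, bool):
                val = val.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                val = int(val)
            elif isinstance(current, float):
                val = float(val)
            setattr(cfg, key, val)
        for key, val in overrides.items():
            if val is not None:
                setattr(cfg, key, val)
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> fit -> diffusivity -> isolines.

    Returns the JSON-serializable report
    ``{fits: [...], deff: [...], v0: [...], meta: {...}}`` and writes it,
    together with CSV grids and isolines, under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = GrainGeometry(radius_a=config.radius_m)

    # --- stage 1: data ---------------------------------------------------
    if config.input_csv is not None:
        logger.info("loading trajectories from %s", config.input_csv)
        dataset = read_trajectories(config.input_csv)
        if not dataset:
            raise ValueError(f"{config.input_csv}: empty dataset")
    else:
        design = ExperimentDesign(replicates=config.replicates,
                                  seed=config.seed)
        noise = NoiseModel(sd_at_t0=config.noise_sd_t0,
                           sd_at_tmax=config.noise_sd_tmax)
        logger.info("simulating design %s with noise %s", design, noise)
        df = generate_trajectories(design, noise=noise)
        write_dataset(df, out / "trajectories.csv", design=design, noise=noise)
        dataset = dataset_to_series(df)

    # --- stage 2: per-ST fits --------------------------------------------
    logger.info("fitting %d steeping-time conditions", len(dataset))
    fits = fit_all_st(dataset, average_replicates=config.average_replicates)
    fit_records = [
        {k: (_round10(v) if isinstance(v, float) else v)
         for k, v in fits[st].to_record().items()}
        for st in sorted(fits)]

    # --- stage 3: diffusivity --------------------------------------------
    deff_records = []
    for st in sorted(fits):
        d = fits[st].deff(geom)
        deff_records.append({"st_h": _round10(st), "k": _round10(d.k),
                             "deff_m2_per_min": _round10(d.deff),
                             "deff_m2_per_hour": _round10(d.deff_m2_per_hour),
                             "radius_m": _round10(d.radius_a)})

    # --- stage 4: initial rates and isolines ------------------------------
    v0_records = [
        {k: _round10(v) for k, v in row.items()}
        for row in v0_series(fits).to_dict("records")]

    grids_written = {}
    if len(fits) >= 2:
        surface = build_param_surface(fits, interpolation=config.interpolation)
        st_axis, t_axis = default_axes(surface, st_step_h=config.st_step_h,
                                       t_step_min=config.t_step_min,
                                       t_max_min=config.t_max_min)
        for name, builder in (("moisture", moisture_grid), ("rate", rate_grid)):
            grid = builder(surface, st_axis, t_axis, n_levels=config.n_levels)
            grid_path = out / f"{name}_grid.csv"
            grid_to_csv(grid, grid_path)
            polylines = {float(lv): extract_isoline(grid, float(lv))
                         for lv in grid.default_levels()}
            iso_path = out / f"{name}_isolines.csv"
            isolines_to_csv(polylines, iso_path)
            grids_written[name] = {"grid": str(grid_path),
                                   "isolines": str(iso_path)}
            logger.info("wrote %s grid (%d x %d) and %d isoline levels",
                        name, len(st_axis), len(t_axis), config.n_levels)

    report = {
        "fits": fit_records,
        "deff": deff_records,
        "v0": v0_records,
        "meta": {
            "seed": config.seed,
            "version": __version__,
            "config": dataclasses.asdict(config),
            "outputs": grids_written,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("report written to %s", out / "report.json")
    return report
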