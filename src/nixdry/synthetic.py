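"""Synthetic dehydration datasets emulating the reference experiment.

The emulated design: nixtamalized corn grains steeped for 0, 2, 4, 6 or 8 h,
then dried at 50 °C with weighings every 15 min over 0–120 min plus a single
long-time point at 2600 min to pin the equilibrium moisture; five replicate
runs per steeping time.  Generating parameters per condition are the
published per-ST rate constants and equilibrium moistures; the initial
moisture profile is a documented synthetic stand-in (no published M0 values
exist), increasing with steeping time toward a ~47 % ceiling.

Measurement noise is additive Gaussian with a standard deviation that decays
from 0.993 % at the start of drying to 0.181 % at 2600 min, linearly in
log(1 + t) — reproducing the reported uncertainty band and its tendency to
stabilise at low values late in drying.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .kinetics import KineticParams, moisture_at_time

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "REFERENCE_KINETICS",
    "default_params_for_st",
    "generate_trajectories",
    "dataset_to_series",
    "write_dataset",
]

#: Published per-ST (k /min, ME %) pairs of the drying-rate table.
REFERENCE_KINETICS: Dict[float, tuple] = {
    0.0: (0.0185, 5.088),
    2.0: (0.0161, 5.399),
    4.0: (0.0158, 5.792),
    6.0: (0.0147, 5.646),
    8.0: (0.0140, 5.836),
}

#: Synthetic stand-in initial moistures (%), increasing with ST to ~47 %.
#: No M0 values are published; these are a documented invention.
DEFAULT_M0: Dict[float, float] = {0.0: 38.0, 2.0: 45.0, 4.0: 47.0,
                                  6.0: 46.5, 8.0: 46.0}


def _default_times() -> list:
    return [float(t) for t in range(0, 121, 15)] + [2600.0]


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of the emulated drying experiment."""

    st_values_h: tuple = (0.0, 2.0, 4.0, 6.0, 8.0)
    sample_times_min: tuple = tuple(_default_times())
    replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        times = np.asarray(self.sample_times_min, dtype=float)
        if np.any(times < 0):
            raise ValueError("sample times must be >= 0")
        if len(np.unique(times)) != len(times) or np.any(np.diff(times) < 0):
            raise ValueError("sample times must be sorted and unique")

    @property
    def n_rows(self) -> int:
        return len(self.st_values_h) * len(self.sample_times_min) * self.replicates


@dataclass(frozen=True)
class NoiseModel:
    """Time-dependent Gaussian measurement noise on moisture readings.

    The standard deviation interpolates from ``sd_at_t0`` down to
    ``sd_at_tmax`` linearly in log(1 + t), so readings stabilise late in
    drying.  Setting both to 0 yields exact model values.
    """

    sd_at_t0: float = 0.993
    sd_at_tmax: float = 0.181
    schedule: str = "linear-in-log-time"

    def __post_init__(self) -> None:
        if self.sd_at_t0 < 0 or self.sd_at_tmax < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.sd_at_tmax > self.sd_at_t0:
            raise ValueError("noise sd must be non-increasing along time")
        if self.schedule != "linear-in-log-time":
            raise ValueError(f"unknown noise schedule: {self.schedule}")

    def sd(self, t, t_max: float = 2600.0):
        """Standard deviation (%) at time(s) ``t`` minutes."""
        t = np.asarray(t, dtype=float)
        frac = np.log1p(np.clip(t, 0.0, t_max)) / np.log1p(t_max)
        out = self.sd_at_t0 + (self.sd_at_tmax - self.sd_at_t0) * frac
        return out if out.ndim else float(out)


ZERO_NOISE = NoiseModel(sd_at_t0=0.0, sd_at_tmax=0.0)


def default_params_for_st(st_h: float) -> KineticParams:
    """Generating parameters for a design steeping time.

    k and ME come from the published drying-rate table; M0 is the synthetic
    stand-in profile (see :data:`DEFAULT_M0`).
    """
    st = float(st_h)
    if st not in REFERENCE_KINETICS:
        raise KeyError(
            f"no published parameters for ST={st_h} h; "
            f"design nodes are {sorted(REFERENCE_KINETICS)}")
    k, me = REFERENCE_KINETICS[st]
    return KineticParams(m0=DEFAULT_M0[st], me=me, k=k)


def generate_trajectories(design: ExperimentDesign = ExperimentDesign(),
                          params_table: Optional[Mapping[float, KineticParams]] = None,
                          noise: Optional[NoiseModel] = None) -> pd.DataFrame:
    """Simulate the full factorial dataset (ST x time x replicate).

    Returns a DataFrame with columns ``steeping_time_h``, ``time_min``,
    ``replicate``, ``moisture_pct`` and ``clipped`` (True where additive
    noise drove a reading below 0 and it was clipped).  Fully reproducible
    from ``design.seed``.
    """
    if noise is None:
        noise = NoiseModel()
    if params_table is None:
        params_table = {st: default_params_for_st(st) for st in design.st_values_h}
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.sample_times_min, dtype=float)
    t_max = float(times.max())
    sds = noise.sd(times, t_max=t_max)
    rows = []
    for st in design.st_values_h:
        params = params_table[st]
        clean = moisture_at_time(params, times)
        for rep in range(1, design.replicates + 1):
            eps = rng.standard_normal(len(times)) * sds
            noisy = clean + eps
            clipped = noisy < 0
            noisy = np.where(clipped, 0.0, noisy)
            for t, m, c in zip(times, noisy, clipped):
                rows.append((float(st), float(t), rep, float(m), bool(c)))
    return pd.DataFrame(
        rows, columns=["steeping_time_h", "time_min", "replicate",
                       "moisture_pct", "clipped"])


def dataset_to_series(df: pd.DataFrame) -> Dict[float, "MoistureSeries"]:
    """Group a trajectory table into per-ST series."""
    from .model import MoistureSeries

    out = {}
    for st, grp in df.groupby("steeping_time_h"):
        out[float(st)] = MoistureSeries(
            st_h=float(st),
            observations=grp[["time_min", "moisture_pct"]
                             + (["replicate"] if "replicate" in grp else [])])
    return out


def write_dataset(df: pd.DataFrame, path, params_table=None,
                  design: Optional[ExperimentDesign] = None,
                  noise: Optional[NoiseModel] = None) -> None:
    """Write the CSV and a JSON sidecar of generating parameters.

    The sidecar records everything needed for recovery tests and flags the
    M0 profile as synthetic.
    """
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {"m0_profile": "synthetic stand-in (no published M0 values)"}
    if params_table is not None:
        meta["params"] = {
            str(st): {"m0": p.m0, "me": p.me, "k": p.k}
            for st, p in params_table.items()}
    if design is not None:
        meta["design"] = {
            "st_values_h": list(design.st_values_h),
            "sample_times_min": list(design.sample_times_min),
            "replicates": design.replicates,
            "seed": design.seed,
        }
    if noise is not None:
        meta["noise"] = {"sd_at_t0": noise.sd_at_t0,
                         "sd_at_tmax": noise.sd_at_tmax,
                         "schedule": noise.schedule}
    path.with_suffix(".params.json").write_text(json.dumps(meta, indent=2))
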