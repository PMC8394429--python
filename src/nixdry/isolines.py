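"""Moisture and dehydration-rate surfaces over the (ST, drying-time) plane.

Per-steeping-time fits give a parameter triple at each measured ST node;
interpolating those triples across ST (piecewise linear by default, monotone
cubic optionally) defines a parameter surface, from which moisture and rate
grids M(ST, t) and vI(ST, t) are evaluated and constant-value isolines
extracted by marching squares.  No extrapolation beyond the measured ST
range is permitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from skimage import measure

from .kinetics import KineticParams, dehydration_rate, moisture_at_time, \
    time_for_moisture
from .model import DryingFitResults

__all__ = [
    "ParamSurface",
    "IsolineGrid",
    "build_param_surface",
    "moisture_grid",
    "rate_grid",
    "extract_isoline",
    "time_to_target_moisture",
    "grid_to_csv",
    "isolines_to_csv",
]

DEFAULT_N_LEVELS = 14


class ParamSurface:
    """Component-wise interpolant of (M0, ME, k) across steeping time.

    interpolation="linear" keeps every interpolated parameter inside the
    convex hull of its node values; "pchip" is shape-preserving monotone
    cubic.  Queries outside [min node, max node] raise: the measured ST
    range supports no extrapolation.
    """

    def __init__(self, st_nodes, params_at_nodes, interpolation: str = "linear"):
        st = np.asarray(st_nodes, dtype=float)
        if len(st) < 2:
            raise ValueError("need at least 2 steeping-time nodes")
        if len(np.unique(st)) != len(st):
            raise ValueError("duplicate steeping-time nodes")
        if np.any(np.diff(st) <= 0):
            raise ValueError("steeping-time nodes must be strictly increasing")
        if len(params_at_nodes) != len(st):
            raise ValueError("one parameter triple required per node")
        self.st_nodes = st
        self.params_at_nodes = list(params_at_nodes)
        if interpolation not in ("linear", "pchip"):
            raise ValueError(f"unknown interpolation: {interpolation}")
        self.interpolation = interpolation
        cols = {name: np.array([getattr(p, name) for p in self.params_at_nodes])
                for name in ("m0", "me", "k")}
        if interpolation == "pchip":
            self._interp = {n: PchipInterpolator(st, v) for n, v in cols.items()}
        else:
            self._interp = {
                n: (lambda v: (lambda x: np.interp(x, st, v)))(v)
                for n, v in cols.items()}

    def _check_range(self, st) -> np.ndarray:
        st = np.asarray(st, dtype=float)
        if np.any(st < self.st_nodes[0]) or np.any(st > self.st_nodes[-1]):
            raise ValueError(
                f"steeping time outside node range "
                f"[{self.st_nodes[0]:g}, {self.st_nodes[-1]:g}] h: "
                "no extrapolation")
        return st

    def components_at(self, st):
        """Vectorised (m0, me, k) arrays at steeping time(s) ``st``."""
        st = self._check_range(st)
        return tuple(np.asarray(self._interp[n](st), dtype=float)
                     for n in ("m0", "me", "k"))

    def __call__(self, st: float) -> KineticParams:
        m0, me, k = self.components_at(float(st))
        return KineticParams(m0=float(m0), me=float(me), k=float(k))


@dataclass
class IsolineGrid:
    """Evaluated surface: ``values[i, j]`` at ``(st_axis[i], t_axis[j])``."""

    st_axis: np.ndarray
    t_axis: np.ndarray
    values: np.ndarray
    quantity: str  # "moisture" | "rate"
    n_levels: int = DEFAULT_N_LEVELS

    def __post_init__(self) -> None:
        self.st_axis = np.asarray(self.st_axis, dtype=float)
        self.t_axis = np.asarray(self.t_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.st_axis), len(self.t_axis)):
            raise ValueError("grid shape must be |st_axis| x |t_axis|")

    def default_levels(self) -> np.ndarray:
        """``n_levels`` interior levels, evenly spaced between grid extremes."""
        lo, hi = float(self.values.min()), float(self.values.max())
        return np.linspace(lo, hi, self.n_levels + 2)[1:-1]


def default_axes(surface: ParamSurface, st_step_h: float = 0.1,
                 t_step_min: float = 10.0, t_max_min: float = 2600.0):
    """Default grid axes: ST at 0.1 h steps over the node range, drying
    time at 10 min steps over 0–2600 min (81 x 261 for the 0–8 h design)."""
    st_axis = np.arange(surface.st_nodes[0],
                        surface.st_nodes[-1] + st_step_h / 2, st_step_h)
    t_axis = np.arange(0.0, t_max_min + t_step_min / 2, t_step_min)
    return st_axis, t_axis


def build_param_surface(fits: Mapping[float, DryingFitResults],
                        interpolation: str = "linear") -> ParamSurface:
    """Parameter surface from per-ST fit results (keyed by ST in hours)."""
    sts = sorted(fits)
    return ParamSurface(st_nodes=sts,
                        params_at_nodes=[fits[st].params for st in sts],
                        interpolation=interpolation)


def _eval_grid(surface: ParamSurface, st_axis, t_axis, func) -> np.ndarray:
    st_axis = np.asarray(st_axis, dtype=float)
    t_axis = np.asarray(t_axis, dtype=float)
    if np.any(t_axis < 0):
        raise ValueError("drying times must be >= 0")
    m0, me, k = surface.components_at(st_axis)
    vals = np.empty((len(st_axis), len(t_axis)))
    for i in range(len(st_axis)):
        p = KineticParams(m0=float(m0[i]), me=float(me[i]), k=float(k[i]))
        vals[i] = func(p, t_axis)
    return vals


def moisture_grid(surface: ParamSurface, st_axis, t_axis,
                  n_levels: int = DEFAULT_N_LEVELS) -> IsolineGrid:
    """Moisture surface M(ST, t); each row strictly decreasing along t."""
    vals = _eval_grid(surface, st_axis, t_axis, moisture_at_time)
    return IsolineGrid(st_axis=st_axis, t_axis=t_axis, values=vals,
                       quantity="moisture", n_levels=n_levels)


def rate_grid(surface: ParamSurface, st_axis, t_axis,
              n_levels: int = DEFAULT_N_LEVELS) -> IsolineGrid:
    """Dehydration-rate surface vI(ST, t); all entries <= 0 (moisture loss)."""
    vals = _eval_grid(surface, st_axis, t_axis, dehydration_rate)
    return IsolineGrid(st_axis=st_axis, t_axis=t_axis, values=vals,
                       quantity="rate", n_levels=n_levels)


def extract_isoline(grid: IsolineGrid, level: float) -> List[np.ndarray]:
    """Level-set polylines of a grid in (ST, t) coordinates.

    Marching squares with linear edge interpolation; each polyline is an
    (n, 2) array of (st_h, time_min) points.  A level outside the grid's
    value range, or a constant grid at exactly the level, yields an empty
    list with a warning rather than an error.
    """
    vmin, vmax = float(grid.values.min()), float(grid.values.max())
    if level < vmin or level > vmax:
        warnings.warn(
            f"level {level:g} outside grid range [{vmin:g}, {vmax:g}]; "
            "no isoline", stacklevel=2)
        return []
    if vmin == vmax:
        warnings.warn(
            "grid is constant and equal to the level: isoline is the whole "
            "domain (degenerate)", stacklevel=2)
        return []
    contours = measure.find_contours(grid.values, level)
    idx_st = np.arange(len(grid.st_axis))
    idx_t = np.arange(len(grid.t_axis))
    out = []
    for c in contours:
        st = np.interp(c[:, 0], idx_st, grid.st_axis)
        t = np.interp(c[:, 1], idx_t, grid.t_axis)
        out.append(np.column_stack([st, t]))
    return out


def time_to_target_moisture(surface: ParamSurface, st: float,
                            target_m: float) -> float:
    """Drying time (minutes) to reach a target moisture at a steeping time.

    Closed-form inversion of the drying curve at the interpolated
    parameters; a target at or below the local equilibrium moisture is
    unreachable and raises.
    """
    return time_for_moisture(surface(st), target_m)


def grid_to_csv(grid: IsolineGrid, path) -> None:
    """CSV matrix with the t axis as header row and the ST axis as first
    column."""
    df = pd.DataFrame(grid.values,
                      index=pd.Index(grid.st_axis, name="st_h"),
                      columns=[f"{t:g}" for t in grid.t_axis])
    df.to_csv(Path(path), float_format="%.10g")


def isolines_to_csv(polylines_by_level: Dict[float, List[np.ndarray]],
                    path) -> None:
    """Polyline table with columns level, segment_id, st_h, time_min."""
    rows = []
    for level, polylines in polylines_by_level.items():
        for seg_id, poly in enumerate(polylines):
            for st, t in poly:
                rows.append((level, seg_id, st, t))
    pd.DataFrame(rows, columns=["level", "segment_id", "st_h", "time_min"]) \
        .to_csv(Path(path), index=False, float_format="%.10g")
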