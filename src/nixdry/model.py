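"""Model/results interface for fitting the drying curve to observations.

:class:`IsothermalDryingModel` wraps one moisture trajectory (one steeping
time); its :meth:`~IsothermalDryingModel.fit` recovers the parameter triple
(M0, ME, k) by nonlinear least squares on

    M(t) = (M0 - ME) exp(-k t) + ME

and returns a :class:`DryingFitResults` carrying the estimates, residual
diagnostics and a ``summary()`` table.  A log-linearised slope fit
(``ln(M - ME)`` vs t) is available via :meth:`fit_loglinear` as the
classical graphical route to k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import KineticParams, initial_rate, moisture_at_time
from .diffusion import DiffusivityResult, GrainGeometry, deff_from_k

__all__ = [
    "MoistureSeries",
    "IsothermalDryingModel",
    "DryingFitResults",
    "LogLinearFit",
    "InsufficientDataError",
    "ConvergenceError",
]

# deterministic jitter stream for fit restarts
_JITTER_SEED = 715


class InsufficientDataError(ValueError):
    """Too few distinct time points for a three-parameter fit."""


class ConvergenceError(RuntimeError):
    """Optimizer failed after bounded restarts; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class MoistureSeries:
    """Moisture observations for one steeping-time condition.

    ``observations`` is a DataFrame with columns ``time_min``,
    ``moisture_pct`` and optionally ``replicate``.
    """

    st_h: float
    observations: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.observations)
        missing = {"time_min", "moisture_pct"} - set(df.columns)
        if missing:
            raise ValueError(f"series is missing columns: {sorted(missing)}")
        if (df["time_min"] < 0).any():
            raise ValueError("observation times must be >= 0")
        if ((df["moisture_pct"] < 0) | (df["moisture_pct"] > 100)).any():
            raise ValueError("moisture percentages must lie in [0, 100]")
        self.observations = df.reset_index(drop=True)

    @property
    def n_distinct_times(self) -> int:
        return int(self.observations["time_min"].nunique())

    def replicate_means(self) -> pd.DataFrame:
        """Mean moisture per time point (the default pre-fit aggregation)."""
        return (
            self.observations.groupby("time_min", as_index=False)["moisture_pct"]
            .mean()
            .sort_values("time_min", ignore_index=True)
        )


@dataclass
class LogLinearFit:
    """Slope/intercept of the log-linearised drying curve.

    The regression is ``ln[(M - me)/(M_first - me)] = intercept - k t``; on
    noiseless model data the intercept is 0 and the slope is exactly -k.
    """

    k: float
    intercept: float
    me: float
    n_obs: int


class IsothermalDryingModel:
    """First-order drying model bound to one observed trajectory.

    Parameters
    ----------
    time_min, moisture_pct : array-like
        Observation times (minutes) and moisture percentages.
    st_h : float, optional
        Steeping time label carried through to results.
    weights : array-like, optional
        Per-observation weights (residuals scaled by sqrt(w)).
    """

    def __init__(self, time_min, moisture_pct, st_h: Optional[float] = None,
                 weights=None):
        t = np.asarray(time_min, dtype=float)
        m = np.asarray(moisture_pct, dtype=float)
        if t.shape != m.shape or t.ndim != 1:
            raise ValueError("time and moisture must be 1-d arrays of equal length")
        if np.any(t < 0):
            raise ValueError("observation times must be >= 0")
        if np.any((m < 0) | (m > 100)):
            raise ValueError("moisture percentages must lie in [0, 100]")
        order = np.argsort(t, kind="stable")
        self.time_min = t[order]
        self.moisture_pct = m[order]
        self.st_h = st_h
        if weights is not None:
            w = np.asarray(weights, dtype=float)[order]
            if np.any(w <= 0):
                raise ValueError("weights must be positive")
            self._sqrt_w = np.sqrt(w)
        else:
            self._sqrt_w = None

    # ---------------------------------------------------------------- ctors
    @classmethod
    def from_series(cls, series: MoistureSeries, average_replicates: bool = True,
                    weights=None) -> "IsothermalDryingModel":
        df = series.replicate_means() if average_replicates else series.observations
        return cls(df["time_min"].to_numpy(), df["moisture_pct"].to_numpy(),
                   st_h=series.st_h, weights=weights)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, st_h: Optional[float] = None,
                       average_replicates: bool = True) -> "IsothermalDryingModel":
        """Build from a trajectory table (``time_min``, ``moisture_pct``,
        optional ``steeping_time_h``/``replicate`` columns)."""
        if st_h is not None and "steeping_time_h" in df.columns:
            df = df[df["steeping_time_h"] == st_h]
        elif st_h is None and "steeping_time_h" in df.columns:
            sts = df["steeping_time_h"].unique()
            if len(sts) > 1:
                raise ValueError(
                    "dataframe holds several steeping times; pass st_h")
            st_h = float(sts[0])
        series = MoistureSeries(st_h=st_h if st_h is not None else math.nan,
                                observations=df[["time_min", "moisture_pct"]])
        return cls.from_series(series, average_replicates=average_replicates)

    # ------------------------------------------------------------- fitting
    def _validate_fittable(self) -> None:
        if len(np.unique(self.time_min)) < 4:
            raise InsufficientDataError(
                f"need >= 4 distinct time points for a 3-parameter fit, "
                f"got {len(np.unique(self.time_min))}")
        if np.ptp(self.moisture_pct) == 0:
            raise ValueError("constant moisture series cannot identify the model")

    def _default_init(self) -> np.ndarray:
        """Deterministic data-driven start: endpoints for M0/ME, log-slope for k."""
        m0_0 = float(self.moisture_pct[0])
        me_0 = float(self.moisture_pct[-1])
        mask = self.moisture_pct > me_0 + 1e-9
        if mask.sum() >= 2:
            y = np.log(self.moisture_pct[mask] - me_0)
            slope = np.polyfit(self.time_min[mask], y, 1)[0]
            k_0 = float(np.clip(-slope, 1e-5, 0.9))
        else:
            k_0 = 0.01
        return np.array([max(m0_0, me_0 + 1e-3), me_0, k_0])

    def fit(self, init: Optional[KineticParams] = None,
            max_restarts: int = 3) -> "DryingFitResults":
        """Nonlinear least-squares estimate of (M0, ME, k).

        Bounds keep the optimizer physical: k in (1e-6, 1) per minute,
        ME in [0, M0_init], M0 in [ME_init, 100].  Up to ``max_restarts``
        deterministic jittered restarts before raising
        :class:`ConvergenceError`.
        """
        self._validate_fittable()
        x0 = (np.array([init.m0, init.me, init.k]) if init is not None
              else self._default_init())
        lo = np.array([x0[1], 0.0, 1e-6])
        hi = np.array([100.0, x0[0], 1.0])
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

        def resid(x):
            m0, me, k = x
            r = (m0 - me) * np.exp(-k * self.time_min) + me - self.moisture_pct
            return r * self._sqrt_w if self._sqrt_w is not None else r

        rng = np.random.default_rng(_JITTER_SEED)
        sol = None
        for attempt in range(max_restarts + 1):
            start = x0 if attempt == 0 else np.clip(
                x0 * rng.uniform(0.8, 1.2, size=3), lo + 1e-12, hi - 1e-12)
            sol = least_squares(resid, start, bounds=(lo, hi), method="trf",
                                ftol=1e-12, xtol=1e-12, gtol=1e-12)
            if sol.success:
                break
        else:
            raise ConvergenceError(
                f"fit did not converge after {max_restarts} restarts", sol)
        if not sol.success:
            raise ConvergenceError(
                f"fit did not converge after {max_restarts} restarts", sol)

        m0, me, k = sol.x
        # guard against a boundary-degenerate me >= m0
        if m0 <= me:
            raise ConvergenceError("degenerate fit: m0 <= me", sol)
        params = KineticParams(m0=float(m0), me=float(me), k=float(k))
        fitted = moisture_at_time(params, self.time_min)
        residuals = self.moisture_pct - fitted
        ss_res = float(np.sum(residuals**2))
        ss_tot = float(np.sum((self.moisture_pct - self.moisture_pct.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        return DryingFitResults(model=self, params=params, method="nls",
                                r_squared=r2, residuals=residuals,
                                nobs=len(self.time_min), cost=float(sol.cost),
                                n_restarts=attempt)

    def fit_loglinear(self, me: float) -> LogLinearFit:
        """Ordinary least-squares line through ``ln MR`` vs t at a given ME.

        Every observation must exceed ``me`` (positive log argument); the
        offending time point is named otherwise.  |slope| estimates k.
        """
        bad = self.moisture_pct <= me
        if bad.any():
            t_bad = self.time_min[bad][0]
            raise ValueError(
                f"moisture at t={t_bad:g} min is <= me={me:g}: "
                "log-linearisation undefined")
        mr = (self.moisture_pct - me) / (self.moisture_pct[0] - me)
        slope, intercept = np.polyfit(self.time_min, np.log(mr), 1)
        return LogLinearFit(k=float(-slope), intercept=float(intercept),
                            me=float(me), n_obs=len(self.time_min))


@dataclass
class DryingFitResults:
    """Estimates and diagnostics from :meth:`IsothermalDryingModel.fit`."""

    model: IsothermalDryingModel
    params: KineticParams
    method: str
    r_squared: float
    residuals: np.ndarray
    nobs: int
    cost: float = math.nan
    n_restarts: int = 0

    @property
    def st_h(self) -> Optional[float]:
        return self.model.st_h

    @property
    def fittedvalues(self) -> np.ndarray:
        return moisture_at_time(self.params, self.model.time_min)

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))

    @property
    def v0(self) -> float:
        """Initial dehydration rate -k (m0 - me), percent per minute."""
        return initial_rate(self.params)

    def predict(self, t) -> np.ndarray:
        """Moisture percentage at time(s) ``t`` under the fitted parameters."""
        return moisture_at_time(self.params, t)

    def deff(self, geom: GrainGeometry = GrainGeometry()) -> DiffusivityResult:
        """Effective diffusivity implied by the fitted k (sphere of radius a)."""
        return deff_from_k(self.params.k, geom)

    def to_record(self) -> dict:
        return {
            "st_h": self.st_h,
            "k": self.params.k,
            "me": self.params.me,
            "m0": self.params.m0,
            "r_squared": self.r_squared,
            "n_obs": self.nobs,
            "method": self.method,
        }

    def summary(self) -> str:
        p = self.params
        st = "n/a" if self.st_h is None or math.isnan(self.st_h) else f"{self.st_h:g} h"
        lines = [
            "Isothermal drying fit (first-order exponential model)",
            "=" * 56,
            f"steeping time        {st}",
            f"n observations       {self.nobs}",
            f"method               {self.method}",
            "-" * 56,
            f"M0  initial moisture     {p.m0:12.6f}  %",
            f"ME  equilibrium moisture {p.me:12.6f}  %",
            f"k   rate constant        {p.k:12.6f}  /min",
            f"v0  initial rate         {self.v0:12.6f}  %/min",
            f"half-life                {p.half_life_min:12.2f}  min",
            "-" * 56,
            f"R^2                      {self.r_squared:12.6f}",
            f"RMSE                     {self.rmse:12.6f}  %",
        ]
        return "\n".join(lines)
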