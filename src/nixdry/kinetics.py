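"""Closed-form first-order dehydration kinetics.

The drying of a nixtamalized corn grain at constant temperature is modelled
as a first-order relaxation of its moisture percentage ``M(t)`` toward an
equilibrium value ``ME``::

    dM/dt = -k (M - ME)   =>   M(t) = (M0 - ME) exp(-k t) + ME

with ``M0`` the initial moisture (percent), ``ME`` the equilibrium moisture
(percent) and ``k`` the dynamical rate constant (per minute).  Everything in
this module is a pure function of a :class:`KineticParams` triple; time is
always in minutes.

The moisture percentage is treated on whatever basis (wet or dry) the data
uses — the model is basis-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticParams",
    "moisture_at_time",
    "dehydration_rate",
    "initial_rate",
    "moisture_ratio",
    "time_for_moisture",
]


@dataclass(frozen=True)
class KineticParams:
    """Parameter triple of the first-order drying model for one condition.

    Attributes
    ----------
    m0 : float
        Initial moisture, percent.  Must satisfy ``me < m0 <= 100``.
    me : float
        Equilibrium (asymptotic) moisture, percent, ``me >= 0``.
    k : float
        Dynamical rate constant, per minute, ``k > 0``.
    """

    m0: float
    me: float
    k: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.m0, self.me, self.k]).all():
            raise ValueError("kinetic parameters must be finite")
        if self.k <= 0:
            raise ValueError(f"rate constant k must be positive, got {self.k}")
        if self.me < 0:
            raise ValueError(f"equilibrium moisture must be >= 0, got {self.me}")
        if self.m0 <= self.me:
            raise ValueError(
                f"initial moisture m0={self.m0} must exceed equilibrium me={self.me}"
            )
        if self.m0 > 100:
            raise ValueError(f"moisture percentage cannot exceed 100, got {self.m0}")

    @property
    def driving_force(self) -> float:
        """Initial moisture excess ``m0 - me`` (percent)."""
        return self.m0 - self.me

    @property
    def asymptote(self) -> float:
        """The t -> infinity moisture limit, i.e. ``me``."""
        return self.me

    @property
    def half_life_min(self) -> float:
        """Time for the moisture excess to halve: ``ln 2 / k`` (minutes)."""
        return float(np.log(2.0) / self.k)


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative (minutes)")
    return t


def moisture_at_time(params: KineticParams, t):
    """Moisture percentage ``M(t) = (m0 - me) exp(-k t) + me``.

    Strictly decreasing in ``t``, bounded in ``(me, m0]``.  ``t`` may be a
    scalar or array of minutes; negative times raise ``ValueError``.
    """
    t = _check_time(t)
    out = params.driving_force * np.exp(-params.k * t) + params.me
    return out if out.ndim else float(out)


def dehydration_rate(params: KineticParams, t):
    """Isothermal dehydration rate ``dM/dt = -k (m0 - me) exp(-k t)``.

    Always negative during drying (moisture is lost); its magnitude decays
    from ``|v0| = k (m0 - me)`` at ``t = 0`` toward zero.
    """
    t = _check_time(t)
    out = -params.k * params.driving_force * np.exp(-params.k * t)
    return out if out.ndim else float(out)


def initial_rate(params: KineticParams) -> float:
    """Initial dehydration rate ``v0 = -k (m0 - me)`` (percent per minute)."""
    return -params.k * params.driving_force


def moisture_ratio(params: KineticParams, t):
    """Dimensionless moisture ratio ``MR = (M(t) - me)/(m0 - me) = exp(-k t)``."""
    t = _check_time(t)
    out = np.exp(-params.k * t)
    return out if out.ndim else float(out)


def time_for_moisture(params: KineticParams, m) -> float:
    """Invert the drying curve: the time (minutes) at which ``M(t) = m``.

    ``t = (1/k) ln[(m0 - me)/(m - me)]``.  Valid only for
    ``me < m <= m0``; equilibrium is approached asymptotically and is
    unreachable in finite time, so ``m <= me`` raises ``ValueError``, as does
    ``m > m0`` (moisture never exceeds its initial value during drying).
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= params.me):
        raise ValueError(
            f"target moisture {m} is at or below equilibrium {params.me}: "
            "unreachable in finite time"
        )
    if np.any(m > params.m0):
        raise ValueError(f"target moisture {m} exceeds initial moisture {params.m0}")
    out = np.log(params.driving_force / (m - params.me)) / params.k
    return out if out.ndim else float(out)
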