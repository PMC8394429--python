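"""Fick's-second-law sphere solution and the k <-> Deff bridge.

Treating the corn grain as a homogeneous sphere of radius ``a`` with constant
effective water diffusivity ``Deff``, the moisture ratio follows the Crank
series solution

    MR(t) = (6/pi^2) * sum_{n>=1} (1/n^2) exp(-Deff n^2 pi^2 t / a^2)

which satisfies MR(0) = 1 (Basel-sum normalisation).  Keeping only the first
term and matching its exponent to the empirical exponential model
``MR = exp(-k t)`` identifies

    Deff = k a^2 / pi^2        k = pi^2 Deff / a^2

so the fitted dynamical constant is directly proportional to the effective
diffusivity.  The "diffusivity rate" ``vk = dM/dk = -t (m0 - me) exp(-k t)``
measures the sensitivity of the drying curve to k; its magnitude peaks at
``t = 1/k``.

Units: time in minutes, Deff stored in m^2/min with an m^2/h view for
reporting, radius in meters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import polygamma

from .kinetics import KineticParams, _check_time, moisture_at_time

__all__ = [
    "GrainGeometry",
    "DiffusivityResult",
    "fick_series_mr",
    "one_term_mr",
    "deff_from_k",
    "k_from_deff",
    "moisture_via_deff",
    "diffusivity_rate",
    "vk_peak_time",
]

#: Average corn-grain radius, meters.
DEFAULT_RADIUS_M = 0.0049


@dataclass(frozen=True)
class GrainGeometry:
    """Spherical grain geometry: radius in meters (default 0.0049 m)."""

    radius_a: float = DEFAULT_RADIUS_M

    def __post_init__(self) -> None:
        if not self.radius_a > 0:
            raise ValueError(f"grain radius must be positive, got {self.radius_a}")


@dataclass(frozen=True)
class DiffusivityResult:
    """Effective diffusivity linked to a rate constant via Deff = k a^2 / pi^2.

    ``deff`` is stored in m^2 per minute; use :attr:`deff_m2_per_hour` for the
    conventional reporting unit.
    """

    deff: float  # m^2 / min
    k: float  # per minute
    radius_a: float  # meters

    def __post_init__(self) -> None:
        if not self.deff > 0:
            raise ValueError("effective diffusivity must be positive")

    @property
    def deff_m2_per_hour(self) -> float:
        return self.deff * 60.0


def fick_series_mr(deff: float, geom: GrainGeometry, t, n_terms: int = 200,
                   term_tol: float = 1e-12, tail_correction: bool = True):
    """Crank sphere-solution moisture ratio, truncated after ``n_terms`` terms.

    Parameters
    ----------
    deff : float
        Effective diffusivity, m^2 per minute (``deff >= 0``; zero means no
        diffusion, MR = 1 for all t).
    geom : GrainGeometry
        Sphere radius ``a``.
    t : scalar or array
        Time, minutes.
    n_terms : int
        Maximum number of series terms (default 200).
    term_tol : float
        Early exit once a term's largest magnitude over ``t`` drops below
        this (default 1e-12).
    tail_correction : bool
        Add the damped trigamma estimate of the truncated tail,
        ``exp(-(N+1)^2 tau) * psi_1(N+1)``, which makes the evaluation
        exactly normalized at t = 0 (the bare Basel partial sum at N terms
        undershoots 1 by ~ (6/pi^2)/N) and is exponentially negligible for
        t > 0 (default True).

    Returns
    -------
    Moisture ratio in [0, 1], decreasing in both ``t`` and ``deff``.
    """
    if n_terms < 1:
        raise ValueError(f"n_terms must be >= 1, got {n_terms}")
    if deff < 0:
        raise ValueError("diffusivity cannot be negative")
    t = _check_time(t)
    tau = deff * np.pi**2 * t / geom.radius_a**2  # dimensionless time
    acc = np.zeros_like(tau)
    n = 0
    for n in range(1, n_terms + 1):
        term = np.exp(-(n**2) * tau) / n**2
        acc = acc + term
        if np.max(term) < term_tol:
            break
    if tail_correction:
        acc = acc + np.exp(-((n + 1) ** 2) * tau) * polygamma(1, n + 1)
    out = (6.0 / np.pi**2) * acc
    return out if out.ndim else float(out)


def one_term_mr(deff: float, geom: GrainGeometry, t):
    """One-term reduction of the sphere series: ``(6/pi^2) exp(-Deff pi^2 t / a^2)``.

    Accurate late in drying (dimensionless time ``Deff pi^2 t/a^2`` of order
    one or larger); at t = 0 it returns 6/pi^2 ~ 0.6079 rather than 1.  Its
    logarithm is affine in t with slope ``-Deff pi^2/a^2 = -k``, which is the
    log-linear route to k.
    """
    t = _check_time(t)
    tau = deff * np.pi**2 * t / geom.radius_a**2
    out = (6.0 / np.pi**2) * np.exp(-tau)
    return out if out.ndim else float(out)


def deff_from_k(k: float, geom: GrainGeometry = GrainGeometry()) -> DiffusivityResult:
    """Effective diffusivity from the fitted rate constant: ``Deff = k a^2 / pi^2``."""
    if not k > 0:
        raise ValueError(f"rate constant must be positive, got {k}")
    return DiffusivityResult(deff=k * geom.radius_a**2 / np.pi**2, k=k,
                             radius_a=geom.radius_a)


def k_from_deff(deff: float, geom: GrainGeometry = GrainGeometry()) -> float:
    """Rate constant from effective diffusivity: ``k = pi^2 Deff / a^2`` (per min)."""
    if not deff > 0:
        raise ValueError(f"diffusivity must be positive, got {deff}")
    return float(np.pi**2 * deff / geom.radius_a**2)


def moisture_via_deff(m0: float, me: float, deff: float, geom: GrainGeometry, t):
    """Moisture curve parameterised by Deff instead of k (identical model)."""
    params = KineticParams(m0=m0, me=me, k=k_from_deff(deff, geom))
    return moisture_at_time(params, t)


def diffusivity_rate(params: KineticParams, t):
    """Diffusivity rate ``vk = dM/dk = -t (m0 - me) exp(-k t)`` (percent·minutes).

    Zero at t = 0, tends to zero as t -> infinity, and its magnitude attains
    a unique maximum at ``t = 1/k`` (see :func:`vk_peak_time`).
    """
    t = _check_time(t)
    out = -t * params.driving_force * np.exp(-params.k * t)
    return out if out.ndim else float(out)


def vk_peak_time(params: KineticParams) -> float:
    """Time (minutes) at which |vk| is maximal: analytically ``1/k``."""
    return 1.0 / params.k
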