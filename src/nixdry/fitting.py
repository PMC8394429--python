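"""Functional fitting interface over :class:`~nixdry.model.IsothermalDryingModel`.

Convenience routines to fit one trajectory, fit every steeping-time
condition of a dataset, and tabulate the derived initial dehydration rates.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Tuple

import pandas as pd

from .kinetics import KineticParams
from .model import (
    DryingFitResults,
    IsothermalDryingModel,
    MoistureSeries,
)

__all__ = ["fit_exponential", "fit_loglinear", "fit_all_st", "v0_series"]


def fit_exponential(series: MoistureSeries,
                    init: Optional[KineticParams] = None,
                    average_replicates: bool = True) -> DryingFitResults:
    """Nonlinear least-squares fit of (M0, ME, k) to one trajectory."""
    model = IsothermalDryingModel.from_series(
        series, average_replicates=average_replicates)
    return model.fit(init=init)


def fit_loglinear(series: MoistureSeries, me: float,
                  average_replicates: bool = True) -> Tuple[float, float]:
    """Log-linear slope estimate of k at a fixed ME.

    Returns ``(k, intercept)`` of the line through ``ln MR`` vs t; the slope
    magnitude is the k estimate.
    """
    model = IsothermalDryingModel.from_series(
        series, average_replicates=average_replicates)
    res = model.fit_loglinear(me)
    return res.k, res.intercept


def fit_all_st(dataset: Iterable[MoistureSeries] | Mapping[float, MoistureSeries],
               average_replicates: bool = True
               ) -> Dict[float, DryingFitResults]:
    """Fit every steeping-time condition; returns results keyed by ST (hours).

    Errors from individual series are re-raised tagged with the ST they
    belong to.
    """
    if isinstance(dataset, Mapping):
        series_list = list(dataset.values())
    else:
        series_list = list(dataset)
    if not series_list:
        raise ValueError("empty dataset: no steeping-time series to fit")
    out: Dict[float, DryingFitResults] = {}
    for series in series_list:
        try:
            out[series.st_h] = fit_exponential(
                series, average_replicates=average_replicates)
        except Exception as exc:
            raise type(exc)(f"ST={series.st_h} h: {exc}") from exc
    return out


def v0_series(fits: Mapping[float, DryingFitResults]) -> pd.DataFrame:
    """Initial dehydration rate ``v0 = -k (m0 - me)`` per steeping time."""
    rows = [
        {"st_h": st, "v0": res.v0, "m0": res.params.m0}
        for st, res in sorted(fits.items())
    ]
    return pd.DataFrame(rows, columns=["st_h", "v0", "m0"])


def fits_to_table(fits: Mapping[float, DryingFitResults]) -> pd.DataFrame:
    """Serializable fit table: one row per ST with k, ME, M0 and R²."""
    return pd.DataFrame([fits[st].to_record() for st in sorted(fits)])
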