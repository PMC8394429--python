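"""Optional matplotlib convenience plots (not part of the numeric surface)."""

from __future__ import annotations

import numpy as np

from .isolines import IsolineGrid
from .model import DryingFitResults


def plot_fit(results: DryingFitResults, ax=None):
    """Observed points and the fitted drying curve for one steeping time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = results.model.time_min
    ax.plot(t, results.model.moisture_pct, "ks", label="observed")
    tt = np.linspace(0, max(t.max(), 1.0), 400)
    ax.plot(tt, results.predict(tt), "r-", label="fit")
    ax.set_xlabel("drying time (min)")
    ax.set_ylabel("moisture (%)")
    st = results.st_h
    ax.set_title(f"ST = {st:g} h" if st is not None else "drying fit")
    ax.legend()
    return ax


def plot_isolines(grid: IsolineGrid, ax=None, levels=None):
    """Filled contour of a moisture or rate surface over (ST, drying time)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if levels is None:
        levels = grid.default_levels()
    cs = ax.contour(grid.st_axis, grid.t_axis, grid.values.T, levels=levels)
    ax.clabel(cs, inline=True, fontsize=7)
    ax.set_xlabel("steeping time (h)")
    ax.set_ylabel("drying time (min)")
    ax.set_title(f"{grid.quantity} isolines")
    return ax
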