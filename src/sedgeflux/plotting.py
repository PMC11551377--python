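"""Optional figures: normalized response curves and heat-wave flux series.

Requires matplotlib (``pip install sedgeflux[plot]``); the rest of the
package does not import it.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .chamber import EmissionObservation
from .megan import FluxSeries
from .response import Q10Fit


def plot_response_curve(
    fit: Q10Fit,
    obs: Sequence[EmissionObservation] | None = None,
    t_grid: np.ndarray | None = None,
    ax=None,
    label: str | None = None,
):
    """Normalized temperature-response curve with its 95% CI band.

    Curve and points are normalized to the fitted emission at the
    reference temperature, so the curve passes through 1 at t_ref.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if t_grid is None:
        t_grid = np.linspace(15.0, 45.0, 121)
    gamma = fit.gamma(t_grid)
    ax.plot(t_grid, gamma, label=label or f"Q10 = {fit.q10:.1f}")
    if np.isfinite(fit.q10_ci_low) and np.isfinite(fit.q10_ci_high):
        x = (t_grid - fit.t_ref) / 10.0
        lo = fit.q10_ci_low ** x
        hi = fit.q10_ci_high ** x
        ax.fill_between(t_grid, np.minimum(lo, hi), np.maximum(lo, hi), alpha=0.25)
    if obs is not None and fit.e_ref > 0:
        ax.scatter([o.t_leaf for o in obs],
                   [o.flux / fit.e_ref for o in obs], s=12, zorder=3)
    ax.set_xlabel("leaf temperature (°C)")
    ax.set_ylabel(f"emission normalized at {fit.t_ref:g} °C")
    ax.legend()
    return ax


def plot_flux_series(series_list: Sequence[FluxSeries], met=None, ax=None):
    """Flux time series for one or more species, optionally with air temperature.

    When ``met`` (a frame with timestamp/t_air) is given, air temperature
    is drawn on a twin right axis in degC.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    for fs in series_list:
        ax.plot(fs.timestamps, fs.flux, label=fs.species)
    ax.set_ylabel("isoprene flux (nmol m$^{-2}$ s$^{-1}$)")
    ax.legend(loc="upper left")
    if met is not None:
        ax2 = ax.twinx()
        ax2.plot(met["timestamp"], np.asarray(met["t_air"]) - 273.15,
                 color="tab:blue", alpha=0.4)
        ax2.set_ylabel("air temperature (°C)")
    return ax
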