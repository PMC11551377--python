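"""Leaf-scale MEGANv2.1-style isoprene emission model.

Flux on a ground-area basis is the product of a species emission factor
(leaf-area basis, standard conditions), leaf area index, and
dimensionless activity factors for light and temperature:

    F = EF * LAI * gamma_P(PPFD, P24, P240) * gamma_T(T, T24, T240)

The temperature activity is pluggable: either the MEGAN default (an
enzyme-kinetics form with an optimum temperature that acclimates to the
past 10 days) or a pure exponential Q10 response as measured for sedges.
Only gamma_T is swapped; the light response and its acclimation are kept
for both, because sedge isoprene emission is light-dependent (it falls
to ~zero in the dark, i.e. there is no storage pool).  The age, soil
moisture and CO2 activity factors of the full model are fixed at 1, leaf
temperature is taken equal to air temperature (met stations measure air
temperature), and no multi-layer canopy radiative transfer is applied —
the single-layer product above is the whole model.

Acclimation drivers are trailing means: T24/T240 of air temperature over
24 h/240 h, and P24/P240 of PPFD over *daytime* steps (PPFD > 0) in the
same windows.  At the start of a series the windows expand from one step
rather than discarding spin-up.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .response import DEFAULT_T_REF, gamma_exponential

log = logging.getLogger(__name__)

T0_CELSIUS = 273.15
#: PPFD per unit shortwave irradiance, umol J-1 (broadband daylight average).
PPFD_PER_SW = 2.1


@dataclass(frozen=True)
class MeganCoefficients:
    """Coefficients of the isoprene gamma_T / gamma_P closed forms.

    Values are the published MEGANv2.1 isoprene set (provenance is noted
    in shipped config files); override fields only for sensitivity
    studies.
    """

    c_t1: float = 95.0  #: kJ mol-1, activation energy of the rising limb
    c_t2: float = 230.0  #: kJ mol-1, deactivation energy of the falling limb
    gas_const: float = 0.00831  #: kJ mol-1 K-1
    eopt_base: float = 2.034  #: peak activity at standard acclimation
    topt_base: float = 313.0  #: K, optimum temperature at T240 = 297 K
    topt_slope: float = 0.6  #: K per K of T240 above 297 K
    p0_sun: float = 200.0  #: umol m-2 s-1, standard P24
    alpha_base: float = 0.004
    alpha_slope: float = 0.0005
    cp_base: float = 0.0468

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not self.c_t2 > self.c_t1:
            raise ValidationError("c_t2 must exceed c_t1")


@dataclass(frozen=True)
class SpeciesParams:
    """Emission factor, LAI and temperature-response choice for one species."""

    name: str
    emission_factor: float  #: nmol m-2 (leaf) s-1 at standard conditions
    lai: float  #: m2 leaf m-2 ground
    response: Literal["megan_default", "exponential"] = "megan_default"
    q10: float | None = None  #: required when response == "exponential"
    t_ref: float = DEFAULT_T_REF  #: degC, reference of the exponential response

    def __post_init__(self) -> None:
        if self.emission_factor < 0:
            raise ValidationError("emission_factor must be >= 0")
        if self.lai < 0:
            raise ValidationError("lai must be >= 0")
        if self.response == "exponential":
            if self.q10 is None or not self.q10 > 0:
                raise ValidationError(
                    f"exponential response requires q10 > 0, got {self.q10}")
        elif self.response != "megan_default":
            raise ValidationError(f"unknown response kind {self.response!r}")


ACCLIMATION_COLS = ("t24", "t240", "p24", "p240")


def rolling_acclimation(met: pd.DataFrame) -> pd.DataFrame:
    """Add trailing acclimation means t24/t240/p24/p240 to a raw met frame.

    ``met`` needs columns ``timestamp`` (strictly increasing, uniform
    step), ``t_air`` (K) and ``ppfd`` (umol m-2 s-1).  Windows shorter
    than nominal at the start of the series use all available data.
    P24/P240 are conditional means over daytime steps only; before the
    first daytime step they are 0 (no daylight history), which the light
    activity maps to zero emission.
    """
    for col in ("timestamp", "t_air", "ppfd"):
        if col not in met.columns:
            raise ValidationError(f"met series lacks column {col!r}")
    ts = pd.DatetimeIndex(met["timestamp"])
    if len(ts) > 1:
        steps = np.diff(ts.asi8)
        if (steps <= 0).any() or np.unique(steps).size != 1:
            raise ValidationError("timestamps must be strictly increasing with a uniform step")
        step_minutes = steps[0] / 60e9
    else:
        step_minutes = None

    out = met.copy()
    if not (out["t_air"] > 0).all():
        raise ValidationError("t_air must be positive (kelvin)")
    if (out["ppfd"] < 0).any():
        raise ValidationError("ppfd must be >= 0")

    def windowed(series: pd.Series, hours: float) -> pd.Series:
        if step_minutes is None:
            window = 1
        else:
            window = max(int(round(hours * 60 / step_minutes)), 1)
        return series.rolling(window=window, min_periods=1).mean()

    day = out["ppfd"] > 0
    ppfd_day = out["ppfd"].where(day)  # NaN at night -> excluded from the mean
    for hours, t_col, p_col in ((24.0, "t24", "p24"), (240.0, "t240", "p240")):
        out[t_col] = windowed(out["t_air"], hours)
        out[p_col] = windowed(ppfd_day, hours).fillna(0.0)
    return out


def gamma_t_megan(t_leaf, t24, t240, coef: MeganCoefficients = MeganCoefficients()):
    """MEGAN default temperature activity (temperatures in K).

    An enzyme-kinetics peak: activity rises with leaf temperature up to
    an optimum Topt and collapses above it.  Both the optimum and the
    peak height acclimate to the trailing 24-h and 240-h mean
    temperatures, so recently warm conditions raise and shift the
    response.  Equals ~1 at standard conditions (303 K leaf, 297 K
    acclimation).
    """
    t_leaf = np.asarray(t_leaf, dtype=float)
    t24 = np.asarray(t24, dtype=float)
    t240 = np.asarray(t240, dtype=float)
    if (t_leaf <= 0).any() or (t24 <= 0).any() or (t240 <= 0).any():
        raise ValidationError("temperatures must be in kelvin and positive")
    topt = coef.topt_base + coef.topt_slope * (t240 - 297.0)
    eopt = coef.eopt_base * np.exp(0.05 * (t24 - 297.0)) * np.exp(0.05 * (t240 - 297.0))
    x = (1.0 / topt - 1.0 / t_leaf) / coef.gas_const
    # exp args bounded: c_t2 * x <= c_t2/(gas_const*topt) ~ 9e3 would overflow
    e1 = np.exp(np.minimum(coef.c_t1 * x, 700.0))
    e2 = np.exp(np.minimum(coef.c_t2 * x, 700.0))
    out = eopt * coef.c_t2 * e1 / (coef.c_t2 - coef.c_t1 * (1.0 - e2))
    return out if out.ndim else float(out)


def gamma_p(ppfd, p24, p240, coef: MeganCoefficients = MeganCoefficients()):
    """MEGAN light activity: saturating response with acclimating gain.

    alpha (initial slope) and C_P (saturation level) depend on the
    trailing daytime PPFD means; the response is C_P * alpha * PPFD /
    sqrt(1 + alpha^2 PPFD^2), zero in the dark.  Steps with no daylight
    history (P240 = 0) return 0 rather than evaluating ln(0).
    """
    ppfd = np.asarray(ppfd, dtype=float)
    p24 = np.asarray(p24, dtype=float)
    p240 = np.asarray(p240, dtype=float)
    if (ppfd < 0).any() or (p24 < 0).any() or (p240 < 0).any():
        raise ValidationError("light inputs must be >= 0")
    lit = p240 > 0
    if not lit.all():
        log.info("gamma_p: %d steps with no daylight history (p240=0) -> activity 0",
                 int(np.sum(~lit)))
    safe_p240 = np.where(lit, p240, 1.0)
    alpha = coef.alpha_base - coef.alpha_slope * np.log(safe_p240)
    c_p = coef.cp_base * np.exp(coef.alpha_slope * (p24 - coef.p0_sun)) * safe_p240 ** 0.6
    out = np.where(lit, c_p * alpha * ppfd / np.sqrt(1.0 + alpha ** 2 * ppfd ** 2), 0.0)
    return out if out.ndim else float(out)


def _gamma_t_for_species(species: SpeciesParams, t_air_k, t24, t240,
                         coef: MeganCoefficients):
    if species.response == "exponential":
        return gamma_exponential(np.asarray(t_air_k, dtype=float) - T0_CELSIUS,
                                 species.q10, species.t_ref)
    return gamma_t_megan(t_air_k, t24, t240, coef)


def leaf_flux(species: SpeciesParams, step, coef: MeganCoefficients = MeganCoefficients()) -> float:
    """Ground-area flux (nmol m-2 s-1) for one met record (with acclimation fields)."""
    g_p = gamma_p(step["ppfd"], step["p24"], step["p240"], coef)
    g_t = _gamma_t_for_species(species, step["t_air"], step["t24"], step["t240"], coef)
    return float(species.emission_factor * species.lai * g_p * g_t)


@dataclass
class FluxSeries:
    """Modelled ground-area flux time series for one species."""

    data: pd.DataFrame  #: columns timestamp, flux
    species: str
    response: str

    @property
    def timestamps(self) -> pd.Series:
        return self.data["timestamp"]

    @property
    def flux(self) -> pd.Series:
        return self.data["flux"]


def simulate_flux_series(
    species: SpeciesParams,
    met: pd.DataFrame,
    coef: MeganCoefficients = MeganCoefficients(),
) -> FluxSeries:
    """Drive the leaf model through a met series (vectorized, deterministic).

    ``met`` must carry the acclimation columns produced by
    :func:`rolling_acclimation`; the output is aligned 1:1 with its
    timestamps.
    """
    missing = [c for c in ACCLIMATION_COLS if c not in met.columns]
    if missing:
        raise ValidationError(
            f"met series lacks acclimation columns {missing}; run rolling_acclimation first")
    g_p = gamma_p(met["ppfd"].to_numpy(), met["p24"].to_numpy(),
                  met["p240"].to_numpy(), coef)
    g_t = _gamma_t_for_species(species, met["t_air"].to_numpy(),
                               met["t24"].to_numpy(), met["t240"].to_numpy(), coef)
    flux = species.emission_factor * species.lai * g_p * g_t
    data = pd.DataFrame({"timestamp": met["timestamp"].to_numpy(), "flux": flux})
    data.attrs.update(met.attrs)
    return FluxSeries(data=data, species=species.name, response=species.response)
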