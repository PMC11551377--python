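"""Synthetic chamber series and meteorological forcing with known structure.

Two generators back the test surface of the whole pipeline:

* :func:`gen_chamber_series` draws equilibrium leaf-chamber observations
  from a known exponential Q10 curve, E(T) = E_ref * Q10**((T - 30)/10),
  with multiplicative lognormal noise.  The lognormal is mean-one, so the
  noiseless expectation of every point sits exactly on the curve and the
  coefficient of variation equals ``noise_cv``.

* :func:`gen_met_series` builds a regular meteorological series with a
  sinusoidal diurnal temperature cycle and a half-sinusoid daylight PPFD
  cycle, split into a baseline block followed by a heat-wave block in
  which a constant temperature boost is added over whole days.  The
  additive boost makes the expected flux change under an exponential
  temperature response analytically computable: the heat-wave/baseline
  flux ratio is exactly Q10**(boost/10).

Temperature peaks at 15:00 and PPFD at 12:00 local time (daylight 06:00
to 18:00), mimicking the early-afternoon co-occurrence of heat and light
in real forcing.  No humidity, wind, or soil moisture is generated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chamber import EmissionObservation
from .errors import ValidationError


@dataclass(frozen=True)
class ChamberSimConfig:
    """Design of a simulated temperature-ramp chamber experiment.

    Defaults emulate a leaf-chamber temperature ramp: a sedge-like
    Q10 of 8, 2 nmol m-2 s-1 at the 30 degC reference, 20-45 degC
    sweep under saturating constant light, and 5% proportional noise.
    """

    true_q10: float = 8.0
    e_ref: float = 2.0  #: emission at 30 degC, nmol m-2 s-1
    t_min: float = 20.0  #: degC
    t_max: float = 45.0  #: degC
    n_points: int = 30
    noise_cv: float = 0.05  #: lognormal coefficient of variation
    ppfd: float = 1000.0  #: umol m-2 s-1, held constant
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_q10 > 0:
            raise ValidationError(f"true_q10 must be > 0, got {self.true_q10}")
        if self.e_ref < 0:
            raise ValidationError(f"e_ref must be >= 0, got {self.e_ref}")
        if not self.t_min < self.t_max:
            raise ValidationError(
                f"t_min must be < t_max, got [{self.t_min}, {self.t_max}]")
        if self.noise_cv < 0:
            raise ValidationError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.n_points < 2:
            raise ValidationError(f"n_points must be >= 2, got {self.n_points}")


@dataclass(frozen=True)
class MetSimConfig:
    """Design of a synthetic baseline + heat-wave meteorological series.

    Defaults sketch a warm-season urban site: 295 K (22 degC) daily
    mean, 7 K diurnal amplitude, an 8 K heat-wave boost, and a midday
    PPFD peak of 1500 umol m-2 s-1 — magnitudes typical of a southern
    California late summer rather than a fit to any particular record.
    """

    n_days_baseline: int = 10
    n_days_heatwave: int = 5
    t_mean_baseline: float = 295.0  #: K
    t_amplitude: float = 7.0  #: K, half peak-to-trough
    t_boost_heatwave: float = 8.0  #: K, added uniformly during the heat wave
    ppfd_max: float = 1500.0  #: umol m-2 s-1
    timestep: int = 30  #: minutes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days_baseline < 1:
            raise ValidationError(
                f"n_days_baseline must be >= 1, got {self.n_days_baseline}")
        if self.n_days_heatwave < 1:
            raise ValidationError(
                f"n_days_heatwave must be >= 1, got {self.n_days_heatwave}")
        if self.t_boost_heatwave < 0:
            raise ValidationError(
                f"t_boost_heatwave must be >= 0, got {self.t_boost_heatwave}")
        if self.ppfd_max < 0:
            raise ValidationError(f"ppfd_max must be >= 0, got {self.ppfd_max}")
        if not (self.timestep > 0 and 1440 % self.timestep == 0):
            raise ValidationError(
                f"timestep must divide 24 h evenly, got {self.timestep} min")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    # mu = -sigma^2/2 makes E[factor] = 1 so noisy points scatter around the curve
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def expected_chamber_flux(t_leaf: np.ndarray | float, cfg: ChamberSimConfig) -> np.ndarray | float:
    """Noiseless expectation E_ref * Q10**((T - 30)/10) of the simulated flux."""
    return cfg.e_ref * cfg.true_q10 ** ((np.asarray(t_leaf, dtype=float) - 30.0) / 10.0)


def gen_chamber_series(cfg: ChamberSimConfig) -> list[EmissionObservation]:
    """Simulate a chamber temperature ramp as independent equilibrium points.

    Leaf temperatures are evenly spaced on [t_min, t_max]; each flux is the
    on-curve expectation times an independent mean-one lognormal factor.
    Identical configs (including seed) give bit-identical series.
    """
    rng = np.random.default_rng(cfg.seed)
    t_leaf = np.linspace(cfg.t_min, cfg.t_max, cfg.n_points)
    flux = expected_chamber_flux(t_leaf, cfg) * _lognormal_factors(rng, cfg.noise_cv, cfg.n_points)
    return [
        EmissionObservation(t_leaf=float(t), ppfd=cfg.ppfd, flux=float(f))
        for t, f in zip(t_leaf, flux)
    ]


#: Local solar hour at which PPFD rises from / falls to zero.
DAWN_HOUR, DUSK_HOUR = 6.0, 18.0
#: Local solar hour of the daily temperature maximum.
T_PEAK_HOUR = 15.0


def gen_met_series(cfg: MetSimConfig, start: str = "2022-08-15") -> pd.DataFrame:
    """Generate a regular met series: baseline days then heat-wave days.

    Returns a DataFrame with columns ``timestamp`` (regular step),
    ``t_air`` (K) and ``ppfd`` (umol m-2 s-1), and attrs
    ``heatwave_start``/``heatwave_end`` marking the half-open heat-wave
    interval.  Temperature is a sinusoid peaking at 15:00; PPFD is a
    half-sinusoid over 06:00-18:00 peaking at solar noon, zero at night.
    """
    n_days = cfg.n_days_baseline + cfg.n_days_heatwave
    steps_per_day = 1440 // cfg.timestep
    ts = pd.date_range(start=start, periods=n_days * steps_per_day,
                       freq=f"{cfg.timestep}min")
    hours = ts.hour + ts.minute / 60.0

    t_air = cfg.t_mean_baseline + cfg.t_amplitude * np.cos(
        2 * np.pi * (hours - T_PEAK_HOUR) / 24.0)
    hw_start = ts[cfg.n_days_baseline * steps_per_day]
    in_heatwave = ts >= hw_start
    t_air = np.where(in_heatwave, t_air + cfg.t_boost_heatwave, t_air)

    day_frac = (hours - DAWN_HOUR) / (DUSK_HOUR - DAWN_HOUR)
    ppfd = np.where((day_frac > 0) & (day_frac < 1),
                    cfg.ppfd_max * np.sin(np.pi * np.clip(day_frac, 0, 1)), 0.0)

    met = pd.DataFrame({"timestamp": ts, "t_air": t_air, "ppfd": ppfd})
    met.attrs["heatwave_start"] = hw_start
    met.attrs["heatwave_end"] = ts[-1] + ts.freq
    return met
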