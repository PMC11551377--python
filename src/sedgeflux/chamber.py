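"""Leaf-chamber mass balance: mixing-ratio differences to area-based emission rates.

A flow-through chamber encloses a leaf of known one-sided area.  The
emission rate follows from the isoprene mixing-ratio difference between
chamber outlet and inlet, the molar flow of air through the chamber, and
the leaf area:

    F = (chi_out - chi_in) * n_dot / A

with n_dot = P * V_dot / (R * T_gas) from the ideal gas law at the
*recorded* gas temperature and pressure, not STP — assuming standard
conditions silently introduces errors of several percent.  Mixing ratios
are mole fractions (ppbv), so the 1e-9 from ppbv and the 1e9 to nmol
cancel and F comes out directly in nmol m-2 s-1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314

#: L min-1 -> m3 s-1.
LPM_TO_M3S = 1e-3 / 60.0


@dataclass(frozen=True)
class EmissionObservation:
    """One leaf-level emission point: temperature, light, flux."""

    t_leaf: float  #: leaf temperature, degC
    ppfd: float  #: photosynthetic photon flux density, umol m-2 s-1
    flux: float  #: isoprene emission rate, nmol m-2 s-1 (leaf area basis)

    def __post_init__(self) -> None:
        if self.ppfd < 0:
            raise ValidationError(f"ppfd must be >= 0, got {self.ppfd}")
        if not pd.notna(self.flux) or abs(self.flux) == float("inf"):
            raise ValidationError(f"flux must be finite, got {self.flux}")


@dataclass(frozen=True)
class ChamberRecord:
    """One raw flow-through chamber measurement."""

    timestamp: object
    t_leaf: float  #: degC
    ppfd: float  #: umol m-2 s-1
    chi_in: float  #: inlet isoprene mixing ratio, ppbv
    chi_out: float  #: outlet isoprene mixing ratio, ppbv
    flow: float  #: volumetric flow at t_gas/pressure, L min-1
    t_gas: float = 298.15  #: gas temperature, K
    pressure: float = 101325.0  #: Pa
    leaf_area: float = 0.01  #: enclosed one-sided leaf area, m2
    background: float = 0.0  #: optional empty-chamber offset subtracted from (chi_out - chi_in), ppbv

    def __post_init__(self) -> None:
        for name in ("flow", "leaf_area", "pressure", "t_gas"):
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(f"{name} must be > 0, got {value}")


def molar_flow(rec: ChamberRecord) -> float:
    """Molar air flow through the chamber, mol s-1 (ideal gas at recorded T, P)."""
    return rec.pressure * rec.flow * LPM_TO_M3S / (R_GAS * rec.t_gas)


def compute_emission_rate(rec: ChamberRecord) -> EmissionObservation:
    """Convert one chamber record into an area-based emission rate.

    Negative fluxes (outlet below inlet, i.e. apparent uptake or
    depletion) are retained with a logged warning rather than clamped;
    downstream fitting excludes non-positive fluxes itself.
    """
    delta_chi = rec.chi_out - rec.chi_in - rec.background
    flux = delta_chi * molar_flow(rec) / rec.leaf_area
    if delta_chi < 0:
        log.warning(
            "chamber record %s: chi_out < chi_in (delta=%.3f ppbv); "
            "keeping negative flux %.4f nmol m-2 s-1",
            rec.timestamp, delta_chi, flux,
        )
    return EmissionObservation(t_leaf=rec.t_leaf, ppfd=rec.ppfd, flux=flux)


def compute_emission_rates(records: Iterable[ChamberRecord]) -> list[EmissionObservation]:
    """Vector convenience wrapper over :func:`compute_emission_rate`."""
    return [compute_emission_rate(r) for r in records]


def observations_to_frame(obs: Sequence[EmissionObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {"t_leaf": [o.t_leaf for o in obs],
         "ppfd": [o.ppfd for o in obs],
         "flux": [o.flux for o in obs]}
    )


def frame_to_observations(df: pd.DataFrame) -> list[EmissionObservation]:
    return [
        EmissionObservation(t_leaf=row.t_leaf, ppfd=row.ppfd, flux=row.flux)
        for row in df.itertuples(index=False)
    ]
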