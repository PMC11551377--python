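"""Period segmentation and summary statistics for modelled flux series.

Splits a flux series into labelled periods (e.g. pre-heat-wave vs
heat-wave), computes per-period means and maxima, the percent change in
mean flux between periods, and cross-species ratios over a shared
period.  Periods are half-open intervals [start, end) in the series'
local time, so every step belongs to exactly one of two adjacent
periods.  Statistics run over all steps by default; a daytime-only
restriction (PPFD > 0) is available since night steps contribute zeros
for a light-dependent emitter.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyPeriodError, ValidationError
from .megan import FluxSeries


@dataclass(frozen=True)
class Period:
    """Half-open time interval [start, end) with a label."""

    label: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not self.start < self.end:
            raise ValidationError(
                f"period {self.label!r}: start {self.start} must precede end {self.end}")

    def mask(self, timestamps: pd.Series) -> pd.Series:
        ts = pd.to_datetime(timestamps)
        return (ts >= self.start) & (ts < self.end)


@dataclass(frozen=True)
class PeriodSummary:
    """Mean and maximum flux over the steps of one period."""

    label: str
    mean_flux: float  #: nmol m-2 s-1
    max_flux: float  #: nmol m-2 s-1
    n_steps: int


def summarize_period(
    flux: FluxSeries, period: Period, *, daytime_ppfd: pd.Series | None = None
) -> PeriodSummary:
    """Arithmetic mean and maximum of flux over steps inside the period.

    Pass the driving PPFD series as ``daytime_ppfd`` to restrict the
    statistics to daytime steps (PPFD > 0).
    """
    mask = period.mask(flux.timestamps)
    if daytime_ppfd is not None:
        mask &= np.asarray(daytime_ppfd) > 0
    values = flux.flux[mask.to_numpy()]
    if values.empty:
        raise EmptyPeriodError(
            f"no flux steps inside period {period.label!r} "
            f"[{period.start}, {period.end})")
    return PeriodSummary(label=period.label,
                         mean_flux=float(values.mean()),
                         max_flux=float(values.max()),
                         n_steps=int(values.size))


def percent_change(before: PeriodSummary, during: PeriodSummary) -> float:
    """Percent change in mean flux from ``before`` to ``during``.

    +320% means the mean quadrupled and change is undefined for a zero
    baseline.
    """
    if not before.mean_flux > 0:
        raise ValidationError(
            f"percent change undefined: baseline mean of {before.label!r} "
            f"is {before.mean_flux}")
    return 100.0 * (during.mean_flux - before.mean_flux) / before.mean_flux


def species_comparison(a: FluxSeries, b: FluxSeries, period: Period) -> dict[str, float]:
    """Compare two species' fluxes over one period on identical timestamps.

    Returns ``mean_ratio_pct`` (mean of a as a percentage of mean of b)
    and ``peak_excess_pct`` (how much higher a's maximum is than b's, in
    percent; negative when a peaks lower).
    """
    ts_a = pd.to_datetime(a.timestamps).reset_index(drop=True)
    ts_b = pd.to_datetime(b.timestamps).reset_index(drop=True)
    if len(ts_a) != len(ts_b) or not ts_a.equals(ts_b):
        raise AlignmentError(
            f"flux series {a.species!r} and {b.species!r} are not on identical timestamps")
    sum_a = summarize_period(a, period)
    sum_b = summarize_period(b, period)
    if sum_b.mean_flux == 0 or sum_b.max_flux == 0:
        raise ValidationError(
            f"comparison undefined: {b.species!r} has zero mean or peak in {period.label!r}")
    return {
        "mean_ratio_pct": 100.0 * sum_a.mean_flux / sum_b.mean_flux,
        "peak_excess_pct": 100.0 * (sum_a.max_flux - sum_b.max_flux) / sum_b.max_flux,
    }


def default_periods(met: pd.DataFrame) -> tuple[Period, Period]:
    """Baseline/heat-wave periods from the markers a synthetic met series carries."""
    hw_start = met.attrs.get("heatwave_start")
    hw_end = met.attrs.get("heatwave_end")
    if hw_start is None or hw_end is None:
        raise ValidationError("met series carries no heat-wave markers; supply periods explicitly")
    first = pd.Timestamp(np.asarray(met["timestamp"])[0])
    return (Period("baseline", first, hw_start),
            Period("heatwave", hw_start, hw_end))
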