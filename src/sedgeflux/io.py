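"""CSV/YAML/JSON input-output and the end-to-end pipeline.

Readers normalize units on the way in (temperatures to kelvin, light to
PPFD in umol m-2 s-1) so the modelling code never sees mixed units.
The met reader tolerates the MesoWest export dialect: leading ``#``
station-header lines, a named timestamp column, and temperature in
either degC or K as declared in the file config.  Every pipeline output
directory receives an echo of the exact configuration that produced it.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .chamber import (ChamberRecord, EmissionObservation, compute_emission_rates,
                      frame_to_observations, observations_to_frame)
from .errors import ConfigError, ValidationError
from .heatwave import Period, default_periods, percent_change, species_comparison, summarize_period
from .megan import (PPFD_PER_SW, FluxSeries, MeganCoefficients, SpeciesParams,
                    rolling_acclimation, simulate_flux_series)
from .response import Q10Fit, fit_q10
from .synthetic import ChamberSimConfig, MetSimConfig, gen_chamber_series, gen_met_series

log = logging.getLogger(__name__)

CHAMBER_COLUMNS = ["timestamp", "t_leaf", "ppfd", "chi_in", "chi_out",
                   "flow", "t_gas", "pressure", "leaf_area"]


# ---------------------------------------------------------------- chamber I/O

def read_chamber_csv(path: str | Path) -> list[ChamberRecord]:
    """Read raw chamber records; one row per record, header-named columns."""
    df = pd.read_csv(path)
    missing = [c for c in CHAMBER_COLUMNS if c not in df.columns and c != "timestamp"]
    if missing:
        raise ConfigError(f"{path}: chamber CSV lacks columns {missing}")
    kwargs_extra = ["background"] if "background" in df.columns else []
    return [
        ChamberRecord(**{c: row[c] for c in CHAMBER_COLUMNS + kwargs_extra if c in df.columns})
        for _, row in df.iterrows()
    ]


def write_observations_csv(obs, path: str | Path) -> None:
    observations_to_frame(obs).to_csv(path, index=False)


def read_observations_csv(path: str | Path) -> list[EmissionObservation]:
    return frame_to_observations(pd.read_csv(path))


# -------------------------------------------------------------------- met I/O

def read_met_csv(path: str | Path, config: Mapping[str, Any] | None = None) -> pd.DataFrame:
    """Read and unit-normalize a meteorological CSV.

    ``config`` keys (all optional):

    * ``timestamp_column`` / ``temperature_column`` / ``light_column`` —
      column names (defaults ``timestamp``, ``t_air``, ``ppfd``);
    * ``units.temperature`` — ``"K"`` or ``"C"`` (default ``"K"``);
    * ``units.light`` — ``"ppfd"`` (umol m-2 s-1) or ``"shortwave"``
      (W m-2, converted at 2.1 umol J-1);
    * ``ppfd_per_sw`` — override the conversion constant.

    Rows with missing values are dropped and counted; duplicated or
    non-monotonic timestamps raise.  Lines starting with ``#`` (MesoWest
    station headers) are skipped.
    """
    config = dict(config or {})
    ts_col = config.get("timestamp_column", "timestamp")
    t_col = config.get("temperature_column", "t_air")
    p_col = config.get("light_column", "ppfd")
    units = dict(config.get("units", {}))
    t_unit = str(units.get("temperature", "K")).upper()
    p_unit = str(units.get("light", "ppfd")).lower()
    if t_unit not in {"K", "C"}:
        raise ConfigError(f"unknown temperature unit {t_unit!r} (use 'K' or 'C')")
    if p_unit not in {"ppfd", "shortwave"}:
        raise ConfigError(f"unknown light unit {p_unit!r} (use 'ppfd' or 'shortwave')")

    df = pd.read_csv(path, comment="#")
    for col in (ts_col, t_col, p_col):
        if col not in df.columns:
            raise ConfigError(f"{path}: met CSV lacks column {col!r}")

    n_raw = len(df)
    df = df[[ts_col, t_col, p_col]].dropna()
    n_dropped = n_raw - len(df)
    if n_dropped:
        log.info("read_met_csv: dropped %d rows with missing values", n_dropped)

    ts = pd.to_datetime(df[ts_col])
    dup = ts[ts.duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicated timestamp {dup.iloc[0]} in {path}")
    if not ts.is_monotonic_increasing:
        raise ValidationError(f"timestamps in {path} are not monotonically increasing")
    if len(ts) > 1:
        gaps = ts.diff().dropna()
        if gaps.nunique() > 1:
            log.warning("read_met_csv: %d gaps in %s (largest %s)",
                        int((gaps > gaps.mode().iloc[0]).sum()), path, gaps.max())

    t_air = df[t_col].astype(float)
    if t_unit == "C":
        t_air = t_air + 273.15
    light = df[p_col].astype(float)
    if p_unit == "shortwave":
        light = light * float(config.get("ppfd_per_sw", PPFD_PER_SW))

    out = pd.DataFrame({"timestamp": ts.to_numpy(), "t_air": t_air.to_numpy(),
                        "ppfd": light.clip(lower=0.0).to_numpy()})
    out.attrs["n_dropped"] = n_dropped
    return out


def write_met_csv(met: pd.DataFrame, path: str | Path) -> None:
    met[["timestamp", "t_air", "ppfd"]].to_csv(path, index=False)


def write_flux_csv(series: FluxSeries, path: str | Path) -> None:
    df = series.data.copy()
    df.insert(1, "species", series.species)
    df.to_csv(path, index=False)


def write_fit_report(fit: Q10Fit, path: str | Path, *, t_grid: tuple[float, float, int] = (15, 45, 61)) -> None:
    """JSON fit report: parameters, CI, counts, and the normalized curve on a grid."""
    import numpy as np
    grid = np.linspace(*t_grid[:2], int(t_grid[2]))
    report = dataclasses.asdict(fit)
    report["curve"] = {"t_leaf": grid.tolist(),
                       "gamma": [float(g) for g in fit.gamma(grid)]}
    Path(path).write_text(json.dumps(report, indent=2))


# ------------------------------------------------------------------- pipeline

def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level of config must be a mapping")
    return cfg


def _species_from_config(entry: Mapping[str, Any]) -> SpeciesParams:
    return SpeciesParams(**entry)


def _periods_from_config(entries) -> list[Period]:
    return [Period(e["label"], e["start"], e["end"]) for e in entries]


def run_pipeline(config: Mapping[str, Any], output_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write all artefacts.

    Stage order: chamber -> fit -> met -> flux simulation -> period
    analysis.  Each stage is skippable: omit ``chamber``/``fit`` if
    species carry their Q10 directly, omit ``met`` to stop after the
    fit.  Returns the report dict (also written to ``report.json``),
    with an echo of the configuration and all seeds under ``"config"``.
    """
    config = dict(config)
    out_dir = Path(output_dir or config.get("output_dir", "sedgeflux_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict[str, Any] = {"version": __version__, "seed": seed, "config": config}

    # --- chamber stage -------------------------------------------------
    obs = None
    chamber_cfg = config.get("chamber")
    if chamber_cfg:
        if "path" in chamber_cfg:
            records = read_chamber_csv(chamber_cfg["path"])
            obs = compute_emission_rates(records)
        elif "simulate" in chamber_cfg:
            sim = ChamberSimConfig(**{"seed": seed, **chamber_cfg["simulate"]})
            obs = gen_chamber_series(sim)
        else:
            raise ConfigError("chamber stage needs 'path' or 'simulate'")
        write_observations_csv(obs, out_dir / "observations.csv")

    # --- fit stage -----------------------------------------------------
    fit = None
    fit_cfg = dict(config.get("fit", {}))
    if obs is not None:
        fit = fit_q10(obs,
                      t_ref=fit_cfg.get("t_ref", 30.0),
                      t_fit_max=fit_cfg.get("t_fit_max", 35.0),
                      method=fit_cfg.get("method", "ols"),
                      ci_method=fit_cfg.get("ci_method", "normal"),
                      n_boot=int(fit_cfg.get("n_boot", 1000)),
                      seed=seed)
        write_fit_report(fit, out_dir / "fit_report.json")
        report["fit"] = {k: v for k, v in dataclasses.asdict(fit).items()}

    # --- met stage -----------------------------------------------------
    met = None
    met_cfg = config.get("met")
    if met_cfg:
        if "path" in met_cfg:
            met = read_met_csv(met_cfg["path"], met_cfg)
        elif "simulate" in met_cfg:
            met = gen_met_series(MetSimConfig(**{"seed": seed, **met_cfg["simulate"]}))
        else:
            raise ConfigError("met stage needs 'path' or 'simulate'")
        met = rolling_acclimation(met)
        trim_days = float(config.get("trim_spinup_days", 0))
        if trim_days:
            cutoff = pd.DatetimeIndex(met["timestamp"])[0] + pd.Timedelta(days=trim_days)
            met = met[met["timestamp"] >= cutoff].reset_index(drop=True)
        write_met_csv(met, out_dir / "met.csv")

    # --- flux + analysis stages ----------------------------------------
    if met is not None:
        coef = MeganCoefficients(**config.get("megan_overrides", {}))
        species_entries = config.get("species") or []
        if not species_entries:
            raise ConfigError("met stage configured but no species to simulate")
        flux_by_species: dict[str, FluxSeries] = {}
        for entry in species_entries:
            entry = dict(entry)
            if entry.get("response") == "exponential" and entry.get("q10") is None and fit is not None:
                entry["q10"] = fit.q10  # fitted response feeds the model
            sp = _species_from_config(entry)
            series = simulate_flux_series(sp, met, coef)
            flux_by_species[sp.name] = series
            write_flux_csv(series, out_dir / f"flux_{sp.name}.csv")

        if "periods" in config:
            periods = _periods_from_config(config["periods"])
        else:
            periods = list(default_periods(met))
        daytime = met["ppfd"] if config.get("daytime_only") else None

        summaries: dict[str, Any] = {}
        for name, series in flux_by_species.items():
            per = {p.label: summarize_period(series, p, daytime_ppfd=daytime)
                   for p in periods}
            entry = {label: dataclasses.asdict(s) for label, s in per.items()}
            if len(periods) == 2:
                entry["percent_change"] = percent_change(per[periods[0].label],
                                                         per[periods[1].label])
            summaries[name] = entry
        if len(flux_by_species) == 2 and len(periods) >= 2:
            a, b = flux_by_species.values()
            summaries["comparison"] = {
                "a": a.species, "b": b.species,
                **species_comparison(a, b, periods[-1]),
            }
        report["analysis"] = summaries

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out_dir / "config_echo.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    log.info("pipeline complete; artefacts in %s", out_dir)
    return report
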