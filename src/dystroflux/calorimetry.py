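"""Indirect-calorimetry analysis of metabolic-cage gas-exchange traces.

Converts VO2/VCO2/activity/feeder time series recorded in an open-circuit
calorimetry cage into per-animal energy budgets: total and phase-specific
energy expenditure (Weir equation), resting energy expenditure (lowest
90-s readings extrapolated to 24 h), respiratory quotient, spillage-
corrected energy intake, and energy balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .reference import (
    DIET_KCAL_PER_G,
    LIGHT_OFF,
    LIGHT_ON,
    WEIR_KCAL_PER_L_CO2,
    WEIR_KCAL_PER_L_O2,
)

__all__ = [
    "GasExchangeTrace",
    "EnergyBudget",
    "weir_ee",
    "summarize_trace",
    "resting_ee",
    "summarize_activity",
]

TRACE_COLUMNS = [
    "timestamp", "vo2_ml_h", "vco2_ml_h", "x_counts", "z_counts",
    "feeder_g", "spill_g",
]

#: Number of 90-s periods in 24 h; the resting-EE extrapolation factor.
PERIODS_90S_PER_DAY = 960


class TraceValidationError(ValueError):
    """A gas-exchange trace violates a structural invariant."""


def weir_ee(vo2_l, vco2_l):
    """Energy expenditure from gas exchange by the abbreviated Weir equation.

    Parameters
    ----------
    vo2_l, vco2_l : float or array-like
        Oxygen consumed and carbon dioxide produced over the period,
        in litres.

    Returns
    -------
    float or ndarray
        kcal expended over the same period:
        ``3.941·VO2 + 1.106·VCO2`` (no urinary-nitrogen term).
    """
    vo2 = np.asarray(vo2_l, dtype=float)
    vco2 = np.asarray(vco2_l, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas volumes must be non-negative")
    out = WEIR_KCAL_PER_L_O2 * vo2 + WEIR_KCAL_PER_L_CO2 * vco2
    return float(out) if out.ndim == 0 else out


@dataclass
class GasExchangeTrace:
    """One animal-cage session of uniformly sampled gas exchange.

    ``data`` columns: timestamp (datetime), vo2_ml_h, vco2_ml_h (mL/h
    instantaneous rates), x_counts, z_counts (beam breaks per epoch),
    feeder_g, spill_g (cumulative masses, g), and optionally a boolean
    ``refill`` column flagging feeder refill events.
    """

    animal_id: str
    data: pd.DataFrame
    epoch_s: int
    light_on: int = LIGHT_ON
    light_off: int = LIGHT_OFF

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise TraceValidationError(f"trace is missing columns {missing}")
        ts = pd.to_datetime(df["timestamp"])
        if len(ts) < 2:
            raise TraceValidationError("trace needs at least two readings")
        deltas = ts.diff().dropna().dt.total_seconds().to_numpy()
        if np.any(deltas <= 0):
            raise TraceValidationError("timestamps must be strictly increasing")
        if not np.allclose(deltas, self.epoch_s):
            raise TraceValidationError(
                f"timestamps must be uniformly spaced at {self.epoch_s} s"
            )
        for col in ("vo2_ml_h", "vco2_ml_h"):
            bad = np.flatnonzero(df[col].to_numpy() < 0)
            if bad.size:
                raise TraceValidationError(f"{col} negative at row {bad[0]}")
        if "refill" not in df.columns:
            df = df.assign(refill=False)
        feeder = df["feeder_g"].to_numpy(dtype=float)
        rises = np.flatnonzero(np.diff(feeder) > 1e-9) + 1
        unflagged = [i for i in rises if not bool(df["refill"].iloc[i])]
        if unflagged:
            t = ts.iloc[unflagged[0]]
            raise TraceValidationError(
                f"feeder mass increases without a refill flag at {t}"
            )
        object.__setattr__(self, "data", df.assign(timestamp=ts))

    @property
    def epoch_h(self) -> float:
        return self.epoch_s / 3600.0

    @property
    def epochs_per_day(self) -> int:
        return int(round(86400 / self.epoch_s))

    def is_light(self) -> np.ndarray:
        """Boolean mask: epoch start falls in the light phase."""
        hours = self.data["timestamp"].dt.hour + self.data["timestamp"].dt.minute / 60.0
        return ((hours >= self.light_on) & (hours < self.light_off)).to_numpy()

    def ee_per_epoch(self) -> np.ndarray:
        """kcal expended during each epoch (Weir on per-epoch gas volumes)."""
        vo2_l = self.data["vo2_ml_h"].to_numpy() * self.epoch_h / 1000.0
        vco2_l = self.data["vco2_ml_h"].to_numpy() * self.epoch_h / 1000.0
        return weir_ee(vo2_l, vco2_l)


@dataclass
class EnergyBudget:
    """Per-animal energy budget over an integer number of days."""

    animal_id: str
    days: float
    ee_24h: float            # kcal/d
    ee_dark: float           # kcal per 12-h dark phase (per day)
    ee_light: float          # kcal per 12-h light phase (per day)
    ee_resting: float        # kcal/d
    rq_24h: float
    rq_dark: float
    rq_light: float
    intake_kcal_d: float
    balance_kcal_d: float
    activity_total: float
    activity_dark_x: float
    activity_dark_z: float
    activity_light_x: float
    activity_light_z: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _window(trace: GasExchangeTrace, days: int | None) -> pd.DataFrame:
    """Select the trailing ``days`` × 24 h of the trace."""
    per_day = trace.epochs_per_day
    n = len(trace.data)
    full_days = n // per_day
    if days is None:
        days = full_days
    if days < 1:
        raise TraceValidationError("analysis window must span at least one full day")
    if days > full_days:
        raise TraceValidationError(
            f"window of {days} d exceeds the {full_days} full days recorded"
        )
    return trace.data.iloc[n - days * per_day:], days


def summarize_activity(trace: GasExchangeTrace, days: int | None = None) -> dict:
    """Beam-break totals per phase and axis, averaged per day."""
    df, days = _window(trace, days)
    light = trace.is_light()[-len(df):]
    x = df["x_counts"].to_numpy(dtype=float)
    z = df["z_counts"].to_numpy(dtype=float)
    return {
        "activity_total": (x.sum() + z.sum()) / days,
        "activity_dark_x": x[~light].sum() / days,
        "activity_dark_z": z[~light].sum() / days,
        "activity_light_x": x[light].sum() / days,
        "activity_light_z": z[light].sum() / days,
    }


def _to_90s_ee(trace: GasExchangeTrace, df: pd.DataFrame) -> np.ndarray:
    """kcal per 90-s period over the window, resampling if needed."""
    vo2_l = df["vo2_ml_h"].to_numpy() * trace.epoch_h / 1000.0
    vco2_l = df["vco2_ml_h"].to_numpy() * trace.epoch_h / 1000.0
    ee = weir_ee(vo2_l, vco2_l)
    if trace.epoch_s == 90:
        return ee
    if 90 % trace.epoch_s == 0:
        k = 90 // trace.epoch_s
        m = (len(ee) // k) * k
        return ee[:m].reshape(-1, k).sum(axis=1)
    raise TraceValidationError(
        "resting EE requires 90-s epochs or an epoch length dividing 90 s"
    )


def resting_ee(
    trace: GasExchangeTrace,
    days: int | None = None,
    quiet_min: float | None = None,
) -> float:
    """Resting energy expenditure, kcal/d.

    Averages the two lowest non-overlapping 90-s EE readings in the
    window and extrapolates over 24 h (×960).  With ``quiet_min`` set,
    only readings preceded by at least that many minutes without beam
    breaks or feeder change are eligible (off by default: no inactivity
    precondition is imposed).
    """
    df, _ = _window(trace, days)
    ee = _to_90s_ee(trace, df)
    if quiet_min is not None and trace.epoch_s == 90:
        k = max(1, int(round(quiet_min * 60 / trace.epoch_s)))
        active = (
            df["x_counts"].to_numpy() + df["z_counts"].to_numpy()
            + np.abs(np.diff(df["feeder_g"].to_numpy(), prepend=df["feeder_g"].iloc[0]))
        ) > 0
        quiet = np.ones(len(ee), dtype=bool)
        for i in range(len(ee)):
            lo = max(0, i - k)
            quiet[i] = not active[lo:i].any()
        ee = ee[quiet]
    if len(ee) < 2:
        raise TraceValidationError("resting EE needs at least two eligible readings")
    order = np.argsort(ee, kind="stable")  # ties: earliest timestamp first
    lowest_two = ee[order[:2]]
    return float(lowest_two.mean() * PERIODS_90S_PER_DAY)


def _intake_g(df: pd.DataFrame) -> float:
    """Food eaten over the window: feeder decrease minus spillage, grams.

    Steps flagged as refills are excluded from the consumption sum.
    """
    feeder = df["feeder_g"].to_numpy(dtype=float)
    refill = df["refill"].to_numpy(dtype=bool)
    step = -np.diff(feeder)
    step[refill[1:]] = 0.0
    consumed = float(step.sum())
    spilled = float(df["spill_g"].iloc[-1] - df["spill_g"].iloc[0])
    return consumed - spilled


def summarize_trace(
    trace: GasExchangeTrace,
    days: int | None = None,
    diet_energy_density: float = DIET_KCAL_PER_G,
) -> EnergyBudget:
    """Full energy budget for one animal over the trailing integer days.

    Energy expenditure integrates the Weir equation per epoch; the
    dark/light split follows the cage light cycle; intake is the
    spillage-corrected feeder loss times the diet energy density; balance
    is ``intake − EE`` computed per animal before any group adjustment.
    """
    df, days = _window(trace, days)
    light = trace.is_light()[-len(df):]
    ee = trace.ee_per_epoch()[-len(df):]
    vo2 = df["vo2_ml_h"].to_numpy(dtype=float)
    vco2 = df["vco2_ml_h"].to_numpy(dtype=float)

    ee_24h = ee.sum() / days
    ee_dark = ee[~light].sum() / days
    ee_light = ee[light].sum() / days

    def rq(mask) -> float:
        denom = vo2[mask].sum()
        return float(vco2[mask].sum() / denom) if denom > 0 else float("nan")

    intake = _intake_g(df) * diet_energy_density / days
    act = summarize_activity(trace, days)
    return EnergyBudget(
        animal_id=trace.animal_id,
        days=days,
        ee_24h=float(ee_24h),
        ee_dark=float(ee_dark),
        ee_light=float(ee_light),
        ee_resting=resting_ee(trace, days),
        rq_24h=rq(np.ones(len(df), dtype=bool)),
        rq_dark=rq(~light),
        rq_light=rq(light),
        intake_kcal_d=float(intake),
        balance_kcal_d=float(intake - ee_24h),
        **act,
    )


def summarize_traces(
    traces: Iterable[GasExchangeTrace],
    days: int | None = None,
    diet_energy_density: float = DIET_KCAL_PER_G,
) -> pd.DataFrame:
    """Energy budgets for a collection of traces, one row per animal."""
    rows = [summarize_trace(t, days, diet_energy_density).as_dict() for t in traces]
    return pd.DataFrame(rows)
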