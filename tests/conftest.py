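"""Shared fixtures: hand-built traces and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dystroflux.calorimetry import GasExchangeTrace
from dystroflux.reference import WEIR_KCAL_PER_L_CO2, WEIR_KCAL_PER_L_O2

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def trace_from_ee(
    ee_per_epoch: np.ndarray,
    epoch_s: int = 90,
    start: str = "2014-03-03 00:00:00",
    rq: float = 1.0,
    animal_id: str = "fixture",
    x_counts: np.ndarray | None = None,
    z_counts: np.ndarray | None = None,
    feeder: np.ndarray | None = None,
    spill: np.ndarray | None = None,
) -> GasExchangeTrace:
    """Build a trace whose per-epoch Weir EE equals ``ee_per_epoch`` (kcal)."""
    ee = np.asarray(ee_per_epoch, dtype=float)
    n = len(ee)
    epoch_h = epoch_s / 3600.0
    vo2_l = ee / (WEIR_KCAL_PER_L_O2 + WEIR_KCAL_PER_L_CO2 * rq)
    df = pd.DataFrame(
        {
            "timestamp": pd.date_range(start, periods=n, freq=f"{epoch_s}s"),
            "vo2_ml_h": vo2_l / epoch_h * 1000.0,
            "vco2_ml_h": vo2_l * rq / epoch_h * 1000.0,
            "x_counts": np.zeros(n, int) if x_counts is None else x_counts,
            "z_counts": np.zeros(n, int) if z_counts is None else z_counts,
            "feeder_g": np.full(n, 50.0) if feeder is None else feeder,
            "spill_g": np.zeros(n) if spill is None else spill,
        }
    )
    return GasExchangeTrace(animal_id=animal_id, data=df, epoch_s=epoch_s)


@pytest.fixture
def flat_day_trace() -> GasExchangeTrace:
    """One full day of constant EE: 9.6 kcal/d at 0.01 kcal per 90 s."""
    return trace_from_ee(np.full(960, 0.01))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140219)
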