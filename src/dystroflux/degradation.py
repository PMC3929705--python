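"""Protein degradation inferred from synthesis and accretion.

Direct degradation tracers were not used; instead degradation follows
from mass balance: everything synthesized that is not accreted into a
growing protein pool must have been degraded,

    degradation = synthesis − accretion.

Two accretion regimes are supported: ``linear_growth`` (protein mass
accrues linearly between two ages, appropriate for juveniles growing to
the 8-wk plateau) and ``steady_state`` (mass stable, accretion 0, so
100% of daily synthesis is degraded and degradation as a percent of
mass equals the FSR).

The module also carries the necrosis-burden arithmetic for dystrophic
muscle: a small daily fraction of fibers undergoing necrosis compounds
into a large weekly tissue burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "AccretionAssumption",
    "DegradationEstimate",
    "infer_degradation",
    "necrosis_burden",
]


@dataclass(frozen=True)
class AccretionAssumption:
    """How protein mass changes over the inference window.

    For ``linear_growth`` the pool grows linearly from ``tp_start`` mg
    at ``age_start`` (days) to ``tp_end`` mg at ``age_end``; for
    ``steady_state`` the pool is stable and only ``regime`` matters.
    """

    regime: str = "steady_state"
    tp_start: float = float("nan")
    tp_end: float = float("nan")
    age_start: float = 0.0
    age_end: float = 0.0

    def __post_init__(self) -> None:
        if self.regime not in ("linear_growth", "steady_state"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "linear_growth" and not self.age_end > self.age_start:
            raise ValueError("linear_growth requires age_end > age_start")

    @property
    def accretion_mg_d(self) -> float:
        if self.regime == "steady_state":
            return 0.0
        return (self.tp_end - self.tp_start) / (self.age_end - self.age_start)


@dataclass(frozen=True)
class DegradationEstimate:
    """Daily protein fluxes for one muscle pool, mg/d."""

    synthesis: float
    accretion: float
    degradation: float
    frac_synth_degraded: float
    deg_pct_of_mass: float   # %/d


def infer_degradation(
    fsr_tp: float, tp_mass: float, assumption: AccretionAssumption
) -> DegradationEstimate:
    """Degradation of a muscle protein pool from its FSR and accretion.

    Parameters
    ----------
    fsr_tp : float
        Total-protein fractional synthesis rate, %/d.
    tp_mass : float
        Protein pool mass, mg, at the age the FSR was measured.
    assumption : AccretionAssumption
        Accretion regime over the window.

    Notes
    -----
    A negative inferred degradation (accretion exceeding synthesis) is
    reported with a warning rather than clipped — it signals mutually
    inconsistent inputs.
    """
    if tp_mass <= 0:
        raise ValueError("tp_mass must be positive")
    if fsr_tp < 0:
        raise ValueError("fsr_tp must be non-negative")
    synthesis = fsr_tp / 100.0 * tp_mass
    accretion = assumption.accretion_mg_d
    degradation = synthesis - accretion
    if degradation < 0:
        warnings.warn(
            "inferred degradation is negative: accretion exceeds synthesis",
            stacklevel=2,
        )
    return DegradationEstimate(
        synthesis=synthesis,
        accretion=accretion,
        degradation=degradation,
        frac_synth_degraded=degradation / synthesis if synthesis > 0 else float("nan"),
        deg_pct_of_mass=100.0 * degradation / tp_mass,
    )


def necrosis_burden(daily_fraction: float, days: float, mode: str = "linear") -> float:
    """Cumulative fraction of muscle tissue subjected to necrosis.

    ``linear`` (default) accumulates ``p·d`` capped at 1, treating each
    day's necrotic fibers as distinct tissue; ``compound`` treats
    necrosis as sampling with replacement, ``1 − (1−p)^d``.
    """
    if not 0 <= daily_fraction <= 1:
        raise ValueError("daily_fraction must be in [0, 1]")
    if days < 0:
        raise ValueError("days must be non-negative")
    if mode == "linear":
        return min(1.0, daily_fraction * days)
    if mode == "compound":
        return 1.0 - (1.0 - daily_fraction) ** days
    raise ValueError(f"unknown mode {mode!r}")
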