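"""Energy cost of muscle protein synthesis at the whole-body level.

A two-parameter partition model: skeletal muscle takes a fraction
``f_muscle`` of whole-body resting O2 consumption (default 0.30), and
protein synthesis takes a fraction ``f_ps`` of resting muscle O2
consumption (default 0.17).  At baseline, muscle protein synthesis then
accounts for ``f_muscle × f_ps`` (≈5%) of whole-body resting energy
expenditure.  A ``k_fsr``-fold change in muscle synthesis rates scales
the synthesis-attributable O2 while the non-synthesis share is held
constant, and a ``m_ratio`` change in whole-body muscle protein mass
(proxied by gastrocnemius total-protein masses) scales it further.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .reference import F_MUSCLE_O2, F_PS_MUSCLE_O2

__all__ = [
    "PartitionParams",
    "baseline_contribution",
    "muscle_ps_share_after_foldchange",
    "wholebody_ee_increment",
    "partition_report",
]


@dataclass(frozen=True)
class PartitionParams:
    """Parameters of the muscle protein-synthesis energy partition."""

    f_muscle: float = F_MUSCLE_O2   # muscle share of whole-body O2
    f_ps: float = F_PS_MUSCLE_O2    # synthesis share of muscle O2
    k_fsr: float = 1.0              # fold-change in muscle FSR
    m_ratio: float = 1.0            # muscle protein mass ratio (case/control)

    def __post_init__(self) -> None:
        if not 0 < self.f_muscle < 1 or not 0 < self.f_ps < 1:
            raise ValueError("fractions must be in (0, 1)")
        if self.k_fsr <= 0 or self.m_ratio <= 0:
            raise ValueError("k_fsr and m_ratio must be positive")


def baseline_contribution(p: PartitionParams) -> float:
    """Muscle protein synthesis as % of whole-body resting EE: 100·f_m·f_ps."""
    return 100.0 * p.f_muscle * p.f_ps


def muscle_ps_share_after_foldchange(f_ps: float, k_fsr: float) -> float:
    """Synthesis share of muscle O2 (%) after a k-fold change in FSR.

    Non-synthesis O2 is held constant:
    ``100 · f_ps·k / ((1 − f_ps) + f_ps·k)``.
    """
    if not 0 < f_ps < 1:
        raise ValueError("f_ps must be in (0, 1)")
    if k_fsr <= 0:
        raise ValueError("k_fsr must be positive")
    return 100.0 * (f_ps * k_fsr) / ((1.0 - f_ps) + f_ps * k_fsr)


def wholebody_ee_increment(p: PartitionParams) -> float:
    """Increase in whole-body resting EE (%) from elevated muscle synthesis.

    Default formula ``100 · f_muscle · f_ps · (k_fsr · m_ratio − 1)``:
    the synthesis-attributable share of whole-body EE scales with both
    the fold-change in FSR and the muscle protein mass ratio.
    """
    return 100.0 * p.f_muscle * p.f_ps * (p.k_fsr * p.m_ratio - 1.0)


def partition_report(p: PartitionParams) -> pd.DataFrame:
    """Small report table of all partition quantities for one scenario."""
    rows = [
        ("baseline muscle PS share of resting EE (%)", baseline_contribution(p)),
        ("muscle PS share of muscle O2 at k-fold FSR (%)",
         muscle_ps_share_after_foldchange(p.f_ps, p.k_fsr)),
        ("whole-body resting EE increment (%)", wholebody_ee_increment(p)),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "value"])
    df.insert(0, "f_muscle", p.f_muscle)
    df.insert(1, "f_ps", p.f_ps)
    df.insert(2, "k_fsr", p.k_fsr)
    df.insert(3, "m_ratio", p.m_ratio)
    return df
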