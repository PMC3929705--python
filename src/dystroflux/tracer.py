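"""Whole-body phenylalanine/tyrosine kinetics from plateau enrichments.

A primed-continuous infusion of ring-D5 phenylalanine and ring-D2
tyrosine, run to isotopic steady state in postabsorptive mice, yields
plasma plateau enrichments from which we estimate: the rates of
appearance (Ra) of phenylalanine and tyrosine by isotope dilution, the
irreversible hydroxylation of phenylalanine to tyrosine (traced by the
appearance of D4 tyrosine from D5 phenylalanine), whole-body protein
synthesis, and net phenylalanine balance.

In the postabsorptive state Ra_phe is phenylalanine released by protein
breakdown; it is either reincorporated by synthesis (PS_phe) or
hydroxylated (Q_pt), so ``PS_phe = Ra_phe − Q_pt`` and the net balance
is ``−Q_pt`` (irreversible loss).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .reference import (
    I_PHE,
    I_TYR,
    PHE_MOLAR_MASS_G,
    PHE_PROTEIN_FRACTION,
    PRIME_PHE,
    PRIME_TYR,
)

__all__ = [
    "TracerProtocol",
    "PlasmaEnrichment",
    "FluxResult",
    "ra_steady_state",
    "plateau_enrichment",
    "hydroxylation_flux",
    "partition_flux",
    "estimate_fluxes",
    "analyze_enrichment_table",
    "adjust_for_ffm",
    "InconsistentEnrichmentsError",
]

#: Enrichments below this floor (mpe) are treated as missing, not zero.
ENRICHMENT_FLOOR_MPE = 0.05


class InconsistentEnrichmentsError(ValueError):
    """Enrichments imply a hydroxylation flux exceeding the phe flux."""


@dataclass(frozen=True)
class TracerProtocol:
    """Infusion rates (µmol·kg⁻¹·h⁻¹) and protein-conversion constants."""

    i_phe: float = I_PHE
    i_tyr: float = I_TYR
    prime_phe: float = PRIME_PHE
    prime_tyr: float = PRIME_TYR
    phe_protein_content: float = PHE_PROTEIN_FRACTION

    def __post_init__(self) -> None:
        if self.i_phe <= 0 or self.i_tyr <= 0:
            raise ValueError("infusion rates must be positive")
        if not 0 < self.phe_protein_content <= 0.1:
            raise ValueError("phe_protein_content must be in (0, 0.1]")


@dataclass(frozen=True)
class PlasmaEnrichment:
    """Plateau plasma enrichments, mole percent excess (mpe)."""

    e_d5_phe: float
    e_d4_tyr: float
    e_d2_tyr: float

    def __post_init__(self) -> None:
        if not 0 < self.e_d5_phe < 100:
            raise ValueError("e_d5_phe must be in (0, 100) mpe")
        if not 0 < self.e_d2_tyr < 100:
            raise ValueError("e_d2_tyr must be in (0, 100) mpe")
        if not 0 <= self.e_d4_tyr < 100:
            raise ValueError("e_d4_tyr must be in [0, 100) mpe")


@dataclass(frozen=True)
class FluxResult:
    """Steady-state whole-body phenylalanine/tyrosine kinetics."""

    ra_phe: float                # µmol·kg⁻¹·h⁻¹
    ra_tyr: float
    q_pt: float                  # phe → tyr hydroxylation
    ps_phe: float                # phe into protein synthesis
    net_balance: float           # ≤ 0 postabsorptive; = −q_pt
    hydroxylation_fraction: float
    protein_breakdown: float     # g protein·kg⁻¹·h⁻¹
    protein_synthesis: float
    protein_balance: float


def ra_steady_state(i: float, e_plateau: float, convention: str = "tracee") -> float:
    """Rate of appearance from isotope dilution at plateau.

    Parameters
    ----------
    i : float
        Tracer infusion rate, µmol·kg⁻¹·h⁻¹.
    e_plateau : float
        Plateau enrichment of the infused tracer, mpe (0 < E < 100).
    convention : {"tracee", "total"}
        ``tracee`` (default) returns the endogenous flux
        ``i·(100/E − 1)``; ``total`` returns ``i·100/E`` (endogenous
        plus tracer).
    """
    if i <= 0:
        raise ValueError("infusion rate must be positive")
    if not 0 < e_plateau < 100:
        raise ValueError("plateau enrichment must be in (0, 100) mpe")
    if convention == "tracee":
        return i * (100.0 / e_plateau - 1.0)
    if convention == "total":
        return i * 100.0 / e_plateau
    raise ValueError(f"unknown Ra convention {convention!r}")


def plateau_enrichment(i: float, ra: float, convention: str = "tracee") -> float:
    """Exact inverse of :func:`ra_steady_state`: enrichment given flux."""
    if i <= 0 or ra <= 0:
        raise ValueError("rates must be positive")
    if convention == "tracee":
        return 100.0 * i / (i + ra)
    if convention == "total":
        return 100.0 * i / ra
    raise ValueError(f"unknown Ra convention {convention!r}")


def hydroxylation_flux(
    ra_tyr: float,
    e_d4_tyr: float,
    e_d5_phe: float,
    i_phe: float,
    ra_phe: float,
    correction: bool = True,
) -> float:
    """Phenylalanine → tyrosine conversion flux Q_pt, µmol·kg⁻¹·h⁻¹.

    ``Q_pt = Ra_tyr · (E_d4tyr / E_d5phe) · c`` where the correction
    ``c = Ra_phe / (i_phe + Ra_phe)`` (default on) removes the portion of
    D4-tyrosine production attributable to hydroxylation of the infused
    phenylalanine tracer itself, leaving the endogenous conversion flux.
    """
    if e_d5_phe <= 0:
        raise ValueError("e_d5_phe must be positive")
    if e_d4_tyr < 0:
        raise ValueError("e_d4_tyr must be non-negative")
    if ra_tyr <= 0 or ra_phe <= 0 or i_phe <= 0:
        raise ValueError("rates must be positive")
    q = ra_tyr * (e_d4_tyr / e_d5_phe)
    if correction:
        q *= ra_phe / (i_phe + ra_phe)
    if q > ra_phe * (1 + 1e-12):
        raise InconsistentEnrichmentsError(
            f"hydroxylation flux {q:.3g} exceeds Ra_phe {ra_phe:.3g}; "
            "enrichments are mutually inconsistent"
        )
    return q


def partition_flux(
    ra_phe: float, q_pt: float, protocol: TracerProtocol | None = None
) -> FluxResult:
    """Partition Ra_phe into synthesis and irreversible loss.

    Protein-equivalent rates assume phenylalanine is 4% of body protein
    by mass (configurable via ``protocol``).
    """
    protocol = protocol or TracerProtocol()
    if q_pt < 0 or ra_phe <= 0:
        raise ValueError("fluxes must be non-negative with ra_phe > 0")
    if q_pt > ra_phe * (1 + 1e-12):
        raise ValueError("q_pt must not exceed ra_phe")
    ps_phe = ra_phe - q_pt
    # µmol·kg⁻¹·h⁻¹ → g protein·kg⁻¹·h⁻¹
    to_protein = PHE_MOLAR_MASS_G * 1e-6 / protocol.phe_protein_content
    return FluxResult(
        ra_phe=ra_phe,
        ra_tyr=float("nan"),
        q_pt=q_pt,
        ps_phe=ps_phe,
        net_balance=-q_pt,
        hydroxylation_fraction=q_pt / ra_phe,
        protein_breakdown=ra_phe * to_protein,
        protein_synthesis=ps_phe * to_protein,
        protein_balance=-q_pt * to_protein,
    )


def estimate_fluxes(
    enrichment: PlasmaEnrichment,
    protocol: TracerProtocol | None = None,
    convention: str = "tracee",
    correction: bool = True,
) -> FluxResult:
    """Full estimation chain: dilution → hydroxylation → partition."""
    protocol = protocol or TracerProtocol()
    ra_phe = ra_steady_state(protocol.i_phe, enrichment.e_d5_phe, convention)
    ra_tyr = ra_steady_state(protocol.i_tyr, enrichment.e_d2_tyr, convention)
    q_pt = hydroxylation_flux(
        ra_tyr, enrichment.e_d4_tyr, enrichment.e_d5_phe,
        protocol.i_phe, ra_phe, correction=correction,
    )
    result = partition_flux(ra_phe, q_pt, protocol)
    return FluxResult(**{**result.__dict__, "ra_tyr": ra_tyr})


def analyze_enrichment_table(
    table: pd.DataFrame,
    convention: str = "tracee",
    correction: bool = True,
    enrichment_floor: float = ENRICHMENT_FLOOR_MPE,
) -> pd.DataFrame:
    """Per-animal flux estimation from an enrichments table.

    Expects columns ``animal_id, e_d5_phe_mpe, e_d4_tyr_mpe,
    e_d2_tyr_mpe, i_phe, i_tyr`` (extra columns such as ``ffm_g`` are
    carried through).  Tracer enrichments below ``enrichment_floor`` are
    treated as missing and yield NaN fluxes; a D4-tyrosine enrichment
    below the floor is a true zero-conversion reading only if exactly 0.
    """
    rows = []
    for rec in table.to_dict("records"):
        e5, e4, e2 = rec["e_d5_phe_mpe"], rec["e_d4_tyr_mpe"], rec["e_d2_tyr_mpe"]
        out = dict(rec)
        if e5 < enrichment_floor or e2 < enrichment_floor or (0 < e4 < enrichment_floor):
            out.update({k: float("nan") for k in (
                "ra_phe", "ra_tyr", "q_pt", "ps_phe", "net_balance",
                "hydroxylation_fraction", "protein_breakdown",
                "protein_synthesis", "protein_balance")})
            rows.append(out)
            continue
        protocol = TracerProtocol(i_phe=rec.get("i_phe", I_PHE), i_tyr=rec.get("i_tyr", I_TYR))
        res = estimate_fluxes(
            PlasmaEnrichment(e5, e4, e2), protocol, convention, correction
        )
        out.update(res.__dict__)
        rows.append(out)
    return pd.DataFrame(rows)


def adjust_for_ffm(
    flux_table: pd.DataFrame,
    outcome: str = "ra_phe",
    ffm_column: str = "ffm_g",
    factors: tuple[str, ...] = ("genotype", "age_group"),
):
    """Covariate-adjusted least-squares means of a flux outcome.

    Delegates to :func:`dystroflux.stats.ancova_lsmeans` with fat-free
    mass as the body-size covariate, mirroring how whole-body fluxes are
    compared across groups of different protein pool size.
    """
    from .stats import ancova_lsmeans

    return ancova_lsmeans(flux_table, outcome, factors=factors, covariates=(ffm_column,))
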