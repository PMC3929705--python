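"""Synthetic data generator for the whole pipeline.

Every input the analysis consumes — cohort tables, metabolic-cage
gas-exchange traces, tracer plateau enrichments, flooding-dose
radioactivities — can be generated here from known ground-truth
parameters, so each estimator is testable by parameter recovery.  Each
simulator is the exact algebraic inverse of its estimator in the
noiseless limit.

Noise is multiplicative, mean-preserving log-normal throughout:
physiological measurements are positive with a roughly constant CV.
One global seed fans out to per-animal substreams keyed by animal
index, so enlarging a cohort never perturbs existing animals.

Default parameterization comes from :mod:`dystroflux.reference`: the
group summaries for juvenile/adult mdx and control mice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reference as ref
from .calorimetry import GasExchangeTrace
from .tracer import PlasmaEnrichment, plateau_enrichment
from .synthesis import FloodingDoseSample, MUSCLES

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "TraceSpec",
    "TracerTruth",
    "FloodingTruth",
    "simulate_cohort",
    "simulate_clams_trace",
    "simulate_tracer_plateau",
    "simulate_flooding_dose",
    "default_cohort_spec",
    "lognormal_factor",
]

GENOTYPES = ("mdx", "control")
AGE_GROUPS = ("juvenile", "adult")


def _substream(seed: int, index: int) -> np.random.Generator:
    """Stable per-unit RNG: stream ``index`` of global ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise factor with unit mean and the given CV."""
    if cv < 0:
        raise ValueError("noise CV must be non-negative")
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


# --------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class GroupSpec:
    """One genotype × age cell: size and per-trait (mean, sd)."""

    genotype: str
    age_group: str
    n: int
    traits: dict                      # trait -> (mean, sd)
    correlations: tuple = ()          # (trait_a, trait_b, rho)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.n < 1:
            raise ValueError("group size must be at least 1")
        for trait, (mean, sd) in self.traits.items():
            if mean <= 0:
                raise ValueError(f"mean of {trait!r} must be positive")
            if sd < 0:
                raise ValueError(f"sd of {trait!r} must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: groups plus the global seed."""

    groups: tuple
    seed: int = 0


def default_cohort_spec(seed: int = 0, n: int | None = None) -> CohortSpec:
    """Cohort spec parameterized from the reference group summaries.

    ``n`` overrides every group size (otherwise the reference sizes are
    used).  Fat-free mass and body length are generated with their
    observed correlation (r = 0.96 in juveniles) via a Gaussian copula.
    """
    body = ref.body_composition()
    groups = []
    for genotype, age_group in ref.GROUPS:
        sub = body[(body.genotype == genotype) & (body.age_group == age_group)]
        n_ref = int(sub["n"].iloc[0])
        traits = {
            row.trait: (row["mean"], ref.se_to_sd(row.se, n_ref))
            for _, row in sub.iterrows()
        }
        mus = ref.muscle_protein()
        gast = mus[
            (mus.muscle == "gastrocnemius")
            & (mus.genotype == genotype)
            & (mus.age_group == age_group)
        ].iloc[0]
        tpc, tpc_se = ref.TP_CONC_MG_G[("gastrocnemius", genotype, age_group)]
        n_m = dict(zip(ref.GROUPS, ref.MUSCLE_PROTEIN_N["gastrocnemius"]))[
            (genotype, age_group)
        ]
        traits["gastroc_tp_mg"] = (gast.tp_mg, ref.se_to_sd(gast.tp_mg_se, n_m))
        traits["tp_conc_mg_g"] = (tpc, ref.se_to_sd(tpc_se, n_m))
        traits["rna_per_tp_mg_g"] = (
            gast.rna_per_tp, ref.se_to_sd(gast.rna_per_tp_se, n_m)
        )
        groups.append(
            GroupSpec(
                genotype=genotype,
                age_group=age_group,
                n=n or n_ref,
                traits=traits,
                correlations=(("ffm_g", "body_len_mm", 0.96),),
            )
        )
    return CohortSpec(groups=tuple(groups), seed=seed)


def _group_chol(names: list[str], correlations) -> np.ndarray:
    k = len(names)
    r = np.eye(k)
    for a, b, rho in correlations:
        if a in names and b in names:
            i, j = names.index(a), names.index(b)
            r[i, j] = r[j, i] = rho
    return np.linalg.cholesky(r)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per animal, traits drawn from moment-matched log-normals.

    Group sample means converge to the specified means as n grows; with
    all SDs zero every animal equals the group mean exactly.  Output is
    bit-identical under a fixed seed.
    """
    rows = []
    index = 0
    for group in spec.groups:
        names = list(group.traits)
        chol = _group_chol(names, group.correlations)
        for i in range(group.n):
            rng = _substream(spec.seed, index)
            z = chol @ rng.standard_normal(len(names))
            row = {
                "animal_id": f"{group.genotype}_{group.age_group}_{i:02d}",
                "genotype": group.genotype,
                "age_group": group.age_group,
            }
            for name, zi in zip(names, z):
                mean, sd = group.traits[name]
                if sd == 0:
                    row[name] = mean
                else:
                    sigma = np.sqrt(np.log1p((sd / mean) ** 2))
                    row[name] = float(np.exp(np.log(mean) - 0.5 * sigma**2 + sigma * zi))
            rows.append(row)
            index += 1
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# metabolic-cage trace


@dataclass(frozen=True)
class TraceSpec:
    """Shape of a simulated cage session.

    The circadian component is a sinusoid peaking mid-dark-phase;
    activity bursts are Bernoulli events per epoch (rate per hour,
    higher in the dark) that raise VO2 by ``burst_gain`` and emit beam
    breaks; meals deplete the feeder mostly at night with a recorded
    spillage fraction.  The noiseless trace integrates exactly (per
    day) to the requested 24-h energy expenditure.
    """

    duration_h: float = 72.0
    epoch_s: int = 90
    circadian_amplitude: float = 0.2
    burst_rate_dark: float = 6.0      # events/h
    burst_rate_light: float = 1.5
    burst_gain: float = 0.5           # fractional VO2 increment during a burst
    noise_cv: float = 0.05
    rq: float = 0.95
    light_on: int = ref.LIGHT_ON
    light_off: int = ref.LIGHT_OFF
    diet_energy_density: float = ref.DIET_KCAL_PER_G
    intake_kcal_d: float = 11.0
    meal_rate_dark: float = 0.8       # meals/h
    meal_rate_light: float = 0.2
    spill_fraction: float = 0.05
    feeder_start_g: float = 60.0
    start: str = "2014-03-03 00:00:00"
    seed: int = 0

    def __post_init__(self) -> None:
        if 86400 % self.epoch_s != 0:
            raise ValueError("epoch_s must divide 86400")
        if not 0 <= self.circadian_amplitude < 1:
            raise ValueError("circadian_amplitude must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if (self.duration_h * 3600) % self.epoch_s != 0:
            raise ValueError("duration must be a whole number of epochs")


def simulate_clams_trace(
    spec: TraceSpec,
    truth_ee_kcal_d: float,
    animal_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> GasExchangeTrace:
    """Simulate one cage session with a known 24-h energy expenditure."""
    if truth_ee_kcal_d <= 0:
        raise ValueError("truth_ee_kcal_d must be positive")
    rng = rng or np.random.default_rng(spec.seed)
    epoch_h = spec.epoch_s / 3600.0
    n = int(spec.duration_h * 3600 // spec.epoch_s)
    per_day = 86400 // spec.epoch_s

    ts = pd.date_range(spec.start, periods=n, freq=f"{spec.epoch_s}s")
    hour = (ts.hour + ts.minute / 60.0 + ts.second / 3600.0).to_numpy(dtype=float)
    light = (hour >= spec.light_on) & (hour < spec.light_off)

    # mid-dark peak: dark runs light_off -> light_on, centre at midnight
    # for the default 18:00-06:00 cycle
    mid_dark = ((spec.light_off + spec.light_on + 24) / 2.0) % 24
    circ = 1.0 + spec.circadian_amplitude * np.cos(2 * np.pi * (hour - mid_dark) / 24.0)

    burst_rate = np.where(light, spec.burst_rate_light, spec.burst_rate_dark)
    burst = rng.random(n) < np.minimum(1.0, burst_rate * epoch_h)
    ee_rel = circ * (1.0 + spec.burst_gain * burst)

    # rescale each day so the noiseless daily integral equals the truth
    day = np.arange(n) // per_day
    ee_rate = np.empty(n)
    for d in np.unique(day):
        m = day == d
        ee_rate[m] = ee_rel[m] * truth_ee_kcal_d * (m.sum() / per_day) / (
            ee_rel[m].sum() * epoch_h
        )

    vo2_l_h = ee_rate / (ref.WEIR_KCAL_PER_L_O2 + ref.WEIR_KCAL_PER_L_CO2 * spec.rq)
    vo2 = vo2_l_h * 1000.0 * lognormal_factor(rng, spec.noise_cv, n)
    vco2 = vo2_l_h * spec.rq * 1000.0 * lognormal_factor(rng, spec.noise_cv, n)

    x = rng.poisson(np.where(light, 0.2, 1.0)) + burst * rng.poisson(40.0, n)
    z = rng.poisson(np.where(light, 0.05, 0.3)) + burst * rng.poisson(8.0, n)

    # feeder: meals concentrated in the dark, spillage recorded separately
    meal_rate = np.where(light, spec.meal_rate_light, spec.meal_rate_dark)
    meal = rng.random(n) < np.minimum(1.0, meal_rate * epoch_h)
    gross = np.where(meal, rng.gamma(2.0, 0.5, n), 0.0)
    eaten_per_day = spec.intake_kcal_d / spec.diet_energy_density
    for d in np.unique(day):
        m = day == d
        if gross[m].sum() == 0:
            idx = np.flatnonzero(m)[rng.integers(m.sum())]
            gross[idx] = 1.0
        target_gross = eaten_per_day * (m.sum() / per_day) / (1.0 - spec.spill_fraction)
        gross[m] *= target_gross / gross[m].sum()
    feeder = spec.feeder_start_g - np.cumsum(gross)
    spill = np.cumsum(gross * spec.spill_fraction)

    df = pd.DataFrame(
        {
            "timestamp": ts,
            "vo2_ml_h": vo2,
            "vco2_ml_h": vco2,
            "x_counts": x.astype(int),
            "z_counts": z.astype(int),
            "feeder_g": feeder,
            "spill_g": spill,
            "refill": False,
        }
    )
    return GasExchangeTrace(
        animal_id=animal_id,
        data=df,
        epoch_s=spec.epoch_s,
        light_on=spec.light_on,
        light_off=spec.light_off,
    )


# --------------------------------------------------------------------------
# tracer plateau


@dataclass(frozen=True)
class TracerTruth:
    """Ground-truth steady-state kinetics for the plateau simulator."""

    ra_phe_true: float                     # µmol·kg⁻¹·h⁻¹
    ra_tyr_true: float
    hydroxylation_fraction_true: float = ref.HYDROXYLATION_FRACTION
    i_phe: float = ref.I_PHE
    i_tyr: float = ref.I_TYR
    enrichment_noise_cv: float = 0.0
    convention: str = "tracee"
    correction: bool = True

    def __post_init__(self) -> None:
        if self.ra_phe_true <= 0 or self.ra_tyr_true <= 0:
            raise ValueError("true fluxes must be positive")
        if self.i_phe <= 0 or self.i_tyr <= 0:
            raise ValueError("infusion rates must be positive")
        if not 0 <= self.hydroxylation_fraction_true <= 1:
            raise ValueError("hydroxylation fraction must be in [0, 1]")
        if self.enrichment_noise_cv < 0:
            raise ValueError("noise CV must be non-negative")


def simulate_tracer_plateau(
    truth: TracerTruth, rng: np.random.Generator | None = None
) -> PlasmaEnrichment:
    """Plateau enrichments that invert exactly to the true kinetics.

    The forward model is the algebraic inverse of the estimation chain
    in :mod:`dystroflux.tracer` under the same Ra convention and
    hydroxylation-correction setting, so noiseless enrichments round-trip
    to ``(ra_phe_true, ra_tyr_true, hydroxylation_fraction_true)`` at
    machine precision.
    """
    rng = rng or np.random.default_rng(0)
    e5 = plateau_enrichment(truth.i_phe, truth.ra_phe_true, truth.convention)
    e2 = plateau_enrichment(truth.i_tyr, truth.ra_tyr_true, truth.convention)
    q_pt = truth.hydroxylation_fraction_true * truth.ra_phe_true
    corr = (
        truth.ra_phe_true / (truth.i_phe + truth.ra_phe_true)
        if truth.correction
        else 1.0
    )
    e4 = q_pt * e5 / (truth.ra_tyr_true * corr)
    cv = truth.enrichment_noise_cv
    return PlasmaEnrichment(
        e_d5_phe=e5 * lognormal_factor(rng, cv),
        e_d4_tyr=e4 * lognormal_factor(rng, cv),
        e_d2_tyr=e2 * lognormal_factor(rng, cv),
    )


# --------------------------------------------------------------------------
# flooding dose


@dataclass(frozen=True)
class FloodingTruth:
    """Ground truth for one simulated flooding-dose muscle sample."""

    fsr_true_tp: float                 # %/d
    fsr_true_mp: float
    muscle: str = "gastrocnemius"
    animal_id: str = "sim"
    s_a: float = 1.0                   # precursor dpm/nmol
    t_label: float = ref.T_LABEL_MIN   # min
    tp_mass: float = 11.1              # mg
    rna_mass: float = 0.2              # mg
    tp_conc: float = 140.0             # mg/g
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.fsr_true_tp < 0 or self.fsr_true_mp < 0:
            raise ValueError("true FSRs must be non-negative")
        if self.t_label <= 0:
            raise ValueError("labelling time must be positive")
        if self.s_a <= 0 or self.tp_mass <= 0 or self.tp_conc <= 0:
            raise ValueError("s_a, tp_mass and tp_conc must be positive")
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}")


def bound_specific_radioactivity(fsr_pct_d: float, s_a: float, t_label: float) -> float:
    """Forward FSR model: S_B = S_A · (FSR/100) · t/1440."""
    return s_a * (fsr_pct_d / 100.0) * t_label / 1440.0


def simulate_flooding_dose(
    truth: FloodingTruth, rng: np.random.Generator | None = None
) -> FloodingDoseSample:
    """Flooding-dose radioactivities consistent with the chosen FSRs."""
    rng = rng or np.random.default_rng(0)
    cv = truth.noise_cv
    s_b_tp = bound_specific_radioactivity(truth.fsr_true_tp, truth.s_a, truth.t_label)
    s_b_mp = bound_specific_radioactivity(truth.fsr_true_mp, truth.s_a, truth.t_label)
    return FloodingDoseSample(
        animal_id=truth.animal_id,
        muscle=truth.muscle,
        s_a_blood=truth.s_a * lognormal_factor(rng, cv),
        s_a_tissue=truth.s_a * lognormal_factor(rng, cv),
        s_b_tp=s_b_tp * lognormal_factor(rng, cv),
        s_b_mp=s_b_mp * lognormal_factor(rng, cv),
        t_label=truth.t_label,
        tp_conc=truth.tp_conc,
        muscle_mass=truth.tp_mass / truth.tp_conc * 1000.0,
        rna_mass=truth.rna_mass,
    )
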