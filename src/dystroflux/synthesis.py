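"""Flooding-dose muscle protein synthesis rates.

A large bolus of labelled plus unlabelled phenylalanine floods the free
amino-acid pools so the precursor specific radioactivity (S_A) is near
constant over a short labelling period; label accumulation in the
protein-bound pool (S_B) then gives the fractional synthesis rate

    FSR (%/d) = S_B / (S_A · t) · 1440 · 100,       t in minutes.

The module also computes the translational decomposition: capacity
(RNA/TP, mg RNA per g protein, a ribosomal-abundance proxy) and
efficiency (K_RNA, g protein synthesized per g RNA per day), plus
absolute synthesis for the total-protein (TP) pool.  Absolute
myofibrillar (MP) synthesis is deliberately not computed: MP
purification is not quantitative, so only the MP FSR is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .reference import T_LABEL_MIN

__all__ = [
    "FloodingDoseSample",
    "SynthesisResult",
    "check_precursor_equilibration",
    "fsr",
    "k_rna",
    "absolute_synthesis",
    "analyze_flooding_sample",
    "analyze_flooding_table",
]

MUSCLES = (
    "gastrocnemius", "quadriceps", "soleus", "tibialis_anterior",
    "diaphragm", "heart",
)

MIN_PER_DAY = 1440.0


@dataclass(frozen=True)
class FloodingDoseSample:
    """One muscle from one animal after a flooding-dose labelling."""

    animal_id: str
    muscle: str
    s_a_blood: float     # precursor specific radioactivity, dpm/nmol
    s_a_tissue: float
    s_b_tp: float        # protein-bound specific radioactivity, dpm/nmol
    s_b_mp: float
    t_label: float = T_LABEL_MIN   # minutes
    tp_conc: float = float("nan")  # mg protein / g muscle
    muscle_mass: float = float("nan")  # mg
    rna_mass: float = float("nan")     # mg

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}")
        if self.s_a_blood <= 0 or self.s_a_tissue <= 0:
            raise ValueError("precursor specific radioactivities must be positive")
        if self.s_b_tp < 0 or self.s_b_mp < 0:
            raise ValueError("bound specific radioactivities must be non-negative")
        if self.t_label <= 0:
            raise ValueError("labelling time must be positive")


@dataclass(frozen=True)
class SynthesisResult:
    """Per-muscle synthesis rates and translational decomposition."""

    animal_id: str
    muscle: str
    fsr_tp: float          # %/d
    fsr_mp: float          # %/d
    mp_tp_ratio: float
    tp_mass: float         # mg
    abs_synthesis_tp: float  # mg/d
    rna_per_tp: float      # mg RNA / g protein
    k_rna: float           # g protein / g RNA / d
    equilibration_ratio: float
    equilibrated: bool


def check_precursor_equilibration(
    s_a_blood: float, s_a_tissue: float, tolerance: float = 0.15
) -> tuple[bool, float]:
    """Verify the flood equilibrated blood and tissue free phe pools.

    Returns ``(passed, tissue/blood ratio)``; passes iff the ratio is
    within ``tolerance`` of 1.  Failing samples are flagged downstream,
    not dropped.
    """
    if s_a_blood <= 0 or s_a_tissue <= 0:
        raise ValueError("specific radioactivities must be positive")
    ratio = s_a_tissue / s_a_blood
    return abs(ratio - 1.0) <= tolerance, ratio


def fsr(s_b: float, s_a: float, t_label: float) -> float:
    """Fractional synthesis rate, percent of the protein pool per day."""
    if s_a <= 0:
        raise ValueError("precursor specific radioactivity must be positive")
    if t_label <= 0:
        raise ValueError("labelling time must be positive")
    if s_b < 0:
        raise ValueError("bound specific radioactivity must be non-negative")
    return s_b / (s_a * t_label) * MIN_PER_DAY * 100.0


def k_rna(fsr_tp: float, rna_per_tp: float) -> float:
    """Translational efficiency: g protein synthesized per g RNA per day.

    ``K_RNA = (FSR/100) / (RNA/TP / 1000) = 10 · FSR / (RNA/TP)``.
    """
    if rna_per_tp <= 0:
        raise ValueError("rna_per_tp must be positive")
    return 10.0 * fsr_tp / rna_per_tp


def absolute_synthesis(fsr_tp: float, tp_mass: float) -> float:
    """Absolute TP synthesis, mg/d: FSR times the TP pool mass."""
    if fsr_tp < 0 or tp_mass < 0:
        raise ValueError("inputs must be non-negative")
    return fsr_tp / 100.0 * tp_mass


def analyze_flooding_sample(
    sample: FloodingDoseSample,
    precursor: str = "tissue",
    equilibration_tol: float = 0.15,
) -> SynthesisResult:
    """All synthesis quantities for one flooding-dose sample.

    ``precursor`` selects the S_A pool: the tissue free pool (default,
    closest to the aminoacyl-tRNA precursor under a flood) or blood.
    """
    if precursor not in ("tissue", "blood"):
        raise ValueError("precursor must be 'tissue' or 'blood'")
    ok, ratio = check_precursor_equilibration(
        sample.s_a_blood, sample.s_a_tissue, equilibration_tol
    )
    s_a = sample.s_a_tissue if precursor == "tissue" else sample.s_a_blood
    fsr_tp = fsr(sample.s_b_tp, s_a, sample.t_label)
    fsr_mp = fsr(sample.s_b_mp, s_a, sample.t_label)
    tp_mass = sample.tp_conc * sample.muscle_mass / 1000.0
    rna_per_tp = sample.rna_mass / tp_mass * 1000.0 if tp_mass > 0 else float("nan")
    return SynthesisResult(
        animal_id=sample.animal_id,
        muscle=sample.muscle,
        fsr_tp=fsr_tp,
        fsr_mp=fsr_mp,
        mp_tp_ratio=fsr_mp / fsr_tp if fsr_tp > 0 else float("nan"),
        tp_mass=tp_mass,
        abs_synthesis_tp=absolute_synthesis(fsr_tp, tp_mass) if tp_mass > 0 else float("nan"),
        rna_per_tp=rna_per_tp,
        k_rna=k_rna(fsr_tp, rna_per_tp) if rna_per_tp > 0 else float("nan"),
        equilibration_ratio=ratio,
        equilibrated=ok,
    )


def analyze_flooding_table(
    table: pd.DataFrame,
    precursor: str = "tissue",
    equilibration_tol: float = 0.15,
) -> pd.DataFrame:
    """Synthesis results for a flooding table, keyed by (animal, muscle).

    Expects columns ``animal_id, muscle, s_a_blood, s_a_tissue, s_b_tp,
    s_b_mp, t_label_min, tp_conc_mg_g, muscle_mass_mg, rna_mass_mg``;
    extra columns are carried through.
    """
    rows = []
    for rec in table.to_dict("records"):
        sample = FloodingDoseSample(
            animal_id=rec["animal_id"],
            muscle=rec["muscle"],
            s_a_blood=rec["s_a_blood"],
            s_a_tissue=rec["s_a_tissue"],
            s_b_tp=rec["s_b_tp"],
            s_b_mp=rec["s_b_mp"],
            t_label=rec.get("t_label_min", T_LABEL_MIN),
            tp_conc=rec.get("tp_conc_mg_g", float("nan")),
            muscle_mass=rec.get("muscle_mass_mg", float("nan")),
            rna_mass=rec.get("rna_mass_mg", float("nan")),
        )
        res = analyze_flooding_sample(sample, precursor, equilibration_tol)
        out = {k: v for k, v in rec.items() if k not in res.__dict__}
        out.update(res.__dict__)
        rows.append(out)
    return pd.DataFrame(rows)
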