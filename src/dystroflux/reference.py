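"""Reference group summaries for juvenile and adult mdx and control mice.

These are the group-level means (± SE, with group sizes) of body
composition, muscle protein synthesis, and energy balance that
parameterize the synthetic cohort generator and the worked examples.
Juveniles are 4- to 5-wk-old, adults 12- to 14-wk-old; genotypes are
dystrophin-deficient ``mdx`` and wild-type ``control``.

SEs convert to per-animal SDs as ``sd = se * sqrt(n)``.
"""

from __future__ import annotations

import math

import pandas as pd

GENOTYPES = ("mdx", "control")
AGE_GROUPS = ("juvenile", "adult")
GROUPS = [
    ("mdx", "juvenile"),
    ("control", "juvenile"),
    ("mdx", "adult"),
    ("control", "adult"),
]

# --- physical and protocol constants -------------------------------------

#: Abbreviated Weir coefficients, kcal per litre of gas exchanged.
WEIR_KCAL_PER_L_O2 = 3.941
WEIR_KCAL_PER_L_CO2 = 1.106

#: Metabolizable energy density of the semi-purified diet, kcal/g.
DIET_KCAL_PER_G = 3.64

#: Light cycle, clock hours.
LIGHT_ON, LIGHT_OFF = 6, 18

#: Primed-continuous infusion rates, µmol·kg⁻¹·h⁻¹ (prime in µmol·kg⁻¹).
I_PHE = 16.0
I_TYR = 11.0
PRIME_PHE = 16.0
PRIME_TYR = 11.0

#: Fraction of whole-body phenylalanine flux irreversibly hydroxylated to
#: tyrosine; constant across age and genotype in the postabsorptive state.
HYDROXYLATION_FRACTION = 0.17

#: Average phenylalanine content of body proteins (g phe / g protein).
PHE_PROTEIN_FRACTION = 0.04
PHE_MOLAR_MASS_G = 165.19

#: Flooding-dose labelling time, minutes.
T_LABEL_MIN = 15.0

#: Linear-accretion window for degradation inference: 4 wk -> 8 wk.
GROWTH_WINDOW_D = 28.0

#: Energy-partition parameters: share of whole-body O2 consumption by
#: skeletal muscle, and share of resting muscle O2 used by protein synthesis.
F_MUSCLE_O2 = 0.30
F_PS_MUSCLE_O2 = 0.17


def se_to_sd(se: float, n: int) -> float:
    """Convert a standard error of the mean to a per-animal SD."""
    return se * math.sqrt(n)


# --- body size and composition (group mean, SE); n per group -------------

BODY_COMPOSITION_N = {
    ("mdx", "juvenile"): 8,
    ("control", "juvenile"): 8,
    ("mdx", "adult"): 12,
    ("control", "adult"): 10,
}

_BODY = {
    # trait: {(genotype, age): (mean, se)}
    "weight_g": {
        ("mdx", "juvenile"): (16.5, 0.7),
        ("control", "juvenile"): (21.0, 0.7),
        ("mdx", "adult"): (29.1, 0.6),
        ("control", "adult"): (28.6, 0.6),
    },
    "ffm_g": {
        ("mdx", "juvenile"): (14.6, 0.4),
        ("control", "juvenile"): (18.0, 0.4),
        ("mdx", "adult"): (27.5, 0.3),
        ("control", "adult"): (23.7, 0.4),
    },
    "fat_g": {
        ("mdx", "juvenile"): (1.96, 0.44),
        ("control", "juvenile"): (2.3, 0.44),
        ("mdx", "adult"): (2.16, 0.36),
        ("control", "adult"): (4.95, 0.39),
    },
    "body_len_mm": {
        ("mdx", "juvenile"): (77.7, 0.4),
        ("control", "juvenile"): (83.0, 0.4),
        ("mdx", "adult"): (96.7, 0.3),
        ("control", "adult"): (96.3, 0.4),
    },
    "femur_len_mm": {
        ("mdx", "juvenile"): (12.6, 0.1),
        ("control", "juvenile"): (13.0, 0.1),
        ("mdx", "adult"): (16.1, 0.1),
        ("control", "adult"): (15.7, 0.1),
    },
    "tibia_len_mm": {
        ("mdx", "juvenile"): (15.5, 0.1),
        ("control", "juvenile"): (16.0, 0.1),
        ("mdx", "adult"): (18.3, 0.1),
        ("control", "adult"): (17.9, 0.1),
    },
}


def body_composition() -> pd.DataFrame:
    """Tidy body-composition reference table (one row per group × trait)."""
    rows = []
    for trait, groups in _BODY.items():
        for (g, a), (mean, se) in groups.items():
            rows.append(
                {
                    "genotype": g,
                    "age_group": a,
                    "trait": trait,
                    "mean": mean,
                    "se": se,
                    "n": BODY_COMPOSITION_N[(g, a)],
                }
            )
    return pd.DataFrame(rows)


# --- muscle protein synthesis summaries ----------------------------------
# Columns: tp_mg (total protein mass), tp_fsr / mp_fsr (%/d), rna_per_tp
# (mg RNA / g protein), k_rna (g protein synthesized / g RNA / d).

MUSCLE_PROTEIN_N = {"gastrocnemius": (8, 8, 8, 7), "diaphragm": (8, 8, 4, 4), "heart": (8, 8, 8, 7)}

_MUSCLE_ROWS = [
    # muscle, genotype, age, tp_mg, se, tp_fsr, se, mp_fsr, se, rna_per_tp, se, k_rna, se
    ("gastrocnemius", "mdx", "juvenile", 11.1, 0.6, 31.1, 1.2, 24.7, 0.9, 17.7, 0.5, 17.6, 0.8),
    ("gastrocnemius", "control", "juvenile", 15.1, 0.6, 12.5, 1.2, 10.4, 0.9, 10.2, 0.5, 12.3, 0.8),
    ("gastrocnemius", "mdx", "adult", 29.2, 0.6, 9.8, 1.2, 6.7, 1.0, 7.7, 0.6, 12.9, 0.9),
    ("gastrocnemius", "control", "adult", 24.8, 0.6, 3.9, 1.3, 3.2, 1.0, 5.3, 0.6, 7.2, 0.9),
    ("diaphragm", "mdx", "juvenile", 7.4, 0.4, 27.3, 1.3, 21.5, 0.9, 25.0, 1.0, 10.9, 0.4),
    ("diaphragm", "control", "juvenile", 7.3, 0.4, 13.7, 1.4, 11.1, 1.0, 18.9, 1.1, 7.2, 0.5),
    ("diaphragm", "mdx", "adult", 15.5, 0.5, 15.7, 1.5, 10.5, 1.1, 18.8, 1.7, 9.0, 0.7),
    ("diaphragm", "control", "adult", 11.2, 0.5, 9.6, 1.4, 7.0, 1.0, 12.9, 1.4, 7.2, 0.6),
    ("heart", "mdx", "juvenile", 14.3, 0.5, 15.1, 0.5, 13.6, 0.5, 16.2, 0.5, 9.5, 0.5),
    ("heart", "control", "juvenile", 14.3, 0.5, 12.9, 0.5, 12.9, 0.5, 16.4, 0.5, 7.9, 0.5),
    ("heart", "mdx", "adult", 19.2, 0.5, 8.4, 0.5, 8.1, 0.5, 12.3, 0.5, 6.9, 0.5),
    ("heart", "control", "adult", 18.2, 0.5, 7.9, 0.5, 8.0, 0.5, 11.4, 0.5, 7.0, 0.5),
]


def muscle_protein() -> pd.DataFrame:
    """Tidy muscle protein-synthesis reference table."""
    cols = [
        "muscle", "genotype", "age_group",
        "tp_mg", "tp_mg_se", "tp_fsr", "tp_fsr_se", "mp_fsr", "mp_fsr_se",
        "rna_per_tp", "rna_per_tp_se", "k_rna", "k_rna_se",
    ]
    return pd.DataFrame(_MUSCLE_ROWS, columns=cols)


#: Muscle total-protein concentrations, mg protein / g wet muscle,
#: {(muscle, genotype, age): (mean, se)}.
TP_CONC_MG_G = {
    ("gastrocnemius", "mdx", "juvenile"): (134.0, 4.0),
    ("gastrocnemius", "control", "juvenile"): (151.0, 3.0),
    ("gastrocnemius", "mdx", "adult"): (142.0, 3.0),
    ("gastrocnemius", "control", "adult"): (163.0, 2.0),
    ("diaphragm", "mdx", "juvenile"): (135.0, 3.0),
    ("diaphragm", "control", "juvenile"): (149.0, 6.0),
    ("diaphragm", "mdx", "adult"): (138.0, 4.0),
    ("diaphragm", "control", "adult"): (146.0, 5.0),
    ("heart", "mdx", "juvenile"): (156.0, 3.0),
    ("heart", "control", "juvenile"): (158.0, 2.0),
    ("heart", "mdx", "adult"): (160.0, 2.0),
    ("heart", "control", "adult"): (162.0, 2.0),
}

# --- energy balance summaries (FFM/fat-adjusted least-square means) ------

ENERGY_BALANCE_N = {
    ("mdx", "juvenile"): 8,
    ("control", "juvenile"): 8,
    ("mdx", "adult"): 9,
    ("control", "adult"): 12,
}

_ENERGY_ROWS = [
    # genotype, age, intake, ee_24h, ee_dark, ee_light, ee_resting, balance,
    # rq_24h, rq_dark, rq_light   (kcal/d, kcal/12 h for phases)
    ("mdx", "juvenile", 11.0, 11.0, 5.9, 5.1, 9.0, 0.44, 0.91, 0.97, 0.84),
    ("control", "juvenile", 11.3, 10.5, 5.7, 4.8, 8.4, 1.03, 0.92, 0.97, 0.87),
    ("mdx", "adult", 11.7, 10.4, 5.5, 4.9, 6.5, 0.74, 0.95, 0.99, 0.92),
    ("control", "adult", 10.9, 10.0, 5.6, 4.4, 6.1, 0.77, 0.96, 0.99, 0.93),
]


def energy_balance() -> pd.DataFrame:
    """Tidy energy-balance reference table (adjusted group means)."""
    cols = [
        "genotype", "age_group", "intake_kcal_d", "ee_24h", "ee_dark",
        "ee_light", "ee_resting", "balance_kcal_d", "rq_24h", "rq_dark",
        "rq_light",
    ]
    df = pd.DataFrame(_ENERGY_ROWS, columns=cols)
    df["n"] = [ENERGY_BALANCE_N[(g, a)] for g, a in zip(df.genotype, df.age_group)]
    return df


# --- whole-body flux defaults --------------------------------------------
# No numeric whole-body fluxes are printed; these are realistic mouse
# phenylalanine fluxes chosen to match the reported relative contrasts
# (juvenile mdx ~35% above control, adult mdx ~60% above control) with a
# constant 17% hydroxylation fraction.  Ra_tyr is set to 0.7 × Ra_phe.

FLUX_DEFAULTS = {
    # (genotype, age): ra_phe µmol·kg⁻¹·h⁻¹
    ("mdx", "juvenile"): 540.0,
    ("control", "juvenile"): 400.0,
    ("mdx", "adult"): 400.0,
    ("control", "adult"): 250.0,
}
RA_TYR_TO_RA_PHE = 0.7
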