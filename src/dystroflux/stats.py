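"""Group-comparison machinery: two-way ANOVA, ANCOVA LS-means, Tukey.

The study design is a 2×2 factorial (genotype × age group) with unequal
cell sizes and strong body-size confounding, so group contrasts for
size-dependent outcomes (energy expenditure, whole-body fluxes) are
reported as least-squares means adjusted for body-size covariates
(fat-free mass, fat mass, bone or body lengths) evaluated at the grand
covariate mean.  When a covariate interacts with a design factor, the
common-slope adjustment is invalid and the analysis is stratified by
that factor.

Model fitting is ordinary least squares (statsmodels) with Type-II sums
of squares; post-hoc pairwise comparisons use Tukey's studentized-range
method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ModelSpec",
    "LsMeansResult",
    "two_way_anova",
    "ancova_lsmeans",
    "tukey_posthoc",
]


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, design factors, covariates and interaction thresholds."""

    outcome: str
    factors: tuple[str, ...] = ("genotype", "age_group")
    covariates: tuple[str, ...] = ()
    interaction_threshold: float = 0.10   # annotation of factor×factor
    stratify_threshold: float = 0.05      # covariate×factor stratification


@dataclass
class LsMeansResult:
    """Adjusted group means with the supporting model evidence."""

    means: pd.DataFrame          # factor levels, lsmean, se, n
    anova: pd.DataFrame          # effect, F, p
    slopes: dict                 # covariate -> fitted common slope
    stratified: bool
    stratified_by: list = field(default_factory=list)
    strata: dict = field(default_factory=dict)
    dropped_covariates: list = field(default_factory=list)
    n_dropped_rows: int = 0


def _formula(outcome: str, factors: list[str], covariates: list[str]) -> str:
    terms = []
    if factors:
        terms.append(" * ".join(f"C({f})" for f in factors))
    terms.extend(f"Q('{c}')" for c in covariates)
    rhs = " + ".join(terms) if terms else "1"
    return f"Q('{outcome}') ~ {rhs}"


def _tidy_anova(fit, typ: int = 2) -> pd.DataFrame:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect-null fits emit 0/0 warnings
        table = sm.stats.anova_lm(fit, typ=typ)
    table = table.reset_index().rename(
        columns={"index": "effect", "PR(>F)": "p", "F": "F"}
    )
    table["effect"] = (
        table["effect"].str.replace(r"C\((\w+)\)", r"\1", regex=True)
        .str.replace(r"Q\('(\w+)'\)", r"\1", regex=True)
    )
    # A perfect-null design (all group means identical) gives F = 0 and an
    # undefined p from anova_lm; report p = 1 for a zero F.
    zero_f = table["F"].notna() & np.isclose(table["F"].fillna(1.0), 0.0)
    table.loc[zero_f & table["p"].isna(), "p"] = 1.0
    return table


def _check_cells(df: pd.DataFrame, factors: list[str], min_per_cell: int = 2) -> None:
    counts = df.groupby(list(factors), observed=True).size()
    expected = int(np.prod([df[f].nunique() for f in factors]))
    if len(counts) < expected or (counts < min_per_cell).any():
        raise ValueError(
            f"every {' × '.join(factors)} cell needs at least "
            f"{min_per_cell} animals"
        )


def two_way_anova(
    table: pd.DataFrame,
    outcome: str,
    factors: tuple[str, ...] = ("genotype", "age_group"),
) -> pd.DataFrame:
    """Factorial ANOVA with Type-II sums of squares.

    Returns a tidy effect table (effect, sum_sq, df, F, p) covering the
    main effects and their interaction.  Factors with a single observed
    level are dropped from the model (degenerate single-age designs are
    analysed for the remaining factor only).
    """
    factors = [f for f in factors if table[f].nunique() > 1]
    if not factors:
        raise ValueError("no factor with at least two levels")
    df = table.dropna(subset=[outcome, *factors])
    _check_cells(df, factors)
    fit = smf.ols(_formula(outcome, factors, []), data=df).fit()
    return _tidy_anova(fit)


def ancova_lsmeans(
    table: pd.DataFrame,
    outcome: str,
    factors: tuple[str, ...] = ("genotype", "age_group"),
    covariates: tuple[str, ...] = (),
    stratify_threshold: float = 0.05,
) -> LsMeansResult:
    """Covariate-adjusted least-squares group means.

    Fits ``outcome ~ factor1 * factor2 + covariates`` and evaluates the
    fitted surface at every observed factor combination with all
    covariates at their grand mean.  Covariate×factor interactions are
    screened at ``stratify_threshold``; when significant, the result is
    flagged ``stratified`` and per-stratum fits (one per level of the
    interacting factor) are attached.

    Zero-variance covariates are dropped with a warning (reducing the
    fit to a plain ANOVA); genuinely collinear covariates raise.
    """
    factors = [f for f in factors if table[f].nunique() > 1]
    if not factors:
        raise ValueError("no factor with at least two levels")
    used = [outcome, *factors, *covariates]
    df = table.dropna(subset=[c for c in used if c in table.columns])
    n_dropped = len(table) - len(df)

    covs, dropped = [], []
    for c in covariates:
        if df[c].std() == 0:
            warnings.warn(f"covariate {c!r} has zero variance; dropped", stacklevel=2)
            dropped.append(c)
        else:
            covs.append(c)
    if len(covs) > 1:
        x = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in covs])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(f"covariates {covs} are collinear")

    fit = smf.ols(_formula(outcome, factors, covs), data=df).fit()
    anova = _tidy_anova(fit)

    # adjusted means at the grand covariate mean
    combos = df[list(factors)].drop_duplicates().sort_values(list(factors))
    pred_frame = combos.copy()
    for c in covs:
        pred_frame[c] = df[c].mean()
    pred = fit.get_prediction(pred_frame)
    means = combos.reset_index(drop=True).assign(
        lsmean=pred.predicted_mean,
        se=pred.se_mean,
        n=[
            len(df[np.logical_and.reduce([df[f] == row[f] for f in factors])])
            for _, row in combos.iterrows()
        ],
    )

    slopes = {c: fit.params[f"Q('{c}')"] for c in covs}

    # covariate × factor interaction screen
    stratified_by: list[str] = []
    strata: dict = {}
    if covs:
        for f in factors:
            extra = " + ".join(f"Q('{c}'):C({f})" for c in covs)
            full = smf.ols(
                _formula(outcome, factors, covs) + " + " + extra, data=df
            ).fit()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp = sm.stats.anova_lm(fit, full)
            p_int = float(cmp["Pr(>F)"].iloc[1])
            if np.isfinite(p_int) and p_int < stratify_threshold:
                stratified_by.append(f)
        for f in stratified_by:
            per_level = {}
            others = [g for g in factors if g != f]
            for level, sub in df.groupby(f, observed=True):
                if others and all(sub[g].nunique() > 1 for g in others):
                    per_level[level] = ancova_lsmeans(
                        sub, outcome, tuple(others), tuple(covs),
                        stratify_threshold=1.1,  # no recursive stratification
                    )
            strata[f] = per_level

    return LsMeansResult(
        means=means,
        anova=anova,
        slopes=slopes,
        stratified=bool(stratified_by),
        stratified_by=stratified_by,
        strata=strata,
        dropped_covariates=dropped,
        n_dropped_rows=n_dropped,
    )


def tukey_posthoc(
    table: pd.DataFrame,
    outcome: str,
    factors: tuple[str, ...] = ("genotype", "age_group"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey studentized-range pairwise comparisons across design cells.

    Cells are the observed factor-level combinations; returns one row
    per pair with the mean difference, adjusted p-value, and the
    confidence interval at ``1 − alpha``.
    """
    df = table.dropna(subset=[outcome, *factors]).copy()
    group = df[list(factors)].astype(str).agg(":".join, axis=1)
    if group.nunique() < 2:
        raise ValueError("Tukey post-hoc needs at least two groups")
    res = pairwise_tukeyhsd(df[outcome].to_numpy(float), group.to_numpy(), alpha=alpha)
    out = pd.DataFrame(
        res.summary().data[1:], columns=[c.strip() for c in res.summary().data[0]]
    )
    out = out.rename(columns={"p-adj": "p_adj", "meandiff": "mean_diff"})
    for col in ("mean_diff", "p_adj", "lower", "upper"):
        out[col] = out[col].astype(float)
    return out
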