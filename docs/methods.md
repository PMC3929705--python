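# Methods

This note documents the models implemented in dystroflux, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical and design choices a maintainer
should know about.

## Indirect calorimetry

Energy expenditure uses the abbreviated Weir equation,
EE = 3.941·VO2 + 1.106·VCO2 (kcal per litre of gas), with no
urinary-nitrogen term — the standard form for rodent cage calorimetry
where urine is not collected. Gas volumes are assumed already
normalized to standard conditions by the instrument; no STP correction
is applied.

Budgets are computed over the trailing integer number of 24-h days in a
trace (default: all full days; the intended acquisition is a 72-h
window after adaptation). The dark phase is 18:00–06:00, configurable.
Phase sums are per day, so `ee_dark + ee_light = ee_24h` holds exactly
on integer-day windows, and `balance = intake − ee_24h` is an identity.

Resting EE is the mean of the two lowest non-overlapping 90-s EE
readings in the window, extrapolated by ×960 (the number of 90-s
periods per day). Ties break to the earliest reading. No inactivity
precondition is imposed by default — the lowest readings in practice
follow quiet periods anyway — but an optional quiet-window filter
(`quiet_min`) is available. Traces at epochs finer than 90 s are
aggregated to 90-s periods; coarser epochs are rejected rather than
interpolated.

Intake is the feeder-mass decrease minus recorded spillage, times the
diet metabolizable energy density (default 3.64 kcal/g for the
semi-purified AIN93G-type diet). Feeder refills must be flagged
explicitly; an unflagged mass increase is an error, never silently
corrected, because unnoticed spillage/refill artefacts are a known
source of intake overestimation in adult mice.

## Tracer kinetics

The model is a primed-continuous infusion at isotopic steady state.
With tracer infused at rate *i* and plateau enrichment *E* (mole
percent excess), the endogenous (tracee) flux is Ra = i·(100/E − 1).
A `convention="total"` switch returns i·100/E instead; the simulator
and estimator always share one convention, so round trips are
convention-invariant.

Hydroxylation of phenylalanine to tyrosine is traced by D4-tyrosine
produced from D5-phenylalanine:

    Q_pt = Ra_tyr · (E_d4tyr / E_d5phe) · Ra_phe/(i_phe + Ra_phe).

The trailing factor corrects for conversion of the infused tracer
itself: at steady state the total conversion flux acts on the mixed
(tracee + tracer) phenylalanine pool, and the endogenous share of
disposal is Ra/(i + Ra). At the default rates (i = 16 µmol·kg⁻¹·h⁻¹
against fluxes of several hundred) the correction is ~4%. It can be
switched off. Q_pt exceeding Ra_phe is flagged as an
inconsistent-enrichments error rather than clipped.

In the postabsorptive state Ra_phe is protein breakdown; synthesis is
PS = Ra − Q_pt and net balance −Q_pt (hydroxylation is irreversible).
Protein-equivalent rates use a phenylalanine molar mass of 165.19 g/mol
and a 4% average phenylalanine content of body protein. Enrichments
below an instrument floor (0.05 mpe) are treated as missing, not zero.

## Flooding-dose synthesis

FSR (%/d) = S_B/(S_A·t) · 1440 · 100, with the labelling time t in
minutes (default 15). The flooding dose is assumed to hold the
precursor specific radioactivity constant over the label; no decay
correction is applied (that is the point of the flood). The precursor
pool defaults to the tissue free pool, with blood as an alternative;
blood/tissue equilibration is checked against a ±15% ratio band and
failing samples are flagged, never dropped.

Translational capacity is RNA/TP (mg RNA per g protein) and efficiency
K_RNA = 10·FSR/(RNA/TP) (g protein per g RNA per day); the identity
K_RNA·(RNA/TP) = 10·FSR holds exactly for all outputs. Absolute
synthesis is computed for total protein only; the myofibrillar
purification is not quantitative, so the result type deliberately has
no absolute-MP field.

## Degradation and necrosis burden

Degradation = synthesis − accretion. Juvenile muscle assumes linear
protein accretion from the 4-wk to the 8-wk (adult-plateau) pool mass
over 28 days; adult muscle assumes steady state, where degradation as a
percent of pool mass equals the FSR identically. Negative inferred
degradation (accretion exceeding synthesis) is reported with a warning
as a signal of inconsistent inputs.

The necrosis burden of a daily fiber-necrosis fraction p over d days is
offered in two modes: linear accumulation min(1, p·d) (default — each
day's necrotic fibers treated as new tissue) and compounding
1 − (1−p)^d (sampling with replacement). At 3%/d over a week they give
21.0% and 19.2%; both are reported because the distinction is below the
precision of the underlying histology.

## Energy partition

Two fractions parameterize the cost of muscle protein synthesis:
f_muscle = 0.30 (skeletal-muscle share of whole-body O2 consumption)
and f_ps = 0.17 (protein-synthesis share of resting muscle O2). The
baseline contribution of muscle protein synthesis to whole-body resting
EE is 100·f_muscle·f_ps ≈ 5.1%. A k-fold change in synthesis rates
raises the muscle-level synthesis share to 100·f_ps·k/((1−f_ps)+f_ps·k)
with non-synthesis O2 held constant (33.9% at k = 2.5). The whole-body
increment uses 100·f_muscle·f_ps·(k·m − 1) with m the muscle protein
mass ratio (proxied by gastrocnemius TP masses). The increment formula
is the simplest consistent with the other two and is configurable; no
single formula reproduces every back-of-envelope variant in circulation,
so the increment is reported as a model output, not a validated
constant.

## Group statistics

Fits are ordinary least squares with Type-II sums of squares (a
reasonable default for the near-balanced 2×2 design; the historical
GLM software's convention is not documented). Factors with a single
observed level are dropped so degenerate (e.g. juvenile-only) designs
analyse the remaining factor. Least-squares means evaluate the fitted
surface at each factor combination with covariates at the grand mean;
SEs come from the prediction variance. Covariate×factor interactions
are screened by an F-test at 0.05; significant interactions flag the
result as stratified and attach per-stratum fits, mirroring the
practice of analysing age groups separately when a body-size covariate
interacts with the design. Zero-variance covariates are dropped with a
warning (the fit then reduces exactly to ANOVA); genuinely collinear
covariates raise. Missing values are deleted listwise with a logged
count. Tukey post-hoc comparisons use the studentized-range
distribution via statsmodels, cross-checked in the tests against a
direct scipy computation.

## Synthetic data generator

The generator emulates the study conditions: four groups (mdx/control ×
juvenile/adult) with the published group means and SEs of body
composition, muscle protein, and energy balance as defaults (SE×√n → SD
with the published group sizes); 72-h cage sessions at 90-s epochs with
a sinusoidal circadian component peaking mid-dark, Bernoulli activity
bursts (higher rate in the dark) that raise VO2 and emit beam breaks,
and dark-concentrated meals with a 5% recorded spillage fraction;
plateau enrichments implied by chosen fluxes and a 17% hydroxylation
fraction; and flooding-dose radioactivities implied by chosen FSRs.

Noise is multiplicative, mean-preserving log-normal everywhere
(positive support, constant CV — the natural model for gas volumes,
enrichments and radioactivities; also used for cohort traits, where
normal draws would go negative for juvenile fat mass). Within-animal
measurement CVs are not published; the 5% default is a convention,
flagged in the configuration. Whole-body flux defaults are realistic
mouse phenylalanine fluxes (250–540 µmol·kg⁻¹·h⁻¹) matching the
reported relative genotype contrasts (~35% higher in juvenile mdx,
~60% in adult mdx); no absolute flux values are published to anchor
them further. The FFM–body-length correlation (r ≈ 0.96 in juveniles)
is injected through a Gaussian copula.

Each simulator is the exact algebraic inverse of its estimator in the
noiseless limit, and one global seed fans out to per-animal substreams
keyed by animal index, so enlarging a cohort never perturbs existing
animals and fixed seeds give bit-identical outputs.

What the generator does **not** emulate: chamber washout dynamics and
instrument drift, the pharmacokinetics of the tracer priming phase
(only the achieved plateau is modelled), diurnal RQ structure (one RQ
per trace), correlated multi-muscle measurements within an animal, and
any histological structure. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated measurement
model, not robustness to these real-data complications.

## Numerical choices and problem sizes

Tolerances: noiseless round trips are asserted at 1e-9–1e-12 relative;
noisy-recovery bias at <1% over 1000 Monte-Carlo replicates; the
type-I-error calibration of the genotype test uses 2000 simulated
null cohorts (n = 8 per cell) against a 0.05 ± 0.01 band. The
end-to-end pipeline tests run 3 animals per group with 24-h traces;
the defaults (published group sizes, 72-h traces) run in well under a
minute. These sizes were chosen so the full suite exercises every
stage at meaningful precision while staying quick to iterate on.

Known limitation: the published adult mdx diaphragm cell is internally
inconsistent at the group-mean level — 10×FSR/(RNA/TP) = 8.35 vs the
tabulated efficiency 9.0 (7.2% apart; it is the n = 4 sub-sample, where
the mean of per-animal ratios can deviate this much from the ratio of
means). The consistency test documents this: 11 of 12 cells agree
within 5%, the juvenile gastrocnemius cells to printed rounding.
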