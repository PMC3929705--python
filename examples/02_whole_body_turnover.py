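"""Whole-body protein turnover from tracer plateau enrichments.

Generates plateau enrichments for a postabsorptive mouse with a true
phenylalanine flux of 430 µmol/kg/h of which 17% is irreversibly
hydroxylated to tyrosine, then runs the estimation chain: isotope
dilution -> hydroxylation flux -> synthesis/balance partition.
"""

from dystroflux import TracerTruth, estimate_fluxes, simulate_tracer_plateau

truth = TracerTruth(
    ra_phe_true=430.0,
    ra_tyr_true=300.0,
    hydroxylation_fraction_true=0.17,
    enrichment_noise_cv=0.0,
)
enrichment = simulate_tracer_plateau(truth)
result = estimate_fluxes(enrichment)

print(f"plateau enrichments  : D5-phe {enrichment.e_d5_phe:.3f} mpe, "
      f"D4-tyr {enrichment.e_d4_tyr:.4f} mpe, D2-tyr {enrichment.e_d2_tyr:.3f} mpe")
print(f"Ra phe (breakdown)   : {result.ra_phe:7.1f} µmol/kg/h")
print(f"Ra tyr               : {result.ra_tyr:7.1f} µmol/kg/h")
print(f"hydroxylation Q_pt   : {result.q_pt:7.1f} µmol/kg/h "
      f"({100 * result.hydroxylation_fraction:.1f}% of flux)")
print(f"synthesis PS_phe     : {result.ps_phe:7.1f} µmol/kg/h")
print(f"net balance          : {result.net_balance:7.1f} µmol/kg/h")
print(f"protein breakdown    : {result.protein_breakdown:7.3f} g/kg/h")
print(f"protein balance      : {result.protein_balance:7.3f} g/kg/h")

# Noiseless enrichments invert exactly: Ra and the 17% hydroxylation
# fraction are recovered to machine precision.  The negative balance is
# the irreversible phenylalanine loss the diet must replace.
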