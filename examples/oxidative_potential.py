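"""Oxidative-potential pipeline: depletion rate, blanks, LOD, mass dose.

Simulates a DTT assay well (12.5 nmol reagent, read at 0/15/30 min) plus
three laboratory blanks, and runs the full blank-correction and
mass-normalization chain; then prints the exposure arithmetic used for
air–liquid-interface dosing.
"""

from geoparticle import assay
from geoparticle.fixtures import make_depletion_series

sample = make_depletion_series(a0=12.5, rate=0.06, sd=0.05, seed=1, well_mass=2.0)
blank_rates = tuple(
    assay.depletion_rate(make_depletion_series(12.5, 0.005, sd=0.02, seed=s))[0]
    for s in (10, 11, 12)
)
result = assay.op_result(sample, assay.BlankSet(blank_rates))

print(f"raw rate:            {result.raw_rate:.4f} nmol/min")
print(f"blank-corrected:     {result.blank_corrected_rate:.4f} nmol/min")
print(f"LOD (3 x blank SD):  {result.lod:.4f} nmol/min  above LOD: {result.above_lod}")
print(f"OP per mass:         {result.mass_normalized:.4f} nmol/min/ug")

print(f"\nDTT in well: {assay.reagent_amount(50, 0.25):g} nmol (50 uL of 0.25 mM)")
print(f"high dose:   {assay.deposition_dose(467, 0.1, 4.67):g} ug/cm^2 "
      f"(100 uL of 467 ug/mL on a 4.67 cm^2 insert)")
print(f"seeding:     {assay.seeding_density(5e5, 4.67):g} cells/cm^2")
# The mass-normalized, blank-corrected depletion rate is the sample's
# oxidative potential; results below the LOD are flagged, not censored.
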