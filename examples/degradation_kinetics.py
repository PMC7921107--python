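"""Degradation kinetics of stored DNA: breakage, freeze-thaw, temperature.

Evaluates the four kinetics models on well-known reference conditions and
prints what each number means for a storage system.
"""

from dnastore import (
    ArrheniusModel,
    FirstOrderBreakage,
    FreezeThawModel,
    LesionModel,
    arrhenius_scale,
    freeze_thaw_intact,
    intact_fraction_breakage,
    lesion_probability,
    rate_from_half_life,
)

# Archival storage: permafrost mtDNA survives with a per-nt fragmentation
# rate of ~5.5e-6 per year.  After 500 years a 242-nt strand is a coin flip.
fossil = FirstOrderBreakage(rate_per_nt_per_year=5.5e-6)
intact = intact_fraction_breakage(fossil, length=242, time=500)
print(f"242-nt strand, 500 yr in permafrost: {intact:.1%} intact "
      f"({1 - intact:.1%} fragmented)")

# The same arithmetic backwards: what rate does a 500-year half-life imply?
inferred = rate_from_half_life(length=242, half_life=500)
print(f"rate implied by a 500-yr half-life: "
      f"{inferred.rate_per_nt_per_year:.2e} /nt/yr")

# Working storage: every access of a frozen aliquot costs a freeze-thaw.
ft = FreezeThawModel()  # fitted: 0.9484 * exp(-0.068 * cycles)
for cycles in (1, 5, 20):
    frac = freeze_thaw_intact(ft, cycles)
    print(f"after {cycles:2d} freeze-thaw cycles: {frac:.1%} intact")

# Accelerated aging: a rate measured at 70 C, extrapolated to room
# temperature with an Arrhenius model (Ea must come from the aging study).
aging = ArrheniusModel(activation_energy=120e3, reference_rate=1.0,
                       reference_temperature=343.15)
ratio = arrhenius_scale(aging, 298.15)
print(f"70 C -> 25 C at Ea = 120 kJ/mol: rate x{ratio:.2e} "
      f"(~{1 / ratio:.0f}x slower when cold)")

# Base lesions corrupt symbols without breaking the strand: ~6% of 200-nt
# strands pick up a depurination/8-oxo-dG per year at room temperature.
lesions = LesionModel.from_strand_fraction(0.06, length=200)
print(f"lesion rate: {lesions.lesion_rate_per_nt_per_year:.2e} /nt/yr; "
      f"2-yr lesioned fraction of a 200-nt strand: "
      f"{lesion_probability(lesions, 200, 2):.1%}")
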