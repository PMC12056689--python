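"""How much silica does it take to confine a drug glass?

Computes the cubic-assumption molecular footprint of celecoxib, the
monolayer capacity of two silica grades, and the two critical mixing
ratios: enough silica that every drug molecule has a monolayer site, and
enough that the pore volume holds the whole drug load as glass.
"""

from mesoglass import (
    BUILTIN_SILICAS,
    BUILTIN_SUBSTANCES,
    loading_report,
)

cel = BUILTIN_SUBSTANCES["celecoxib"]
print(f"drug: {cel.name}  M = {cel.molar_mass} g/mol, glass density {cel.glass_density} g/cm³\n")

for grade in ("SYL350", "SYL730"):
    rep = loading_report(BUILTIN_SILICAS[grade], cel, ms_fraction_full_rigid=None)
    print(f"{grade}  (SA {BUILTIN_SILICAS[grade].surface_area} m²/g, "
          f"Vp {BUILTIN_SILICAS[grade].pore_volume} mL/g)")
    print(f"  footprint            {rep.footprint_nm2:.3f} nm²/molecule")
    print(f"  monolayer capacity   {rep.monolayer_capacity_per_g:.2e} molecules/g")
    print(f"  f(monolayer)         {100 * rep.ms_fraction_monolayer:.1f} % silica")
    print(f"  f(pore filling)      {100 * rep.ms_fraction_pore_filling:.1f} % silica\n")

print("f(monolayer): below this silica mass fraction some drug has no wall")
print("contact; f(pore filling): below it some drug must sit outside the pores.")
print("A 25% silica mixture is 'overloaded' by both measures for both grades.")
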