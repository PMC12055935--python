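"""Evaluate the shipped constitutive models at a few material points.

Prints each component's small-strain Young's modulus and its uniaxial
stress at 5% stretch, plus the calcified plaque's elastic-plastic path:
linear up to the 0.48 MPa yield plateau, then perfectly plastic.
"""

from lesionlab import (
    MATERIAL_LIBRARY,
    get_material,
    small_strain_modulus,
    uniaxial_cauchy_stress,
    uniaxial_elastoplastic_path,
)

print(f"{'material':>12} {'E (small strain)':>18} {'sigma @ 5% stretch':>20}")
for name in sorted(MATERIAL_LIBRARY):
    model = get_material(name)
    mod = small_strain_modulus(model)
    sig = uniaxial_cauchy_stress(model, 1.05)
    print(f"{name:>12} {mod.value:12.3f} {mod.unit:<5} {sig:14.3f} {model.stress_unit}")

calcium = get_material("calcium")
path = uniaxial_elastoplastic_path(calcium, [0.0, 0.005, 0.02, 0.015])
print("\ncalcium strain path 0 -> 0.005 -> 0.02 -> 0.015 (load, yield, unload):")
print("  stresses [MPa]:", [round(float(s), 4) for s in path])
print("  (0.22 elastic, 0.48 plateau, then elastic unloading by E * 0.005)")
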