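"""Build a calcified lesion with an arc-splitting defect and export meshes.

Constructs the 90-degree-arc lesion, carves a through defect of normalized
width 1/3, and reports the exact stenosis, the carved calcium volume, and
the number of calcium fragments (an arc-splitting defect leaves two).
STL shells are written under scratch/ when run from the repository root.
"""

import math
from pathlib import Path

from lesionlab import DefectSpec, LesionConfig, build_cross_section, build_solid, carve_defect
from lesionlab.mesh import tessellate_and_export

config = LesionConfig(calcium_arc_angle=90.0)
section = build_cross_section(config, config.lesion_center)
healthy = math.pi * config.healthy_lumen_radius**2
print(f"mid-lesion lumen area : {section.area('lumen'):.4f} mm^2")
print(f"area stenosis         : {100 * (1 - section.area('lumen') / healthy):.1f} %")

intact = build_solid(config)
solid = carve_defect(intact, DefectSpec("through", w=1 / 3, l=1.0))
print(f"intact calcium volume : {intact.calcium_volume():.3f} mm^3")
print(f"carved calcium volume : {solid.carved_volume():.3f} mm^3 "
      f"({100 * solid.carved_volume() / intact.calcium_volume():.1f} % removed)")
print(f"calcium fragments     : {solid.calcium_component_count()}")

out = Path("scratch/example_meshes")
written = tessellate_and_export(solid, "stl", out, pitch=0.15)
print(f"wrote {len(written)} STL shells to {out}/")
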