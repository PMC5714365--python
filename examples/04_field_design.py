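"""Fit a treatment field to the phantom PTV and inspect its hardware.

Designs the posterior field of an AVG-CT plan: the range R is the deepest
water-equivalent depth of the distal PTV surface, the modulation M covers
the thickest PTV chord, the aperture is the PTV projection with a 1 cm
margin, and the compensator brings every target ray's distal surface to
exactly R (no smearing, 1 cm border smoothing).
"""

import numpy as np

from protonmotion import (
    BeamGeometry,
    PhantomConfig,
    average_ct,
    build_structures,
    fit_field,
    generate_phase_series,
    hu_to_rsp,
)

series = generate_phase_series(
    PhantomConfig(grid_shape=(48, 48, 48), voxel_spacing=4.0, seed=5)
)
structures = build_structures(series, 5.0)
rsp = hu_to_rsp(average_ct(series))

field = fit_field(structures.ptv, rsp, BeamGeometry(180), weight=0.5)

print(f"gantry angle: {field.geometry.gantry_angle} deg (posterior)")
print(f"distal range R:   {field.distal_range_cm:6.2f} cm WEPL")
print(f"SOBP width M:     {field.modulation_cm:6.2f} cm")
print(f"aperture: {int(field.aperture.sum())} open BEV pixels "
      f"({field.aperture_margin_cm} cm margin around the PTV projection)")
proj = structures.ptv.any(axis=field.geometry.axis)
print(f"compensator over the projection: min {field.compensator[proj].min():.2f}, "
      f"max {field.compensator[proj].max():.2f} cm WEPL")
print("(thick compensator rays point at shallow distal PTV surface)")
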