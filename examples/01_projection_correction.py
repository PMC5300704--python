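"""Convert projected flagellar lengths to true 3D arc lengths.

Fluorescence images show only the 2D projection of the helical filament
(0.16 um radius, 1.5 um pitch for the V. alginolyticus polar flagellum).
The slope of L3D against L2D gives a single correction factor.
"""

from flagrow import (
    VIBRIO_HELIX,
    arc_length_2d,
    arc_length_3d,
    correct_2d_to_3d,
    projection_correction_factor,
)

factor = projection_correction_factor(VIBRIO_HELIX, z_max=10_000.0, n_points=100)
print(f"one helical turn: L3D = {arc_length_3d(VIBRIO_HELIX, 1500):.1f} nm, "
      f"L2D = {arc_length_2d(VIBRIO_HELIX, 1500):.1f} nm")
print(f"correction factor over 0-10 um: L3D = {factor:.4f} * L2D")
print(f"a filament measured at 2000 nm in the image is really "
      f"{correct_2d_to_3d(2000.0, factor):.0f} nm long")
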