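"""Convert between pixels and degrees of visual angle on a known display.

Builds the reference apparatus — a 27-inch 1920x1080 monitor viewed at
60 cm — and converts the verification-target corner insets to visual angle.
"""

from gazeqc import DisplayModel, ViewingGeometry, deg_to_px, pixel_pitch, px_offset_to_deg
from gazeqc.geometry import target_annulus_diameters

display = DisplayModel.from_diagonal_inches(27.0, 1920, 1080)
viewing = ViewingGeometry(60.0)

print(f"pixel pitch: {pixel_pitch(display)[0]:.5f} cm/px (square pixels)")
print(f"480 px horizontal -> {px_offset_to_deg(480, display, viewing, 'x'):.2f} deg")
print(f"270 px vertical   -> {px_offset_to_deg(270, display, viewing, 'y'):.2f} deg")
print(f"0.63 deg target core -> {deg_to_px(0.63, display, viewing):.1f} px across")
print(f"target ring diameters: {[round(d, 2) for d in target_annulus_diameters()]} deg")

# The corner targets sit 480 px in from the left/right edges and 270 px in
# from the top/bottom edges — about 14 and 8 degrees of visual angle at a
# 60 cm viewing distance, spanning the eccentricities typical experiments use.
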