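"""2D vs 3D measurement arithmetic and the bidimensional progression rule.

Clinical trials call progression when the product of two perpendicular
diameters on the largest tumor slice grows by 25%.  Equal per-dimension
growth inflates a 2D product far less than a 3D volume, so volumetry sees
growth much earlier than bidimensional measurement.
"""

from gliogrow import bidim_progression, homogeneous_scaling

for d in (0.12, 0.20, 0.25):
    g2 = homogeneous_scaling(d, 2)
    g3 = homogeneous_scaling(d, 3)
    print(f"+{d:.0%} per dimension -> product +{g2:.0%} (2D), volume +{g3:.0%} (3D)")

fold = 1 + homogeneous_scaling(0.44, 3)
print(f"+44% per dimension -> {fold:.2f}-fold volume")

# the 2D rule at its own threshold: a product going 40 -> 50 is exactly +25%
print("product 40 -> 50 px^2 progresses (2D rule):", bidim_progression(40, 50))
print("product 40 -> 49 px^2 progresses (2D rule):", bidim_progression(40, 49))
# a tumor can therefore double in volume (+100%) while every dimension grew
# only 26%, a +59% product change... but if growth is anisotropic and off
# the measured slice, the 2D product may not move at all (see example 01)
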