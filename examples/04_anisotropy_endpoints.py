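"""Mean-intercept-length anisotropy on its two ideal endpoints.

The anisotropy factor is scaled from 0 (total isotropy) to 1 (total
anisotropy).  A voxelized solid ball has no preferred direction and should
score ~0; thin parallel plates are the maximally aligned structure and
should score ~1.
"""

from pomoct import anisotropy, make_ball, make_plates

ball = make_ball(radius_vox=40, shape=(128, 128, 128))
plates = make_plates(spacing_vox=16, thickness_vox=1, shape=(128, 128, 128))

a_ball = anisotropy(ball, n_directions=128)
a_plates = anisotropy(plates, n_directions=128)

print(f"solid ball      anisotropy = {a_ball:.3f}   (isotropy endpoint, expect ~0)")
print(f"parallel plates anisotropy = {a_plates:.3f}   (total-anisotropy endpoint, expect ~1)")
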