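"""Full orthogonal-phase reconstruction of the monocyte nucleus.

Simulates the monocyte phase maps, extracts the inflexion-curve boundaries
on both planes, reconciles the phase centres across the shared x axis,
merges the two nucleus outlines into a closed surface and fits an
axis-aligned ellipsoid.  The printed centre and semi-axes should match the
preset values (0, 0, 3.00) μm and (3.40, 3.70, 3.00) μm to within a few
hundredths of a micrometre; the equivalent volume approximates
(4/3)π·3.4·3.7·3.0 = 158.06 μm³.
"""

import numpy as np

from phasecell import build_monocyte_edward, characterize_nucleus

scene = build_monocyte_edward()
res = characterize_nucleus(scene)

rep = res.report
print("recovered nucleus centre (μm):", np.round(res.center_centroid, 3))
print("extremum-rule centre (μm):    ", np.round(res.center_extremum, 3))
print("fitted semi-axes (μm):        ", np.round(rep.semi_axes, 3))
print(f"equivalent volume (μm³):       {rep.equivalent_volume:.2f}")
print(f"mesh volume (μm³):             {rep.mesh_volume:.2f}")
print("ellipsoidal degree (b/a, c/a, c/b):",
      tuple(round(r, 3) for r in rep.ellipsoidal_degree))
print(f"fit residual (μm):             {rep.residual:.4f}")
print()
print("The centroid-rule centre drives the reconstruction; the extremum rule")
print("is reported for comparison — on the x-z view the membrane thickness")
print("dominates the phase, so its z estimate sits below the nucleus centre.")
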