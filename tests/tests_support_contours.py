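"""Shared synthetic-contour helpers for the test suite."""

import numpy as np

from phasecell.boundary_extraction import BoundaryContour


def circle_contour(r=3.0, n=721, cx=0.0, cy=0.0, plane="xy"):
    t = np.linspace(0, 2 * np.pi, n)
    return BoundaryContour(
        plane=plane, points=np.stack([cx + r * np.cos(t), cy + r * np.sin(t)], 1)
    )


def ellipse_contour(a, b, plane="xy", n=721):
    t = np.linspace(0, 2 * np.pi, n)
    return BoundaryContour(
        plane=plane, points=np.stack([a * np.cos(t), b * np.sin(t)], 1)
    )
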