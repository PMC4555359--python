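import numpy as np
import pytest

import phasecell as pc
from phasecell.cell_models import HalfEllipsoidPair

# default membrane of the two-half-ellipsoid monocyte builder
MEMBRANE = dict(a=6.0, b=6.0, c_top=6.5, c_bottom=3.5)

# clearance (μm) required between the nucleus surface and the membrane for
# the random-recovery sweeps: interfaces closer than ~1 μm produce merged
# curvature signatures that no two-view method can separate (see
# docs/methods.md)
EMBED_MARGIN = 1.1


def nucleus_fits(semi_axes, center, margin=EMBED_MARGIN) -> bool:
    """True when the ellipsoid keeps ``margin`` clearance inside the default
    membrane (tested against the margin-eroded membrane)."""
    shrunk = HalfEllipsoidPair(
        center=(0, 0, 0),
        refractive_index=1.37,
        priority=1,
        a=MEMBRANE["a"] - margin,
        b=MEMBRANE["b"] - margin,
        c_top=MEMBRANE["c_top"] - margin,
        c_bottom=MEMBRANE["c_bottom"] - margin,
    )
    rng = np.random.default_rng(0)
    u = rng.normal(size=(400, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = np.asarray(center) + u * np.asarray(semi_axes)
    return bool(np.all(shrunk.contains(pts)))


def random_embedded_nucleus(rng):
    """Random ellipsoidal nucleus (semi-axes U(2,4) μm, centre within ±2 μm)
    embedded with clearance in the default membrane."""
    while True:
        semi = rng.uniform(2.0, 4.0, 3)
        cen = rng.uniform(-2.0, 2.0, 3)
        if not nucleus_fits(semi, cen):
            continue
        try:
            return semi, cen, pc.build_monocyte_edward(
                nucleus_semiaxes=semi, nucleus_center=cen
            )
        except ValueError:
            continue


@pytest.fixture(scope="session")
def monocyte():
    return pc.build_monocyte_edward()


@pytest.fixture(scope="session")
def monocyte_maps(monocyte):
    return (
        pc.project_phase(monocyte, "xy"),
        pc.project_phase(monocyte, "xz"),
    )


@pytest.fixture(scope="session")
def monocyte_contours(monocyte_maps):
    out = {}
    for pm in monocyte_maps:
        out[pm.plane] = pc.extract_contours(pc.inflexion_field(pm), pm)
    return out


@pytest.fixture(scope="session")
def monocyte_result(monocyte):
    return pc.characterize_nucleus(monocyte, assemble=True)
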