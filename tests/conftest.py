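import numpy as np
import pytest

import coroalign as ca


@pytest.fixture(scope="session")
def slab_phantom() -> ca.WallPhantom:
    """Small slab phantom shared by read-only tests."""
    spec = ca.WallPhantomSpec(
        geometry="slab", n_segments=300, extent_um=400.0, thickness_um=300.0,
        kappa=8.0, seed=42, min_depth_um=20.0, surface_spacing_um=4.0,
    )
    return ca.make_wall_phantom(spec)


@pytest.fixture(scope="session")
def slab_vectors(slab_phantom):
    v_ab = np.asarray(slab_phantom.base_um) - np.asarray(slab_phantom.apex_um)
    v_ab = v_ab / np.linalg.norm(v_ab)
    vectors, counts = ca.analyze_segments(slab_phantom.graph, slab_phantom.surface, v_ab)
    return vectors, counts


def axes_frame() -> ca.LocalFrame:
    """Exact analytic frame: g1 = +z, g2 = +y, g3 = g2 x g1 = +x."""
    return ca.LocalFrame(
        g1=np.array([0.0, 0.0, 1.0]),
        g2=np.array([0.0, 1.0, 0.0]),
        g3=np.array([1.0, 0.0, 0.0]),
        depth_um=10.0,
    )
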