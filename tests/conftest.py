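import math

import numpy as np
import pytest

import scarq


@pytest.fixture(scope="session")
def annulus_stack():
    """10-slice annulus, r_endo 20 mm, r_epi 30 mm, 1 mm pixels, 10 mm spans."""
    return scarq.make_annulus_stack(10, 20.0, 30.0, 1.0, 10.0)


@pytest.fixture(scope="session")
def wedge_case(annulus_stack):
    """The canonical phantom: a 60-degree wedge of depth 0.5 aligned to sector 1."""
    scar, truth = scarq.apply_wedge(
        annulus_stack, scarq.WedgeScarSpec(0.0, math.pi / 3, 0.5))
    summary = scarq.summarize_patient(annulus_stack, scar)
    return annulus_stack, scar, truth, summary


def star_ring(center, r0, amplitude, lobes, phase, n_vertices=256):
    """Star-convex ring r(theta) = r0 * (1 + amplitude * sin(lobes*theta + phase))."""
    th = np.arange(n_vertices) / n_vertices * 2 * np.pi
    r = r0 * (1.0 + amplitude * np.sin(lobes * th + phase))
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def star_slice(z, rng=None, side=80, r_endo=22.0, r_epi=32.0, amplitude=0.12):
    """A random star-convex slice on a side x side 1 mm grid."""
    rng = rng or np.random.default_rng(0)
    c = (side / 2.0 + rng.uniform(-1, 1), side / 2.0 + rng.uniform(-1, 1))
    lobes = int(rng.integers(2, 6))
    phase = rng.uniform(0, 2 * np.pi)
    endo = star_ring(c, r_endo, amplitude * rng.uniform(0.3, 1.0), lobes, phase)
    epi = star_ring(c, r_epi, amplitude * rng.uniform(0.3, 1.0), lobes, phase + 0.3)
    return scarq.SliceGeometry(z, endo, epi, (1.0, 1.0), 10.0, (side, side))
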