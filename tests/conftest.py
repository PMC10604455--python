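"""Shared fixtures: phantom geometry, small meshes, and cached forward runs.

Expensive artifacts (meshes, transient runs, optimizations) are session-
scoped so the acceptance-style tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from thyrorfa import geometry as geo
from thyrorfa.geometry import Mesh, structured_box_mesh


@pytest.fixture(scope="session")
def phantom():
    return geo.build_phantom()


@pytest.fixture(scope="session")
def tiny_mesh_10mm(phantom):
    el = geo.ElectrodeSpec.centered_in(phantom, 10e-3)
    return geo.mesh_phantom(phantom, el, "tiny"), el


def make_cube_mesh(n: int = 4, L: float = 0.01, region: str = "thyroid"
                   ) -> Mesh:
    """Uniform cube mesh with a single region label and no labeled
    boundary facets (used for insulated scalar-ODE oracles)."""
    xs = np.linspace(0.0, L, n)
    nodes, tets = structured_box_mesh(xs, xs, xs)
    return Mesh(nodes=nodes, tets=tets,
                region=np.full(len(tets), geo.REGIONS.index(region)),
                boundary_tris=np.zeros((0, 3), dtype=int),
                boundary_label=np.zeros(0, dtype=int))
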