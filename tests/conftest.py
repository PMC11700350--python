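"""Shared fixtures: synthetic structures and their (expensive) void networks."""

from __future__ import annotations

import numpy as np
import pytest

from voidwire.fixtures import (
    constant_profile,
    make_blocked_tube,
    make_polar_cavity,
    make_toy_axis,
    make_tube,
    sinusoidal_profile,
)
from voidwire.voids import build_void_network, trace_channel


@pytest.fixture(scope="session")
def tube_bundle():
    """Plain constant-lumen tube (2.0 Å) with its network and traced channel."""
    st, truth = make_tube(length=30.0, lumen_profile=constant_profile(2.0), seed=7)
    net = build_void_network(st)
    ch = trace_channel(net, truth.axis_point(1.0), truth.axis_point(29.0))
    return st, truth, net, ch


@pytest.fixture(scope="session")
def polar_tube_bundle():
    st, truth = make_tube(
        length=30.0, lumen_profile=constant_profile(2.0), seed=7, polar=True
    )
    net = build_void_network(st)
    ch = trace_channel(net, truth.axis_point(1.0), truth.axis_point(29.0))
    return st, truth, net, ch


@pytest.fixture(scope="session")
def sinus_tube_bundle():
    st, truth = make_tube(
        length=30.0, lumen_profile=sinusoidal_profile(0.8, 2.4, 30.0), seed=3
    )
    net = build_void_network(st)
    ch = trace_channel(net, truth.axis_point(1.0), truth.axis_point(29.0))
    return st, truth, net, ch


@pytest.fixture(scope="session")
def blocked_bundle():
    """Blocked tube: native and ILE→ALA-truncated networks and channels."""
    from voidwire.wire import mutate_to_alanine

    native, truth = make_blocked_tube(seed=2)
    mutant = mutate_to_alanine(native, [(r.chain_id, r.residue_number) for r in truth.block_residues])
    net_native = build_void_network(native)
    net_mutant = build_void_network(mutant)
    ch_native = trace_channel(net_native, truth.tube.axis_point(1.0), truth.tube.axis_point(29.0))
    ch_mutant = trace_channel(net_mutant, truth.tube.axis_point(1.0), truth.tube.axis_point(29.0))
    return {
        "native": native,
        "mutant": mutant,
        "truth": truth,
        "net_native": net_native,
        "net_mutant": net_mutant,
        "ch_native": ch_native,
        "ch_mutant": ch_mutant,
    }


@pytest.fixture(scope="session")
def cavity_one():
    st, truth = make_polar_cavity(1, seed=5)
    return st, truth, build_void_network(st)


@pytest.fixture(scope="session")
def cavity_zero():
    st, truth = make_polar_cavity(0, seed=5)
    return st, truth, build_void_network(st)


@pytest.fixture(scope="session")
def toy_axis_bundle():
    from voidwire.structure import classify_protonatable
    from voidwire.wire import build_proton_graph

    st, truth = make_toy_axis(seed=3)
    net = build_void_network(st)
    graph = build_proton_graph(truth.waters, st, classify_protonatable(st))
    return st, truth, net, graph


def grid_flood_fill(structure, probe: float, resolution: float = 0.25):
    """Independent voxel oracle: free voxels (clearance ≥ probe) and their
    6-connected components.  Returns (points array, labels array)."""
    from scipy.ndimage import label

    from voidwire.voids import AtomGeometry

    geom = AtomGeometry.from_structure(structure)
    lo = geom.coords.min(axis=0) - 3.0
    hi = geom.coords.max(axis=0) + 3.0
    axes = [np.arange(lo[i], hi[i] + resolution, resolution) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    shape = grid.shape[:3]
    clear = geom.clearance(grid.reshape(-1, 3)).reshape(shape)
    free = clear >= probe
    labels, n = label(free)
    return grid, clear, labels, n
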