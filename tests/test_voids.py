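"""Void network geometry: clearance, vertices, channels, surfaces, branches."""

import math

import networkx as nx
import numpy as np
import pytest

from voidwire.structure import Atom, Structure
from voidwire.voids import (
    NoChannelError,
    build_void_network,
    clearance_at,
    enumerate_branches,
    find_surface_vertices,
    profile_channel,
    prune_network,
    surface_exits,
    trace_channel,
    widest_path,
)


def _cloud(n=50, seed=11, radius=1.5):
    rng = np.random.default_rng(seed)
    atoms = [
        Atom(
            serial=i + 1, name="C", element="C", residue_name="UNK",
            residue_number=i + 1, chain_id="A",
            position=rng.uniform(-10, 10, 3), vdw_radius=radius,
        )
        for i in range(n)
    ]
    return Structure(atoms=atoms)


class TestClearance:
    def test_single_atom_definition(self):
        st = _cloud(n=1)
        st.atoms[0].position = np.zeros(3)
        assert clearance_at(np.array([4.0, 0, 0]), st) == pytest.approx(2.5)
        assert clearance_at(np.zeros(3), st) == pytest.approx(-1.5)

    def test_matches_brute_force_scan(self):
        """k-d-tree-accelerated clearance equals the exhaustive minimum."""
        st = _cloud(n=50, seed=11)
        rng = np.random.default_rng(4)
        pts = rng.uniform(-12, 12, (100, 3))
        coords = st.coords()
        radii = st.radii()
        expected = np.min(
            np.linalg.norm(pts[:, None, :] - coords[None], axis=-1) - radii[None],
            axis=1,
        )
        got = clearance_at(pts, st)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_mixed_radii_brute_force(self):
        st = _cloud(n=40, seed=2)
        rng = np.random.default_rng(7)
        for a in st.atoms:
            a.vdw_radius = float(rng.uniform(1.2, 2.3))
        pts = rng.uniform(-12, 12, (100, 3))
        coords, radii = st.coords(), st.radii()
        expected = np.min(
            np.linalg.norm(pts[:, None, :] - coords[None], axis=-1) - radii[None],
            axis=1,
        )
        np.testing.assert_allclose(clearance_at(pts, st), expected, atol=1e-9)

    def test_empty_structure_errors(self):
        with pytest.raises(ValueError):
            clearance_at(np.zeros(3), Structure(atoms=[]))


class TestNetworkConstruction:
    def test_regular_tetrahedron_vertex(self):
        """Circumcenter clearance for a regular tetrahedron: R = a·√(3/8) − r."""
        a = 4.0
        verts = np.array(
            [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float
        ) * (a / (2 * math.sqrt(2)))
        positions = list(verts) + [np.array([12.0, 0.0, 0.0])]  # distant anchor
        st = Structure(
            atoms=[
                Atom(serial=i + 1, name="C", element="C", residue_name="UNK",
                     residue_number=i + 1, chain_id="A", position=p, vdw_radius=1.2)
                for i, p in enumerate(positions)
            ]
        )
        net = build_void_network(st)
        centroid = verts.mean(axis=0)
        d = [np.linalg.norm(v.position - centroid) for v in net.vertices]
        central = net.vertices[int(np.argmin(d))]
        assert np.linalg.norm(central.position - centroid) < 1e-6
        assert central.clearance == pytest.approx(a * math.sqrt(3 / 8) - 1.2, abs=1e-6)

    def test_cube_central_vertex(self):
        """8 atoms at cube corners: central clearance a·√3/2 − r."""
        a = 4.0
        corners = [
            np.array([x, y, z]) * (a / 2.0)
            for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)
        ]
        st = Structure(
            atoms=[
                Atom(serial=i + 1, name="C", element="C", residue_name="UNK",
                     residue_number=i + 1, chain_id="A", position=p, vdw_radius=1.2)
                for i, p in enumerate(corners)
            ]
        )
        net = build_void_network(st)
        d = [np.linalg.norm(v.position) for v in net.vertices]
        central = net.vertices[int(np.argmin(d))]
        assert np.linalg.norm(central.position) < 1e-6
        assert central.clearance == pytest.approx(a * math.sqrt(3) / 2 - 1.2, abs=1e-6)

    def test_vertex_equidistance_with_mixed_radii(self):
        """Refined vertices are equidistant (surface distance) from their four
        defining atoms within 1e-4 Å."""
        st = _cloud(n=60, seed=9)
        rng = np.random.default_rng(1)
        for a in st.atoms:
            a.vdw_radius = float(rng.uniform(1.3, 2.1))
        net = build_void_network(st)
        coords, radii = st.coords(), st.radii()
        checked = 0
        for v in net.vertices:
            if v.interior or v.clearance > 5.0:
                continue
            sd = [
                np.linalg.norm(v.position - coords[i]) - radii[i]
                for i in v.defining_atoms
            ]
            if np.ptp(sd) < 1e-4:
                checked += 1
        # refinement converges for the overwhelming majority of proper voids
        proper = [v for v in net.vertices if not v.interior and v.clearance <= 5.0]
        assert checked >= 0.9 * len(proper)

    def test_degenerate_input_errors_without_jitter(self):
        grid = [
            np.array([x * 2.0, y * 2.0, 0.0]) for x in range(4) for y in range(4)
        ]
        st = Structure(
            atoms=[
                Atom(serial=i + 1, name="C", element="C", residue_name="UNK",
                     residue_number=i + 1, chain_id="A", position=p, vdw_radius=1.5)
                for i, p in enumerate(grid)
            ]
        )
        with pytest.raises(ValueError, match="jitter"):
            build_void_network(st)
        net = build_void_network(st, jitter=True)  # deterministic jitter recovers
        assert len(net.vertices) > 0

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            build_void_network(_cloud(n=4))


class TestPruning:
    def test_monotone_nesting_and_limits(self):
        st = _cloud(n=60, seed=3)
        net = build_void_network(st)
        p0 = prune_network(net, 0.0)
        assert all(not v.interior for v in p0.vertices)
        p1 = prune_network(net, 1.0)
        p2 = prune_network(net, 2.0)
        ids1 = {v.id for v in p1.vertices}
        ids2 = {v.id for v in p2.vertices}
        assert ids2 <= ids1 <= {v.id for v in p0.vertices}
        e1 = {e.endpoints for e in p1.edges}
        e2 = {e.endpoints for e in p2.edges}
        assert e2 <= e1
        assert prune_network(net, math.inf).vertices == []

    def test_tube_splits_at_constriction(self, sinus_tube_bundle):
        """Pruning above the throat radius severs the axial channel."""
        st, truth, net, ch = sinus_tube_bundle
        pruned = prune_network(net, 1.4)  # throat is 0.8 Å
        g = pruned.graph()
        lo = [v.id for v in pruned.vertices
              if np.hypot(*v.position[:2]) < 1.0 and v.position[2] < 10]
        hi = [v.id for v in pruned.vertices
              if np.hypot(*v.position[:2]) < 1.0 and v.position[2] > 20]
        assert lo and hi
        assert not nx.has_path(g, lo[0], hi[0])


class TestWidestPath:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        """Max-min Dijkstra equals brute-force path enumeration on ≤12 edges."""
        rng = np.random.default_rng(seed)
        g = nx.gnm_random_graph(7, 12, seed=int(seed))
        for u, v in g.edges:
            g[u][v]["bottleneck"] = float(rng.uniform(0.5, 3.0))
            g[u][v]["length"] = 1.0
        nodes = sorted(g.nodes)
        for s in nodes[:3]:
            for t in nodes[-3:]:
                if s == t:
                    continue
                if not nx.has_path(g, s, t):
                    with pytest.raises(nx.NetworkXNoPath):
                        widest_path(g, s, t)
                    continue
                _, got = widest_path(g, s, t)
                best = max(
                    min(g[u][v]["bottleneck"] for u, v in zip(p[:-1], p[1:]))
                    for p in nx.all_simple_paths(g, s, t)
                )
                assert got == pytest.approx(best)

    def test_y_network_picks_wide_arm(self):
        g = nx.Graph()
        # two arms from 0 to 3: wide (r=2) via 1, narrow (r=1) via 2
        g.add_edge(0, 1, bottleneck=2.0, length=1.0)
        g.add_edge(1, 3, bottleneck=2.0, length=1.0)
        g.add_edge(0, 2, bottleneck=1.0, length=1.0)
        g.add_edge(2, 3, bottleneck=1.0, length=1.0)
        path, bn = widest_path(g, 0, 3)
        assert path == [0, 1, 3]
        assert bn == pytest.approx(2.0)


class TestChannels:
    def test_tube_channel_recovers_design(self, tube_bundle):
        st, truth, net, ch = tube_bundle
        assert ch.bottleneck == pytest.approx(2.0, abs=0.1)
        assert ch.length == pytest.approx(28.0, abs=2.5)  # seeds span 28 Å
        assert ch.bottleneck == pytest.approx(float(np.min(ch.radii)))
        steps = np.linalg.norm(np.diff(ch.points, axis=0), axis=1)
        assert steps.max() <= 0.5

    def test_profile_uniform_spacing_and_constant_radius(self, tube_bundle):
        st, truth, net, ch = tube_bundle
        prof = profile_channel(ch, 50)
        assert prof.n_samples == 50
        spacing = np.diff(prof.arclengths)
        np.testing.assert_allclose(spacing, spacing[0], atol=1e-6)
        np.testing.assert_allclose(prof.radii, 2.0, atol=0.1)

    def test_profile_recovers_sinusoidal_extremes(self, sinus_tube_bundle):
        st, truth, net, ch = sinus_tube_bundle
        prof = profile_channel(trace_channel(net, truth.axis_point(0.8),
                                             truth.axis_point(29.2)), 80)
        assert prof.radii.min() == pytest.approx(0.8, abs=0.1)
        assert prof.radii.max() == pytest.approx(2.4, abs=0.1)

    def test_profile_validates_inputs(self, tube_bundle):
        *_, ch = tube_bundle
        with pytest.raises(ValueError):
            profile_channel(ch, 1)

    def test_disconnected_seeds_carry_closest_approach(self, sinus_tube_bundle):
        st, truth, net, _ = sinus_tube_bundle
        pruned = prune_network(net, 1.4)
        with pytest.raises(NoChannelError) as err:
            trace_channel(pruned, truth.axis_point(2.0), truth.axis_point(28.0))
        assert np.isfinite(err.value.closest_approach)
        assert err.value.closest_approach > 0


class TestSurface:
    @pytest.mark.parametrize("caps,n_exits", [("none", 2), ("one", 1), ("both", 0)])
    def test_tube_end_exits(self, caps, n_exits):
        from voidwire.fixtures import constant_profile, make_tube

        st, truth = make_tube(
            length=30.0, lumen_profile=constant_profile(2.0), seed=7, caps=caps
        )
        net = build_void_network(st)
        surf = find_surface_vertices(net, st, probe=1.4)
        exits = surface_exits(net, surf)
        axial = []
        for vid in exits:
            p = net.vertex(vid).position
            t = float(np.clip(p[2], 0.0, truth.length))
            if np.linalg.norm(p - truth.axis_point(t)) <= 1.5:
                axial.append(vid)
        assert len(axial) == n_exits

    def test_sealed_cavity_interior_unreachable(self, cavity_one):
        st, truth, net = cavity_one
        surf = find_surface_vertices(net, st, probe=1.4)
        inner = [
            v.id for v in net.vertices
            if np.linalg.norm(v.position - truth.center) < truth.inner_radius
        ]
        assert inner  # the cavity exists in the network
        assert not (set(inner) & surf)

    def test_grid_oracle_agrees_on_sealed_interior(self, cavity_one):
        """Voxel flood fill confirms the pocket is disconnected from outside."""
        from conftest import grid_flood_fill

        st, truth, net = cavity_one
        grid, clear, labels, n = grid_flood_fill(st, probe=1.1, resolution=0.4)
        # label of the voxel nearest the pocket center vs a corner (bulk) voxel
        flat = grid.reshape(-1, 3)
        ci = int(np.argmin(np.linalg.norm(flat - truth.center, axis=1)))
        pocket_label = labels.reshape(-1)[ci]
        corner_label = labels.reshape(-1)[0]
        assert pocket_label != 0  # free space at the pocket
        assert corner_label != 0
        assert pocket_label != corner_label  # sealed


@pytest.fixture(scope="module")
def side_tube_net():
    from voidwire.fixtures import constant_profile, make_tube

    st, truth = make_tube(
        length=30.0, lumen_profile=constant_profile(2.0), seed=7,
        side_tubes=[(8.0, 1.0), (15.0, 1.5), (22.0, 2.0)],
    )
    net = build_void_network(st)
    surf = find_surface_vertices(net, st, probe=0.9)
    ch = trace_channel(net, truth.axis_point(1.0), truth.axis_point(29.0))
    return st, truth, net, surf, ch


class TestBranches:
    def test_single_side_tube_found_with_its_lumen(self):
        from voidwire.fixtures import constant_profile, make_tube

        st, truth = make_tube(
            length=30.0, lumen_profile=constant_profile(2.0), seed=7,
            side_tubes=[(15.0, 1.5)],
        )
        net = build_void_network(st)
        surf = find_surface_vertices(net, st, probe=0.9)
        ch = trace_channel(net, truth.axis_point(1.0), truth.axis_point(29.0))
        branches = enumerate_branches(net, ch, surf, min_radius=0.9)
        assert len(branches) == 1
        assert branches[0].bottleneck == pytest.approx(1.5, abs=0.15)

    def test_min_radius_filters_narrow_side_tubes(self, side_tube_net):
        st, truth, net, surf, ch = side_tube_net
        assert len(enumerate_branches(net, ch, surf, min_radius=1.2)) == 2
        assert len(enumerate_branches(net, ch, surf, min_radius=0.5)) == 3

    def test_plain_tube_has_no_branches(self, tube_bundle):
        st, truth, net, ch = tube_bundle
        surf = find_surface_vertices(net, st, probe=0.9)
        assert enumerate_branches(net, ch, surf, min_radius=0.5) == []


class TestMutationMonotonicity:
    def test_deleting_atoms_never_decreases_clearance(self, blocked_bundle):
        b = blocked_bundle
        rng = np.random.default_rng(0)
        pts = rng.uniform([-4, -4, 0], [4, 4, 30], (200, 3))
        before = clearance_at(pts, b["native"])
        after = clearance_at(pts, b["mutant"])
        assert np.all(after >= before - 1e-9)
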