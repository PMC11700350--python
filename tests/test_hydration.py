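"""Water binding energetics, greedy placement, and matching."""

import math

import numpy as np
import pytest

from voidwire.fixtures import make_polar_cavity, make_water_chain
from voidwire.hydration import (
    CUTOFF,
    COULOMB_CONSTANT,
    LJ_DEFAULT,
    LJ_PARAMS,
    LJ_WATER_H,
    LJ_WATER_O,
    WATER_Q,
    _ORIENTATIONS,
    WaterSite,
    match_waters,
    place_waters,
    water_energy,
)
from voidwire.structure import Atom, Structure


def oracle_energy(site, atoms, orientations=_ORIENTATIONS):
    """Literal pair-sum reimplementation of the binding score: explicit loops
    over orientations, water sites, and environment atoms."""
    wq = [WATER_Q["O"], WATER_Q["H"], WATER_Q["H"]]
    wlj = [LJ_WATER_O, LJ_WATER_H, LJ_WATER_H]
    best = math.inf
    site = np.asarray(site, float)
    env = [
        (a.position, a.partial_charge, LJ_PARAMS.get(a.element, LJ_DEFAULT))
        for a in atoms
        if np.linalg.norm(a.position - site) <= CUTOFF + 0.9572
    ]
    for rot in orientations:
        e = 0.0
        for wi in range(3):
            wpos = site + rot[wi]
            for apos, q, (sig_a, eps_a) in env:
                r = max(float(np.linalg.norm(wpos - apos)), 0.05)
                sig = 0.5 * (wlj[wi][0] + sig_a)
                eps = math.sqrt(wlj[wi][1] * eps_a)
                sr6 = (sig / r) ** 6
                e += 4.0 * eps * (sr6 * sr6 - sr6)
                e += COULOMB_CONSTANT * wq[wi] * q / (4.0 * r * r)
        best = min(best, e)
    return best


def _atoms(entries):
    out = []
    for i, (pos, q, elem) in enumerate(entries):
        out.append(
            Atom(serial=i + 1, name=f"{elem}{i}", element=elem, residue_name="ENV",
                 residue_number=i + 1, chain_id="E",
                 position=np.asarray(pos, float),
                 vdw_radius=1.70 if elem == "C" else 1.52, partial_charge=q)
        )
    return out


class TestWaterEnergy:
    def test_isolated_water_scores_zero(self):
        st = Structure(atoms=_atoms([((60.0, 0, 0), 0.3, "O")]))
        st.charges_assigned = True
        e, site = water_energy(np.zeros(3), st)
        assert e == 0.0

    def test_inside_atom_is_infinite(self):
        st = Structure(atoms=_atoms([((0, 0, 0), 0.0, "C")] * 1 + [((4, 0, 0), 0.0, "C")] * 4))
        for i, a in enumerate(st.atoms[1:], 1):
            a.position = np.array([4.0 + i, i * 0.5, 0.0])
        st.charges_assigned = True
        e, _ = water_energy(np.zeros(3), st)
        assert e == math.inf

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pair_sum_oracle(self, seed):
        """Vectorized energy equals the literal loop oracle to 1e-6 kcal/mol."""
        rng = np.random.default_rng(seed)
        entries = []
        for i in range(12):
            pos = rng.uniform(-4, 4, 3)
            while np.linalg.norm(pos) < 2.6:
                pos = rng.uniform(-4, 4, 3)
            entries.append((pos, float(rng.uniform(-0.5, 0.5)), "O" if i % 3 else "C"))
        st = Structure(atoms=_atoms(entries))
        st.charges_assigned = True
        e, site = water_energy(np.zeros(3), st)
        assert e == pytest.approx(oracle_energy(np.zeros(3), st.atoms), abs=1e-6)
        # the reported orientation is the argmin: rigid geometry is preserved
        doh, dang = site.geometry_errors()
        assert doh < 1e-3 and dang < 0.1

    def test_water_pair_matches_direct_sum(self):
        """Two waters at O–O 2.8 Å: the vectorized energy equals a literal
        double loop over the orientation grid and the partner's three sites."""
        st = Structure(atoms=[])
        st.charges_assigned = True
        partner = WaterSite.from_oxygen(np.array([2.8, 0.0, 0.0]),
                                        orientation=_ORIENTATIONS[7])
        e, _ = water_energy(np.zeros(3), st, placed=[partner])

        env = [
            (partner.oxygen_position, WATER_Q["O"], LJ_WATER_O),
            (partner.hydrogen_positions[0], WATER_Q["H"], LJ_WATER_H),
            (partner.hydrogen_positions[1], WATER_Q["H"], LJ_WATER_H),
        ]
        wq = [WATER_Q["O"], WATER_Q["H"], WATER_Q["H"]]
        wlj = [LJ_WATER_O, LJ_WATER_H, LJ_WATER_H]
        expected = math.inf
        for rot in _ORIENTATIONS:
            etot = 0.0
            for wi in range(3):
                wpos = rot[wi]
                for apos, q, (sig_a, eps_a) in env:
                    r = max(float(np.linalg.norm(wpos - apos)), 0.05)
                    sig = 0.5 * (wlj[wi][0] + sig_a)
                    eps = math.sqrt(wlj[wi][1] * eps_a)
                    sr6 = (sig / r) ** 6
                    etot += 4.0 * eps * (sr6 * sr6 - sr6)
                    etot += COULOMB_CONSTANT * wq[wi] * q / (4.0 * r * r)
            expected = min(expected, etot)
        assert e < 0  # an H-bond-like arrangement exists in the grid
        assert e == pytest.approx(expected, abs=1e-6)

    def test_cavity_energy_is_charge_driven(self, cavity_one):
        st, truth, net = cavity_one
        e_polar, _ = water_energy(truth.center, st)
        zeroed = st.copy()
        for a in zeroed.atoms:
            a.partial_charge = 0.0
        e_apolar, _ = water_energy(truth.center, zeroed)
        assert e_polar < -5.0
        assert e_apolar > -5.0


class TestPlacement:
    def test_narrow_tube_has_no_candidates(self):
        from voidwire.fixtures import constant_profile, make_tube
        from voidwire.voids import build_void_network, trace_channel

        # tight ring spacing keeps the between-ring scalloping below the
        # 1.1 Å candidate clearance floor everywhere
        st, truth = make_tube(length=20.0, lumen_profile=constant_profile(1.0),
                              seed=4, ring_spacing=1.2)
        net = build_void_network(st)
        # seeds away from the flared mouths so every centerline point sits in
        # the 1.0 Å lumen, below the 1.1 Å candidate clearance floor
        ch = trace_channel(net, truth.axis_point(3.0), truth.axis_point(17.0))
        with pytest.warns(UserWarning):
            res = place_waters(ch, st)
        assert res.accepted_count == 0

    def test_cavity_accepts_exactly_one(self, cavity_one):
        st, truth, net = cavity_one
        res = place_waters(net, st)
        assert res.accepted_count == 1
        assert res.waters[0].binding_energy <= -5.0

    def test_two_site_search_confirms_single_placement(self, cavity_one):
        """Exhaustive two-site check: no pair of candidate sites in the pocket
        is simultaneously placeable (exclusion distance or energy fails)."""
        st, truth, net = cavity_one
        verts = [
            v.position for v in net.vertices
            if not v.interior and v.clearance >= 1.1
            and np.linalg.norm(v.position - truth.center) < truth.inner_radius
        ]
        placeable = [p for p in verts if water_energy(p, st)[0] <= -5.0]
        assert placeable  # at least one single placement works
        for i, p in enumerate(placeable):
            first, fsite = water_energy(p, st)
            for q in placeable[i + 1:]:
                if np.linalg.norm(p - q) < 2.5:
                    continue  # violates exclusion — cannot be a second site
                second, _ = water_energy(q, st, placed=[fsite])
                assert second > -5.0  # energy forbids a second water

    def test_apolar_cavity_rejects_all(self, cavity_zero):
        st, truth, net = cavity_zero
        assert place_waters(net, st).accepted_count == 0

    def test_zeroing_charges_eliminates_acceptance(self, cavity_one):
        st, truth, net = cavity_one
        zeroed = st.copy()
        for a in zeroed.atoms:
            a.partial_charge = 0.0
        assert place_waters(net, zeroed).accepted_count == 0

    def test_determinism_across_reruns(self, polar_tube_bundle):
        st, truth, net, ch = polar_tube_bundle
        r1 = place_waters(ch, st)
        r2 = place_waters(ch, st)
        assert r1.accepted_count == r2.accepted_count
        np.testing.assert_array_equal(r1.oxygen_array(), r2.oxygen_array())
        assert [w.binding_energy for w in r1.waters] == [
            w.binding_energy for w in r2.waters
        ]

    def test_exclusion_and_threshold_invariants(self, polar_tube_bundle):
        st, truth, net, ch = polar_tube_bundle
        res = place_waters(ch, st)
        assert res.accepted_count > 0
        oxy = res.oxygen_array()
        d = np.linalg.norm(oxy[:, None] - oxy[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2.5
        assert all(w.binding_energy <= res.threshold for w in res.waters)
        for w in res.waters:
            doh, dang = w.geometry_errors()
            assert doh < 1e-3 and dang < 0.1

    def test_threshold_monotonicity(self, polar_tube_bundle):
        """A stricter (more negative) threshold never accepts more waters."""
        st, truth, net, ch = polar_tube_bundle
        counts = [
            place_waters(ch, st, threshold=t).accepted_count
            for t in (-5.0, -6.0, -7.0, -9.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestMatching:
    def test_identity_matches_all(self):
        sites = make_water_chain(10, 3.0, seed=1)
        rep = match_waters(sites, [WaterSite.from_oxygen(w.oxygen_position)
                                   for w in sites])
        assert rep.n_matched == 10
        assert rep.rmsd == pytest.approx(0.0, abs=1e-12)
        assert rep.unmatched_predicted == [] and rep.unmatched_experimental == []

    def test_disjoint_sets_do_not_match(self):
        a = make_water_chain(5, 3.0, seed=1)
        b = [WaterSite.from_oxygen(w.oxygen_position + np.array([0, 8.0, 0]))
             for w in a]
        rep = match_waters(a, b, tolerance=1.0)
        assert rep.n_matched == 0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_jittered_matching_equals_optimal_assignment(self, seed):
        """Greedy nearest-pair matching of 0.5 Å-jittered copies agrees with
        the optimal (Hungarian) assignment on n ≤ 10."""
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(seed)
        exp = [WaterSite.from_oxygen(rng.uniform(0, 20, 3)) for _ in range(10)]
        jit = rng.normal(scale=0.5 / math.sqrt(3), size=(10, 3))
        pred = [WaterSite.from_oxygen(w.oxygen_position + j)
                for w, j in zip(exp, jit)]
        rep = match_waters(pred, exp, tolerance=1.0)
        d = np.linalg.norm(
            np.array([p.oxygen_position for p in pred])[:, None]
            - np.array([e.oxygen_position for e in exp])[None],
            axis=-1,
        )
        ri, ci = linear_sum_assignment(d)
        optimal = {(i, j) for i, j in zip(ri, ci) if d[i, j] <= 1.0}
        assert rep.n_matched == len(optimal)
        jitter_norms = np.linalg.norm(jit, axis=1)
        assert rep.rmsd == pytest.approx(
            math.sqrt(np.mean(jitter_norms**2)), rel=0.35
        )


class TestRegions:
    def test_hydrate_regions_counts(self, polar_tube_bundle):
        from voidwire.hydration import hydrate_regions

        st, truth, net, ch = polar_tube_bundle
        table = hydrate_regions(
            st, {"axis": ch}, charge_modes=("charged",), experimental=[]
        )
        row = table.iloc[0]
        assert row["region"] == "axis"
        assert row["n_predicted"] > 0
        assert row["n_experimental"] == 0 and row["n_matched"] == 0

    def test_unknown_region_errors(self, polar_tube_bundle):
        from voidwire.hydration import hydrate_regions

        st, *_ = polar_tube_bundle
        with pytest.raises(KeyError):
            hydrate_regions(st, {"ghost": None})
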