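"""Semi-empirical water placement in channels and matching to experiment.

The binding-energy function is a documented surrogate for the black-box
scorers used by dedicated hydration programs: a rigid three-site water
(TIP3P geometry and charges) is scored against protein atoms and already
placed waters within an 8 Å cutoff with a 12-6 Lennard-Jones term
(Lorentz–Berthelot combination over a small per-element parameter set) plus
a screened Coulomb term with the distance-dependent dielectric ε(r) = 4r,

    E = Σ_pairs 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] + 332.0636 q_i q_j / (4 r²),

minimized over a discrete rigid-body orientation grid (12 icosahedral dipole
directions × 5 spins = 60 orientations).  Placement is greedy and
deterministic: the lowest-energy candidate below the acceptance threshold
(default −5 kcal/mol) is accepted if it keeps ≥ 2.5 Å from accepted oxygens,
then neighboring candidates are re-scored with the new water present.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import (
    BACKBONE_CHARGES,
    SIDECHAIN_CHARGES,
    ChargeModel,
    Structure,
    apply_charge_model,
)
from .voids import AtomGeometry, Channel, VoidNetwork

__all__ = [
    "WaterSite",
    "HydrationResult",
    "MatchReport",
    "water_energy",
    "place_waters",
    "match_waters",
    "hydrate_regions",
    "add_polar_hydrogens",
    "COULOMB_CONSTANT",
    "DEFAULT_THRESHOLD",
    "EXCLUSION_DISTANCE",
    "CANDIDATE_CLEARANCE_FLOOR",
]

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)
CUTOFF = 8.0  # Å, neighbor cutoff on the oxygen position
DEFAULT_THRESHOLD = -5.0  # kcal/mol acceptance threshold
EXCLUSION_DISTANCE = 2.5  # Å, minimum O–O between accepted waters
CANDIDATE_CLEARANCE_FLOOR = 1.1  # Å, minimum clearance for a candidate site
CONTACT_SCALE = 0.8  # accepted O must be ≥ 0.8·(r_O + r_atom) from heavy atoms

# rigid water geometry (TIP3P)
OH_BOND = 0.9572  # Å
HOH_ANGLE = math.radians(104.52)
WATER_Q = {"O": -0.834, "H": 0.417}

# 12-6 LJ parameters (σ Å, ε kcal/mol) per element; polar H gets a small
# core.  Well depths are ≈5× shallower than standard additive force-field
# values: the score has no desolvation/reference term, and full-depth
# dispersion alone would pull any snug cavity below the −5 kcal/mol
# acceptance threshold, destroying its polar/apolar discrimination.
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (0.40, 0.009),
    "C": (3.40, 0.017),
    "N": (3.25, 0.032),
    "O": (3.00, 0.040),
    "S": (3.55, 0.047),
    "P": (3.74, 0.038),
}
LJ_DEFAULT = LJ_PARAMS["C"]
LJ_WATER_O = (3.1507, 0.029)
LJ_WATER_H = (0.40, 0.009)


def _water_template() -> np.ndarray:
    """O at origin, dipole along +z; rows O, H1, H2."""
    half = HOH_ANGLE / 2.0
    h1 = np.array([OH_BOND * math.sin(half), 0.0, OH_BOND * math.cos(half)])
    h2 = np.array([-OH_BOND * math.sin(half), 0.0, OH_BOND * math.cos(half)])
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def _icosahedron_vertices() -> np.ndarray:
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    base = [
        (0, 1, phi), (0, 1, -phi), (0, -1, phi), (0, -1, -phi),
        (1, phi, 0), (1, -phi, 0), (-1, phi, 0), (-1, -phi, 0),
        (phi, 0, 1), (phi, 0, -1), (-phi, 0, 1), (-phi, 0, -1),
    ]
    v = np.array(base, dtype=float)
    return v / np.linalg.norm(v, axis=1)[:, None]


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to ``direction`` (unit)."""
    z = np.array([0.0, 0.0, 1.0])
    d = direction / np.linalg.norm(direction)
    c = float(z @ d)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, d)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _orientation_grid(n_spins: int = 5) -> np.ndarray:
    """(60, 3, 3) array: water-site template rotated over 12 dipole
    directions × ``n_spins`` spins (rows O, H1, H2)."""
    template = _water_template()
    out = []
    for d in _icosahedron_vertices():
        R = _rotation_to(d)
        for k in range(n_spins):
            ang = 2.0 * math.pi * k / n_spins
            ca, sa = math.cos(ang), math.sin(ang)
            Rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
            out.append(template @ (R @ Rz).T)
    return np.array(out)


_ORIENTATIONS = _orientation_grid()


@dataclass(slots=True)
class WaterSite:
    """A positioned water molecule, predicted or experimental."""

    oxygen_position: np.ndarray
    hydrogen_positions: np.ndarray  # (2, 3)
    binding_energy: float = math.nan
    source: str = "predicted"
    matched_to: int | None = None
    region_tag: str = ""
    label: str = ""

    @classmethod
    def from_oxygen(
        cls,
        position,
        orientation: np.ndarray | None = None,
        energy: float = math.nan,
        source: str = "predicted",
        label: str = "",
    ) -> "WaterSite":
        o = np.asarray(position, dtype=float)
        rot = orientation if orientation is not None else _ORIENTATIONS[0]
        return cls(
            oxygen_position=o,
            hydrogen_positions=o + rot[1:],
            binding_energy=energy,
            source=source,
            label=label,
        )

    def geometry_errors(self) -> tuple[float, float]:
        """(max |OH − 0.9572|, |∠HOH − 104.52°| in degrees)."""
        d = self.hydrogen_positions - self.oxygen_position
        r = np.linalg.norm(d, axis=1)
        cosang = float(d[0] @ d[1] / (r[0] * r[1]))
        ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        return float(np.max(np.abs(r - OH_BOND))), abs(ang - math.degrees(HOH_ANGLE))


@dataclass
class HydrationResult:
    waters: list[WaterSite]
    candidate_count: int
    threshold: float
    charge_mode: str = "charged"

    @property
    def accepted_count(self) -> int:
        return len(self.waters)

    def oxygen_array(self) -> np.ndarray:
        if not self.waters:
            return np.zeros((0, 3))
        return np.array([w.oxygen_position for w in self.waters])

    def write_pdb(self, path) -> None:
        """Waters as HETATM HOH; B-factor column carries |binding energy|."""
        with open(path, "w") as fh:
            for i, w in enumerate(self.waters, start=1):
                p = w.oxygen_position
                b = abs(w.binding_energy) if math.isfinite(w.binding_energy) else 0.0
                fh.write(
                    f"HETATM{i:5d}  O   HOH W{i:4d}    "
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.00:6.2f}{min(b, 999.0):6.2f}"
                    f"           O\n"
                )
            fh.write("END\n")


# ---------------------------------------------------------------------------
# Polar hydrogen construction
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


NH_BOND = 1.01
OH_POLAR_BOND = 0.96


def add_polar_hydrogens(structure: Structure, model: ChargeModel | None = None,
                        selection=None) -> Structure:
    """Return a copy with geometrically constructed polar hydrogens.

    Covers backbone amide H and side-chain H of the protonatable set (Lys NZ,
    neutral Glu/Asp carboxyl H, Ser/Thr/Tyr hydroxyl H, neutral His NE2-H).
    Hydroxyl hydrogens point toward the nearest O/N acceptor within 4 Å, else
    anti to the attached carbon.  Charges for built hydrogens come from the
    charge templates, so the structure should already carry a charge model
    (one is applied with defaults otherwise).
    """
    st = structure.copy()
    if not st.charges_assigned:
        apply_charge_model(st, model or ChargeModel(mode="charged"), selection)
    heavy = [a for a in st.atoms if not a.is_hydrogen and not a.is_water]
    if not heavy:
        return st
    polar = np.array(
        [a.position for a in heavy if a.element in ("N", "O")]
    )
    polar_tree = cKDTree(polar) if len(polar) else None
    existing_h = {
        (a.chain_id, a.residue_number, a.name) for a in st.atoms if a.is_hydrogen
    }
    residues = st.residues()
    new_atoms = []
    serial = max(a.serial for a in st.atoms)

    def emit(name, pos, ref_atom, charge):
        nonlocal serial
        serial += 1
        new_atoms.append(
            type(ref_atom)(
                serial=serial,
                name=name,
                element="H",
                residue_name=ref_atom.residue_name,
                residue_number=ref_atom.residue_number,
                chain_id=ref_atom.chain_id,
                position=np.asarray(pos, dtype=float),
                vdw_radius=1.20,
                partial_charge=charge,
                is_hetero=ref_atom.is_hetero,
            )
        )

    def acceptor_direction(o_pos, fallback):
        if polar_tree is None:
            return fallback
        idx = polar_tree.query_ball_point(o_pos, 4.0)
        best, best_d = None, math.inf
        for i in idx:
            d = float(np.linalg.norm(polar[i] - o_pos))
            if 1e-6 < d < best_d:
                best, best_d = polar[i], d
        if best is None:
            return fallback
        return _unit(best - o_pos)

    for rid, atoms in residues.items():
        if rid.residue_name == "HOH":
            continue
        by_name = {a.name: a for a in atoms}
        state_charges = _hydrogen_charges(st, rid)
        for hname, q in state_charges.items():
            if (rid.chain_id, rid.residue_number, hname) in existing_h:
                continue
            pos = _place_hydrogen(hname, by_name, acceptor_direction)
            if pos is not None:
                emit(hname, pos, atoms[0], q)
    st.atoms.extend(new_atoms)
    return st


def _hydrogen_charges(st: Structure, rid) -> dict[str, float]:
    """Hydrogen names (and charges) this residue should carry, inferred from
    the partial charges already assigned to its heavy atoms."""
    out: dict[str, float] = {}
    atoms = st.residue_atoms(rid.chain_id, rid.residue_number)
    names = {a.name for a in atoms}
    sc = SIDECHAIN_CHARGES.get(rid.residue_name)
    if sc is not None:
        # recover the state by comparing assigned heavy-atom charges
        assigned = {a.name: a.partial_charge for a in atoms}
        best_state, best_err = "neutral", math.inf
        for state, tmpl in sc.items():
            err = sum(
                abs(assigned.get(n, 0.0) - q)
                for n, q in tmpl.items()
                if not n.startswith("H")
            )
            if err < best_err:
                best_state, best_err = state, err
        for n, q in sc[best_state].items():
            if n.startswith("H"):
                out[n] = q
    if "N" in names and "CA" in names and "C" in names:
        out.setdefault("H", BACKBONE_CHARGES["H"])
    return out


def _place_hydrogen(hname, by_name, acceptor_direction):
    """Geometric placement rules per hydrogen name; None if anchors missing."""
    def tetra_frame(center, anchor):
        axis = _unit(center - anchor)
        perp = _any_perpendicular(axis)
        return axis, perp

    if hname == "H" and all(n in by_name for n in ("N", "CA")):
        n, ca = by_name["N"].position, by_name["CA"].position
        c = by_name.get("C")
        d = _unit(_unit(n - ca) + (_unit(n - c.position) if c is not None else 0))
        return n + NH_BOND * d
    if hname.startswith("HZ") and "NZ" in by_name and "CE" in by_name:
        nz, ce = by_name["NZ"].position, by_name["CE"].position
        axis, perp = tetra_frame(nz, ce)
        k = int(hname[-1]) - 1
        ang = 2.0 * math.pi * k / 3.0
        perp2 = np.cross(axis, perp)
        direction = _unit(
            math.cos(math.radians(70.5)) * axis
            + math.sin(math.radians(70.5)) * (math.cos(ang) * perp + math.sin(ang) * perp2)
        )
        return nz + NH_BOND * direction
    if hname == "HE2" and "OE2" in by_name and "CD" in by_name:
        o, c = by_name["OE2"].position, by_name["CD"].position
        return o + OH_POLAR_BOND * acceptor_direction(o, _unit(o - c))
    if hname == "HD2" and "OD2" in by_name and "CG" in by_name:
        o, c = by_name["OD2"].position, by_name["CG"].position
        return o + OH_POLAR_BOND * acceptor_direction(o, _unit(o - c))
    if hname == "HE2" and "NE2" in by_name and "CE1" in by_name and "CD2" in by_name:
        ne2 = by_name["NE2"].position
        d = _unit(
            _unit(ne2 - by_name["CE1"].position) + _unit(ne2 - by_name["CD2"].position)
        )
        return ne2 + NH_BOND * d
    if hname == "HD1" and "ND1" in by_name and "CG" in by_name and "CE1" in by_name:
        nd1 = by_name["ND1"].position
        d = _unit(
            _unit(nd1 - by_name["CG"].position) + _unit(nd1 - by_name["CE1"].position)
        )
        return nd1 + NH_BOND * d
    for oname, cname, h in (("OG", "CB", "HG"), ("OG1", "CB", "HG1"), ("OH", "CZ", "HH")):
        if hname == h and oname in by_name and cname in by_name:
            o, c = by_name[oname].position, by_name[cname].position
            return o + OH_POLAR_BOND * acceptor_direction(o, _unit(o - c))
    return None


# ---------------------------------------------------------------------------
# Energy evaluation
# ---------------------------------------------------------------------------


class _Environment:
    """Flattened interaction environment: positions, charges, LJ parameters."""

    def __init__(self, structure: Structure, placed: list[WaterSite]):
        pos, q, sig, eps = [], [], [], []
        for a in structure.atoms:
            if a.is_water:
                continue
            s, e = LJ_PARAMS.get(a.element, LJ_DEFAULT)
            pos.append(a.position)
            q.append(a.partial_charge)
            sig.append(s)
            eps.append(e)
        self.n_protein = len(pos)
        for w in placed:
            pos.append(w.oxygen_position)
            q.append(WATER_Q["O"])
            sig.append(LJ_WATER_O[0])
            eps.append(LJ_WATER_O[1])
            for h in w.hydrogen_positions:
                pos.append(h)
                q.append(WATER_Q["H"])
                sig.append(LJ_WATER_H[0])
                eps.append(LJ_WATER_H[1])
        self.pos = np.array(pos) if pos else np.zeros((0, 3))
        self.q = np.array(q)
        self.sig = np.array(sig)
        self.eps = np.array(eps)
        self.tree = cKDTree(self.pos) if len(self.pos) else None

    def energy(self, site: np.ndarray, orientations: np.ndarray = _ORIENTATIONS):
        """(best energy, best orientation index) over the orientation grid."""
        if self.tree is None:
            return 0.0, 0
        idx = self.tree.query_ball_point(site, CUTOFF + OH_BOND)
        if not idx:
            return 0.0, 0
        idx = np.asarray(sorted(idx), dtype=int)
        epos = self.pos[idx]
        eq = self.q[idx]
        esig = self.sig[idx]
        eeps = self.eps[idx]
        # water atoms for all orientations: (n_or, 3, 3)
        watoms = site[None, None, :] + orientations
        diff = watoms[:, :, None, :] - epos[None, None, :, :]
        r = np.sqrt(np.einsum("oawx,oawx->oaw", diff, diff))
        np.maximum(r, 0.05, out=r)
        wq = np.array([WATER_Q["O"], WATER_Q["H"], WATER_Q["H"]])
        wsig = np.array([LJ_WATER_O[0], LJ_WATER_H[0], LJ_WATER_H[0]])
        weps = np.array([LJ_WATER_O[1], LJ_WATER_H[1], LJ_WATER_H[1]])
        sij = 0.5 * (wsig[None, :, None] + esig[None, None, :])
        eij = np.sqrt(weps[None, :, None] * eeps[None, None, :])
        sr6 = (sij / r) ** 6
        lj = 4.0 * eij * (sr6 * sr6 - sr6)
        coul = COULOMB_CONSTANT * wq[None, :, None] * eq[None, None, :] / (4.0 * r * r)
        e = (lj + coul).sum(axis=(1, 2))
        best = int(np.argmin(e))
        return float(e[best]), best


def water_energy(
    site,
    structure: Structure,
    placed: list[WaterSite] | None = None,
    charge_model: ChargeModel | None = None,
    geometry: AtomGeometry | None = None,
) -> tuple[float, WaterSite]:
    """Best binding energy (kcal/mol) of a water at ``site`` and the
    corresponding oriented :class:`WaterSite`.

    The structure must carry radii; a charge model is applied with defaults
    if none has been.  Returns +inf for sites inside an atom.
    """
    site = np.asarray(site, dtype=float)
    if not structure.charges_assigned:
        structure = add_polar_hydrogens(structure, charge_model)
    geom = geometry
    if geom is None and structure.heavy_atoms():
        geom = AtomGeometry.from_structure(structure)
    if geom is not None and geom.clearance_one(site) < 0:
        return math.inf, WaterSite.from_oxygen(site, energy=math.inf)
    env = _Environment(structure, placed or [])
    e, oi = env.energy(site)
    return e, WaterSite.from_oxygen(site, orientation=_ORIENTATIONS[oi], energy=e)


def _candidate_sites(channel_or_network, geom: AtomGeometry, floor: float):
    """Candidate oxygen sites with their clearances, deterministic order."""
    if isinstance(channel_or_network, Channel):
        # centerline points are docking focusing sites; waters usually sit
        # against the lining, so each point also seeds a small perpendicular
        # disc of candidates
        base = np.asarray(channel_or_network.points)
        offsets = _disc_offsets(base)
        pts = np.concatenate([base, offsets]) if len(offsets) else base
        clear = geom.clearance(pts)
    elif isinstance(channel_or_network, VoidNetwork):
        verts = [v for v in channel_or_network.vertices if not v.interior]
        pts = np.array([v.position for v in verts]) if verts else np.zeros((0, 3))
        clear = np.array([v.clearance for v in verts])
    else:  # raw points
        pts = np.atleast_2d(np.asarray(channel_or_network, dtype=float))
        clear = geom.clearance(pts)
    keep = clear >= floor
    return pts[keep], clear[keep]


def place_waters(
    channel_or_network,
    structure: Structure,
    charge_model: ChargeModel | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    selection=None,
    exclusion: float = EXCLUSION_DISTANCE,
    clearance_floor: float = CANDIDATE_CLEARANCE_FLOOR,
    region_tag: str = "",
) -> HydrationResult:
    """Greedy deterministic water placement along a channel or void network.

    Candidates are centerline points / void vertices with clearance ≥
    ``clearance_floor``; the lowest-energy candidate with energy ≤
    ``threshold`` is accepted if its oxygen stays ≥ ``exclusion`` from
    accepted oxygens and ≥ 0.8·(r_O + r_atom) from protein heavy atoms,
    after which nearby candidates are re-scored with the new water included.
    """
    mode = charge_model.mode if charge_model is not None else "charged"
    prepared = structure
    if not structure.charges_assigned:
        prepared = add_polar_hydrogens(structure, charge_model, selection)
    geom = AtomGeometry.from_structure(prepared)
    sites, clear = _candidate_sites(channel_or_network, geom, clearance_floor)
    if len(sites) == 0:
        warnings.warn("no candidate sites above the clearance floor", stacklevel=2)
        return HydrationResult([], 0, threshold, mode)

    # minimum heavy-atom contact: clearance floor may admit sites closer than
    # the scaled-contact rule allows; enforce via clearance against r_O
    r_o = 1.52
    dmin_ok = np.array(
        [
            _contact_ok(geom, s, r_o)
            for s in sites
        ]
    )
    sites, clear = sites[dmin_ok], clear[dmin_ok]
    candidate_count = len(sites)
    if candidate_count == 0:
        return HydrationResult([], 0, threshold, mode)

    placed: list[WaterSite] = []
    env = _Environment(prepared, placed)
    energies = np.empty(candidate_count)
    orient = np.zeros(candidate_count, dtype=int)
    for i, s in enumerate(sites):
        energies[i], orient[i] = env.energy(s)
    active = np.ones(candidate_count, dtype=bool)

    while True:
        masked = np.where(active, energies, np.inf)
        order = np.lexsort((np.arange(candidate_count), masked))
        best = order[0]
        if not active[best] or not (masked[best] <= threshold):
            break
        pos = sites[best]
        ok = all(
            np.linalg.norm(pos - w.oxygen_position) >= exclusion for w in placed
        )
        active[best] = False
        if not ok:
            continue
        site = WaterSite.from_oxygen(
            pos,
            orientation=_ORIENTATIONS[orient[best]],
            energy=float(energies[best]),
            source="predicted",
        )
        site.region_tag = region_tag
        placed.append(site)
        # deactivate candidates violating exclusion, re-score neighbors
        env = _Environment(prepared, placed)
        d = np.linalg.norm(sites - pos, axis=1)
        active &= d >= exclusion
        near = np.flatnonzero(active & (d <= CUTOFF + exclusion))
        for i in near:
            energies[i], orient[i] = env.energy(sites[i])
    return HydrationResult(placed, candidate_count, threshold, mode)


def _disc_offsets(points: np.ndarray, radii=(0.6, 1.2), n_dirs: int = 4) -> np.ndarray:
    if len(points) < 2:
        return np.zeros((0, 3))
    tang = np.gradient(points, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1)[:, None], 1e-9)
    ref = np.where(np.abs(tang[:, :1]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    u = np.cross(tang, ref)
    u /= np.maximum(np.linalg.norm(u, axis=1)[:, None], 1e-9)
    v = np.cross(tang, u)
    out = []
    for r in radii:
        for k in range(n_dirs):
            ang = 2.0 * math.pi * k / n_dirs
            out.append(points + r * (math.cos(ang) * u + math.sin(ang) * v))
    return np.concatenate(out) if out else np.zeros((0, 3))


def _contact_ok(geom: AtomGeometry, site: np.ndarray, r_o: float) -> bool:
    idx = geom.tree.query_ball_point(site, r_o + geom.rmax)
    for i in idx:
        d = float(np.linalg.norm(geom.coords[i] - site))
        if d < CONTACT_SCALE * (r_o + geom.radii[i]):
            return False
    return True


# ---------------------------------------------------------------------------
# Matching and region tables
# ---------------------------------------------------------------------------


@dataclass
class MatchReport:
    pairs: list[tuple[int, int, float]]  # (predicted idx, experimental idx, dist)
    unmatched_predicted: list[int]
    unmatched_experimental: list[int]
    rmsd: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_waters(
    predicted: list[WaterSite],
    experimental: list[WaterSite],
    tolerance: float = 1.0,
) -> MatchReport:
    """Greedy one-to-one nearest-pair matching under a distance tolerance."""
    cand: list[tuple[float, int, int]] = []
    for i, p in enumerate(predicted):
        for j, e in enumerate(experimental):
            d = float(np.linalg.norm(p.oxygen_position - e.oxygen_position))
            if d <= tolerance:
                cand.append((d, i, j))
    cand.sort()
    used_p: set[int] = set()
    used_e: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, i, j in cand:
        if i in used_p or j in used_e:
            continue
        used_p.add(i)
        used_e.add(j)
        pairs.append((i, j, d))
        predicted[i].matched_to = j
        experimental[j].matched_to = i
    rmsd = (
        math.sqrt(sum(d * d for _, _, d in pairs) / len(pairs)) if pairs else math.nan
    )
    return MatchReport(
        pairs=pairs,
        unmatched_predicted=[i for i in range(len(predicted)) if i not in used_p],
        unmatched_experimental=[j for j in range(len(experimental)) if j not in used_e],
        rmsd=rmsd,
    )


def hydrate_regions(
    structure: Structure,
    regions: dict[str, "Channel | list"],
    charge_modes: tuple[str, ...] = ("charged", "neutral"),
    selection=None,
    threshold: float = DEFAULT_THRESHOLD,
    match_tolerance: float = 1.0,
    experimental: list[WaterSite] | None = None,
    region_margin: float = 5.0,
) -> pd.DataFrame:
    """Per-region hydration table across charge modes.

    ``regions`` maps a name to a Channel (or candidate point list); for each
    (region, charge mode) the predicted count, the experimental count within
    ``region_margin`` of the region, and the matched count are tabulated.
    """
    from .structure import extract_experimental_waters

    rows = []
    for mode in charge_modes:
        model = ChargeModel(mode=mode)
        for name, region in regions.items():
            if region is None:
                raise KeyError(f"unknown region {name!r}")
            result = place_waters(
                region, structure, model, threshold=threshold,
                selection=selection, region_tag=name,
            )
            if experimental is not None:
                exp = experimental
            else:
                exp = extract_experimental_waters(
                    structure,
                    region if isinstance(region, Channel) else None,
                    margin=region_margin,
                )
            report = match_waters(result.waters, list(exp), tolerance=match_tolerance)
            rows.append(
                {
                    "region": name,
                    "charge_mode": mode,
                    "n_predicted": result.accepted_count,
                    "n_experimental": len(exp),
                    "n_matched": report.n_matched,
                }
            )
    return pd.DataFrame(rows)
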