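"""Deterministic synthetic structures with machine-readable ground truth.

Every generator builds pseudo-atom structures from a (spec, seed) pair,
bit-exactly reproducible, and returns the designed ground truth alongside:
tube lumen profiles, designed water counts, break lengths.  Pseudo-atoms
are carbon-like rigid spheres (r = 1.70 Å); "polar" walls interleave
oxygen-like atoms carrying balanced partial charges so the hydration
energetics have something to bind to.  None of this mimics real secondary
structure — the fixtures exist to give every analysis stage an input with
a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hydration import WaterSite, _ORIENTATIONS
from .structure import Atom, ResidueId, Structure

__all__ = [
    "TubeTruth",
    "CavityTruth",
    "BlockedTubeTruth",
    "ToyAxisTruth",
    "make_tube",
    "make_polar_cavity",
    "make_water_chain",
    "make_blocked_tube",
    "make_toy_axis",
    "constant_profile",
    "sinusoidal_profile",
]

CARBON_R = 1.70
OXY_R = 1.52
WALL_SPACING = 1.4  # Å between wall pseudo-atom centers
POLAR_Q = 0.75  # polar-lining charge magnitude (C +q, O −q)
DIPOLE_EVERY = 2  # every n-th wall atom becomes an inward-facing carbonyl O
CO_OFFSET = 1.23  # Å radial offset of the buried carbonyl-carbon partner


def constant_profile(r: float):
    return lambda z: r


def sinusoidal_profile(r_min: float, r_max: float, length: float):
    """Lumen varying sinusoidally: r_max at the ends, r_min at the midpoint."""
    mid = 0.5 * (r_min + r_max)
    amp = 0.5 * (r_max - r_min)
    return lambda z: mid + amp * math.cos(2.0 * math.pi * z / length)


@dataclass
class TubeTruth:
    length: float
    lumen: "callable" = field(repr=False)
    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    min_lumen: float = 0.0
    max_lumen: float = 0.0
    side_tubes: list = field(default_factory=list)  # (z, lumen radius)

    def axis_point(self, z: float) -> np.ndarray:
        return self.axis_origin + z * self.axis_direction

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("z_A\tlumen_A\n")
            for z in np.linspace(0.0, self.length, 50):
                fh.write(f"{z:.3f}\t{self.lumen(z):.3f}\n")


def _ring(center, axis, radius, n, phase, element="C", charge=0.0):
    axis = axis / np.linalg.norm(axis)
    u = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = u - (u @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    out = []
    for k in range(n):
        ang = 2.0 * math.pi * k / n + phase
        out.append(center + radius * (math.cos(ang) * u + math.sin(ang) * v))
    return out


def _tube_positions(origin, direction, length, lumen, atom_radius, ring_spacing):
    """(position, ring index, in-ring index) triples for a tube wall."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n_rings = int(round(length / ring_spacing)) + 1
    out = []
    for i in range(n_rings):
        z = i * ring_spacing
        wall_r = lumen(z) + atom_radius
        n = max(8, int(math.ceil(2.0 * math.pi * wall_r / WALL_SPACING)))
        phase = (i % 2) * math.pi / n
        center = np.asarray(origin, dtype=float) + z * direction
        for j, p in enumerate(_ring(center, direction, wall_r, n, phase)):
            out.append((p, i, j))
    return out


def _disc_positions(center, axis, radius, spacing=1.2, hole_radius=0.0):
    """Filled disc of positions (an end cap or a plug), optional central hole."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    out = []
    r = hole_radius + (spacing if hole_radius > 0 else 0.0)
    first = hole_radius <= 0
    if first:
        out.append(np.asarray(center, dtype=float))
        r = spacing
    while r <= radius + 1e-9:
        n = max(6, int(math.ceil(2.0 * math.pi * r / spacing)))
        out.extend(_ring(center, axis, r, n, 0.0))
        r += spacing
    return out


def _make_structure(positions, elements=None, charges=None, chain="T",
                    resname="UNK", title="fixture") -> Structure:
    atoms = []
    for i, p in enumerate(positions):
        elem = elements[i] if elements is not None else "C"
        atoms.append(
            Atom(
                serial=i + 1,
                name=f"{elem}{i % 99 + 1}",
                element=elem,
                residue_name=resname,
                residue_number=i // 8 + 1,
                chain_id=chain,
                position=np.round(np.asarray(p, dtype=float), 4),
                vdw_radius=CARBON_R if elem == "C" else OXY_R,
                partial_charge=0.0 if charges is None else charges[i],
            )
        )
    st = Structure(atoms=atoms, title=title)
    st.charges_assigned = charges is not None
    return st


def make_tube(
    length: float = 30.0,
    lumen_profile=None,
    atom_radius: float = CARBON_R,
    ring_spacing: float = 1.5,
    seed: int = 0,
    polar: bool = False,
    caps: str = "none",  # none | one | both
    side_tubes: list | None = None,
) -> tuple[Structure, TubeTruth]:
    """Straight cylindrical channel of designed lumen-radius profile.

    ``side_tubes`` is a list of (z position, lumen radius) perpendicular
    branch tubes drilled through the wall.  ``polar`` walls alternate ±q
    charges (O-like/C-like atoms) so waters can bind.
    """
    lumen = lumen_profile or constant_profile(2.0)
    zs = np.linspace(0.0, length, 64)
    vals = [lumen(z) for z in zs]
    if min(vals) <= 0:
        raise ValueError("lumen profile must stay positive")
    origin = np.zeros(3)
    direction = np.array([0.0, 0.0, 1.0])
    entries = _tube_positions(origin, direction, length, lumen, atom_radius, ring_spacing)

    side_specs = []
    for z0, side_lumen in side_tubes or []:
        s_origin = np.array([0.0, 0.0, z0])
        s_dir = np.array([1.0, 0.0, 0.0])
        wall_r0 = lumen(z0) + atom_radius
        side_len = wall_r0 + 6.0
        side_specs.append((s_origin, s_dir, side_len, side_lumen))

    positions = []
    for p, i, j in entries:
        # drill wall holes where side tubes pass through
        drilled = False
        for s_origin, s_dir, s_len, s_lumen in side_specs:
            rel = p - s_origin
            t = float(rel @ s_dir)
            if 0.0 <= t <= s_len + atom_radius:
                radial = np.linalg.norm(rel - t * s_dir)
                if radial < s_lumen + atom_radius - 1e-6:
                    drilled = True
                    break
        if not drilled:
            positions.append(p)
    # side tube walls, skipping atoms protruding into the main lumen
    for s_origin, s_dir, s_len, s_lumen in side_specs:
        for p, i, j in _tube_positions(
            s_origin, s_dir, s_len, constant_profile(s_lumen), atom_radius, ring_spacing
        ):
            t = float((p - origin) @ direction)
            radial = np.linalg.norm((p - origin) - t * direction)
            if radial > lumen(min(max(t, 0.0), length)) + atom_radius - 1e-6:
                positions.append(p)
    # end caps
    if caps in ("one", "both"):
        cap_r = lumen(0.0) + 2.0 * atom_radius
        for p in _disc_positions(origin - 1.2 * direction, direction, cap_r):
            positions.append(p)
    if caps == "both":
        cap_r = lumen(length) + 2.0 * atom_radius
        for p in _disc_positions(
            origin + (length + 1.2) * direction, direction, cap_r
        ):
            positions.append(p)

    def tube_outward(p):
        t = float((p - origin) @ direction)
        radial = p - origin - t * direction
        nrm = np.linalg.norm(radial)
        return radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])

    positions, elements, charges = _polarize(positions, polar, tube_outward)
    st = _make_structure(positions, elements, charges, resname="TUB",
                         title=f"tube len={length} seed={seed}")
    truth = TubeTruth(
        length=length,
        lumen=lumen,
        axis_origin=origin,
        axis_direction=direction,
        min_lumen=float(min(vals)),
        max_lumen=float(max(vals)),
        side_tubes=list(side_tubes or []),
    )
    return st, truth


def _polarize(positions, polar, outward_fn):
    """Turn every DIPOLE_EVERY-th wall atom into an inward-facing carbonyl:
    the atom becomes O (−q) and a buried C partner (+q) is appended radially
    outward, so the lining presents aligned dipoles to the lumen and the net
    charge is exactly zero."""
    if not polar:
        return list(positions), None, None
    out_positions = list(positions)
    elements = ["C"] * len(positions)
    charges = [0.0] * len(positions)
    for i in range(0, len(positions), DIPOLE_EVERY):
        p = np.asarray(positions[i], dtype=float)
        elements[i] = "O"
        charges[i] = -POLAR_Q
        out_positions.append(p + CO_OFFSET * outward_fn(p))
        elements.append("C")
        charges.append(POLAR_Q)
    return out_positions, elements, charges


@dataclass
class CavityTruth:
    n_water_sites: int
    center: np.ndarray
    inner_radius: float


def make_polar_cavity(n_water_sites: int, seed: int = 0) -> tuple[Structure, CavityTruth]:
    """Sealed spherical pocket sized/lined to host exactly n ∈ {0, 1, 2} waters.

    n = 0: apolar carbon shell (no charges) — nothing binds below threshold.
    n = 1: carbonyl-lined shell sized so a second oxygen would violate the
    2.5 Å exclusion distance.  n = 2: prolate (two-center) polar pocket.
    """
    if n_water_sites not in (0, 1, 2):
        raise ValueError("n_water_sites must be 0, 1 or 2")
    shell_r = 3.55
    centers = [np.zeros(3)]
    if n_water_sites == 2:
        centers = [np.array([-1.45, 0.0, 0.0]), np.array([1.45, 0.0, 0.0])]
    positions = []
    # fibonacci-lattice shells around each center, dropping points inside the
    # other pocket to merge them into one capsule
    golden = math.pi * (3.0 - math.sqrt(5.0))
    n_pts = int(4.0 * math.pi * shell_r**2 / (WALL_SPACING**2 * 0.8))
    for ci, c in enumerate(centers):
        for k in range(n_pts):
            y = 1.0 - 2.0 * (k + 0.5) / n_pts
            r_xy = math.sqrt(max(0.0, 1.0 - y * y))
            theta = golden * k
            p = c + shell_r * np.array(
                [r_xy * math.cos(theta), y, r_xy * math.sin(theta)]
            )
            if any(
                np.linalg.norm(p - other) < shell_r - 1e-6
                for oi, other in enumerate(centers)
                if oi != ci
            ):
                continue
            positions.append(p)
    # outer reinforcement shell so the pocket is sealed for the probe
    for ci, c in enumerate(centers):
        for k in range(n_pts):
            y = 1.0 - 2.0 * (k + 0.25) / n_pts
            r_xy = math.sqrt(max(0.0, 1.0 - y * y))
            theta = golden * k + 0.5 * golden
            p = c + (shell_r + 1.3) * np.array(
                [r_xy * math.cos(theta), y, r_xy * math.sin(theta)]
            )
            if any(
                np.linalg.norm(p - other) < shell_r + 1.3 - 1e-6
                for oi, other in enumerate(centers)
                if oi != ci
            ):
                continue
            positions.append(p)

    polar = n_water_sites > 0

    def cavity_outward(p):
        nearest = min(centers, key=lambda c: np.linalg.norm(p - c))
        radial = p - nearest
        nrm = np.linalg.norm(radial)
        return radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])

    positions, elements, charges = _polarize(positions, polar, cavity_outward)
    st = _make_structure(
        positions, elements, charges, resname="CAV",
        title=f"polar cavity n={n_water_sites} seed={seed}",
    )
    if not polar:
        st.charges_assigned = True  # apolar by design, charges all zero
    truth = CavityTruth(
        n_water_sites=n_water_sites,
        center=np.mean(centers, axis=0),
        inner_radius=shell_r - CARBON_R,
    )
    return st, truth


def make_water_chain(n: int, spacing: float, seed: int = 0) -> list[WaterSite]:
    """Collinear waters with the given O–O spacing and random rigid orientations."""
    if n < 1 or spacing <= 0:
        raise ValueError("need n ≥ 1 and spacing > 0")
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(n):
        rot = _ORIENTATIONS[int(rng.integers(0, len(_ORIENTATIONS)))]
        sites.append(
            WaterSite.from_oxygen(
                np.array([i * spacing, 0.0, 0.0]), orientation=rot, source="predicted"
            )
        )
    return sites


@dataclass
class BlockedTubeTruth:
    tube: TubeTruth
    block_residues: list[ResidueId]
    block_z_range: tuple[float, float]
    designed_open_lumen: float


def make_blocked_tube(
    seed: int = 0,
    length: float = 30.0,
    lumen: float = 2.0,
    block_z: float = 15.0,
) -> tuple[Structure, BlockedTubeTruth]:
    """Polar tube blocked mid-length by two bulky isoleucine analogs.

    The ILE side chains (CB in the wall, CG1/CG2/CD1 protruding into the
    lumen from opposite sides) choke the channel well below the 1.4 Å water
    probe; truncating them to alanine restores the designed 2.0 Å lumen.
    """
    st, tube_truth = make_tube(
        length=length,
        lumen_profile=constant_profile(lumen),
        seed=seed,
        polar=True,
        caps="none",
    )
    wall_r = lumen + CARBON_R
    serial = max(a.serial for a in st.atoms)
    resnum_base = 900
    block_ids = []
    for k, (z, sign) in enumerate([(block_z - 0.8, 1.0), (block_z + 0.8, -1.0)]):
        resnum = resnum_base + k
        u = np.array([sign, 0.0, 0.0])
        v = np.array([0.0, sign, 0.0])
        backbone = {
            "N": u * (wall_r + 1.2) + np.array([0, 0, z - 1.0]),
            "CA": u * (wall_r + 0.8) + np.array([0, 0, z]),
            "C": u * (wall_r + 1.2) + np.array([0, 0, z + 1.0]),
            "O": u * (wall_r + 2.3) + np.array([0, 0, z + 1.2]),
            "CB": u * (wall_r + 0.7) + np.array([0, 0, z]),
            "CG1": u * (wall_r - 1.5) + v * 0.5 + np.array([0, 0, z]),
            "CG2": u * (wall_r - 1.4) - v * 0.9 + np.array([0, 0, z + 0.9]),
            "CD1": u * (wall_r - 2.9) + v * 0.2 + np.array([0, 0, z]),
        }
        for name, pos in backbone.items():
            serial += 1
            st.atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_name="ILE",
                    residue_number=resnum,
                    chain_id="B",
                    position=np.round(pos, 4),
                    vdw_radius=CARBON_R if name[0] == "C" else (1.55 if name[0] == "N" else OXY_R),
                    partial_charge=0.0,
                )
            )
        block_ids.append(ResidueId("B", resnum, "ILE"))
    truth = BlockedTubeTruth(
        tube=tube_truth,
        block_residues=block_ids,
        block_z_range=(block_z - 2.5, block_z + 2.5),
        designed_open_lumen=lumen,
    )
    return st, truth


@dataclass
class ToyAxisTruth:
    axis_residues: list[ResidueId]
    waters: list[WaterSite]
    plug_z: list[float]  # x positions of full plugs (gaps)
    orifice_z: list[float]  # x positions of narrow orifices
    designed_gap_lengths: list[float]
    n_designed_gaps: int


def make_toy_axis(seed: int = 0) -> tuple[Structure, ToyAxisTruth]:
    """A sealed channel with a residue axis, water patches, and designed gaps.

    A capped tube along x holds eight lysine analogs.  Full wall plugs sever
    the lumen at three places (proton-wire gaps); one additional partition
    is only a narrow orifice.  Water chains hydrate some segments and leave
    one segment dry, so the connectivity table exercises every class:
    water channel, narrow channel, dry channel, and gap.
    """
    length = 52.0
    lumen = 3.0
    st, _ = make_tube(
        length=length,
        lumen_profile=constant_profile(lumen),
        seed=seed,
        polar=True,
        caps="both",
    )
    # rotate tube axis z → x for readability of "left/right" along x
    for a in st.atoms:
        z = a.position[2]
        a.position = np.array([z, a.position[1], a.position[0]])

    axis = np.array([1.0, 0.0, 0.0])
    wall_r = lumen + CARBON_R
    plug_x = [13.0, 39.0]
    orifice_x = [26.0]
    serial = max(a.serial for a in st.atoms)
    for x in plug_x:
        for p in _disc_positions(np.array([x, 0.0, 0.0]), axis, wall_r, spacing=1.2):
            serial += 1
            st.atoms.append(
                Atom(serial=serial, name="C1", element="C", residue_name="PLG",
                     residue_number=800 + int(x), chain_id="P",
                     position=np.round(p, 4), vdw_radius=CARBON_R)
            )
    for x in orifice_x:
        for p in _disc_positions(
            np.array([x, 0.0, 0.0]), axis, wall_r, spacing=1.2,
            hole_radius=1.0 + CARBON_R,
        ):
            serial += 1
            st.atoms.append(
                Atom(serial=serial, name="C1", element="C", residue_name="PLG",
                     residue_number=850 + int(x), chain_id="P",
                     position=np.round(p, 4), vdw_radius=CARBON_R)
            )

    # lysine analogs: CE in the wall, NZ reaching into the lumen
    residue_x = [3.0, 10.0, 16.0, 23.0, 29.0, 36.0, 42.0, 49.0]
    axis_residues = []
    for i, x in enumerate(residue_x):
        resnum = i + 1
        ce = np.array([x, 0.0, wall_r])
        nz = np.array([x, 0.0, 2.2])
        for name, pos, elem, r in (("CE", ce, "C", CARBON_R), ("NZ", nz, "N", 1.55)):
            serial += 1
            st.atoms.append(
                Atom(serial=serial, name=name, element=elem, residue_name="LYS",
                     residue_number=resnum, chain_id="X",
                     position=np.round(pos, 4), vdw_radius=r)
            )
        axis_residues.append(ResidueId("X", resnum, "LYS"))

    # water chains: hydrate segments 1 (0–13), 2 (13–26) and 4 (39–52);
    # segment 3 (26–39) stays dry
    rng_seed = seed + 1
    waters: list[WaterSite] = []
    for x0, x1 in ((1.5, 11.5), (15.0, 24.5), (41.0, 50.5)):
        n = int((x1 - x0) / 2.8) + 1
        for i in range(n):
            waters.append(
                WaterSite.from_oxygen(
                    np.array([x0 + 2.8 * i, 0.0, 0.0]), source="predicted"
                )
            )
    # designed proton-wire gaps: residue pairs straddling the plugs/orifice
    gaps = [
        float(np.linalg.norm([16.0 - 10.0, 0.0, 0.0])),  # across plug 1 (NZ–NZ)
        float(np.linalg.norm([29.0 - 23.0, 0.0, 0.0])),  # across the orifice
        float(np.linalg.norm([42.0 - 36.0, 0.0, 0.0])),  # across plug 2
    ]
    truth = ToyAxisTruth(
        axis_residues=axis_residues,
        waters=waters,
        plug_z=plug_x,
        orifice_z=orifice_x,
        designed_gap_lengths=gaps,
        n_designed_gaps=3,
    )
    st.charges_assigned = True
    return st, truth
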