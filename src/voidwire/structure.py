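"""Structure input/output and atom-level annotation.

Structures are modelled as collections of rigid spheres: each heavy atom
carries a van der Waals radius (Bondi set by default) and, once a charge
model has been applied, a partial charge in elementary-charge units.
Reading and writing of PDB/mmCIF goes through :mod:`gemmi`; this module
only adds the annotations the channel/hydration analysis needs —
protonatable-residue classification, protonation-state charge templates,
and extraction of experimentally resolved waters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

import gemmi

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "ChargeModel",
    "ResidueId",
    "BONDI_RADII",
    "DEFAULT_VDW_RADIUS",
    "PROTONATABLE_RESIDUES",
    "read_structure",
    "write_pdb",
    "assign_radii",
    "classify_protonatable",
    "apply_charge_model",
    "extract_experimental_waters",
    "parse_selection",
]

#: Bondi van der Waals radii (Å) by element symbol (upper case).
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
}

#: Fallback radius (Å) for elements missing from the table (carbon-like).
DEFAULT_VDW_RADIUS = 1.70

#: Residues with protonatable side-chain groups (E, D, H, K, S, T, Y).
PROTONATABLE_RESIDUES = frozenset({"GLU", "ASP", "HIS", "LYS", "SER", "THR", "TYR"})

#: Side-chain polar atoms that can act as proton donors/acceptors.
PROTONATABLE_SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "SOL"}


class ResidueId(NamedTuple):
    """Identifies one residue by chain, number and name."""

    chain_id: str
    residue_number: int
    residue_name: str


@dataclass(slots=True)
class Atom:
    """One atom as a rigid sphere with residue/chain metadata."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    vdw_radius: float = DEFAULT_VDW_RADIUS
    partial_charge: float = 0.0
    is_hetero: bool = False
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")
        if not self.element:
            self.element = _infer_element(self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.residue_name == "HOH"

    @property
    def residue_id(self) -> ResidueId:
        return ResidueId(self.chain_id, self.residue_number, self.residue_name)


def _infer_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if len(stripped) >= 2 and stripped[:2].upper() in BONDI_RADII and stripped[:2].isalpha():
        # Two-letter element only when it is not a remoteness code (CA, CB, ...)
        if stripped[:2].upper() in {"FE", "ZN", "MG", "CL", "BR", "NA"}:
            return stripped[:2].upper()
    return stripped[0].upper()


@dataclass
class Structure:
    """An ordered list of atoms plus provenance metadata."""

    atoms: list[Atom] = field(default_factory=list)
    title: str = ""
    source_format: str = "PDB"
    charges_assigned: bool = False

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    # -- array views -------------------------------------------------

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        """(n, 3) array of atom positions (heavy atoms only by default)."""
        sel = self.heavy_atoms() if heavy_only else self.atoms
        if not sel:
            return np.zeros((0, 3))
        return np.array([a.position for a in sel], dtype=float)

    def radii(self, heavy_only: bool = True) -> np.ndarray:
        sel = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.vdw_radius for a in sel], dtype=float)

    def heavy_atoms(self) -> list[Atom]:
        """Atoms used for the rigid-sphere clearance model (no H, no water)."""
        return [a for a in self.atoms if not a.is_hydrogen and not a.is_water]

    # -- residue access ----------------------------------------------

    def residues(self) -> dict[ResidueId, list[Atom]]:
        out: dict[ResidueId, list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]

    def get_atom(self, chain_id: str, residue_number: int, name: str) -> Atom | None:
        for a in self.atoms:
            if (
                a.chain_id == chain_id
                and a.residue_number == residue_number
                and a.name == name
            ):
                return a
        return None

    def copy(self) -> "Structure":
        return Structure(
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            title=self.title,
            source_format=self.source_format,
            charges_assigned=self.charges_assigned,
        )


@dataclass
class ChargeModel:
    """Protonation-state assignment for the selected (central-axis) residues.

    ``mode`` is ``"charged"`` (Lys side chains +1, Glu/Asp side chains −1),
    ``"neutral"`` (all net 0) or ``"custom"``; per-residue overrides flip
    individual residues.  Residues outside the selection always get the
    neutral-state template.
    """

    mode: str = "charged"
    per_residue_overrides: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("charged", "neutral", "custom"):
            raise ValueError(f"unknown charge mode {self.mode!r}")

    def state_for(self, chain_id: str, residue_number: int, selected: bool) -> str:
        override = self.per_residue_overrides.get((chain_id, residue_number))
        if override is not None:
            return override
        if not selected:
            return "neutral"
        return "charged" if self.mode == "charged" else "neutral"


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def read_structure(path: str | Path, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Altlocs are resolved to the highest-occupancy conformer (ties broken
    alphabetically, i.e. 'A' wins).  Hydrogens are retained but flagged;
    only model 1 of multi-model files is used.  Water residue names are
    normalised to HOH.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc
    source_format = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    if fmt != "auto":
        source_format = fmt

    if len(st) == 0:
        raise ValueError(f"{path.name}: structure contains no models")
    model = st[0]

    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            resname = res.name.upper()
            if resname in _WATER_NAMES:
                resname = "HOH"
            # altloc resolution: group by atom name, keep best occupancy
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                elif at.occ > prev.occ or (
                    at.occ == prev.occ and (at.altloc or "Z") < (prev.altloc or "Z")
                ):
                    by_name[at.name] = at
            for at in by_name.values():
                serial += 1
                elem = at.element.name.upper() if at.element else ""
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=elem or _infer_element(at.name),
                        residue_name=resname,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_hetero=res.het_flag == "H" or resname == "HOH",
                        b_factor=at.b_iso,
                        occupancy=at.occ,
                        altloc=at.altloc or "",
                    )
                )
    if not atoms:
        raise ValueError(f"{path.name}: no atoms found")
    return Structure(atoms=atoms, title=st.name or path.stem, source_format=source_format)


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.title or "voidwire"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for atom in structure.atoms:
        chain = chains.get(atom.chain_id)
        if chain is None:
            chain = gemmi.Chain(atom.chain_id or "A")
            chains[atom.chain_id] = chain
        res = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if last.seqid.num == atom.residue_number and last.name == atom.residue_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(atom.residue_number, " ")
            res.het_flag = "H" if atom.is_hetero else "A"
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        g = gemmi.Atom()
        g.name = atom.name
        g.element = gemmi.Element(atom.element.capitalize())
        g.pos = gemmi.Position(*atom.position)
        g.occ = atom.occupancy
        g.b_iso = atom.b_factor
        g.serial = atom.serial
        res.add_atom(g)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure to PDB (coordinates at standard 3-decimal precision)."""
    _to_gemmi(structure).write_pdb(str(path))


def write_atom_table(structure: Structure, path: str | Path) -> None:
    """Dump atoms as TSV (serial, name, residue, chain, x, y, z, radius, charge)."""
    with open(path, "w") as fh:
        fh.write(
            "serial\tname\telement\tresidue_name\tresidue_number\tchain_id"
            "\tx\ty\tz\tvdw_radius\tpartial_charge\n"
        )
        for a in structure.atoms:
            fh.write(
                f"{a.serial}\t{a.name}\t{a.element}\t{a.residue_name}\t"
                f"{a.residue_number}\t{a.chain_id}\t{a.position[0]:.3f}\t"
                f"{a.position[1]:.3f}\t{a.position[2]:.3f}\t{a.vdw_radius:.3f}\t"
                f"{a.partial_charge:.4f}\n"
            )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def assign_radii(
    structure: Structure,
    radii_table: dict[str, float] | None = None,
    default: float = DEFAULT_VDW_RADIUS,
) -> Structure:
    """Assign van der Waals radii from an element table (Bondi by default).

    Unknown elements receive ``default`` and trigger a single logged warning.
    Returns the same structure (modified in place) for chaining.
    """
    table = {k.upper(): v for k, v in (radii_table or BONDI_RADII).items()}
    unknown: set[str] = set()
    for atom in structure.atoms:
        r = table.get(atom.element.upper())
        if r is None:
            unknown.add(atom.element)
            r = default
        atom.vdw_radius = r
    if unknown:
        logger.warning(
            "elements %s not in radii table; using default %.2f Å",
            sorted(unknown),
            default,
        )
        warnings.warn(
            f"elements {sorted(unknown)} not in radii table; default {default:.2f} Å used",
            stacklevel=2,
        )
    return structure


def classify_protonatable(structure: Structure) -> set[ResidueId]:
    """Residues bearing protonatable side-chain groups (Glu, Asp, His, Lys, Ser, Thr, Tyr)."""
    if not structure.atoms:
        raise ValueError("empty structure")
    return {
        a.residue_id for a in structure.atoms if a.residue_name in PROTONATABLE_RESIDUES
    }


# Partial-charge templates (elementary charges).  Backbone polar group is the
# same for every amino acid; side-chain templates cover the protonatable set
# in both protonation states.  Hydrogen entries refer to polar hydrogens that
# the hydration module constructs geometrically; their charges are included
# here so that each group's net charge is exact by construction.
BACKBONE_CHARGES: dict[str, float] = {
    "N": -0.47,
    "H": 0.31,
    "CA": 0.16,
    "C": 0.51,
    "O": -0.51,
}

SIDECHAIN_CHARGES: dict[str, dict[str, dict[str, float]]] = {
    "LYS": {
        "charged": {"CE": 0.25, "NZ": -0.30, "HZ1": 0.35, "HZ2": 0.35, "HZ3": 0.35},
        "neutral": {"CE": 0.00, "NZ": -0.60, "HZ1": 0.30, "HZ2": 0.30},
    },
    "GLU": {
        "charged": {"CD": 0.62, "OE1": -0.81, "OE2": -0.81},
        "neutral": {"CD": 0.55, "OE1": -0.50, "OE2": -0.60, "HE2": 0.55},
    },
    "ASP": {
        "charged": {"CG": 0.62, "OD1": -0.81, "OD2": -0.81},
        "neutral": {"CG": 0.55, "OD1": -0.50, "OD2": -0.60, "HD2": 0.55},
    },
    # NE2-H tautomer for neutral His
    "HIS": {
        "charged": {"ND1": -0.40, "NE2": -0.40, "HE2": 0.40, "HD1": 0.40, "CE1": 0.50,
                    "CG": 0.10},
        "neutral": {"ND1": -0.40, "NE2": -0.40, "HE2": 0.40, "CE1": 0.40},
    },
    "SER": {
        "charged": {"OG": -0.65, "HG": 0.42, "CB": 0.23},
        "neutral": {"OG": -0.65, "HG": 0.42, "CB": 0.23},
    },
    "THR": {
        "charged": {"OG1": -0.65, "HG1": 0.42, "CB": 0.23},
        "neutral": {"OG1": -0.65, "HG1": 0.42, "CB": 0.23},
    },
    "TYR": {
        "charged": {"OH": -0.56, "HH": 0.40, "CZ": 0.16},
        "neutral": {"OH": -0.56, "HH": 0.40, "CZ": 0.16},
    },
}

#: nominal net side-chain charge per (residue, state)
NOMINAL_SIDECHAIN_CHARGE = {
    ("LYS", "charged"): 1.0,
    ("GLU", "charged"): -1.0,
    ("ASP", "charged"): -1.0,
}


def apply_charge_model(
    structure: Structure,
    model: ChargeModel,
    selection: Iterable[ResidueId] | Iterable[tuple[str, int]] | None = None,
) -> Structure:
    """Set partial charges per the charge templates and protonation model.

    ``selection`` names the residues (typically the central-axis Lys/Glu/Asp)
    whose protonation state follows ``model.mode``; everything else gets the
    neutral-state template.  Backbone polar charges are applied to every
    standard amino-acid residue.  Raises if a selected residue is absent.
    """
    selected: set[tuple[str, int]] = set()
    if selection is not None:
        for item in selection:
            selected.add((item[0], int(item[1])))
        present = {(a.chain_id, a.residue_number) for a in structure.atoms}
        missing = selected - present
        if missing:
            raise ValueError(f"selection residues not in structure: {sorted(missing)}")

    for atom in structure.atoms:
        if atom.is_water:
            atom.partial_charge = 0.0
            continue
        resname = atom.residue_name
        state = model.state_for(
            atom.chain_id, atom.residue_number, (atom.chain_id, atom.residue_number) in selected
        )
        charge = 0.0
        sc = SIDECHAIN_CHARGES.get(resname)
        if sc is not None and atom.name in sc[state]:
            charge = sc[state][atom.name]
        elif atom.name in BACKBONE_CHARGES and resname not in ("HOH",):
            charge = BACKBONE_CHARGES[atom.name]
        atom.partial_charge = charge
    structure.charges_assigned = True
    return structure


def sidechain_charge_sum(structure: Structure, chain_id: str, residue_number: int) -> float:
    """Sum of side-chain partial charges of one residue (backbone excluded)."""
    total = 0.0
    for a in structure.residue_atoms(chain_id, residue_number):
        if a.name not in BACKBONE_CHARGES:
            total += a.partial_charge
    return total


# ---------------------------------------------------------------------------
# Experimental waters and selections
# ---------------------------------------------------------------------------


def extract_experimental_waters(
    structure: Structure,
    region: "object | None" = None,
    margin: float = 5.0,
):
    """Extract resolved water oxygens as experimental :class:`WaterSite` records.

    ``region`` restricts the result: it may be a Channel (waters within
    ``margin`` of the centerline), a set of :class:`ResidueId` (waters within
    ``margin`` of any selected-residue atom) or None (all waters).
    """
    from .hydration import WaterSite  # deferred; hydration imports structure

    oxygens = [
        a
        for a in structure.atoms
        if a.is_water and (a.element == "O" or a.name.startswith("O"))
    ]
    sites = [
        WaterSite.from_oxygen(a.position, source="experimental", label=f"{a.chain_id}{a.residue_number}")
        for a in oxygens
    ]
    if region is None or not sites:
        return sites

    if hasattr(region, "points"):  # a Channel
        ref = np.asarray(region.points, dtype=float)
    else:  # residue selection
        wanted = {(r[0], int(r[1])) for r in region}
        ref = np.array(
            [
                a.position
                for a in structure.atoms
                if (a.chain_id, a.residue_number) in wanted
            ]
        )
        if ref.size == 0:
            return []
    from scipy.spatial import cKDTree

    tree = cKDTree(ref)
    dists, _ = tree.query(np.array([s.oxygen_position for s in sites]))
    return [s for s, d in zip(sites, dists) if d <= margin]


def parse_selection(spec: str) -> list[tuple[str, int]]:
    """Parse ``"A:10-20,B:5"`` into [(chain, resnum), ...] (1-based, inclusive)."""
    out: list[tuple[str, int]] = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        chain, _, rng = part.partition(":")
        if not rng:
            raise ValueError(f"selection {part!r} must look like CHAIN:NUM or CHAIN:LO-HI")
        if "-" in rng:
            lo, hi = rng.split("-")
            out.extend((chain, n) for n in range(int(lo), int(hi) + 1))
        else:
            out.append((chain, int(rng)))
    return out
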