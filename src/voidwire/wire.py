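"""Proton-wire connectivity: donor–acceptor graphs, patches, gaps, and the
channel classification table.

A proton wire is operationalized as an undirected graph whose nodes are
water oxygens and the polar side-chain atoms of protonatable residues, with
edges between every pair within a donor–acceptor cutoff (3.5 Å by default —
the distance across which a Grotthuss proton hop between oxygens is treated
as facile).  Connected components of this graph are conductive *patches*;
the break between two patches is a *gap*, reported as the minimum
heavy-atom donor–acceptor distance between them.  Channels linking two
endpoints are classified as water channels (a full proton-graph path),
narrow channels (a geometric channel with some water but no full path), dry
channels (a geometric channel holding no water), or gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .hydration import WaterSite, match_waters
from .structure import (
    PROTONATABLE_RESIDUES,
    PROTONATABLE_SIDECHAIN_ATOMS,
    ResidueId,
    Structure,
)
from .voids import (
    Channel,
    NoChannelError,
    VoidNetwork,
    trace_channel,
)

__all__ = [
    "ProtonNode",
    "ProtonGraph",
    "GapRecord",
    "ConnectivityRecord",
    "PROTON_CUTOFF",
    "NARROW_CHANNEL_FLOOR",
    "CONNECTIVITY_CLASSES",
    "build_proton_graph",
    "patches",
    "measure_gap",
    "classify_connectivity",
    "mutate_to_alanine",
    "connectivity_table",
    "pool_waters",
]

#: donor–acceptor cutoff (Å) for a facile proton hop
PROTON_CUTOFF = 3.5
#: geometric bottleneck floor (Å) for a channel to count as "narrow"
NARROW_CHANNEL_FLOOR = 0.9

#: classification vocabulary of the connectivity table
CONNECTIVITY_CLASSES = ("water channel", "narrow channel", "dry channel", "none", "gap")

#: backbone atoms retained by alanine truncation
_ALA_KEEP = {"N", "CA", "C", "O", "CB", "OXT", "H", "HA"}


@dataclass(slots=True)
class ProtonNode:
    id: int
    kind: str  # "water_O" | "sidechain"
    position: np.ndarray
    residue: tuple | None = None  # (chain, resnum, resname, atom name)


@dataclass
class ProtonGraph:
    nodes: list[ProtonNode]
    edges: list[tuple[int, int, float]]
    cutoff: float = PROTON_CUTOFF
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)

    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            for n in self.nodes:
                g.add_node(n.id, kind=n.kind, residue=n.residue)
            for a, b, d in self.edges:
                g.add_edge(a, b, distance=d)
            self._graph = g
        return self._graph

    def nodes_of_residue(self, chain_id: str, residue_number: int) -> list[int]:
        return [
            n.id
            for n in self.nodes
            if n.residue is not None
            and n.residue[0] == chain_id
            and n.residue[1] == residue_number
        ]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tdistance_A\n")
            for a, b, d in self.edges:
                fh.write(f"{a}\t{b}\t{d:.3f}\n")


@dataclass
class GapRecord:
    patch_a: int
    patch_b: int
    gap_length: float
    nearest_pair: tuple[int, int]
    along_channel: tuple[float, float] | None = None
    connected: bool = False

    def label(self) -> str:
        return "connected" if self.connected else f"G{self.gap_length:.1f}"


@dataclass
class ConnectivityRecord:
    residue: ResidueId
    direction: str  # left | right | top | bottom
    partner: str
    channel_class: str  # one of CONNECTIVITY_CLASSES
    gap_length: float | None = None
    via: list[str] = field(default_factory=list)

    def class_label(self) -> str:
        if self.channel_class == "gap":
            return f"none (G{self.gap_length:.1f})"
        return self.channel_class


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def build_proton_graph(
    waters: list[WaterSite],
    structure: Structure | None = None,
    residues: set[ResidueId] | None = None,
    cutoff: float = PROTON_CUTOFF,
) -> ProtonGraph:
    """Donor–acceptor graph over water oxygens and protonatable side-chain
    polar atoms, with edges for every pair within ``cutoff`` Å."""
    nodes: list[ProtonNode] = []
    for w in waters:
        nodes.append(
            ProtonNode(id=len(nodes), kind="water_O", position=np.asarray(w.oxygen_position))
        )
    if structure is not None:
        wanted = residues
        for a in structure.atoms:
            if a.is_water or a.is_hydrogen:
                continue
            polar = PROTONATABLE_SIDECHAIN_ATOMS.get(a.residue_name, ())
            if a.name not in polar:
                continue
            if wanted is not None and a.residue_id not in wanted:
                continue
            nodes.append(
                ProtonNode(
                    id=len(nodes),
                    kind="sidechain",
                    position=a.position,
                    residue=(a.chain_id, a.residue_number, a.residue_name, a.name),
                )
            )
    edges: list[tuple[int, int, float]] = []
    if nodes:
        pos = np.array([n.position for n in nodes])
        tree = cKDTree(pos)
        for i, j in sorted(tree.query_pairs(cutoff)):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            edges.append((i, j, d))
    return ProtonGraph(nodes=nodes, edges=edges, cutoff=cutoff)


def patches(graph: ProtonGraph) -> list[list[int]]:
    """Connected components (conductive patches), ordered by smallest node id."""
    comps = [sorted(c) for c in nx.connected_components(graph.graph())]
    return sorted(comps, key=lambda c: c[0])


def measure_gap(graph: ProtonGraph, set_a, set_b) -> GapRecord:
    """Minimum pairwise distance between two node (or residue) sets.

    Sets may be node-id iterables or residue identifiers; they must be
    non-empty and disjoint.  Distances ≤ cutoff report ``connected``.
    """
    ids_a = _resolve_node_set(graph, set_a)
    ids_b = _resolve_node_set(graph, set_b)
    if not ids_a or not ids_b:
        raise ValueError("gap measurement requires two non-empty sets")
    if ids_a & ids_b:
        raise ValueError("gap measurement requires disjoint sets")
    pos = {n.id: n.position for n in graph.nodes}
    best = (math.inf, -1, -1)
    for i in sorted(ids_a):
        for j in sorted(ids_b):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d < best[0]:
                best = (d, i, j)
    comp_index = _component_index(graph)
    return GapRecord(
        patch_a=comp_index.get(best[1], -1),
        patch_b=comp_index.get(best[2], -1),
        gap_length=best[0],
        nearest_pair=(best[1], best[2]),
        connected=best[0] <= graph.cutoff,
    )


def _resolve_node_set(graph: ProtonGraph, spec) -> set[int]:
    ids: set[int] = set()
    for item in spec:
        if isinstance(item, (int, np.integer)):
            ids.add(int(item))
        else:  # residue identifier (chain, resnum[, ...])
            ids.update(graph.nodes_of_residue(item[0], int(item[1])))
    return ids


def _component_index(graph: ProtonGraph) -> dict[int, int]:
    out: dict[int, int] = {}
    for ci, comp in enumerate(patches(graph)):
        for n in comp:
            out[n] = ci
    return out


def isolating_gaps(graph: ProtonGraph, min_patch_size: int = 1) -> list[GapRecord]:
    """Gap records between consecutive patches ordered along the first
    principal axis of the node cloud (a channel-like geometry)."""
    comps = [c for c in patches(graph) if len(c) >= min_patch_size]
    if len(comps) < 2:
        return []
    pos = np.array([n.position for n in graph.nodes])
    centroid = pos.mean(axis=0)
    u, s, vt = np.linalg.svd(pos - centroid, full_matrices=False)
    axis = vt[0]
    order = sorted(comps, key=lambda c: float(np.mean((pos[c] - centroid) @ axis)))
    gaps = []
    for a, b in zip(order[:-1], order[1:]):
        rec = measure_gap(ProtonGraph(graph.nodes, graph.edges, graph.cutoff), a, b)
        if not rec.connected:
            gaps.append(rec)
    return gaps


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def mutate_to_alanine(structure: Structure, residues) -> Structure:
    """In-silico truncation of side chains to alanine.

    Atoms beyond CB are deleted and the residue renamed ALA; indices and
    chains are preserved.  Glycine (no CB) and non-protein residues raise.
    """
    targets = {(r[0], int(r[1])) for r in residues}
    present: dict[tuple[str, int], str] = {}
    has_cb: set[tuple[str, int]] = set()
    for a in structure.atoms:
        key = (a.chain_id, a.residue_number)
        if key in targets:
            present[key] = a.residue_name
            if a.name == "CB":
                has_cb.add(key)
    missing = targets - set(present)
    if missing:
        raise ValueError(f"residues not in structure: {sorted(missing)}")
    for key, name in present.items():
        if name not in _STANDARD_AA:
            raise ValueError(f"{key}: {name} is not a standard amino acid")
        if name == "GLY" or key not in has_cb:
            raise ValueError(f"{key}: residue has no CB atom; cannot truncate")
    out = structure.copy()
    out.atoms = [
        a
        for a in out.atoms
        if (a.chain_id, a.residue_number) not in targets or a.name in _ALA_KEEP
    ]
    for a in out.atoms:
        if (a.chain_id, a.residue_number) in targets:
            a.residue_name = "ALA"
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def pool_waters(
    predicted: list[WaterSite],
    experimental: list[WaterSite],
    dedup_tolerance: float = 1.0,
    pool: str = "both",
) -> list[WaterSite]:
    """Pool predicted and experimental waters, deduplicating matched pairs
    (the experimental copy wins)."""
    if pool == "predicted":
        return list(predicted)
    if pool == "experimental":
        return list(experimental)
    report = match_waters(list(predicted), list(experimental), tolerance=dedup_tolerance)
    matched_pred = {i for i, _, _ in report.pairs}
    out = list(experimental)
    out.extend(p for i, p in enumerate(predicted) if i not in matched_pred)
    return out


def _residue_anchor(structure: Structure, rid: ResidueId) -> np.ndarray:
    polar = PROTONATABLE_SIDECHAIN_ATOMS.get(rid.residue_name, ())
    atoms = structure.residue_atoms(rid.chain_id, rid.residue_number)
    for name in polar:
        for a in atoms:
            if a.name == name:
                return a.position
    if not atoms:
        raise ValueError(f"residue {rid} not in structure")
    return np.mean([a.position for a in atoms], axis=0)


def classify_connectivity(
    residue: ResidueId,
    direction: str,
    graph: ProtonGraph,
    network: VoidNetwork,
    waters,
    structure: Structure,
    partner: ResidueId | None = None,
    membrane_normal=None,
    surface_vertices: set[int] | None = None,
    narrow_floor: float = NARROW_CHANNEL_FLOOR,
    water_margin: float = 3.0,
) -> ConnectivityRecord:
    """Classify the channel from ``residue`` toward one endpoint.

    left/right endpoints are neighboring axis residues (``partner``);
    top/bottom endpoints are surface exits along ±``membrane_normal``.
    Rules: *water channel* if a proton-graph path connects the endpoints;
    *narrow channel* if a geometric channel of bottleneck ≥ ``narrow_floor``
    exists with at least one water near it but no full path; *dry channel*
    if the geometric channel holds no water; *gap(L)* with L the minimum
    donor–acceptor distance if no geometric channel exists; *none* when
    there is no meaningful endpoint.
    """
    water_list = getattr(waters, "waters", waters) or []
    src_nodes = set(graph.nodes_of_residue(residue.chain_id, residue.residue_number))
    start = _residue_anchor(structure, residue)

    if direction in ("left", "right"):
        if partner is None:
            return ConnectivityRecord(residue, direction, "none", "none")
        end = _residue_anchor(structure, partner)
        dst_nodes = set(graph.nodes_of_residue(partner.chain_id, partner.residue_number))
        partner_name = f"{partner.residue_name}{partner.residue_number}"
    elif direction in ("top", "bottom"):
        if membrane_normal is None or not surface_vertices:
            return ConnectivityRecord(residue, direction, "none", "none")
        normal = np.asarray(membrane_normal, dtype=float)
        if direction == "bottom":
            normal = -normal
        end_vid = _surface_endpoint(network, surface_vertices, start, normal)
        if end_vid is None:
            return ConnectivityRecord(residue, direction, "none", "none")
        end = network.vertex(end_vid).position
        dst_nodes = _nodes_near(graph, end, 2 * graph.cutoff)
        partner_name = "surface"
    else:
        raise ValueError(f"unknown direction {direction!r}")

    # proton-graph path?
    g = graph.graph()
    path_nodes = _connecting_path(g, src_nodes, dst_nodes)
    if path_nodes is not None:
        via = _via_labels(graph, path_nodes, residue, partner)
        return ConnectivityRecord(residue, direction, partner_name, "water channel", via=via)

    # geometric channel?
    channel = None
    try:
        # seeds snap to open vertices so the tight terminal approach to a
        # side chain does not mask an otherwise open channel
        channel = trace_channel(
            network, start, end, cost="max_bottleneck", seed_clearance=narrow_floor
        )
    except (NoChannelError, ValueError):
        channel = None
    if channel is not None and channel.bottleneck >= narrow_floor:
        n_near = _waters_near_channel(water_list, channel, water_margin)
        cls = "narrow channel" if n_near > 0 else "dry channel"
        return ConnectivityRecord(residue, direction, partner_name, cls)

    # no geometric channel: report the donor–acceptor gap
    if src_nodes and dst_nodes and not (src_nodes & dst_nodes):
        rec = measure_gap(graph, src_nodes, dst_nodes)
        return ConnectivityRecord(
            residue, direction, partner_name, "gap", gap_length=rec.gap_length
        )
    gap = float(np.linalg.norm(np.asarray(end) - start))
    return ConnectivityRecord(residue, direction, partner_name, "gap", gap_length=gap)


def _surface_endpoint(network, surface_vertices, start, normal, cone_cos=0.5):
    best, best_d = None, math.inf
    for vid in sorted(surface_vertices):
        disp = network.vertex(vid).position - start
        d = float(np.linalg.norm(disp))
        if d < 1e-6:
            continue
        if float(disp @ normal) / d < cone_cos:
            continue
        if d < best_d:
            best, best_d = vid, d
    return best


def _nodes_near(graph: ProtonGraph, point, radius) -> set[int]:
    p = np.asarray(point, dtype=float)
    return {
        n.id for n in graph.nodes if float(np.linalg.norm(n.position - p)) <= radius
    }


def _connecting_path(g: nx.Graph, src: set[int], dst: set[int]):
    if not src or not dst:
        return None
    if src & dst:
        return sorted(src & dst)[:1]
    for s in sorted(src):
        for t in sorted(dst):
            if s in g and t in g and nx.has_path(g, s, t):
                return nx.shortest_path(g, s, t)
    return None


def _via_labels(graph, path_nodes, residue, partner) -> list[str]:
    labels: list[str] = []
    n_water = 0
    skip = {
        (residue.chain_id, residue.residue_number),
        (partner.chain_id, partner.residue_number) if partner is not None else None,
    }
    for nid in path_nodes:
        node = graph.nodes[nid]
        if node.kind == "water_O":
            n_water += 1
            continue
        key = (node.residue[0], node.residue[1])
        if key in skip:
            continue
        lbl = f"{node.residue[2]}{node.residue[1]}"
        if lbl not in labels:
            labels.append(lbl)
    if n_water:
        labels.append(f"W×{n_water}")
    return labels


def _waters_near_channel(water_list, channel: Channel, margin: float) -> int:
    if not water_list:
        return 0
    tree = cKDTree(np.asarray(channel.points))
    pos = np.array([w.oxygen_position for w in water_list])
    d, _ = tree.query(pos)
    return int(np.sum(d <= margin))


def connectivity_table(
    structure: Structure,
    axis_residues: list[ResidueId],
    graph: ProtonGraph,
    network: VoidNetwork,
    waters,
    membrane_normal=None,
    surface_vertices: set[int] | None = None,
) -> list[ConnectivityRecord]:
    """One record per axis residue per direction (left, right, top, bottom).

    The axis order is supplied by the caller (the Lys/Glu central-axis
    chain); left/right follow that ordering.
    """
    for rid in axis_residues:
        if rid.residue_name not in PROTONATABLE_RESIDUES:
            raise ValueError(f"{rid}: not a protonatable residue")
    records: list[ConnectivityRecord] = []
    for i, rid in enumerate(axis_residues):
        neighbors = {
            "left": axis_residues[i - 1] if i > 0 else None,
            "right": axis_residues[i + 1] if i < len(axis_residues) - 1 else None,
        }
        for direction in ("left", "right", "top", "bottom"):
            records.append(
                classify_connectivity(
                    rid,
                    direction,
                    graph,
                    network,
                    waters,
                    structure,
                    partner=neighbors.get(direction),
                    membrane_normal=membrane_normal,
                    surface_vertices=surface_vertices,
                )
            )
    return records


def connectivity_table_frame(records: list[ConnectivityRecord]):
    """Wide table mirroring the four direction columns."""
    import pandas as pd

    rows: dict[ResidueId, dict[str, str]] = {}
    for r in records:
        row = rows.setdefault(r.residue, {})
        row[r.direction] = r.class_label() if r.channel_class != "water channel" else (
            r.partner + (f" (via {'-'.join(r.via)})" if r.via else "")
        )
        if r.channel_class in ("narrow channel", "dry channel"):
            row[r.direction] = r.channel_class
    out = []
    for rid, row in rows.items():
        out.append(
            {
                "subunit": rid.chain_id,
                "residue": f"{rid.residue_name}{rid.residue_number}",
                "left": row.get("left", "none"),
                "right": row.get("right", "none"),
                "top": row.get("top", "none"),
                "bottom": row.get("bottom", "none"),
            }
        )
    return pd.DataFrame(out, columns=["residue", "subunit", "left", "right", "top", "bottom"])
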