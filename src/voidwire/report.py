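"""Pipeline orchestration and report bundles.

``run_pipeline`` chains the full analysis — void network → channel →
hydration → proton wire → classification — from a single :class:`RunConfig`
and emits a directory of artifacts (channel PDB + profile TSV, water PDB,
proton-graph TSV, connectivity table, gap list, JSON summary).  Outputs are
bit-reproducible: every stage is deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fixtures as fixture_mod
from .hydration import (
    DEFAULT_THRESHOLD,
    match_waters,
    place_waters,
    water_energy,
)
from .structure import (
    ChargeModel,
    Structure,
    assign_radii,
    classify_protonatable,
    extract_experimental_waters,
    parse_selection,
    read_structure,
    write_pdb,
)
from .voids import (
    NoChannelError,
    build_void_network,
    find_surface_vertices,
    profile_channel,
    trace_channel,
)
from .wire import (
    PROTON_CUTOFF,
    build_proton_graph,
    connectivity_table,
    connectivity_table_frame,
    isolating_gaps,
    mutate_to_alanine,
    patches,
    pool_waters,
)

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through TOML."""

    input: str = ""
    start: list[float] | None = None  # seed coordinates (Å)
    end: list[float] | None = None
    start_selection: str = ""  # alternative: residue selection "A:10-12"
    end_selection: str = ""
    charge_mode: str = "charged"
    charge_selection: str = ""  # central-axis residues, "A:10-20,B:5"
    min_radius: float = 0.9
    probe_radius: float = 1.4
    energy_threshold: float = DEFAULT_THRESHOLD
    proton_cutoff: float = PROTON_CUTOFF
    match_tolerance: float = 1.0
    n_profile_samples: int = 100
    cost: str = "max_bottleneck"
    pool: str = "both"  # waters used for the wire: both | predicted | experimental
    mutate: str = ""  # residues to truncate to ALA before analysis
    axis: str = ""  # ordered axis residues for the connectivity table
    membrane_normal: list[float] = field(default_factory=lambda: [0.0, 0.0, 1.0])
    output_dir: str = "voidwire_out"
    log_level: str = "INFO"
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_radius", "probe_radius", "proton_cutoff", "match_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.energy_threshold >= 0:
            raise ValueError("energy_threshold is a binding energy (negative kcal/mol)")

    # -- serialization -------------------------------------------------

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            elif isinstance(v, (int, float)):
                lines.append(f"{f.name} = {v!r}")
            elif isinstance(v, (list, tuple)):
                lines.append(f"{f.name} = [{', '.join(repr(x) for x in v)}]")
        Path(path).write_text("\n".join(lines) + "\n")


def _resolve_seed_point(structure: Structure, coords, selection: str):
    if coords is not None:
        return np.asarray(coords, dtype=float)
    if selection:
        wanted = set(parse_selection(selection))
        pts = [
            a.position
            for a in structure.atoms
            if (a.chain_id, a.residue_number) in wanted
        ]
        if not pts:
            raise ValueError(f"selection {selection!r} matches no atoms")
        return np.mean(pts, axis=0)
    raise ValueError("seed needs coordinates or a residue selection")


def run_pipeline(config: RunConfig, structure: Structure | None = None) -> dict:
    """Run the full analysis; returns the JSON-serializable summary dict.

    ``structure`` may be passed directly (e.g. a generated fixture);
    otherwise ``config.input`` is read.  Artifacts land in
    ``config.output_dir``; any stage failure raises with the stage named.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        if structure is None:
            structure = read_structure(config.input)
            assign_radii(structure)
        summary: dict = {
            "schema_version": SUMMARY_SCHEMA_VERSION,
            "n_atoms": len(structure.atoms),
            "thresholds": {
                "min_radius_A": config.min_radius,
                "probe_radius_A": config.probe_radius,
                "energy_threshold_kcal_mol": config.energy_threshold,
                "proton_cutoff_A": config.proton_cutoff,
                "match_tolerance_A": config.match_tolerance,
            },
        }

        if config.mutate:
            stage = "mutate"
            targets = parse_selection(config.mutate)
            structure = mutate_to_alanine(structure, targets)
            summary["mutated"] = [f"{c}:{n}" for c, n in targets]

        stage = "void_network"
        network = build_void_network(structure)
        summary["n_void_vertices"] = len(network.vertices)
        summary["n_void_edges"] = len(network.edges)
        network.write_edge_list(out / "void_network.tsv")

        stage = "channel"
        start = _resolve_seed_point(structure, config.start, config.start_selection)
        end = _resolve_seed_point(structure, config.end, config.end_selection)
        try:
            channel = trace_channel(network, start, end, cost=config.cost)
        except NoChannelError as exc:
            summary["channel"] = {
                "found": False,
                "closest_approach_A": exc.closest_approach,
            }
            channel = None
        if channel is not None:
            profile = profile_channel(channel, config.n_profile_samples)
            channel.write_pdb(out / "channel.pdb")
            profile.write_tsv(out / "channel_profile.tsv")
            summary["channel"] = {
                "found": True,
                "length_A": round(channel.length, 3),
                "bottleneck_A": round(channel.bottleneck, 3),
                "radius_min_A": round(float(profile.radii.min()), 3),
                "radius_max_A": round(float(profile.radii.max()), 3),
            }

        stage = "hydration"
        model = ChargeModel(mode=config.charge_mode)
        selection = (
            parse_selection(config.charge_selection) if config.charge_selection else None
        )
        target = channel if channel is not None else network
        hydration = place_waters(
            target,
            structure,
            model,
            threshold=config.energy_threshold,
            selection=selection,
        )
        hydration.write_pdb(out / "predicted_waters.pdb")
        experimental = extract_experimental_waters(structure, channel, margin=5.0)
        match = match_waters(
            hydration.waters, experimental, tolerance=config.match_tolerance
        )
        summary["hydration"] = {
            "charge_mode": config.charge_mode,
            "n_candidates": hydration.candidate_count,
            "n_predicted": hydration.accepted_count,
            "n_experimental": len(experimental),
            "n_matched": match.n_matched,
            "rmsd_matched_A": None if not match.pairs else round(match.rmsd, 3),
        }

        stage = "proton_wire"
        pooled = pool_waters(
            hydration.waters, experimental, config.match_tolerance, config.pool
        )
        protonatable = (
            classify_protonatable(structure)
            if any(a.residue_name in
                   ("GLU", "ASP", "HIS", "LYS", "SER", "THR", "TYR")
                   for a in structure.atoms)
            else set()
        )
        graph = build_proton_graph(
            pooled, structure, protonatable or None, cutoff=config.proton_cutoff
        )
        graph.write_tsv(out / "proton_graph.tsv")
        comps = patches(graph)
        gaps = isolating_gaps(graph)
        with open(out / "gap_list.tsv", "w") as fh:
            fh.write("patch_a\tpatch_b\tgap_A\tnode_a\tnode_b\n")
            for g in gaps:
                fh.write(
                    f"{g.patch_a}\t{g.patch_b}\t{g.gap_length:.2f}"
                    f"\t{g.nearest_pair[0]}\t{g.nearest_pair[1]}\n"
                )
        summary["proton_wire"] = {
            "n_nodes": len(graph.nodes),
            "n_edges": len(graph.edges),
            "n_patches": len(comps),
            "n_gaps": len(gaps),
            "gap_lengths_A": [round(g.gap_length, 2) for g in gaps],
        }

        if config.axis:
            stage = "connectivity_table"
            axis_pairs = parse_selection(config.axis)
            rid_map = {
                (a.chain_id, a.residue_number): a.residue_id for a in structure.atoms
            }
            axis_residues = [rid_map[p] for p in axis_pairs if p in rid_map]
            surface = find_surface_vertices(network, structure, probe=config.probe_radius)
            records = connectivity_table(
                structure,
                axis_residues,
                graph,
                network,
                pooled,
                membrane_normal=config.membrane_normal,
                surface_vertices=surface,
            )
            frame = connectivity_table_frame(records)
            frame.to_csv(out / "connectivity_table.tsv", sep="\t", index=False)
            summary["connectivity"] = {
                "n_residues": len(axis_residues),
                "classes": sorted(
                    {r.channel_class for r in records}
                ),
            }

        stage = "write_summary"
        config.to_toml(out / "run_config.toml")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        return summary
    except Exception as exc:
        logger.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def compare_waters_report(
    predicted,
    experimental,
    tolerance: float = 1.0,
    structure: Structure | None = None,
) -> dict:
    """Matched/unmatched counts, RMSD, and (optionally) binding energies
    evaluated at the experimental sites — the threshold-validation view."""
    report = match_waters(list(predicted), list(experimental), tolerance=tolerance)
    out = {
        "n_predicted": len(predicted),
        "n_experimental": len(experimental),
        "n_matched": report.n_matched,
        "match_fraction_experimental": (
            report.n_matched / len(experimental) if experimental else None
        ),
        "rmsd_matched_A": None if not report.pairs else round(report.rmsd, 3),
        "unmatched_predicted": report.unmatched_predicted,
        "unmatched_experimental": report.unmatched_experimental,
    }
    if structure is not None:
        energies = []
        for w in experimental:
            e, _ = water_energy(w.oxygen_position, structure)
            energies.append(round(e, 2))
        out["experimental_site_energies_kcal_mol"] = energies
    return out


def make_fixture(kind: str, seed: int = 0, out_prefix: str | Path | None = None, **kw):
    """Generate a named fixture, optionally writing PDB + ground-truth TSV."""
    if kind == "tube":
        profile = kw.pop("profile", None)
        if isinstance(profile, str):
            if profile.startswith("const:"):
                profile = fixture_mod.constant_profile(float(profile.split(":")[1]))
            elif profile.startswith("sin:"):
                rmin, rmax = map(float, profile.split(":")[1].split(","))
                profile = fixture_mod.sinusoidal_profile(
                    rmin, rmax, kw.get("length", 30.0)
                )
            else:
                raise ValueError(f"unknown profile spec {profile!r}")
        st, truth = fixture_mod.make_tube(seed=seed, lumen_profile=profile, **kw)
    elif kind == "cavity":
        st, truth = fixture_mod.make_polar_cavity(kw.pop("n_water_sites", 1), seed=seed)
    elif kind == "blocked_tube":
        st, truth = fixture_mod.make_blocked_tube(seed=seed, **kw)
    elif kind == "toy_axis":
        st, truth = fixture_mod.make_toy_axis(seed=seed)
    elif kind == "water_chain":
        sites = fixture_mod.make_water_chain(
            kw.pop("n", 5), kw.pop("spacing", 2.8), seed=seed
        )
        return sites, None
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        write_pdb(st, out_prefix.with_suffix(".pdb"))
        if hasattr(truth, "write_tsv"):
            truth.write_tsv(out_prefix.with_suffix(".truth.tsv"))
    return st, truth
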