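# Methods

## Rigid-sphere model and clearance

Heavy atoms are rigid spheres with van der Waals radii from the Bondi set
(C 1.70, N 1.55, O 1.52, S 1.80 Å, ...); unknown elements fall back to
1.70 Å with a warning, and the table is user-overridable.  Hydrogens in the
input are retained but ignored for all clearance computations — cryo-EM
models usually lack them, and the hydration stage builds its own polar
hydrogens.  The *clearance* at a point is min over atoms of
(center distance − radius): the radius of the largest sphere centered there
touching no atom, negative inside an atom.  Queries run over a k-d tree
with an exact fix-up pass, so they equal the brute-force scan to 1e-9 Å
(tested against it).

## Void network

The network is the Voronoi dual of the atom centers, built from
`scipy.spatial.Delaunay`:

- one vertex per tetrahedron at its circumcenter.  With mixed radii the
  circumcenter is not equidistant from the four atom *surfaces*, so each
  vertex is Newton-refined to the additively weighted (Apollonius) point,
  tolerance 1e-4 Å.  We deliberately use the ordinary Voronoi diagram with
  surface-distance re-evaluation rather than an exact Apollonius diagram —
  the practical convention of tunnel-analysis tools — because radii differ
  by at most ~0.3 Å among protein heavy atoms;
- one edge per face-adjacent tetrahedron pair, annotated with a bottleneck
  sampled at ≤0.25 Å steps along the straight segment;
- sliver tetrahedra (nearly coplanar atom quadruples) throw their
  circumcenters far outside the tet; such vertices are geometric noise but
  removing them would sever real corridors, so each cluster of dropped
  slivers is *contracted*: its surviving neighbor tets are connected
  directly, with bottlenecks sampled on the new segments.  Large boundary
  clusters are connected 3-nearest-neighbor-sparsely instead of pairwise;
- vertices inside atoms are kept but flagged `interior`; pruning at any
  radius threshold removes them along with all edges below the threshold
  (monotone by construction: prune(t₂) ⊆ prune(t₁) for t₁ < t₂);
- degenerate (cospherical/coplanar) inputs raise, unless deterministic
  1e-6 Å jitter seeded from atom serials is enabled.

## Channels

Seeds (coordinates or residue selections) snap to the nearest non-interior
vertex within 8 Å.  The default cost is the maximum-bottleneck (widest)
path via a max-min Dijkstra, verified against exhaustive path enumeration
on small graphs; among all widest paths the geometrically shortest is taken
so ties between parallel corridors do not inflate the centerline.  The
Caver-style alternative minimizes Σ length/max(bottleneck, 0.05 Å)².  Two
practical guards shape the search space:

- **Bulk-solvent exclusion.**  Edges joining two vertices strictly outside
  the heavy-atom convex hull are removed from the path graph, so a channel
  may reach the surface but cannot take a shortcut around the outside of
  the protein (open tubes made this failure mode obvious: the widest path
  from mouth to mouth otherwise runs through open space).
- **Centerline recentering.**  Straight segments between Voronoi vertices
  cut corners; each densified point is nudged perpendicular to the local
  tangent toward the clearance maximum (12 iterations × 0.2 Å, move only
  when clearance improves).  On a 2.0 Å tube this restores the designed
  bottleneck to within 0.1 Å.

Profiles re-evaluate clearance at n uniformly spaced arclength positions.
Surface-reachable vertices are found by flooding from hull-boundary
vertices (within 1.0 Å of a hull facet) along edges with bottleneck ≥ the
probe radius; distinct exits are 3 Å spatial clusters of reachable boundary
vertices.  Side branches are widest off-trunk paths from trunk vertices to
exits at least 4 Å from the trunk centerline, deduplicated per exit cluster
and merged when >80 % of the shorter branch runs within 2 Å of a kept one.
If seeds land in different components, the error carries the components'
closest-approach distance.

## Water placement

The binding score is this package's own documented energy function (the
placement programs used in the field embed unpublished scorers; the
acceptance surface here is threshold behavior and counts, not any exact
functional form):

    E = Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] + 332.0636 q_i q_j / (4 r²)   kcal/mol

- rigid TIP3P water (O–H 0.9572 Å, ∠HOH 104.52°, q_O −0.834 e), scored
  over 60 orientations (12 icosahedral dipole directions × 5 spins) against
  all protein atoms and already-placed waters within 8 Å of the oxygen;
- ε(r) = 4r distance-dependent dielectric, the common implicit-screening
  choice for buried electrostatics;
- per-element 12-6 parameters with Lorentz–Berthelot combination.  Well
  depths are ≈5× shallower than standard additive force-field values: the
  score has no desolvation/reference term, and at full depth the summed
  dispersion of any snug cavity alone exceeds |−5| kcal/mol, which would
  destroy the threshold's polar/apolar discrimination.  With the shallow
  set, an apolar cavity scores ≈ −3 to −4 (rejected) while a single
  H-bond-like contact contributes ≈ −3 to −6 (accepted when lined);
- protein polar hydrogens are built geometrically (amide H in-plane, Lys NZ
  tetrahedral ×3 charged / ×2 neutral, hydroxyl H toward the nearest
  acceptor within 4 Å else anti to the C–O bond, His NE2-H tautomer when
  neutral), with template charges chosen so each side chain's net charge is
  exactly its protonation state (+1 Lys⁺, −1 Glu⁻/Asp⁻, 0 neutral).

Placement is greedy and deterministic: candidates are centerline points
(plus a small perpendicular disc of offsets at 0.6/1.2 Å — channel points
are focusing sites, waters physically sit near the lining) or network
vertices, filtered to clearance ≥ 1.1 Å (deliberately below the 1.4 Å
probe: narrow sites can still hydrate) and to ≥ 0.8·(r_O + r_atom) from
heavy atoms.  The lowest-energy candidate ≤ threshold is accepted if ≥
2.5 Å from accepted oxygens; neighbors within the cutoff are re-scored with
the new water present; ties break on candidate index.  Experimental waters
are *not* frozen into the context by default — prediction is independent,
then compared (greedy one-to-one nearest-pair matching under a 1 Å
tolerance, checked against the optimal assignment on small sets).

## Proton wires and classification

Nodes: water oxygens plus the polar side-chain atoms of protonatable
residues (Glu OE1/OE2, Asp OD1/OD2, His ND1+NE2 regardless of tautomer,
Lys NZ, Ser OG, Thr OG1, Tyr OH).  Edges: all pairs within 3.5 Å
(inclusive), the standard donor–acceptor distance for a facile Grotthuss
hop; the neighbor search is verified against the O(n²) scan.  Patches are
connected components; a gap between two node sets is the *minimum
heavy-atom donor–acceptor distance* between them — not centerline
arclength, since a single length must survive re-measurement after waters
are added.  `isolating_gaps` orders patches along the first principal axis
of the node cloud and reports consecutive inter-patch gaps.

Channel classes, per residue and direction (left/right = neighbors in the
user-supplied axis order; top/bottom = surface exits within a 60° cone of
the user-supplied ±membrane normal):

- **water channel** — a proton-graph path connects the endpoints
  (mediating residues and water counts recorded);
- **narrow channel** — a geometric channel of bottleneck ≥ 0.9 Å exists
  (below the water probe: such bottlenecks can still pass protons) with ≥1
  water within 3 Å of the centerline but no full path;
- **dry channel** — the geometric channel holds no water;
- **gap (G L)** — no geometric channel; L is the donor–acceptor distance;
- **none** — no meaningful endpoint.

For classification, channel seeds snap to the nearest vertex with clearance
≥ 0.9 Å so the tight terminal approach to a side chain does not mask an
open channel.  Alanine truncation deletes side-chain atoms beyond CB and
renames the residue; glycine and residues without CB are rejected.  Atom
deletion can only increase clearances (tested as an invariant), so
truncation can only open channels.

## Synthetic structures and what they do (not) show

The fixtures are pseudo-atom geometries, bit-reproducible from (spec,
seed): wall atoms are carbon-like spheres on rings (spacing 1.4 Å) or
Fibonacci shells; "polar" linings convert every 2nd wall atom into an
inward-facing carbonyl-like dipole (O −0.75 e with a buried C +0.75 e
partner 1.23 Å behind), strong enough that lined channels hydrate below
the −5 kcal/mol threshold while apolar geometry stays above it.  The
blocked tube plants two full isoleucines whose side chains choke a 2.0 Å
lumen below 0.4 Å; truncation restores ≈1.9 Å and rehydration shrinks the
across-block donor–acceptor gap from ≈7.5 to ≈3.7 Å (measured by the
acceptance script, not asserted as constants).  The toy axis is a sealed
capped tube with eight lysine analogs, two full plugs, one 1.0 Å orifice
and one dry segment, exercising every connectivity class and ≥3 isolating
gaps.

Passing on these fixtures shows the geometric and graph machinery is
correct against independent oracles (brute-force scans, voxel flood fill,
exhaustive path enumeration, literal pair-sum energies).  It does *not*
show that the surrogate energy function reproduces any particular program's
hydration counts on a real structure — fixtures have no conformational
strain, no partial occupancy, no resolution limits, and their lining
charges are idealized.  Real-structure numbers (channel length >200 Å,
region water counts, the 12.0 → 4.6 Å truncation gap) are therefore
tracked by `scripts/benchmark_7o71.py` as benchmark quantities with a ±20 %
tolerance, not unit tests.

## Numerical choices and limitations

- Edge bottleneck sampling and centerline densification both use 0.25 Å
  steps; profiles interpolate linearly between densified samples.
- Problem sizes: fixtures run 200–1600 atoms, networks of 1–8 k vertices;
  the full suite plus acceptance script completes in a couple of minutes on
  one CPU.  On a full membrane complex (~10⁵ atoms) network construction is
  the dominant cost and scales with the tetrahedron count.
- Determinism: fixed iteration orders everywhere; greedy ties break on
  index; jitter and water-chain orientations derive from explicit seeds.
- Not modeled: structural dynamics (a single snapshot is analyzed), pKa
  prediction (charge states are assigned manually per the charged/neutral
  models), proton-transfer rates or energetics (classification is
  geometric/connective only), membrane detection (the normal is an input),
  and MD re-scoring of water energies.
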