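# Methods

This note documents the model behind `pocketpharm`, its assumptions,
the parameters that matter, and the design decisions taken where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Receptor numbering and alignment handling

Transmembrane residues are addressed by Ballesteros–Weinstein labels
`helix.position`, anchored at the most conserved residue of each helix
(position 50) and counting down toward the N-terminus, up toward the
C-terminus. The seven default label spans are TM I 1.33–1.56,
TM II 2.40–2.65, TM III 3.25–3.51, TM IV 4.43–4.64, TM V 5.38–5.63,
TM VI 6.37–6.59, TM VII 7.34–7.56.

Anchor columns are **configuration, never inference**: a `TMLayout`
(YAML) supplies per-helix alignment-column spans and the x.50 column.
`propose_anchors` can suggest the most conserved column per span, but a
proposal never silently overrides the configured anchor. Numbering
counts ungapped target residues only; an anchor falling on a gap in the
target is an error naming the helix.

Each helix carries an integer start-shift, applied toward the
N-terminus, so a positive shift increases the label of a fixed residue.
TM V defaults to shift 3: with the helix start moved three residues
N-terminal (so that hydrophobic side chains face the membrane), the
residue that unshifted numbering would call 5.42 becomes 5.45. This is
how the T5.45 hot-spot of the bitter-receptor model corresponds to the
5.42 activation position of the beta-1 adrenergic receptor.

Sequence alphabet: the 20 standard amino acids plus X; X occupies
columns but is excluded from conservation counts, as are gaps.

## Conservation-based binding-residue scoring

The premise: residues binding subfamily-specific ligands are conserved
within the subfamily but variable across the family; residues conserved
family-wide serve structure or activation and should score low.

Per column, conservation is the normalized Shannon-entropy complement
`c = 1 − H/log 20` over non-gap symbols (0 for an all-gap column, with
a warning; columns with < 50 % coverage are flagged). The binding score
combines the subfamily and family levels:

    binding = c_sub · (1 − c_fam^γ),   γ = 2 (configurable)

This is a deliberate surrogate for the tree-weighted residue-scoring
method the original pipeline cites without formulas; only its
qualitative contract is guaranteed (monotone in subfamily conservation,
vanishing for subfamily-variable or fully family-conserved columns),
not any external method's numeric output. No amino-acid similarity
matrix is used in v1; a substitution-matrix-weighted variant is left as
a configuration hook. Note one subtlety of frequency-based scores:
duplicating a *minority* sequence legitimately lowers a column's
conservation; only modal-row duplication is monotone.

## TM-only homology model and rotamer ensemble

Threading keeps the template backbone bit-exact and replaces residue
identities by the target amino acid at each BW label; loops are never
modelled. Unmatched labels are reported; a helix missing more than a
tolerance (default 5) of its template positions is an error.

Side-chain flexibility is a small backbone-independent rotamer library:
coarse per-residue-type side-chain templates (linear chains with
terminal branches, planar six-rings for aromatics) expressed in a local
frame whose x-axis points outward from the helix axis, with up to four
azimuthal states per residue and fixed occurrence weights, renormalized
to 1 at attachment. Glycine keeps a single empty state so every residue
has ≥ 1 rotamer. The library is a synthetic stand-in at the geometric
fidelity the pipeline needs (feature placement and pocket occupancy),
not a crystallographic rotamer survey.

## Pocket detection

Delaunay tetrahedralization over the model's heavy atoms (backbone plus
the highest-weight rotamer per residue; the all-rotamer union is a
configuration option). Then:

1. discard tetrahedra with any of their six edges > `edge_cutoff`
   (default **8.0 Å**, the tightened value that keeps the cavity from
   leaking through inter-helix gaps);
2. keep a tetrahedron as *interstitial* when its circumcenter clears
   every atom's van der Waals sphere by `probe_radius` (default 1.4 Å)
   **and** its four vertices span ≥ 3 distinct helices — the second
   condition excludes the thin two-helix slabs between adjacent
   helices, which otherwise connect the cavity to the membrane side;
3. the pocket is the connected interstitial component (shared facets)
   lined by the most distinct helices, largest volume as tie-break —
   the TM binding cavity threads between all helices, whereas the open
   voids between staggered helix ends touch only three or four.

Pocket sample points are the retained tetrahedron centroids (always
inside the convex hull). Lining residues are those with any rotamer or
backbone atom within `contact_distance` (default 4.5 Å) of a sample
point. Pruning is provably monotone in the cutoff and rigid-motion
equivariant (tested to 1e-6 Å); both properties are exercised against
brute-force edge checking.

A consequence worth stating: the 8 Å edge filter bounds the *width* of
any detectable cavity at roughly one edge length, so pocket volume is
monotone in bundle radius only over a narrow supported range (about
8.8–9.2 Å for the seven-helix fixture) and collapses for much wider
bundles. That is inherent to the pruning approach — the same lever the
original method used (8.5 → 8.0 Å) to *shrink* an oversized pocket.

## Interaction points and fuzzy feature clustering

Residue typing: donors {S,T,Y,N,Q,K,R,W,H}, acceptors
{S,T,Y,N,Q,D,E,H}, hydrophobic {A,V,L,I,F,M,P,W,Y,C}; aromatic
π-stacking is subsumed under hydrophobic (the model has no separate
aromatic type).

Features live in *ligand space* — where the interacting ligand atom
would sit, not on the protein:

- donor/acceptor points: `hbond_length` (default 2.9 Å) beyond the
  polar tip atom along the CA→tip axis;
- hydrophobic points: `hydrophobic_contact` (default 3.0 Å) beyond the
  side-chain carbon centroid along the CA→centroid axis, placing the
  point one van der Waals contact past the outermost side-chain
  carbons. (Placing hydrophobic points *at* the centroid puts them
  inside the cavity wall, where they are never inside the pocket
  volume.)

Points outside the pocket volume are discarded. Each point's weight is
rotamer likelihood × residue binding score. The pipeline seeds
placement from the top-`n_binding_residues` (default 20) lining
residues ranked by binding score, following the principle that feature
density tracks ligand-binding likelihood; using every lining residue
floods the density with low-score background.

Clustering is weighted mean-shift per type with a Gaussian kernel of
scale **Rc = 2.5 Å**, *truncated at Rc*, modes merged below Rc/2.
The truncation makes Rc a true locality bound: hot-spots farther apart
than Rc can never pull each other's modes together regardless of weight
imbalance — the contract "clusters farther apart than Rc never merge"
holds by construction, where a plain Gaussian provably violates it.
Cluster center = weighted mean of members; radius = weighted RMS member
distance, floored at `min_radius` 0.8 Å; score = summed weight.

The top three clusters per type form the pharmacophore, indexed
acceptor 0–2, donor 3–5, hydrophobic 6–8 in descending score (ties:
smaller radius, then lexicographic center). Contributions are each
residue's share of cluster weight, sorted descending; they sum to 1 per
feature by construction. Fewer than three clusters of a type is an
error naming the type.

## Compound preparation and subset matching

SMILES tables (id/smiles/activity) and SDF are read through RDKit;
unspecified tetrahedral centers are enumerated into R/S entries sharing
a parent id (assay racemates are mixtures, so a parent is a hit when
any stereoisomer's conformer matches). Conformers come from ETKDGv3
distance-geometry embedding (seeded, RMS-pruned at 0.25 Å) with MMFF
minimization capped at 200 iterations and at most 200 conformers —
the package's mapping of a stochastic conformational search with a
conformation limit of 200 onto RDKit; search-control knobs with no
RDKit equivalent (rejection limit 100, iteration limit 1000, RMS
gradient 0.005) are accepted and recorded but have no effect.

Ligand typing: donors and acceptors from RDKit's standard chemical
feature definitions (hydrogen-bearing N/O; N/O acceptors), organic
fluorine optionally as a weak acceptor (`fluorine_acceptor`, default
on — motivated by the most potent known blocker being 4'-fluorinated);
hydrophobic points at carbon-dominated ring centroids, fused
ring-system centroids, and aliphatic carbon clusters of ≥ 2 atoms.

Matching a conformer to a k-feature subset (k ∈ {5, 6}) searches all
injective type-compatible assignments of typed points to features
(exhaustive when ≤ 5000 assignments — always, in tests; seeded
stochastic search with swap refinement beyond). Each assignment is
scored by rigid superposition: radius-weighted Kabsch (weights 1/r²)
minimizing Σ(dᵢ/rᵢ)², refined by Nelder–Mead minimization of
max(dᵢ/rᵢ) when the least-squares pose is marginally infeasible.
**Matched** means max(dᵢ/rᵢ) ≤ 1: every point inside its feature
sphere. Minimizing the *maximum* normalized deviation is what makes
matching monotone under subset restriction — a conformer matching a
6-subset matches every contained 5-subset, since the 6-subset's
feasible pose is feasible for any 5 of its constraints. Radius is read
as a matching tolerance (the alternative reading — density spread — is
noted but not used).

## Validation metrics

Per subset: active & hit → TP, active & miss → FN, inactive & hit → FP,
inactive & miss → TN; blockers and unknowns are excluded. Compounds
failing conformer generation are dropped and reported, not counted.
recall = TP/(TP+FN), precision = TP/(TP+FP), and MCC per the standard
formula with the zero-denominator convention MCC = 0. Ranking filters
to recall strictly > 0.5, sorts by MCC, ties broken by precision, then
recall, then lexicographic subset. Combined-set evaluation unions hit
tables (per-compound any-hit), rejecting conflicting labels.

## Synthetic fixtures: what they emulate, what they do not

Every generator is a pure function of (parameters, seed).

- **Toy alignments** plant subfamily-conserved columns on a random
  background, with family-wide conserved anchor columns emulating
  structural x.50 positions. They model conservation *contrast* only —
  no phylogeny, no indel structure, no similarity between related
  residues.
- **Helical bundles** are ideal parallel helices (rise 1.5 Å/residue,
  100°/residue, CA ring radius 2.3 Å) on a circle of default radius
  9.0 Å, with designated pocket residues phased toward the axis and
  their side-chain frames aimed at the bundle center (the
  inward-rotamer choice); helices without designated residues face
  x.50 to the membrane. Per-helix depth references tier the polar key
  residues along the pocket axis (N5.40 deep; T5.45, N3.36, H4.56,
  Q7.35 mid; N7.39 shallow) so donor/acceptor hot-spots are separated
  at the 2.5 Å kernel scale. The bitter-receptor-like bundle carries
  the published pocket lining (T5.45, N3.36, N5.40, N7.39, Q7.35,
  H4.56, F6.55, F3.32, I3.33, F3.37, L3.40, V5.44, L5.41, I6.48,
  A6.51, V6.52, I6.56, Y7.45). No helix tilts, kinks, loops or
  membrane.
- **Planted libraries** are rigid typed-point bodies: hits carry points
  exactly on the planted subset's feature centers under random rigid
  motions; decoys either lack a required polar type or have every point
  displaced by 2–4 × the largest feature radius (each decoy verified at
  generation to fail the planted subset); one blocker-like entry
  carries acceptor and hydrophobic points only, on features
  {0, 1, 2, 7, 8}. Geometric mode bypasses conformer search so
  screening tests isolate the matcher; a second chemical mode supplies
  real flavonoid SMILES (kaempferol, luteolin, naringenin, epicatechin,
  the three 6-methoxyflavanone blockers, flavone, xanthone) for
  integration tests.

Passing the planted-recovery test therefore shows that the pipeline's
*machinery* — numbering, scoring, geometry, clustering, matching,
ranking — is internally consistent and recovers designed ground truth.
It does not show that the generated features coincide with the
published model's coordinates, which depended on the original rotamer
library, scoring method and receptor model.

## Numerical choices and degenerate inputs

- Coordinates in Å throughout; model files written at 3-decimal
  precision.
- Circumcenters solve a 3×3 linear system; degenerate (near-coplanar)
  tetrahedra fall back to the vertex centroid. Coplanar point sets
  raise a geometry error.
- Mean-shift: 200 iterations, 1e-6 convergence; deterministic point
  order (BW label, rotamer index) makes clustering reproducible.
- Matcher refinement triggers only for poses with max-deviation in
  (1, 2.5); Nelder–Mead, 400 iterations.
- MCC uses exact integer arithmetic in the numerator and one square
  root; any zero factor short-circuits to 0.
- Tie-breaks are total orders everywhere (documented per operation) so
  equal seeds give byte-identical outputs.

## Problem sizes used by the test suite and acceptance script

Planted scenario: 30-sequence family, 8-sequence subfamily, 171-residue
7-helix bundle, 40 hits + 40 decoys + 1 blocker, all 126 + 84 subsets —
chosen to exercise every code path at interactive runtimes. MCC oracle:
10⁴ random confusion matrices; pruning oracle: 20 clouds × 50 points;
matcher oracle: 50 constructed instances plus exhaustive-enumeration
equivalence on mixed ones.

## Known limitations

- The conservation score is a surrogate; it does not reproduce the
  cited tree-weighted method's numbers.
- The rotamer library is coarse and backbone-independent; side-chain
  packing and chi-angle statistics are not modelled.
- Pocket detection bounds detectable cavity width at the edge cutoff;
  very open or very wide sites need a different cutoff.
- The matcher's stochastic fallback (beyond 5000 assignments) is not
  exhaustive; exact mode is forced in all tests.
- Hydrophobic typing (ring/cluster centroids) ignores partial charges
  and halogen-bond geometry; fluorine-as-acceptor is a binary flag.
- Feature weights are not used in screening (subset membership only),
  matching the combinatorial validation design.
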