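# Methods

## Scope and overall procedure

`pubshape3d` builds bounded conformer models for small molecules and
computes 3-D shape/feature similarity between conformers. The pipeline is:

1. **Eligibility** — six rules gate model construction (size ≤ 50 heavy
   atoms, ≤ 15 rotatable bonds, an 11-element whitelist, single covalent
   unit, MMFF94s-typeable atoms, < 6 undefined stereo centers). Thresholds
   live in `EligibilityConfig` so the filter can be relaxed.
2. **Sampling** — a raw conformer ensemble (produced by any external
   generator satisfying the `GeneratorConfig` contract: energy window
   25 kcal/mol, ≤ 100,000 conformers per stereoisomer) is reduced at the
   predicted RMSD `0.219 + 0.0099·nha + 0.040·er`, rounded to the nearest
   0.2 Å (exact midpoints round up — coarser sampling, deterministic) and
   floored at 0.4 Å. If more than 500 conformers survive, the RMSD is
   incremented by 0.2 Å and re-clustered until the cap holds.
3. **Description** — retained conformers are canonicalized to principal
   steric axes and annotated with analytic volume, self-overlap volume,
   steric multipoles, pharmacophore features, a diverse ordering, shape
   fingerprints, and a packed 64-bit identifier.
4. **Search** — shape-optimized ST/CT/ComboT scores, a strict-inequality
   neighbor predicate, score matrices, single-linkage clustering, and
   shard-parallel search with optional fingerprint prefiltering.

Conformer generation itself (torsion driving, stereo enumeration) is out of
scope by design; the sampling stage consumes any ensemble.

## Gaussian shape description

Each heavy atom contributes `rho_i(r) = p·exp(−alpha_i|r−c_i|²)` with
amplitude `p = 2.7` and `alpha_i` fixed so an isolated atom integrates to
its hard-sphere volume `4/3·pi·R_i³` (the standard Grant–Pickup
construction; the amplitude and the per-element van der Waals radii — Bondi
values, C = 1.70 Å — are configurable in `ShapeParams`). Hydrogens are
excluded everywhere; `carbon_radius_mode` treats all heavy atoms as carbon
for element-blind shape comparison. Synthetic point-cloud conformers carry
no element labels and default to carbon radii.

Two volume notions are exposed deliberately:

* **analytic (union) volume** — inclusion-exclusion expansion of
  `1 − prod(1 − rho_i)`, truncated at order 2 by default (configurable to
  6). A single atom's value is exactly its hard-sphere volume. Used for the
  conformer-volume property and the multipole monopole.
* **self-overlap volume** `V_AA = Σ_ij ∫rho_i·rho_j` — the quantity in the
  Tanimoto denominators. For a single atom this is `p/2^{3/2} ≈ 0.955` of
  the hard-sphere volume; the two notions must not be conflated, and
  `ST(A,A) = 1` holds exactly because numerator and denominator use the
  same convention.

Order-2 truncation overestimates pair subtractions when three or more atoms
mutually overlap; on densely packed clouds the union volume can even
decrease when an atom is added. This is an inherent truncation artifact
(documented, not corrected); bonded-geometry molecules at ~1.5 Å spacings
are far from this regime, and higher truncation orders are available.

Steric multipoles are moments of the order-2 density expansion about the
steric center in the canonical frame, computed from closed-form Gaussian
integrals: monopole (Å³), second moments `Qx ≥ Qy ≥ Qz` (Å⁵, `Qx` describes
length), and the ten third moments (Å⁶). Density moments (not hard-sphere
moments) are used; the ordering is enforced by axis permutation in the rare
near-degenerate cases where atom-coordinate and density orderings differ.

## Canonical frame

The principal steric axes diagonalize the unit-weight (non-mass-weighted)
second-moment tensor of the heavy atoms about their centroid; x is the
longest extent. Axis signs follow the third-moment convention (flip so the
per-axis third moment of the projections is non-negative); symmetric
distributions (third moment ≈ 0) fall back to a lexicographic comparison of
the sorted projections, and z = x × y enforces a proper rotation.
Canonicalization is idempotent to 1e-9. Spherically degenerate spectra
(e.g. a single atom) keep the eigensolver's stable basis — the frame is
then not unique across different coordinate representations of the same
shape, which is acceptable because the overlap optimizer explores rotations
anyway.

## Superposition optimization

`optimize_overlap` canonicalizes both conformers, then runs derivative-free
Nelder–Mead refinement over a rotation vector plus translation (6 dof,
≤ 300 iterations, `xatol` 1e-3) from the four proper sign-flip poses of the
canonical frames, keeping the best result and never returning a pose worse
than its start. In shape mode the objective is `V_AB` (sum of cross
product-Gaussian integrals); in feature mode it is the total same-type
color overlap. CT is always a single-point evaluation at the final pose.
The optimizer is local by construction; the four principal-axes starts are
the standard remedy and on toy shapes the result matches a 30° exhaustive
rotation-grid oracle within 0.02 ST (tested). The returned transform maps
the second conformer's input coordinates onto the first conformer's input
frame, rotation applied before translation.

## RMSD and sampling

Heavy-atom RMSD is Kabsch-minimized over rigid motions (overlay) and
optionally minimized over element-preserving automorphisms of the
heavy-atom bond graph (networkx `GraphMatcher`). The automorphism search is
capped (10,000 mappings by default) and falls back to the identity when
exceeded or when the record has no bonds (point clouds).

Sampling is two-stage exclusion-region clustering, conformers visited in
ascending energy (ties by input order) so the lowest-energy conformer is
always retained:

1. hierarchical partition pass with exclusion radii 4×, 2×, 1× the sampling
   RMSD (members only compared within their parent cluster — the hierarchy
   prunes comparisons);
2. an O(K²) pass over the stage-1 representatives that removes partition
   edge effects;
3. a coverage-repair pass that promotes any conformer left farther than the
   RMSD from all retained representatives.

The result satisfies both contracts exactly: retained pairs ≥ RMSD apart,
every input conformer within the RMSD of a retained one (verified against
an all-pairs oracle in the tests). The geometric 4×→1× level sequence and
the energy-ordered greedy representative choice are this package's
interpretations of the partition-clustering scheme, chosen for determinism.

## Pharmacophore features

The six feature types are perceived by an explicit, inspectable rule set at
an assumed pH-7 protonation model (drawn protonation state is ignored for
acids/amines): carboxylate/sulfonate/phosphonate groups → anion; quaternary
or aliphatic amines and guanidinium groups → cation; N/O atoms with an
available lone pair (excluding amide N and pyrrole-type N–H) → acceptor;
N–H/O–H → donor; maximal connected sets (≥ 2 atoms) of non-aromatic
carbons without polar neighbors plus halogens → hydrophobe; each smallest
ring → ring. No parity with any proprietary feature dictionary is claimed;
patterns are configurable in `FeatureRuleSet`.

Each feature is a fictitious color atom at the unweighted mean of its
member heavy atoms. Same-type features within 1.0 Å merge iteratively
(closest pair first, ties by lowest type then smallest member index);
cascades use merged positions, so a merge can move a center out of range of
a third feature — the documented alternative (original positions) would
merge more aggressively. Color atoms are 1.0 Å Gaussians of the same
amplitude as shape atoms (the radius is a package choice; configurable).
CT of two empty feature sets is 0, not 1 — featureless pairs are handled by
the separate shape-only neighbor threshold, so crediting empty feature
similarity would double-count.

## Diverse ordering, fingerprints, neighboring

The diverse ordering starts at the lowest-energy conformer (ties by local
id); each next pick minimizes the summed ComboT to the already-assigned
conformers, ties broken by the largest summed ComboT to the unassigned
ones, then by smallest local id. Pairwise ComboT uses shape-optimized
overlays with single-point CT, recomputed per pair (no pose caching).

Shape fingerprints record, per reference conformer with ST-optimized
similarity above the bit threshold (default 0.8, a package choice), a
64-bit packed transform: 2 bits index the largest quaternion component,
3×14 bits store the smallest three components on a uniform grid over
[−1/√2, 1/√2], and 3×6 bits store the translation on a 0.1 Å grid over
[−3.2, 3.15] Å (canonicalized conformers have near-zero optimal
translations). Round-trip error is < 5e-4 in rotation elements and ≤ 0.05 Å
per translation component. Reference sets are greedy leader clusterings
(no two references exceed the construction threshold); instead of skipping
comparisons by volume bin, a rigorous prune is used — `ST ≤
min(V_AA,V_BB)/max(V_AA,V_BB)`, so a skipped pair provably cannot exceed
the threshold and the mutual-dissimilarity invariant survives. Bin labels
(50 Å³ width) remain available for grouping and serialization. Alignment
recycling composes the two stored conformer→reference transforms of a
shared bit and evaluates ST single-point, taking the best shared reference;
replayed ST never exceeds the fully optimized value (up to tolerance) and
pairs with disjoint fingerprints are skipped outright.

Neighboring applies strict inequalities — ST > 0.795 and CT > 0.495 for
featured pairs, ST > 0.925 for featureless pairs; mixed featured/
featureless pairs are never neighbors (the conservative resolution of a
case the thresholds do not define). Three diverse conformers per compound
enter the search by default (at most ten). The corpus is split into even
contiguous shards processed independently; results are identical for any
shard count. Score matrices keep, per compound pair, the conformer pair
with the largest ComboT (up to ten conformers per compound, 10⁶ conformer-
pair budget); single-linkage clustering is connected components of the
similarity-above-threshold graph via union-find. Each unordered neighbor
pair is emitted once with the smaller GID first.

## Identifiers and serialization

GIDs pack structure id (32 bits), version (16 bits, 0 ⇔ compound conformer)
and local id (16 bits); hex rendering is zero-padded to 16 digits,
case-insensitive on input. SDF serialization uses the tag dialect listed in
`sdfio`; coordinates at the V2000 standard 4 decimals, scores at 4
decimals, transforms at 6. Unknown tags survive read→write verbatim.
XML/ASN.1 are out of scope.

## Synthetic data

The fixture module generates three input families, all deterministic under
a seed: (1) a toy SMILES panel (dopamine, aspirin, caffeine, small probes)
embedded with RDKit ETKDG and MMFF94s energies — note these energies
include coulombic terms, as the host force field offers no term-wise
removal, which only affects the energy ordering of ensembles, not any
geometric quantity; (2) anisotropic random point clouds (distinct principal
extents, so canonical frames are well defined) with controlled jitter and
random rigid perturbations, including duplicate-group ensembles whose group
bases are redrawn until mutually > 8× the jitter apart in overlay RMSD —
sampling then provably recovers one representative per group; and (3)
degenerate geometries (single atom, linear chain, symmetric ring).

Point clouds emulate shape-space structure only: no bonds, no features, no
chemistry. Tests passing on them demonstrate the geometric contracts
(coverage/separation, invariances, codec bijectivity), not the quality of
feature perception or descriptor counting on real molecules — those are
covered separately by the SMILES panel. Neither family reproduces
archive-scale statistics (coverage percentages, ~110 conformers/compound,
the random-similarity distribution of biologically tested molecules);
those require the archive corpus and its proprietary generation stack and
are not claimed.

## Problem sizes and numerical choices

Test and demonstration sizes are chosen so every oracle is exhaustive:
grid-integration checks on ≤ 10-atom toys (0.12–0.15 Å grids, 2%
tolerance), clustering oracles on ≤ 50 conformers, ordering oracles on ≤ 6,
the cap demonstration on 5,000 near-duplicates, 10⁴ random GID triples.
Tanimoto values are clamped to [0, 1] against round-off; Tanimoto
denominators are asserted positive; inclusion-exclusion terms with
integrals below 1e-14 are pruned; rotation matrices are validated
orthonormal to 1e-6 and re-orthonormalized (SVD) after reading truncated
text transforms.

## Known limitations

* Rotatable-bond and stereo perception delegate to the host toolkit; counts
  may differ from other production systems at unusual functional groups.
* MMFF94s atom-typing eligibility is approximated by whether the host
  toolkit assigns types without error.
* The hydrogen-relaxation and bump-check post-processing steps are exposed
  as a backend hook, not part of the tested core.
* Feature perception has no pKa model or tautomer awareness.
* The overlap optimizer is local; pathological shapes could in principle
  defeat the four-start heuristic.
* Degenerate (spherical-top) canonical frames are stable but not unique.
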