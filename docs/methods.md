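# Methods

This note documents the models, parameter choices and interpretations behind
`discopep`, including the points where the underlying procedure was open to
more than one reading and which reading this package pins down.

## Coordinate model

PDB text is parsed with Biopython and reduced to an immutable model: chains
of residues (author numbering + insertion code is the public convention),
residues of atoms with Å coordinates. Only ATOM records of the 20 standard
amino acids are kept (plus caller-supplied extras such as MSE); waters and
heteroatoms are dropped, and alternate locations resolve to the
highest-occupancy conformer (ties → lexicographically first altloc).
Multi-model files default to the first model. Structure repair, hydrogen
addition and assembly generation are out of scope.

## Solvent accessibility

Absolute per-residue SASA is computed by the Shrake–Rupley algorithm
implemented over this coordinate model: each atom carries a Bondi van der
Waals radius (C 1.70, N 1.55, O 1.52, S 1.80 … unknown elements 1.70 Å)
expanded by the probe radius (default 1.4 Å) and covered with a
golden-spiral lattice of test points (default 960; doubling the count
changes per-residue values by < 2 % on the test fixtures). Points buried in
any neighbouring expanded sphere are removed; surviving fractions scale the
sphere area and per-atom areas are summed per residue. The test suite
cross-checks every value against Biopython's independent Shrake–Rupley at
the same radii (≤ 5 % per residue).

Relative SASA divides by a per-type theoretical maximum (Tien et al. 2013)
and clamps to [0, 1]. A residue is *surface-accessible* when
rSASA ≥ threshold. **The threshold is the one deliberately exposed surface
parameter (default 0.25, the common surface-residue convention): the
segment census of a real protein depends directly on it**, and published
segment counts for specific antigens can only be matched by calibrating it.
A parser for classic DSSP output (ACC column) is included so an external
DSSP run can substitute for the internal SASA in parity experiments.

## Segments and their scores

Segments are maximal runs of consecutive accessible residues on one chain;
a chain break or a gap in author numbering (missing density) terminates a
run even when both flanking residues are accessible. Ids are assigned
0..n−1 in chain-then-sequence order and are deterministic. Each segment
carries its G point — the mean of member Cα positions (Cα-only by choice:
robust to side-chain disorder and consistent with backbone-level assembly)
— and five scores: mean Kyte–Doolittle hydropathy, mean rSASA, length, mean
Chou–Fasman β-turn propensity, and the fraction of residues in {W, R, Y, P}.
The hydropathy and turn scales are conventions, not canon; both are
module-level tables a caller can swap.

## Areas: clusters and patches

All region geometry is Euclidean over G points (segments) or Cα (residues).

- **Clusters**: single-linkage agglomerative clustering of segment G points
  cut at 10 Å (exposed as `cluster_threshold`). Clusters partition the
  segment set.
- **Fixed patches** gather the *segments* within 10 Å or 15 Å of the
  reference G point, boundary inclusive (≤ r, the deterministic reading of
  "inside a radius").
- **Varying patch** gathers the *residues* within r ∈ {15, 16, 17, 18, 19,
  20} Å, where r is the radius whose residue count is closest to the
  arithmetic mean of the six counts; ties resolve to the smaller radius.
  "Average number" is read as the arithmetic mean; the rule, including the
  tie-break, is pinned by tests.

## Path engines

Element *selection* uses G-point distances (region level); path *costs* use
the junction distance — from the Cα of one element's outgoing terminus to
the Cα of the next element's incoming terminus (backbone level). Reversal
(C→N reading) swaps an element's termini; single residues are
orientation-invariant.

- **Greedy NN** appends the nearest unused candidate C-terminally;
  **flanking** alternates C side then N side (C first), keeping the
  reference central. Growth stops at the first total size ≥ the requested
  peptide length. When reversal is allowed, orientations are re-optimised
  over the final chain by a two-state dynamic program, which guarantees a
  reversible variant never costs more than its natural-only counterpart.
- **Exact shortest open path**: Held–Karp dynamic programming over
  (subset, last element, last orientation) states, n ≤ 12 (the problem is
  NP-hard; 12 keeps the state space ≈ 10^5 at design-relevant sizes). The
  named classical TSP algorithm is substituted by this DP, which provably
  reaches the same optimum at these sizes. Beyond 12 elements a
  deterministic greedy chain refined by 2-opt is used and the solution is
  flagged inexact in provenance. Open paths, never closed tours — peptides
  are linear. Among equal-cost optima the lexicographically smallest id
  sequence is returned (cost ties compared at 1e-9 Å), which also makes
  solutions invariant under rigid motion.
- **Dijkstra route** (SHP): a proximity graph joins elements closer than a
  cutoff (default 10 Å); the route is the shortest path from the reference
  to the element farthest from it in graph distance, and elements off the
  route are excluded. This is an interpretation — a two-terminal
  shortest-path algorithm does not by itself define an ordering of all
  elements — and is pinned by tests. An isolated reference raises an error
  suggesting a larger cutoff.

All tie-breaks are by ascending element id; nothing is randomised.

## Linkers

Linker length is quantised from the terminus Cα gap g at a per-residue span
of 3.8 Å (the extended-chain Cα–Cα step): k = max(0, round(g/span) − 1), so
adjacent termini need no linker; rounding is half-up. ALA linkers are
alanine runs. The original structural-alphabet (SA) and superposed
structural-alphabet (SAS) linker computations are not recoverable from the
published description; they are implemented as clearly-labelled
distance-model stand-ins behind a pluggable policy: SA applies the same
span model, SAS first superposes the termini onto canonical fragment
geometry, reducing the effective gap by one span per side
(g_eff = max(0, g − 2·span)). SA/SAS linkers are emitted as glycine so they
remain distinguishable from ALA spacers in provenance, and peptides built
with them carry a note naming the stand-in. Parity with the original
implementation's SA/SAS output is therefore not guaranteed.

## The 35 methods

One continuous method (FPS: extend the reference along the native chain,
one residue C-side then one N-side, clamped at chain ends, trimmed to the
exact requested length) and 34 discontinuous ones: 6 prime (NN, uNN, FNN,
ONN, OFN, OPP), 6 ALA, 5 SA and 5 SAS linker variants, 3 SHP and 9 TSP
graph methods. Discontinuous methods never split a segment and stop at the
first size ≥ the requested length.

Interpretations pinned where the method table and prose leave latitude:

- **OFN**: its table entry says "shortest path between the segments of FNN
  peptides" while the prose describes flanking addition that keeps the
  reference central. Both are honoured: elements are selected by
  flanking-NN, then re-ordered by the minimal-cost order *with the
  reference pinned at its flanking position* (exhaustive over ≤ 8
  non-reference elements); both the raw flanking order and the final order
  are kept in the peptide's notes.
- **ONN / OPP** re-order the greedy selection by the exact shortest path;
  OPP selects from the reference's 10 Å patch, ONN from the method area
  (all segments by default).
- **TSP variants** (under-specified upstream; config-pinned here):
  1 pre-filters candidates by a composite of the five property scores
  (accessibility + WRYP + turn/1.5 − hydropathy/4.5, higher = more
  favourable interaction profile); 2 uses every segment of the area;
  3 picks the k nearest segments whose combined length best matches the
  target; 4 force-includes the reference's two nearest neighbours.
  *rev* variants optimise orientations jointly.
- **SHPaa / TSPaa** operate on the individual surface residues of the
  reference residue's varying-radius patch; TSPaa takes the residues
  nearest the reference up to the target count before solving.
- **Segment methods with a residue reference** resolve it to the containing
  segment; residue methods given a segment use the member residue nearest
  the G point.

The default design area is the whole segment set for the NN family, the
10 Å patch for OPP, and the reference's cluster for SHP/TSP (patch by
option). Segment handling is per chain; homo-multimer symmetry is not
collapsed by default.

## Paired design

Pair 1 is the globally most distant accessible Cα pair (exhaustive O(n²)
scan; an anchor residue, if given, fixes one endpoint and the partner is
the farthest point from it). Pair 2 is the most distant pair within ±5 Å
(inclusive — the total band is "about 5 Å" each side, the pinned reading)
of the plane orthogonal to the pair-1 axis through its midpoint (the only
symmetric choice of plane position). Pair 3 is the most distant pair lying
within ±5 Å of *both* pairs' perpendicular-bisector planes — the
intersection of the two 10 Å-thick bisectors. The alternative reading (a
single slab about a plane parallel to both axes) collapses pair 3 onto
pair 1 and contradicts the defining octahedron case, so the intersection
reading is pinned. Pairs 4 and 5 are alternates: an endpoint of pair 2
(resp. 3) with the farthest surface residue, excluding the source pair's
own partner so the alternate is genuinely distinct; both endpoints are
tried and the larger distance kept. Degenerate constructions (fewer than
two candidates) drop that pair; the set degrades gracefully to as few as
one pair. All ties break by ascending (chain, number, insertion code).

Steric modelling of the bound antibodies is out of scope; distance and
orthogonality are the proxies for simultaneous binding.

## Peptide banks

One record per method × segment-as-reference, so the pre-filter count is
exactly |methods| × |segments|. The default method set is prime + ALA + SA
(17 methods), the default requested length 10. The length filter keeps
7 ≤ length ≤ 24 inclusive ("shorter than 7" / "longer than 24" are
eliminated, so 7 and 24 survive); eliminated records are flagged rather
than discarded so both counts stay reportable — published bank sizes do not
say whether they are pre- or post-filter. Duplicate sequences can be
collapsed with provenance retained.

## Synthetic fixtures

The generators emit CA-only PDB text with analytically known geometry
(octahedron, cube, collinear runs, seeded clouds, multi-segment clouds, a
two-region clustering toy, and a 12-residue jittered-octahedron scaffold
for paired design). Residues are placed sparsely so every residue is
accessible by construction, decoupling geometry tests from the SASA
threshold; author-number gaps control exactly where segments break. The
scaffold uses a symmetric skeleton plus seeded ±1.5 Å jitter: the symmetry
guarantees every pair construction has candidates for any seed, the jitter
removes exact ties. What these fixtures do *not* emulate: realistic
backbone geometry, side chains, packing density, or buried cores — so
passing tests validate the combinatorial and geometric machinery, not
SASA-threshold calibration against real proteins, which requires real
structures and is sensitive to the threshold above.

## Problem sizes

The exact path solver is exercised against exhaustive enumeration up to 8
elements over 100 seeded instances; cost inequalities over 50 instances;
SASA oracle checks on 30-residue clouds; paired-design invariants on
100 seeded 20-residue clouds. These sizes keep the whole suite under a
minute while covering every branch of the solvers.

## Known limitations

- SA/SAS linkers are stand-ins (above); ALA and all linker-free methods are
  exact to their descriptions.
- The Dijkstra-route and TSP-variant semantics are documented
  interpretations pinned by tests.
- Real-protein segment censuses depend on the accessibility threshold;
  reproducing published per-antigen counts requires calibrating it against
  those structures.
- Surface distances are Euclidean, not geodesic; peptide conformation,
  cyclisation and ranking are out of scope.
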