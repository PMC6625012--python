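# discopep

Design linear peptides that mimic **continuous and discontinuous B-cell
epitopes** from a protein 3D structure.

Most epitopes are discontinuous: several short sequence fragments that are
scattered along the chain but adjacent on the folded surface. A linear
peptide can only mimic such an epitope if its fragments are concatenated in
an arrangement an antibody can still recognise. `discopep` automates that
arrangement problem: it reads a PDB structure, finds the surface-accessible
**segments** (maximal runs of consecutive accessible residues), and
assembles them into candidate peptides with **35 combinatorial design
methods** — 34 for discontinuous epitopes plus one continuous-epitope
method (FPS). It supports three workflows:

- **one specific peptide** from a chosen reference segment (immunogen
  design);
- **paired peptides** anchored at geometrically distant surface residues,
  for raising antibody pairs that capture the antigen in sandwich format;
- **peptide banks** enumerating every segment × every chosen method, length
  filtered for array synthesis (epitope mapping, inhibitor screening).

Peptides are deliberately **not ranked**: the rules of molecular mimicry are
too poorly understood for a trustworthy scoring function, so the intended
companion to a bank is a high-throughput binding experiment.

## The model in brief

- A residue is *surface-accessible* when its relative solvent accessibility
  rSASA = SASA / SASA_max(type) ≥ 0.25 (Shrake–Rupley, probe 1.4 Å,
  normalised by the Tien et al. theoretical maxima; all configurable).
- Segments get a **G point** (Cα centroid) and five scores: mean
  Kyte–Doolittle hydropathy, mean rSASA, length, mean Chou–Fasman β-turn
  propensity, and WRYP content (fraction of Trp/Arg/Tyr/Pro).
- A design *area* is either a single-linkage **cluster** of segments (10 Å
  threshold), a fixed **patch** (segments within 10 or 15 Å of the
  reference G point), or a **varying patch** of residues whose radius
  r ∈ {15…20 Å} is the one whose residue count is closest to the mean count
  over the grid.
- Assembly minimises the total **junction length** Σ‖Cα(out) − Cα(in)‖
  between consecutive elements: greedy nearest-neighbour growth (NN/uNN),
  alternating C/N flanking that keeps the reference central (FNN), exact
  shortest open Hamiltonian paths by Held–Karp dynamic programming
  (O-variants and TSP methods, exact to 12 elements, 2-opt beyond),
  and Dijkstra routes through a proximity graph (SHP methods).
- ALA / SA / SAS variants insert computed linkers at the junctions:
  k = max(0, round(gap/3.8 Å) − 1) alanines (ALA) or structural-alphabet
  stand-ins (SA; SAS first superposes the termini, shortening the gap).
- Paired design constructs up to five pairs of mutually distant surface
  residues (global maximum; orthogonal-plane band; double-bisector slab;
  two alternates) and designs one peptide per endpoint.

## Worked example

The bundled fixture generators emit valid PDB text with analytically known
geometry, so the full pipeline runs without any downloads:

```python
from discopep.fixtures import synth_structure, paired_scaffold_spec, flanking_demo_spec
open("scaffold.pdb", "w").write(synth_structure(paired_scaffold_spec(seed=0)))
open("worked.pdb", "w").write(synth_structure(flanking_demo_spec()))
```

A single peptide with the OFN method (flanking selection, then a
shortest-path reordering that keeps the reference segment central) on a
four-segment fixture:

```text
$ discopep specific --pdb worked.pdb --method OFN --ref 1 --length 17
method    OFN
reference 1
area      all
peptide   KYGDGDHNGLYADVETR  (17 aa)
parts     K[segment] + YGDGDHNGLYAD[segment] + V[segment] + ETR[segment]
```

The 17-mer gathers four segments; the 12-residue reference stays central,
flanked N-terminally by a lysine segment and C-terminally by V and ETR —
the arrangement with the smallest total through-space junction length.

Paired design on the 12-residue scaffold:

```text
$ discopep paired --pdb scaffold.pdb --method NN --length 4
 rank             rule residue_a residue_b  distance_A peptide_a peptide_b
    1          primary      A:10      A:20      32.010      AKEN      CIMD
    2 orthogonal_plane      A:50      A:60      30.734      FMDH      GNEK
    3         bisector      A:30      A:40      29.801      DMHA      ENGH
    4   alternate_of_2      A:50     A:120      25.124      FMDH      NEKA
    5   alternate_of_3      A:30      A:90      25.378      DMHA      KENG
```

Five pairs, ten peptides; pair 1 spans the largest Cα–Cα distance on the
surface (32 Å) and the later pairs probe roughly orthogonal directions so
two antibodies can bind simultaneously.

A peptide bank (every segment as reference × the six prime methods):

```text
$ discopep bank --pdb scaffold.pdb --methods prime --length 10 --out bank/
72 peptides designed (60 kept, 12 eliminated by the 7-24 aa filter); exports in bank
```

Outputs: FASTA (headers encode method|reference|parts), TSV, JSON with full
per-residue provenance, and a PyMOL script colouring each peptide's source
residues on the antigen.

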