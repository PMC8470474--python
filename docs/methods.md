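# Methods

## Model

An Ig(-like) domain is treated as two *protodomains* — the N-terminal
AB-CC′ and C-terminal DE-FG two-hairpin units — related by an internal
approximately two-fold (C2) rotation whose axis runs through the sandwich.
The strand-level symmetry correspondence is A↔D, B↔E, C↔F, C′↔G; lateral
strands break it class-by-class (split A/A′ in V/I-sets, missing C′ in
C1/cadherin, missing D in C2/FN3), and the B,C,E,F core with its BC/EF
sheet-straddling connections is the invariant anchor shared by every
class. Quaternary Ig-Ig pairing adds a second C2; in idealized homodimers
the tertiary and quaternary axes are mutually orthogonal and concurrent
(quasi-D2), and the parallel and inverted interface orientations are the
two quaternary two-folds of that D2. The CD19-style double Ig is modelled
as four protodomains p1..p4: short linkers keep p1-p2 and p3-p4 parallel,
a long inverter segment lets the two pairs interdigitate antiparallel, the
halves fuse their sheets through lateral C′|C′ and D|D ladders, and the
composite domains are (p1,p4) regular and (p2,p3) inverse (its DE-FG unit
precedes its AB-CC′ unit in sequence — a fold-level circular permutation).

## Pipeline and numerical choices

**Strand detection.** Strands are maximal "extended runs" of Cα positions
(consecutive distances within [1.8, 5.0] Å, virtual-bond angles below 60°;
one-residue bulges tolerated when the flanks stay collinear) that
participate in at least one inter-strand ladder. In `ca_only` mode a
ladder needs ≥ 2 consecutive rungs with Cα–Cα ≤ 5.5 Å and a consistent
register; single jittered rungs are healed and the register is continued
at both ends at 1.25× the cutoff, because genuine terminal rungs
fluctuate past a hard threshold. Run ends that pair in no ladder are
trimmed (loop fray is not strand). In `backbone` mode a ladder must also
carry ≥ 2 geometric hydrogen bonds (N···O ≤ 3.5 Å, angle at an inferred
amide H ≥ 120°), scanning the ±1-shifted rungs that parallel sheets use.
Sheets are connected components of the ladder graph, ordered laterally by
walking the adjacency path.

**Labelling.** The core is the highest-scoring strand quadruple b < c < e
< f (sequence order) with the sheet pattern (S1,S2,S1,S2), antiparallel
B|E and C|F ladders, and maximal total length; remaining labels follow by
sequence position and sheet membership (pre-core strands → A and/or A′;
between C and E → C′, C″ on the C-side sheet and D on the E side; after F
→ G). A lone pre-core strand on the G-side sheet is labelled A′ (the
CD4/cadherin arrangement). The A/A′ hinge is the first proline in the gap,
else the midpoint of the longest glycine run, else the geometric midpoint.
A manual override (label → residue range) wins over detection after
validation. Failure to find the core yields a typed "not Ig-like" verdict.

**Superposition.** Rigid superposition is the closed-form orthogonal-
Procrustes/Kabsch solution via SVD with reflections excluded; the
correspondence is register-free: mapped strand pairs are centre-aligned,
the longer strand trimmed symmetrically (odd excess trimmed from the C
side, keeping the window toward N), residues paired index-by-index reading
both strands N→C (no antiparallel reversal — the C2 acts on the whole
unit). A↔D is mapped only when A sits on the ABED sheet. The axis comes
from the rotation's trace (angle), invariant direction (eigenvector near
180°, skew part otherwise), screw = translation component along the axis,
and the axis point nearest the protodomain-centroid midpoint; |angle| ≥
180° − 30° (configurable) is labelled C2. An optional refinement pass
drops pairs beyond 3.5 Å and re-fits (≤ 3 rounds), emulating the trimmed
alignments interactive tools report; it is off by default. Two independent
oracles back the solver in the tests: a quaternion-parameterised numeric
minimiser and biotite's superimpose.

**Classification.** Rules fire in a fixed order: C″ → V-set; short C′
(≤ 3 residues) with split A/A′ → I-set; no C′ with A on ABED → C1-set; no
C′ with A on the A′|GFC sheet → cadherin; no D → C2-set vs FN3 by the
CCW(L) signature (≥ 3 of 4 strict hits → C2-set; I/V/M accepted as
non-strict stand-ins for the E-strand leucine). VNAR vs I-set is biology,
not geometry: an optional hydrophilicity heuristic can flag VNAR-like and
is clearly marked heuristic. Chains with ≥ 12 strands are first tested for
the double Ig: inverter = largest inter-strand gap (> 10 residues),
protodomain pairs split 4/4 within each half with linkers ≤ 5 residues and
B-vs-E directions < 90°, fused C′|C′ and D|D ladders with ≥ 2 rungs each;
composite pairing is chosen by compactness, the odd-type (AB-CC′) member
identified by its 3+1 sheet contribution (even-type contributes 2+2), and
both composite groupings can be superposed explicitly.

**Quaternary analysis.** Interface contacts are heavy-atom pairs within
4.5 Å; attribution takes the sheet group with ≥ 60% of strand-resident
contacts, testing the A′G-hinge and C″D groups (which require their
defining minor element) before GFCC′/ABED, else "mixed". The quaternary
axis comes from the label-matched cross-domain superposition; orientation
from the angle between the two G-strand N→C directions (< 60° parallel,
> 120° inverted, else tilted — the explicit tilted band reflects the
continuum of observed interfaces). The quasi-D2 report gives the three
inter-axis angles and the centre offset, computed as the worst
line-to-line miss distance between a tertiary axis and the quaternary
axis (zero when all three two-folds concur). Protodomain-swap detection
asks whether each chain closes as a single Ig (then not swapped);
otherwise chains are split at their largest inter-strand gap and closure
(centroid proximity ≤ 12 Å plus a ≥ 150° internal rotation with RMSD
≤ 3 Å over the positionally paired last three strands) is tested for
sequential and cross pairings.

**Interaction networks.** Contact types are geometric and symmetric: vdW
≤ 4.0 Å (any heavy-atom pair), H-bond donor–acceptor ≤ 3.8 Å with ≥ 90°
at the donor antecedent, ionic ≤ 6.0 Å between Asp/Glu and Lys/Arg/His
charged groups, π-stacking ≤ 5.5 Å and π-cation ≤ 6.0 Å on ring
centroids, disulfide Sγ–Sγ ≤ 2.5 Å; no hydrogens are placed, and residues
missing side-chain atoms are evaluated on what is present and flagged
partial. Core networks cover B,C,E,F with edges classed lateral (B|E,
C|F) or cross-sheet (B-F, C-E); network comparison under a residue mapping
counts an edge conserved iff both mapped endpoints share ≥ 1 type.

## The synthetic generator

The generator emulates exactly the features the pipeline measures, and
nothing else: flat two-sheet sandwiches (strands along z at 3.4 Å/residue,
4.8 Å lateral spacing, 10 Å sheet separation — textbook values), strand
presence fixed per topology preset, and the second protodomain produced by
an exact 180° rotation about the sheet normal, so noise-free domains carry
a perfect internal C2 by construction. The I-set's short C′ sits on the C2
image of G's centre-trimmed window so even the symmetry-broken class is
exact. Loops are deliberately non-extended coil: anchor points sit beyond
the strand termini outside the extended-bond window and coil points are
spaced so they can never join a run or a ladder; the forced-length
inverter zig-zags sharply and bows away from the sheets instead. Dimer
presets place the second copy by an exact quaternary two-fold (about the
strand direction for parallel, the lateral sheet direction for inverted)
with a 3.5 Å facing-sheet gap so Cα-level van der Waals contacts exist at
the interface; the swapped preset distributes two complete domains'
protodomains across two chains with extended linkers. Optional ideal
backbone atoms (N, C, O with an alternating lateral pleat, phase-shifted
on A′ whose only partner is parallel) provide a native test path for the
H-bond criteria. Gaussian coordinate noise (σ, seeded) models experimental
imprecision.

What the generator does *not* emulate: β-sheet twist and pleat dihedrals,
side chains (so cross-sheet core packing contacts are absent from
synthetic networks and contact chemistry beyond vdW/H-bond appears only in
hand-constructed residue pairs), realistic loop conformations, sequence
diversity beyond the CCW(L) decoration, and crystallographic artefacts.
Passing tests therefore demonstrate the correctness of the geometric
machinery and decision rules under controlled conditions, not performance
on distorted natural folds, where boundaries come from detection noise the
idealized fixtures do not contain. For real structures the manual override
and configurable thresholds are the intended recourse.

## Validation conditions and problem sizes

The validation suite measures: exactness (RMSD ≤ 1e-6 Å, angle 180 ±
1e-6°) on noise-free domains; superposition agreement with the quaternion
minimiser within 1e-6 on 100 random 20-point sets; topology recovery of
≥ 19/20 seeds per preset at σ = 0.3 Å across all ten presets; axis
recovery within 5° (observed ≤ ~1.6°) over 20 seeds; and exact C2 symmetry
of the idealized homodimer interface network. Domains are 60–100 residues
(strand length 6), the double Ig 144 residues — the scale at which every
geometric margin of the detector (bond window, ladder cutoff, bend angle)
is exercised with ≥ 3σ headroom at the chosen noise level.

## Known limitations

- Strand detection is tuned for sandwich ladders; it is not a general
  secondary-structure assignment (no helices, no isolated bridges).
- CTLA-4-style closed barrels (C″ joining the ABED sheet) annotate with a
  diagnostic rather than a dedicated label; MXRA8-style AB-swapped tandem
  domains report as not-Ig at single-domain level, with the swap machinery
  aimed at the CD2-style protodomain exchange.
- Biological-unit judgement (crystal contact vs functional interface) is
  out of scope: the caller supplies the intended pair.
- Printed RMSDs from interactive alignment tools depend on their pair
  trimming; the `refine` mode approximates but does not reproduce any
  specific tool's selection.
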