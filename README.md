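# igproto

Pseudosymmetry analysis of immunoglobulin folds: protodomain decomposition,
internal C2 measurement, topology classification (including the CD19-style
double Ig fold), quaternary interface geometry, and residue-interaction
networks.

## The problem

The Ig fold — a two-sheet β-sandwich of 7–10 strands labelled
A/A′/B/C/C′/C″/D/E/F/G — dominates antibodies, TCRs and a large fraction of
cell-surface receptors. Beyond its familiar quaternary symmetry (VH-VL,
CD8αα and VL-VL dimers pair with a two-fold axis), the fold itself is
pseudosymmetric: every Ig domain can be read as a covalently linked dimer
of two *protodomains*, the AB-CC′ and DE-FG two-hairpin units, related by
an internal ~180° (C2) rotation. The lateral strands (A/A′, C′, C″, D)
break this symmetry differently in each topology class — V-set, C1-set,
C2-set, I-set, FN3, cadherin — and CD19's extracellular region realises a
unique *double* Ig fold in which four protodomains from two parallel-linked
pairs interdigitate into two composite domains, one of them an *inverse* Ig
(a circular permutation achieved purely by folding).

`igproto` makes this analysis operational for structural bioinformaticians:
given coordinates (PDB/mmCIF), it

- detects β-strands and sheets geometrically (Cα-ladder or backbone
  H-bond criteria) and assigns the canonical Ig strand labels, anchored on
  the invariant B,C,E,F core whose BC and EF connections straddle the two
  sheets;
- decomposes a domain into protodomains, superposes them under the
  symmetry correspondence (A↔D, B↔E, C↔F, C′↔G) with the standard
  least-squares (Kabsch) solution, and extracts the rotation angle, axis,
  and screw component;
- classifies the topology by strand-presence rules, with the CCW(L)
  sequence signature (Cys on B and F, Trp on C, Leu on E) separating the
  structurally identical C2-set and FN3;
- detects the double Ig fold (parallel protodomain pairs, inverter segment,
  fused C′|C′ and D|D sheet ladders, inverse composite) and CD2-style
  protodomain-swapped dimers;
- analyses Ig-Ig interfaces: sheet attribution (GFCC′ / ABED / C″D /
  A′G-hinge), quaternary C2 axis, parallel vs inverted vs tilted
  orientation, and the quasi-D2 report (inter-axis angles, centre offset);
- computes typed residue-interaction networks (van der Waals, H-bond,
  ionic, π-stacking, π-cation, disulfide) at protodomain cores and
  quaternary interfaces, and compares networks under a residue mapping.

A first-class synthetic generator builds idealized β-sandwiches for every
topology class and assembly mode with exact ground truth (strand labels,
protodomain membership, symmetry axes), so the entire pipeline is testable
without any downloads.

## Worked example

```python
from igproto import (analyse_protodomains, classify_structure,
                     detect_strands, label_ig_strands, make_ig_domain)
from igproto.synthetic import SandwichSpec

structure, truth = make_ig_domain(
    SandwichSpec(topology_preset="V_set", noise_sigma=0.3, seed=3))
strands, sheets = detect_strands(structure, "A")
annotation = label_ig_strands(strands, sheets, structure.chain("A"))
report = analyse_protodomains(annotation)
print(classify_structure(structure, "A").topology.label)
print(f"protodomain RMSD {report['rmsd']:.3f} A, "
      f"axis angle {report['axis'].angle:.2f} deg")
```

prints

```
V_set
protodomain RMSD 0.758 A, axis angle 179.44 deg
```

i.e. the domain classifies as V-set and its two protodomains superpose
within 0.76 Å under a rotation of essentially 180° — a clean internal C2.
On the noise-free construction the same call prints RMSD 0.000 and exactly
180.00°. Natural Ig variants typically superpose their protodomains within
1–2.5 Å. The `examples/` directory holds one short script per capability
(classification, protodomain symmetry, double Ig, dimer interfaces,
interaction networks); each prints the numbers it computes with a line on
what they mean.

The same pipeline runs on real structures from files:

```bash
igproto classify my_structure.pdb --chain A
igproto protodomains my_structure.pdb --chain A --refine
igproto dimer my_dimer.pdb --chains A,B
igproto simulate --preset double_ig -o double.pdb --truth truth.json
```

All commands emit JSON with the tool version and full effective
configuration embedded; every threshold can be overridden with
`--config thresholds.yaml`, and manual strand annotations with
`--strands strands.yaml`.

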