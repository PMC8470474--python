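"""Measure the internal C2 pseudosymmetry of a single Ig domain.

An Ig domain is a covalently linked dimer of two protodomains -- AB-CC' and
DE-FG -- related by an internal ~180-degree rotation.  This script builds a
V-set domain (noise-free, then noisy), decomposes it, superposes the two
protodomains under the symmetry correspondence (A<->D, B<->E, C<->F,
C'<->G) and reports RMSD, rotation angle and screw component.
"""

from igproto import analyse_protodomains, detect_strands, label_ig_strands, \
    make_ig_domain
from igproto.synthetic import SandwichSpec

for sigma in (0.0, 0.3):
    structure, _ = make_ig_domain(SandwichSpec(
        topology_preset="V_set", noise_sigma=sigma, seed=3))
    strands, sheets = detect_strands(structure, "A")
    annotation = label_ig_strands(strands, sheets, structure.chain("A"))
    report = analyse_protodomains(annotation)
    p1, p2 = report["protodomains"]
    axis = report["axis"]
    print(f"noise sigma = {sigma} A")
    print(f"  p1 = {'-'.join(p1.strand_labels)},  p2 = "
          f"{'-'.join(p2.strand_labels)}")
    print(f"  RMSD {report['rmsd']:.3f} A over {report['n_pairs']} Ca pairs, "
          f"sequence identity {100 * report['identity']:.0f}%")
    print(f"  axis: angle {axis.angle:.2f} deg, screw {axis.screw:.3f} A, "
          f"order {axis.order_label}")

print("\nA noise-free idealized domain gives RMSD 0 and exactly 180 deg; "
      "natural Ig\nvariants superpose their protodomains within roughly "
      "1-2.5 A.")
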