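"""Residue-interaction networks at the protodomain core and dimer interface.

The protodomain-protodomain interface inside every Ig domain runs through
the central strands: lateral beta-sheet pairing B|E and C|F plus cross-sheet
core packing B-F and C-E.  At a quaternary interface of an exact-C2
homodimer, the typed contact network maps onto itself under the symmetry
correspondence.
"""

from igproto import compare_networks, core_network, detect_strands, \
    interface_network, label_ig_strands, make_dimer, make_ig_domain
from igproto.synthetic import SandwichSpec


def annotate(structure, chain_id):
    strands, sheets = detect_strands(structure, chain_id)
    return label_ig_strands(strands, sheets, structure.chain(chain_id))


structure, _ = make_ig_domain(SandwichSpec(topology_preset="V_set",
                                           full_backbone=True))
graph = core_network(annotate(structure, "A"))
by_class: dict = {}
for _u, _v, data in graph.edges(data=True):
    by_class[data["core_class"]] = by_class.get(data["core_class"], 0) + 1
print(f"BC/EF core network: {graph.number_of_nodes()} residues, "
      f"{graph.number_of_edges()} typed contacts")
print(f"  by class: {by_class}")

dimer, truth = make_dimer(SandwichSpec(topology_preset="parallel_dimer"))
g = interface_network(annotate(dimer, "A"), annotate(dimer, "B"))
c2_map = {node: (("B" if node[0] == "A" else "A"),
                 truth.residue_map[node[1]], node[2]) for node in g.nodes}
comparison = compare_networks(g, g, c2_map)
print(f"\nquaternary GFCC' interface network: {g.number_of_edges()} edges")
print(f"  conserved under the C2 residue mapping: "
      f"{100 * comparison.conserved_fraction:.0f}%")
print("\nAn exact-C2 homodimer interface is perfectly symmetric; real "
      "homodimers come\nclose (small experimental differences), heterodimers"
      " rewire side-chain contacts\nwhile conserving the overall geometry.")
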