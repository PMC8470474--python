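"""Classify every Ig topology class from coordinates alone.

Builds one idealized domain per topology preset (with mild coordinate
noise), runs strand detection, canonical labelling and the rule-based
classifier, and prints the verdicts.  The C2-set and FN3 share an identical
strand topology and are separated only by the CCW(L) sequence signature.
"""

from igproto import classify_structure, make_ig_domain
from igproto.synthetic import SandwichSpec

for preset in ("V_set", "C1_set", "C2_set", "I_set", "FN3", "cadherin",
               "double_Ig"):
    structure, truth = make_ig_domain(SandwichSpec(
        topology_preset=preset, noise_sigma=0.2, seed=11))
    result = classify_structure(structure, "A")
    print(f"{preset:10s} -> {result.topology.label:10s}"
          f"  ({result.topology.rule_trace[-1]})")

print("\nEach line shows the generating preset, the label recovered from "
      "coordinates,\nand the final decision rule that fired.")
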