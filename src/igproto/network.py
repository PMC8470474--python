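"""Typed residue-interaction networks at protodomain cores and interfaces.

Contacts are classified geometrically, without hydrogen placement (crystal
structures rarely carry hydrogens): van der Waals by heavy-atom proximity,
hydrogen bonds by donor/acceptor heavy-atom distance with an angle check at
the donor, salt bridges between charged side-chain groups, aromatic
pi-stacking and pi-cation by ring-centroid distances, and disulfides by
S-gamma proximity.  Thresholds follow common interactive-viewer defaults
and are all configurable.  Networks are held as networkx graphs with typed
edges, so standard graph tooling applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .config import Config, DEFAULT
from .geometry import angle_between_deg
from .model import Chain, Residue, ResidueKey
from .strands import IgAnnotation

#: node id: (chain_id, seq_id, insertion_code)
NodeId = tuple[str, int, str]

DONORS = {
    "backbone": ("N",),
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",), "GLN": ("NE2",), "SER": ("OG",), "THR": ("OG1",),
    "TYR": ("OH",), "TRP": ("NE1",), "CYS": ("SG",),
}
ACCEPTORS = {
    "backbone": ("O",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}
NEGATIVE = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
POSITIVE = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
            "HIS": ("ND1", "NE2")}
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
#: antecedent heavy atoms used for the geometric donor-angle check
ANTECEDENT = {"N": ("CA",), "NE": ("CD", "CZ"), "NH1": ("CZ",), "NH2": ("CZ",),
              "NZ": ("CE",), "ND1": ("CG", "CE1"), "NE2": ("CD2", "CE1", "CD"),
              "ND2": ("CG",), "OG": ("CB",), "OG1": ("CB",), "OH": ("CZ",),
              "NE1": ("CD1", "CE2"), "SG": ("CB",)}


@dataclass
class InteractionEdge:
    residues: tuple[tuple[str, ResidueKey, str], tuple[str, ResidueKey, str]]
    types: set[str]
    min_distance: float
    partial: bool = False            # missing side-chain atoms


def _ring_centroid(res: Residue) -> Optional[np.ndarray]:
    names = AROMATIC_RINGS.get(res.name)
    if not names:
        return None
    pos = [res.atom(n).position for n in names if res.atom(n)]
    if len(pos) < 3:
        return None
    return np.mean(pos, axis=0)


def _atoms(res: Residue, names: tuple[str, ...]) -> list:
    return [res.atom(n) for n in names if res.atom(n) is not None]


def classify_contact(chain_i: Chain, res_i: Residue,
                     chain_j: Chain, res_j: Residue,
                     config: Config = DEFAULT) -> Optional[InteractionEdge]:
    """Evaluate every interaction-type criterion between two residues.

    Returns None when no criterion fires.  Symmetric in its arguments.
    Residues with missing side-chain atoms are evaluated on the atoms
    present and flagged ``partial``.
    """
    heavy_i, heavy_j = res_i.heavy_atoms(), res_j.heavy_atoms()
    if not heavy_i or not heavy_j:
        return None
    pos_i = np.array([a.position for a in heavy_i])
    pos_j = np.array([a.position for a in heavy_j])
    dmat = np.linalg.norm(pos_i[:, None] - pos_j[None, :], axis=2)
    dmin = float(dmat.min())
    types: set[str] = set()
    if dmin <= config.vdw_max:
        types.add("vdw")
    if _hbond(res_i, res_j, config) or _hbond(res_j, res_i, config):
        types.add("hbond")
    if _ionic(res_i, res_j, config) or _ionic(res_j, res_i, config):
        types.add("ionic")
    ci, cj = _ring_centroid(res_i), _ring_centroid(res_j)
    if ci is not None and cj is not None and \
            np.linalg.norm(ci - cj) <= config.pi_stack_max:
        types.add("pi_stack")
    if _pi_cation(res_i, res_j, config) or _pi_cation(res_j, res_i, config):
        types.add("pi_cation")
    if res_i.name == "CYS" and res_j.name == "CYS":
        si, sj = res_i.atom("SG"), res_j.atom("SG")
        if si and sj and np.linalg.norm(si.position - sj.position) \
                <= config.disulfide_max:
            types.add("disulfide")
    if not types:
        return None
    partial = _is_partial(res_i) or _is_partial(res_j)
    return InteractionEdge(
        residues=((chain_i.chain_id, res_i.key, res_i.name),
                  (chain_j.chain_id, res_j.key, res_j.name)),
        types=types, min_distance=dmin, partial=partial)


def _is_partial(res: Residue) -> bool:
    if res.name in ("GLY", "ALA"):
        return False
    have = {a.name for a in res.atoms}
    return "CB" not in have


def _hbond(donor_res: Residue, acceptor_res: Residue, config: Config) -> bool:
    donors = list(DONORS.get("backbone", ())) + \
        list(DONORS.get(donor_res.name, ()))
    acceptors = list(ACCEPTORS.get("backbone", ())) + \
        list(ACCEPTORS.get(acceptor_res.name, ()))
    for dn in donors:
        da = donor_res.atom(dn)
        if da is None:
            continue
        for an in acceptors:
            aa = acceptor_res.atom(an)
            if aa is None:
                continue
            if np.linalg.norm(da.position - aa.position) > config.hbond_contact_max:
                continue
            ants = _atoms(donor_res, ANTECEDENT.get(dn, ()))
            if not ants:
                return True  # no antecedent available: distance criterion only
            for ant in ants:
                ang = angle_between_deg(ant.position - da.position,
                                        aa.position - da.position)
                if ang >= config.hbond_contact_angle_min:
                    return True
    return False


def _ionic(neg_res: Residue, pos_res: Residue, config: Config) -> bool:
    neg = _atoms(neg_res, NEGATIVE.get(neg_res.name, ()))
    pos = _atoms(pos_res, POSITIVE.get(pos_res.name, ()))
    for a in neg:
        for b in pos:
            if np.linalg.norm(a.position - b.position) <= config.ionic_max:
                return True
    return False


def _pi_cation(ring_res: Residue, cat_res: Residue, config: Config) -> bool:
    c = _ring_centroid(ring_res)
    if c is None:
        return False
    for a in _atoms(cat_res, POSITIVE.get(cat_res.name, ())):
        if np.linalg.norm(c - a.position) <= config.pi_cation_max:
            return True
    return False


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _node(chain: Chain, res: Residue) -> NodeId:
    return (chain.chain_id, res.seq_id, res.insertion_code)


def _build_network(residues_a: list[tuple[Chain, Residue, Optional[str]]],
                   residues_b: Optional[list[tuple[Chain, Residue, Optional[str]]]],
                   interface_name: str,
                   config: Config) -> nx.Graph:
    """Typed contact graph; ``residues_b=None`` means all-vs-all within A
    (sequence-adjacent pairs excluded), else A-vs-B across partners."""
    g = nx.Graph(interface_name=interface_name)
    for chain, res, strand in residues_a + (residues_b or []):
        g.add_node(_node(chain, res), name=res.name, strand=strand,
                   chain=chain.chain_id)
    if residues_b is None:
        pool = residues_a
        idx = {id(r[1]): i for i, r in enumerate(pool)}
        pairs = []
        chain_order = {}
        for chain, res, _s in pool:
            chain_order.setdefault(chain.chain_id,
                                   [r.key for r in chain.residues])
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                ci, ri, _ = pool[i]
                cj, rj, _ = pool[j]
                if ci.chain_id == cj.chain_id:
                    order = chain_order[ci.chain_id]
                    if abs(order.index(ri.key) - order.index(rj.key)) < 2:
                        continue  # sequence-adjacent pairs excluded
                pairs.append((i, j))
        iter_pairs = (((pool[i]), (pool[j])) for i, j in pairs)
    else:
        iter_pairs = ((a, b) for a in residues_a for b in residues_b)
    for (ci, ri, si), (cj, rj, sj) in iter_pairs:
        edge = classify_contact(ci, ri, cj, rj, config)
        if edge is None:
            continue
        g.add_edge(_node(ci, ri), _node(cj, rj),
                   types=sorted(edge.types), min_distance=edge.min_distance,
                   partial=edge.partial)
    return g


_CORE_CLASSES = {frozenset({"B", "E"}): "lateral", frozenset({"C", "F"}): "lateral",
                 frozenset({"B", "F"}): "cross_sheet",
                 frozenset({"C", "E"}): "cross_sheet"}


def core_network(annotation: IgAnnotation, include_loops: bool = False,
                 config: Config = DEFAULT) -> nx.Graph:
    """Protodomain-interface network over the central strands B, C, E, F
    (optionally with the BC/EF loop residues); edges annotated as lateral
    (B|E, C|F beta-sheet pairing) or cross-sheet (B-F, C-E core packing)."""
    chain = annotation.chain
    residues: list[tuple[Chain, Residue, Optional[str]]] = []
    for label in ("B", "C", "E", "F"):
        s = annotation.strand(label)
        if s is None:
            raise ValueError(f"core strand {label} not annotated")
        for k in s.residue_keys:
            r = chain.residue(k)
            if r is not None:
                residues.append((chain, r, label))
    if include_loops:
        keys = [r.key for r in chain]
        for loop in ("CDR1",):
            iv = annotation.loops.get(loop)
            if iv:
                for k in keys[keys.index(iv[0]):keys.index(iv[1]) + 1]:
                    residues.append((chain, chain.residue(k), None))
        # the EF loop has no CDR name; take the F-start to E-end gap
        e, f = annotation.strand("E"), annotation.strand("F")
        i0, i1 = keys.index(e.residue_keys[-1]) + 1, \
            keys.index(f.residue_keys[0])
        for k in keys[i0:i1]:
            residues.append((chain, chain.residue(k), None))
    g = _build_network(residues, None, "BC/EF core", config)
    for u, v, data in g.edges(data=True):
        su, sv = g.nodes[u].get("strand"), g.nodes[v].get("strand")
        data["core_class"] = _CORE_CLASSES.get(frozenset({su, sv}), "other") \
            if su and sv else "loop"
    return g


def interface_network(annotation_a: IgAnnotation, annotation_b: IgAnnotation,
                      interface_name: str = "quaternary",
                      config: Config = DEFAULT) -> nx.Graph:
    """Cross-partner network over all residues of the two domains."""
    ra = [(annotation_a.chain, r, _strand_of(annotation_a, r.key))
          for r in annotation_a.chain]
    rb = [(annotation_b.chain, r, _strand_of(annotation_b, r.key))
          for r in annotation_b.chain]
    g = _build_network(ra, rb, interface_name, config)
    g.remove_nodes_from([n for n in g.nodes if g.degree(n) == 0])
    return g


def _strand_of(ann: IgAnnotation, key: ResidueKey) -> Optional[str]:
    for s in ann.strands:
        if s.label and key in s.residue_keys:
            return s.label
    return None


@dataclass
class NetworkComparison:
    conserved_edges: int
    total_edges_1: int
    total_edges_2: int
    conserved_fraction: float
    node_conservation: dict[NodeId, bool]    # same amino acid under mapping
    per_type_conserved: dict[str, int]


def compare_networks(net1: nx.Graph, net2: nx.Graph,
                     mapping: dict[NodeId, NodeId]) -> NetworkComparison:
    """Compare two networks under a residue mapping (e.g. the C2 symmetry
    correspondence): an edge is conserved iff both mapped endpoints exist
    in the second network sharing at least one interaction type."""
    if not mapping:
        raise ValueError("empty residue mapping")
    n_nodes1 = net1.number_of_nodes()
    covered = sum(1 for n in net1.nodes if n in mapping)
    if n_nodes1 and covered / n_nodes1 < 0.5:
        raise ValueError(
            f"mapping covers only {covered}/{n_nodes1} nodes (< 50%)")
    conserved = 0
    per_type: dict[str, int] = {}
    for u, v, data in net1.edges(data=True):
        mu, mv = mapping.get(u), mapping.get(v)
        if mu is None or mv is None or not net2.has_edge(mu, mv):
            continue
        shared = set(data["types"]) & set(net2.edges[mu, mv]["types"])
        if shared:
            conserved += 1
            for t in shared:
                per_type[t] = per_type.get(t, 0) + 1
    node_cons = {}
    for n in net1.nodes:
        m = mapping.get(n)
        node_cons[n] = bool(m in net2.nodes and
                            net1.nodes[n]["name"] == net2.nodes[m]["name"])
    total1 = net1.number_of_edges()
    return NetworkComparison(
        conserved_edges=conserved,
        total_edges_1=total1,
        total_edges_2=net2.number_of_edges(),
        conserved_fraction=conserved / total1 if total1 else 0.0,
        node_conservation=node_cons,
        per_type_conserved=per_type,
    )


def edge_list_tsv(g: nx.Graph) -> str:
    lines = ["chain_i\tres_i\tname_i\tchain_j\tres_j\tname_j\ttypes\tmin_distance"]
    for u, v, data in sorted(g.edges(data=True)):
        lines.append("\t".join([
            u[0], f"{u[1]}{u[2]}", g.nodes[u]["name"],
            v[0], f"{v[1]}{v[2]}", g.nodes[v]["name"],
            ",".join(data["types"]), f"{data['min_distance']:.2f}"]))
    return "\n".join(lines) + "\n"
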