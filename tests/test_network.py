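"""Typed residue-interaction networks."""

import numpy as np
import pytest

from igproto import compare_networks, core_network, interface_network, \
    make_dimer, make_ig_domain
from igproto.model import Atom, Chain, Residue
from igproto.network import classify_contact
from igproto.synthetic import SandwichSpec

from .conftest import annotate, random_rigid_motion, transform_structure


def _res(name, seq, atoms):
    return Residue(seq, "", name, [Atom(n, e, np.array(p, float))
                                   for n, e, p in atoms])


CH = Chain("X")


def test_vdw_contact_between_alanines():
    r1 = _res("ALA", 1, [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))])
    r2 = _res("ALA", 5, [("CA", "C", (6.5, 0, 0)), ("CB", "C", (5.0, 0, 0))])
    edge = classify_contact(CH, r1, CH, r2)
    assert edge.types == {"vdw"}
    assert edge.min_distance == pytest.approx(3.5)


def test_salt_bridge_fires_all_criteria():
    """Asp O-delta to Lys N-zeta at 3.0 A satisfies vdw, hbond and ionic."""
    asp = _res("ASP", 10, [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0)),
                           ("CG", "C", (2.5, 0, 0)), ("OD1", "O", (3.5, 0, 0)),
                           ("OD2", "O", (2.5, 1.2, 0))])
    lys = _res("LYS", 14, [("CA", "C", (9, 0, 0)), ("CB", "C", (8, 0, 0)),
                           ("CE", "C", (7.5, 0, 0)), ("NZ", "N", (6.5, 0, 0))])
    edge = classify_contact(CH, asp, CH, lys)
    assert edge.types == {"vdw", "hbond", "ionic"}


def test_disulfide():
    c1 = _res("CYS", 1, [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0)),
                         ("SG", "S", (2.8, 0, 0))])
    c2 = _res("CYS", 9, [("CA", "C", (7, 0, 0)), ("CB", "C", (6.0, 0, 0)),
                         ("SG", "S", (4.8, 0, 0))])
    edge = classify_contact(CH, c1, CH, c2)
    assert "disulfide" in edge.types


def test_pi_stack_and_pi_cation():
    ring = [("CG", "C", (0, 0, 0)), ("CD1", "C", (1.4, 0, 0)),
            ("CD2", "C", (-0.7, 1.2, 0)), ("CE1", "C", (2.1, 1.2, 0)),
            ("CE2", "C", (0, 2.4, 0)), ("CZ", "C", (1.4, 2.4, 0))]
    phe1 = _res("PHE", 1, [("CA", "C", (-2, 0, 0))] + ring)
    phe2 = _res("PHE", 8, [("CA", "C", (-2, 0, 4))] +
                [(n, e, (x, y, 4.0)) for n, e, (x, y, _z) in ring])
    edge = classify_contact(CH, phe1, CH, phe2)
    assert "pi_stack" in edge.types
    arg = _res("ARG", 20, [("CA", "C", (0, 0, 8)), ("CZ", "C", (0.7, 1.2, 5)),
                           ("NH1", "N", (0.7, 1.2, 4.5)),
                           ("NH2", "N", (1.5, 2, 5)), ("NE", "N", (0, 0, 5))])
    edge = classify_contact(CH, phe1, CH, arg)
    assert "pi_cation" in edge.types


def test_contact_classification_symmetric():
    rng = np.random.default_rng(0)
    a = _res("ASP", 1, [("CA", "C", rng.normal(size=3)),
                        ("OD1", "O", rng.normal(size=3) + 2)])
    b = _res("ARG", 5, [("CA", "C", rng.normal(size=3) + 1),
                        ("NH1", "N", rng.normal(size=3) + 2),
                        ("CZ", "C", rng.normal(size=3) + 2)])
    e1, e2 = classify_contact(CH, a, CH, b), classify_contact(CH, b, CH, a)
    assert (e1 is None) == (e2 is None)
    if e1:
        assert e1.types == e2.types
        assert e1.min_distance == pytest.approx(e2.min_distance)


def test_no_contact_returns_none():
    r1 = _res("ALA", 1, [("CA", "C", (0, 0, 0))])
    r2 = _res("ALA", 9, [("CA", "C", (50, 0, 0))])
    assert classify_contact(CH, r1, CH, r2) is None


def test_missing_sidechain_flagged_partial():
    r1 = _res("LYS", 1, [("CA", "C", (0, 0, 0))])       # no side chain
    r2 = _res("ALA", 5, [("CA", "C", (3.5, 0, 0)), ("CB", "C", (2.2, 0, 0))])
    edge = classify_contact(CH, r1, CH, r2)
    assert edge is not None and edge.partial


# ---------------------------------------------------------------------------
# networks on synthetic structures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def backbone_domain():
    st, _ = make_ig_domain(SandwichSpec(topology_preset="V_set",
                                        full_backbone=True))
    return st


def test_core_network_classes(backbone_domain):
    g = core_network(annotate(backbone_domain, "A"))
    classes = {d["core_class"] for _u, _v, d in g.edges(data=True)}
    assert "lateral" in classes          # B|E and C|F sheet pairing
    # poly-ala/gly backbone: no side-chain-mediated interaction types
    types = {t for _u, _v, d in g.edges(data=True) for t in d["types"]}
    assert types <= {"vdw", "hbond"}
    assert g.number_of_edges() > 0


def test_network_invariant_under_rigid_motion(backbone_domain):
    g0 = core_network(annotate(backbone_domain, "A"))
    moved = transform_structure(backbone_domain,
                                *random_rigid_motion(np.random.default_rng(3)))
    g1 = core_network(annotate(moved, "A"))
    e0 = {(u, v, tuple(d["types"])) for u, v, d in g0.edges(data=True)}
    e1 = {(u, v, tuple(d["types"])) for u, v, d in g1.edges(data=True)}
    assert e0 == e1


@pytest.fixture(scope="module")
def dimer_network():
    st, truth = make_dimer(SandwichSpec(topology_preset="parallel_dimer"))
    g = interface_network(annotate(st, "A"), annotate(st, "B"))
    return g, truth


def test_dimer_network_exactly_symmetric_under_c2(dimer_network):
    """The quaternary interface network of an exact-C2 homodimer maps onto
    itself under the symmetry correspondence."""
    g, truth = dimer_network
    flip = {n: ("B" if n[0] == "A" else "A", n[1], n[2]) for n in g.nodes}
    cmp = compare_networks(g, g, flip)
    assert cmp.conserved_fraction == 1.0
    assert cmp.total_edges_1 == g.number_of_edges() > 0


def test_network_vs_itself_identity(dimer_network):
    g, _ = dimer_network
    cmp = compare_networks(g, g, {n: n for n in g.nodes})
    assert cmp.conserved_fraction == 1.0
    assert all(cmp.node_conservation.values())


def test_random_edge_deletion_conserved_fraction(dimer_network):
    """Deleting 20% of edges leaves exactly the complementary fraction
    conserved under the identity mapping."""
    g, _ = dimer_network
    h = g.copy()
    edges = sorted(h.edges)
    rng = np.random.default_rng(12)
    drop = rng.choice(len(edges), size=len(edges) // 5, replace=False)
    h.remove_edges_from([edges[i] for i in drop])
    cmp = compare_networks(g, h, {n: n for n in g.nodes})
    assert cmp.conserved_edges == len(edges) - len(drop)


def test_sparse_mapping_rejected(dimer_network):
    g, _ = dimer_network
    few = dict(list({n: n for n in g.nodes}.items())[:2])
    with pytest.raises(ValueError):
        compare_networks(g, g, few)
    with pytest.raises(ValueError):
        compare_networks(g, g, {})
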