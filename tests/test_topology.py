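"""Topology classification, CCW(L) signature, double-Ig detection, maps."""

import pytest

from igproto import classify_structure, classify_topology, detect_ccwl, \
    detect_double_ig, make_ig_domain, render_text, topology_map
from igproto.synthetic import SandwichSpec

from .conftest import SINGLE_PRESETS, annotate


@pytest.mark.parametrize("preset", SINGLE_PRESETS)
def test_clean_presets_classify_to_their_class(preset, clean_domains):
    st, _ = clean_domains[preset]
    assert classify_structure(st, "A").topology.label == preset


def test_rule_trace_is_populated(clean_annotations):
    topo = classify_topology(clean_annotations["I_set"])
    assert topo.label == "I_set"
    assert any("short C'" in line for line in topo.rule_trace)


def test_c_double_prime_dominates():
    """Rule order: a V-set domain with a short C' is still V-set because
    the C'' test fires first."""
    st, _ = make_ig_domain(SandwichSpec(topology_preset="V_set"))
    ann = annotate(st, "A")
    # artificially shorten C' below the I-set threshold
    cp = ann.strand("C'")
    cp.residue_keys = cp.residue_keys[:3]
    cp.positions = cp.positions[:3]
    assert classify_topology(ann).label == "V_set"


def test_g_strand_required_for_any_class(clean_annotations):
    """B, C, E, F and G are all required; without G the verdict is not-Ig."""
    import copy
    ann = copy.deepcopy(clean_annotations["C1_set"])
    for s in ann.strands:
        if s.label == "G":
            s.label = None
    assert classify_topology(ann).label == "not_Ig"


def test_c2_vs_fn3_discriminated_by_signature(clean_domains):
    """Identical strand topology, different sequence: the CCW(L) signature
    is the only discriminator."""
    st_c2, _ = clean_domains["C2_set"]
    st_fn3, _ = clean_domains["FN3"]
    assert classify_structure(st_c2, "A").topology.label == "C2_set"
    assert classify_structure(st_fn3, "A").topology.label == "FN3"


def test_ccwl_complete_on_decorated_domain(clean_annotations):
    sig = detect_ccwl(clean_annotations["V_set"])
    assert sig.complete and sig.n_strict == 4
    assert all(v is not None for v in sig.positions.values())


def test_ccwl_absent_on_poly_ala(clean_annotations):
    sig = detect_ccwl(clean_annotations["FN3"])
    assert not sig.complete and sig.n_strict == 0


def test_ccwl_leucine_fallback(clean_domains):
    """An isoleucine in place of the E-strand leucine is a tolerated,
    non-strict hit (incomplete signature, no reclassification)."""
    import copy
    st, truth = clean_domains["V_set"]
    st = copy.deepcopy(st)
    e_ids = truth.strand_residues[("A", "E")]
    res = st.chain("A").residue((e_ids[len(e_ids) // 2 - (len(e_ids)+1) % 2], ""))
    # locate the decorated L robustly
    for sid in e_ids:
        r = st.chain("A").residue((sid, ""))
        if r.one_letter == "L":
            r.name = "ILE"
    ann = annotate(st, "A")
    sig = detect_ccwl(ann)
    assert not sig.complete and sig.n_strict == 3
    assert classify_topology(ann).label == "V_set"


# ---------------------------------------------------------------------------
# double Ig
# ---------------------------------------------------------------------------

def test_double_ig_detected_with_all_evidence(clean_double_ig):
    st, truth = clean_double_ig
    model, diags = detect_double_ig(st, "A")
    assert model is not None
    assert model.parallel_pairs == [(1, 2), (3, 4)]
    assert model.inverter_length > 10
    assert all(n >= 2 for n in model.fused_ladders.values())
    assert set(model.fused_ladders) == {"C'|C'", "D|D"}


def test_double_ig_composites_and_inverse(clean_double_ig):
    """Composites are (p1,p4) regular and (p2,p3) inverse: the DE-FG member
    precedes the AB-CC' member in sequence only in the inverse one."""
    st, _ = clean_double_ig
    model, _ = detect_double_ig(st, "A")
    assert tuple(sorted(model.composite_regular)) == (1, 4)
    assert tuple(sorted(model.composite_inverse)) == (2, 3)
    odd, even = model.composite_inverse
    assert even < odd  # sequence order makes it the inverse Ig


def test_double_ig_local_and_central_c2_exact(clean_double_ig):
    st, _ = clean_double_ig
    model, _ = detect_double_ig(st, "A")
    for name, rmsd in model.rmsds.items():
        assert rmsd <= 1e-6, name
    for name, ax in model.axes.items():
        assert ax is not None and ax.angle == pytest.approx(180.0, abs=1e-6)


def test_single_domain_is_not_double_ig(clean_domains):
    st, _ = clean_domains["V_set"]
    model, diags = detect_double_ig(st, "A")
    assert model is None
    assert diags  # lists which evidence failed


def test_partial_evidence_diagnosed(clean_double_ig):
    """Raising the inverter threshold above the actual linker length must
    fail evidence (b) with a diagnostic naming it."""
    from igproto.config import Config
    st, _ = clean_double_ig
    model, diags = detect_double_ig(st, "A", config=Config(inverter_min=50))
    assert model is None
    assert any("(b)" in d for d in diags)


def test_double_ig_noisy_recovery():
    for seed in range(20):
        st, _ = make_ig_domain(SandwichSpec(topology_preset="double_Ig",
                                            noise_sigma=0.3, seed=seed))
        assert classify_structure(st, "A").topology.label == "double_Ig", seed


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def test_v_set_map_sheet_rows(clean_annotations):
    doc = topology_map(clean_annotations["V_set"])
    rows = {sid: "".join(s.label or "?" for s in row)
            for sid, row in doc.sheets.items()}
    assert "ABED" in rows.values()
    assert "A'GFCC'C''" in rows.values()
    assert not doc.fallback_packing
    text = render_text(doc)
    assert "CDR1" in text and "CDR3" in text


def test_double_ig_map_fused_sheets(clean_double_ig):
    st, _ = clean_double_ig
    res = classify_structure(st, "A")
    doc = topology_map(res.annotation)
    rows = ["".join(s.label or "?" for s in row)
            for row in doc.sheets.values()]
    assert "B1E1D1D2E2B2" in rows
    assert "A'1G1F1C1C'1C'2C2F2G2A'2" in rows


def test_map_register_columns_align_ladder_partners(clean_annotations):
    """Residues paired in a ladder share a column (register rendering)."""
    ann = clean_annotations["C1_set"]
    doc = topology_map(ann)
    col = {}
    for row in doc.sheets.values():
        for s in row:
            for r in s.residues:
                col[(r["seq_id"])] = r["column"]
    for lad in ann.sheet_model.ladders:
        for (ki, kj) in lad.pairs:
            assert col[ki[0]] == col[kj[0]]
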