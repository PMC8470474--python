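"""Protodomain decomposition, correspondence and internal C2 symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igproto import analyse_protodomains, build_correspondence, decompose, \
    make_ig_domain, superpose
from igproto.protodomains import CorrespondenceError, _trim
from igproto.synthetic import SandwichSpec

from .conftest import SINGLE_PRESETS, annotate, random_rigid_motion, \
    transform_structure


def test_v_set_decomposition(clean_annotations):
    p1, p2 = decompose(clean_annotations["V_set"])
    assert p1.strand_labels == ["A", "A'", "B", "C", "C'"]
    assert p2.strand_labels == ["D", "E", "F", "G"]


def test_fn3_decomposition_lacks_d(clean_annotations):
    p1, p2 = decompose(clean_annotations["FN3"])
    assert p1.strand_labels == ["A", "B", "C", "C'"]
    assert p2.strand_labels == ["E", "F", "G"]


def test_decomposition_requires_core(clean_annotations):
    import copy
    from igproto.protodomains import DecompositionError
    ann = copy.deepcopy(clean_annotations["C1_set"])
    for s in ann.strands:
        if s.label == "E":
            s.label = None
    with pytest.raises(DecompositionError):
        decompose(ann)


@pytest.mark.parametrize("n_long,n_short,expect", [
    (6, 6, (0, 6)),
    (7, 4, (1, 5)),   # tie resolved toward the N side
    (8, 4, (2, 6)),
])
def test_centre_trim_rule(n_long, n_short, expect):
    assert _trim(n_long, n_short) == expect


@settings(derandomize=True, max_examples=200)
@given(n_short=st.integers(1, 40), excess=st.integers(0, 40))
def test_centre_trim_properties(n_short, excess):
    """The trimmed window always has the short strand's length, stays in
    bounds, is centred, and resolves odd excess toward the N side."""
    n_long = n_short + excess
    a, b = _trim(n_long, n_short)
    assert b - a == n_short
    assert 0 <= a and b <= n_long
    n_trim_n, n_trim_c = a, n_long - b
    assert n_trim_c - n_trim_n in (0, 1)


def test_equal_length_strands_pair_fully(clean_annotations):
    ann = clean_annotations["C1_set"]
    p1, p2 = decompose(ann)
    corr = build_correspondence(p1, p2)
    # A<->D, B<->E, C<->F all 6/6
    assert len(corr) == 18
    assert set(corr.strand_map) == {("A", "D"), ("B", "E"), ("C", "F")}


def test_strand_restriction_excludes_edges(clean_annotations):
    ann = clean_annotations["V_set"]
    p1, p2 = decompose(ann)
    corr = build_correspondence(p1, p2, strands=["B", "C", "C'"])
    assert set(corr.strand_map) == {("B", "E"), ("C", "F"), ("C'", "G")}
    mapped = {lab for pair in corr.pair_labels for lab in pair}
    assert "A" not in mapped and "A'" not in mapped and "D" not in mapped


def test_too_few_strands_raise(clean_annotations):
    ann = clean_annotations["V_set"]
    p1, p2 = decompose(ann)
    with pytest.raises(CorrespondenceError):
        build_correspondence(p1, p2, strands=["C'"])


@pytest.mark.parametrize("preset", SINGLE_PRESETS)
def test_noise_free_exact_c2(preset, clean_annotations):
    """Noise-free synthetic domains carry an exact internal C2: RMSD 0 and
    axis angle 180 degrees to numerical precision."""
    rep = analyse_protodomains(clean_annotations[preset])
    assert rep["rmsd"] <= 1e-6
    ax = rep["axis"]
    assert ax is not None and ax.order_label == "C2"
    assert ax.angle == pytest.approx(180.0, abs=1e-6)
    assert abs(ax.screw) <= 1e-6


def test_cadherin_default_correspondence_is_core_only(clean_annotations):
    """With A on the A'|GFC sheet and no C', only B<->E and C<->F map."""
    rep = analyse_protodomains(clean_annotations["cadherin"])
    assert set(rep["correspondence"].strand_map) == {("B", "E"), ("C", "F")}


def test_a_maps_to_d_when_split(clean_annotations):
    """The split A (on the ABED sheet) keeps its correspondence with D."""
    rep = analyse_protodomains(clean_annotations["V_set"])
    assert ("A", "D") in rep["correspondence"].strand_map
    assert all(lab != "A'" for pair in rep["correspondence"].pair_labels
               for lab in pair)


@pytest.mark.parametrize("preset", SINGLE_PRESETS)
def test_noisy_rmsd_in_plausible_band(preset):
    """At sigma=0.3 A the protodomain RMSD stays well inside the 2.6 A band
    typical of natural Ig variants."""
    for seed in range(5):
        st, _ = make_ig_domain(SandwichSpec(topology_preset=preset,
                                            noise_sigma=0.3, seed=seed))
        rep = analyse_protodomains(annotate(st, "A"))
        assert 0.0 < rep["rmsd"] <= 2.6


def test_rmsd_invariant_under_rigid_motion(clean_domains):
    st, _ = clean_domains["I_set"]
    noisy, _ = make_ig_domain(SandwichSpec(topology_preset="I_set",
                                           noise_sigma=0.3, seed=4))
    base = analyse_protodomains(annotate(noisy, "A"))
    R, t = random_rigid_motion(np.random.default_rng(1))
    moved = transform_structure(noisy, R, t)
    rep = analyse_protodomains(annotate(moved, "A"))
    assert rep["rmsd"] == pytest.approx(base["rmsd"], abs=1e-9)
    ax0, ax1 = base["axis"], rep["axis"]
    assert ax1.angle == pytest.approx(ax0.angle, abs=1e-6)
    # axis direction transforms covariantly
    assert abs(np.dot(R @ ax0.direction, ax1.direction)) == \
        pytest.approx(1.0, abs=1e-6)


def test_refinement_drops_outlier_pairs(clean_annotations):
    import copy
    ann = copy.deepcopy(clean_annotations["C1_set"])
    # displace one strand-B residue far off the fold
    b = ann.strand("B")
    b.positions = b.positions.copy()
    b.positions[2] += np.array([25.0, 0.0, 0.0])
    p1, p2 = decompose(ann)
    corr = build_correspondence(p1, p2)
    sp_raw, _ = superpose(corr, refine=False)
    sp_ref, trimmed = superpose(corr, refine=True)
    assert sp_ref.rmsd < sp_raw.rmsd
    assert len(trimmed) < len(corr)


def test_identity_reported_not_used(clean_annotations):
    rep = analyse_protodomains(clean_annotations["V_set"])
    assert 0.0 <= rep["identity"] <= 1.0
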