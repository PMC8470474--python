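import numpy as np
import pytest

from igproto import detect_strands, label_ig_strands, make_dimer, \
    make_ig_domain
from igproto.synthetic import SandwichSpec

SINGLE_PRESETS = ["V_set", "C1_set", "C2_set", "I_set", "FN3", "cadherin"]


def annotate(structure, chain_id, mode="ca_only", override=None):
    strands, sm = detect_strands(structure, chain_id, mode=mode)
    return label_ig_strands(strands, sm, structure.chain(chain_id),
                            override=override)


@pytest.fixture(scope="session")
def clean_domains():
    """Noise-free single-Ig structures + ground truth, one per preset."""
    out = {}
    for preset in SINGLE_PRESETS:
        out[preset] = make_ig_domain(SandwichSpec(topology_preset=preset))
    return out


@pytest.fixture(scope="session")
def clean_annotations(clean_domains):
    return {preset: annotate(st, "A")
            for preset, (st, _t) in clean_domains.items()}


@pytest.fixture(scope="session")
def clean_double_ig():
    return make_ig_domain(SandwichSpec(topology_preset="double_Ig"))


@pytest.fixture(scope="session")
def clean_parallel_dimer():
    return make_dimer(SandwichSpec(topology_preset="parallel_dimer"))


@pytest.fixture(scope="session")
def clean_inverted_dimer():
    return make_dimer(SandwichSpec(topology_preset="inverted_dimer"))


def random_rigid_motion(rng):
    """A uniform random rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.normal(scale=20.0, size=3)
    return R, t


def transform_structure(structure, R, t):
    """Apply a rigid motion to every atom (in place on a deep copy)."""
    import copy
    moved = copy.deepcopy(structure)
    for chain in moved.chains:
        for res in chain:
            for atom in res.atoms:
                atom.position = R @ atom.position + t
    return moved
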