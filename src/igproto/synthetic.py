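"""Idealized beta-sandwich generator with ground-truth labels.

Builds synthetic Ig(-like) domains as flat two-sheet sandwiches: strands run
along z (one residue per ``rise``), laterally spaced within a sheet along x,
with the two sheets separated along y.  Each topology preset (V-set, C1-set,
C2-set, I-set, FN3, cadherin, double-Ig, and the dimeric presets) fixes the
strand-presence table; the second protodomain is the exact 180-degree image
of the first about the sandwich normal, so noise-free domains carry an exact
internal C2 (protodomain RMSD 0, angle 180).  Loops and linkers are routed
as non-extended zig-zag coil away from the sheets so that strand detection
recovers precisely the designed strands.

The generated coordinates are C-alpha-only by default; ``full_backbone``
adds ideal N/C/O positions whose geometry satisfies the package's
hydrogen-bond ladder criterion between designed sheet neighbours (a native
test path for backbone-mode detection, not a physical model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import Atom, Chain, Residue, StructureModel

SINGLE_PRESETS = ("V_set", "C1_set", "C2_set", "I_set", "FN3", "cadherin",
                  "double_Ig")
DIMER_PRESETS = ("parallel_dimer", "inverted_dimer", "swapped_dimer")

ONE_TO_THREE = {"A": "ALA", "G": "GLY", "C": "CYS", "W": "TRP", "L": "LEU",
                "P": "PRO"}


class SpecError(ValueError):
    pass


@dataclass
class SandwichSpec:
    topology_preset: str
    strand_length: int = 6
    rise: float = 3.4                 # A per residue along a strand
    strand_spacing: float = 4.8       # A between laddered strands
    sheet_separation: float = 10.0    # A between the two sheets
    noise_sigma: float = 0.0          # A, isotropic Gaussian on every atom
    seed: int = 0
    sequence_mode: str = "auto"       # auto | poly_ala | ccwl_decorated
    full_backbone: bool = False
    dimer_gap: float = 3.5            # A between facing sheets in dimers
    site_offset: float = 40.0         # A between domain sites (swapped dimer)

    def __post_init__(self) -> None:
        if self.topology_preset not in SINGLE_PRESETS + DIMER_PRESETS:
            raise SpecError(f"unknown preset {self.topology_preset!r}")
        for name in ("strand_length", "rise", "strand_spacing",
                     "sheet_separation", "dimer_gap", "site_offset"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if self.sequence_mode not in ("auto", "poly_ala", "ccwl_decorated"):
            raise SpecError(f"unknown sequence_mode {self.sequence_mode!r}")
        if self.topology_preset == "FN3" and \
                self.sequence_mode == "ccwl_decorated":
            raise SpecError("FN3 is defined by the absence of the CCW(L) "
                            "signature; use preset C2_set for a decorated "
                            "domain of this topology")

    @property
    def effective_sequence_mode(self) -> str:
        if self.sequence_mode != "auto":
            return self.sequence_mode
        return "poly_ala" if self.topology_preset == "FN3" else "ccwl_decorated"


@dataclass
class GroundTruth:
    preset: str
    # (chain_id, label) -> list of residue seq_ids
    strand_residues: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    # (chain_id, seq_id) -> protodomain index (1..4), strand residues only
    protodomain_of: dict[tuple[str, int], int] = field(default_factory=dict)
    # name -> (direction, point); tertiary / quaternary / local axes
    axes: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    orientation: Optional[str] = None          # dimers: parallel | inverted
    swapped: bool = False
    linkers: dict[str, tuple[int, int]] = field(default_factory=dict)
    # residue map chainA seq_id -> chainB seq_id under the quaternary C2
    residue_map: dict[int, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# strand tables: (label, sheet, lateral slot, direction, length factor)
# sheet "A" is the ABED side (y = 0); "B" the A'GFCC'C'' side (y = sep).
# x = slot * spacing on both sheets; the internal C2 axis runs along y
# through slot 1.5.
# ---------------------------------------------------------------------------

_TABLES: dict[str, list[tuple[str, str, float, int]]] = {
    "V_set": [("A", "A", 0, -1), ("A'", "B", -1, -1), ("B", "A", 1, +1),
              ("C", "B", 2, -1), ("C'", "B", 3, +1), ("C''", "B", 4, -1),
              ("D", "A", 3, +1), ("E", "A", 2, -1), ("F", "B", 1, +1),
              ("G", "B", 0, -1)],
    "I_set": [("A", "A", 0, -1), ("A'", "B", -1, -1), ("B", "A", 1, +1),
              ("C", "B", 2, -1), ("C'", "B", 3, +1),
              ("D", "A", 3, +1), ("E", "A", 2, -1), ("F", "B", 1, +1),
              ("G", "B", 0, -1)],
    "C1_set": [("A", "A", 0, -1), ("B", "A", 1, +1), ("C", "B", 2, -1),
               ("D", "A", 3, +1), ("E", "A", 2, -1), ("F", "B", 1, +1),
               ("G", "B", 0, -1)],
    "C2_set": [("A", "A", 0, -1), ("B", "A", 1, +1), ("C", "B", 2, -1),
               ("C'", "B", 3, +1), ("E", "A", 2, -1), ("F", "B", 1, +1),
               ("G", "B", 0, -1)],
    "cadherin": [("A'", "B", -1, -1), ("B", "A", 1, +1), ("C", "B", 2, -1),
                 ("D", "A", 3, +1), ("E", "A", 2, -1), ("F", "B", 1, +1),
                 ("G", "B", 0, -1)],
}
_TABLES["FN3"] = _TABLES["C2_set"]

#: signature positions for ccwl_decorated mode: strand label -> residue
_CCWL = {"B": "C", "C": "W", "E": "L", "F": "C"}

#: strand membership of the two protodomains for ground truth
_P_ODD = ("A", "A'", "B", "C", "C'")


@dataclass
class _StrandGeom:
    label: str
    x: float
    y: float
    direction: int
    length: int
    z_offset: float = 0.0

    def positions(self, rise: float) -> np.ndarray:
        h = (self.length - 1) * rise / 2.0
        z = np.linspace(-h, h, self.length)[::self.direction] + self.z_offset
        out = np.zeros((self.length, 3))
        out[:, 0] = self.x
        out[:, 1] = self.y
        out[:, 2] = z
        return out


def _strand_geoms(spec: SandwichSpec) -> list[_StrandGeom]:
    geoms = []
    for label, sheet, slot, direction in _TABLES[spec.topology_preset]:
        y = 0.0 if sheet == "A" else spec.sheet_separation
        length = spec.strand_length
        z_off = 0.0
        if spec.topology_preset == "I_set" and label == "C'":
            length = 3  # the I-set C' is very short
            # sit on the C2 image of the trimmed central window of G so the
            # short strand pairs exactly under the centre-trim rule
            if (spec.strand_length - length) % 2 == 1:
                z_off = -spec.rise / 2.0
        geoms.append(_StrandGeom(label, slot * spec.strand_spacing, y,
                                 direction, length, z_off))
    return geoms


# ---------------------------------------------------------------------------
# chain assembly
# ---------------------------------------------------------------------------

def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, ref)) > 0.9 * np.linalg.norm(v):
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _loop_points(p_end: np.ndarray, d_prev: np.ndarray,
                 q_start: np.ndarray, d_next: np.ndarray,
                 rise: float, n_total: Optional[int] = None,
                 centre: Optional[np.ndarray] = None) -> np.ndarray:
    """Coil path between two strands.

    The coil is deliberately non-extended: anchor points sit well beyond
    the strand termini and successive coil points are spaced outside the
    extended-bond window, so every coil residue is a clean chain break and
    can never join a strand run or a ladder.  Loops with a forced residue
    count (the double-Ig inverter) are dense instead, and zig-zag sharply
    while bowing away from the sandwich so they stay clear of the sheets.
    """
    ext = 6.5
    first = p_end + d_prev * ext
    last = q_start - d_next * ext
    drift = last - first
    drift -= np.dot(drift, d_prev) * d_prev
    norm = np.linalg.norm(drift)
    if norm > 1e-6:
        first = first + drift / norm * 1.5
    away = first - last
    away -= np.dot(away, d_next) * d_next
    norm = np.linalg.norm(away)
    if norm > 1e-6:
        last = last - away / norm * 1.5
    d_fl = float(np.linalg.norm(last - first))
    if n_total is None:
        n_mid, zig_amp, bow_amp = max(0, round(d_fl / 6.4) - 1), 0.0, 2.0
    else:
        n_mid, zig_amp, bow_amp = max(n_total - 2, 0), 1.6, 4.0
    pts = [first]
    if n_mid:
        axis = (last - first) / max(d_fl, 1e-6)
        perp = _perp(axis)
        bow = np.zeros(3)
        if centre is not None:
            bow = (first + last) / 2.0 - centre
            bow[2] = 0.0
            bow -= np.dot(bow, axis) * axis
            norm = np.linalg.norm(bow)
            bow = bow / norm * bow_amp if norm > 1e-6 else np.zeros(3)
        for k in range(1, n_mid + 1):
            t = k / (n_mid + 1)
            zig = perp * (zig_amp if k % 2 else -zig_amp)
            pts.append(first + t * (last - first) + zig + bow)
    pts.append(last)
    return np.asarray(pts)


def _build_chain(chain_id: str, segments: list[dict], spec: SandwichSpec,
                 start_seq: int = 1
                 ) -> tuple[Chain, dict[str, list[int]], dict[str, tuple[int, int]]]:
    """Assemble strands + loops into a chain.

    ``segments`` is an ordered list of {"geom": _StrandGeom} entries with
    optional {"loop_n": int} overrides and {"loop_name": str} on the segment
    *preceding* each loop.
    """
    seq_mode = spec.effective_sequence_mode
    chain = Chain(chain_id=chain_id)
    strand_ids: dict[str, list[int]] = {}
    linkers: dict[str, tuple[int, int]] = {}
    seq = start_seq

    def add_residue(pos: np.ndarray, aa: str) -> int:
        nonlocal seq
        res = Residue(seq_id=seq, insertion_code="", name=ONE_TO_THREE[aa],
                      atoms=[Atom("CA", "C", np.array(pos, float))])
        chain.residues.append(res)
        seq += 1
        return res.seq_id

    all_strand_pos = [seg.get("positions", seg["geom"].positions(spec.rise))
                      for seg in segments]
    centre = np.vstack(all_strand_pos).mean(axis=0)
    prev_geom: Optional[_StrandGeom] = None
    prev_pos: Optional[np.ndarray] = None
    for seg in segments:
        geom: _StrandGeom = seg["geom"]
        pos = seg.get("positions")
        if pos is None:
            pos = geom.positions(spec.rise)
        if prev_geom is not None:
            d_prev = (prev_pos[-1] - prev_pos[-2])
            d_prev /= np.linalg.norm(d_prev)
            d_next = (pos[1] - pos[0]) / np.linalg.norm(pos[1] - pos[0])
            loop = _loop_points(prev_pos[-1], d_prev, pos[0], d_next,
                                spec.rise, seg.get("loop_n"), centre)
            lo = seq
            for p in loop:
                add_residue(p, "G")
            if seg.get("loop_name"):
                linkers[seg["loop_name"]] = (lo, seq - 1)
        ids = []
        centre = (geom.length - 1) // 2
        for i, p in enumerate(pos):
            aa = "A"
            if seq_mode == "ccwl_decorated" and i == centre:
                aa = _CCWL.get(geom.label.rstrip("12"), "A")
            ids.append(add_residue(p, aa))
        strand_ids[seg.get("truth_label", geom.label)] = ids
        prev_geom, prev_pos = geom, pos
    return chain, strand_ids, linkers


def _apply_noise(structure: StructureModel, sigma: float, seed: int) -> None:
    if sigma <= 0:
        return
    rng = np.random.default_rng(seed)
    for chain in structure.chains:
        for res in chain:
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0.0, sigma, 3)


def _add_backbone(structure: StructureModel, spec: SandwichSpec,
                  strand_keys: dict[tuple[str, int], int]) -> None:
    """Ideal N/C/O atoms; sheet residues get the alternating lateral pleat
    that realises the N...O ladder geometry.  ``strand_keys`` maps residue
    keys to a pleat phase: 0 for antiparallel (same-rung) pairing, 1 for
    the A' strand whose only partner (G) is parallel and therefore bonds
    on a shifted register."""
    for chain in structure.chains:
        n = len(chain.residues)
        cas = np.array([r.ca.position for r in chain.residues])
        for i, res in enumerate(chain.residues):
            if i == 0:
                d = cas[1] - cas[0]
            elif i == n - 1:
                d = cas[-1] - cas[-2]
            else:
                d = cas[i + 1] - cas[i - 1]
            d = d / np.linalg.norm(d)
            if (chain.chain_id, res.seq_id) in strand_keys:
                # stable grid index: the z grid sits at half-integer
                # multiples of the rise for even strand lengths
                zi = int(np.floor(float(cas[i][2]) / spec.rise + 0.25))
                slot = round(float(cas[i][0]) / spec.strand_spacing)
                phase = strand_keys[(chain.chain_id, res.seq_id)]
                sign = 1.0 if (zi + slot + phase) % 2 == 0 else -1.0
                o = np.array([sign, 0.0, 0.0])
                # keep the pleat lateral in the sheet plane after any dimer
                # transform: project off the strand direction
                o = o - np.dot(o, d) * d
                nn = np.linalg.norm(o)
                o = o / nn if nn > 1e-6 else _perp(d)
            else:
                o = _perp(d)
            ca = cas[i]
            res.atoms.append(Atom("N", "N", ca - 1.5 * d + 1.2 * o))
            c = ca + 1.5 * d
            res.atoms.append(Atom("C", "C", c))
            res.atoms.append(Atom("O", "O", c + 1.4 * o))


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------

def make_ig_domain(spec: SandwichSpec) -> tuple[StructureModel, GroundTruth]:
    """Single Ig(-like) domain (or the CD19-style double Ig) with ground truth."""
    if spec.topology_preset in DIMER_PRESETS:
        raise SpecError(f"{spec.topology_preset} is dimeric: use make_dimer")
    if spec.topology_preset == "double_Ig":
        return _make_double_ig(spec)
    geoms = _strand_geoms(spec)
    segments = [{"geom": g} for g in geoms]
    chain, strand_ids, linkers = _build_chain("A", segments, spec)
    structure = StructureModel(id=f"synthetic_{spec.topology_preset}",
                               chains=[chain])
    truth = GroundTruth(preset=spec.topology_preset)
    for label, ids in strand_ids.items():
        truth.strand_residues[("A", label)] = ids
        p = 1 if label in _P_ODD else 2
        for sid in ids:
            truth.protodomain_of[("A", sid)] = p
    truth.linkers = linkers
    centre_x = 1.5 * spec.strand_spacing
    truth.axes["tertiary"] = (np.array([0.0, 1.0, 0.0]),
                              np.array([centre_x, spec.sheet_separation / 2, 0.0]))
    _finish(structure, spec, truth)
    return structure, truth


def _make_double_ig(spec: SandwichSpec) -> tuple[StructureModel, GroundTruth]:
    s, sep, rise = spec.strand_spacing, spec.sheet_separation, spec.rise
    # left composite-domain template: a V-like domain without A and C''
    left = {lbl: _StrandGeom(lbl, slot * s, 0.0 if sheet == "A" else sep,
                             d, spec.strand_length)
            for lbl, sheet, slot, d in _TABLES["V_set"]
            if lbl not in ("A", "C''")}
    mirror_x = 2 * 3.5 * s  # central C2 at slot 3.5 (between the fused strands)

    def right(lbl: str) -> _StrandGeom:
        g = left[lbl]
        return _StrandGeom(lbl + "2", mirror_x - g.x, g.y, -g.direction,
                           g.length)

    order = [  # p1 (left odd) | p2 (right even) | p3 (right odd) | p4 (left even)
        {"geom": left["A'"], "truth_label": "A'1"},
        {"geom": left["B"], "truth_label": "B1"},
        {"geom": left["C"], "truth_label": "C1"},
        {"geom": left["C'"], "truth_label": "C'1"},
        {"geom": right("D"), "truth_label": "D2", "loop_name": "p1-p2"},
        {"geom": right("E"), "truth_label": "E2"},
        {"geom": right("F"), "truth_label": "F2"},
        {"geom": right("G"), "truth_label": "G2"},
        {"geom": right("A'"), "truth_label": "A'2", "loop_name": "inverter",
         "loop_n": 12},
        {"geom": right("B"), "truth_label": "B2"},
        {"geom": right("C"), "truth_label": "C2"},
        {"geom": right("C'"), "truth_label": "C'2"},
        {"geom": left["D"], "truth_label": "D1", "loop_name": "p3-p4"},
        {"geom": left["E"], "truth_label": "E1"},
        {"geom": left["F"], "truth_label": "F1"},
        {"geom": left["G"], "truth_label": "G1"},
    ]
    chain, strand_ids, linkers = _build_chain("A", order, spec)
    structure = StructureModel(id="synthetic_double_Ig", chains=[chain])
    truth = GroundTruth(preset="double_Ig", linkers=linkers)
    pd_of = {"A'1": 1, "B1": 1, "C1": 1, "C'1": 1,
             "D2": 2, "E2": 2, "F2": 2, "G2": 2,
             "A'2": 3, "B2": 3, "C2": 3, "C'2": 3,
             "D1": 4, "E1": 4, "F1": 4, "G1": 4}
    for label, ids in strand_ids.items():
        truth.strand_residues[("A", label)] = ids
        for sid in ids:
            truth.protodomain_of[("A", sid)] = pd_of[label]
    y_mid = sep / 2
    truth.axes["local_p1_p4"] = (np.array([0.0, 1.0, 0.0]),
                                 np.array([1.5 * s, y_mid, 0.0]))
    truth.axes["local_p2_p3"] = (np.array([0.0, 1.0, 0.0]),
                                 np.array([mirror_x - 1.5 * s, y_mid, 0.0]))
    truth.axes["central"] = (np.array([0.0, 1.0, 0.0]),
                             np.array([3.5 * s, y_mid, 0.0]))
    _finish(structure, spec, truth)
    return structure, truth


def make_dimer(spec: SandwichSpec) -> tuple[StructureModel, GroundTruth]:
    """Two-chain Ig dimer related by an exact quaternary C2.

    ``parallel_dimer``: face-to-face GFCC' packing with both G strands in
    the same direction (quaternary axis along the strand direction).
    ``inverted_dimer``: the 180-degree flipped interface (quaternary axis
    along the lateral sheet direction, tertiary axes collinear: exact D2).
    ``swapped_dimer``: two chains exchanging their DE-FG protodomains
    between two distant domain sites (CD2-style).
    """
    if spec.topology_preset not in DIMER_PRESETS:
        raise SpecError(f"{spec.topology_preset} is not dimeric: "
                        "use make_ig_domain")
    if spec.topology_preset == "swapped_dimer":
        return _make_swapped(spec)
    base_spec = SandwichSpec(
        topology_preset="V_set", strand_length=spec.strand_length,
        rise=spec.rise, strand_spacing=spec.strand_spacing,
        sheet_separation=spec.sheet_separation,
        sequence_mode=spec.effective_sequence_mode)
    dom, base_truth = make_ig_domain(base_spec)
    chain_a = dom.chains[0]
    s, sep = spec.strand_spacing, spec.sheet_separation
    cx = 1.5 * s
    y_mid = sep + spec.dimer_gap / 2.0
    centre = np.array([cx, y_mid, 0.0])
    if spec.topology_preset == "parallel_dimer":
        axis_dir = np.array([0.0, 0.0, 1.0])   # strand direction
    else:
        axis_dir = np.array([1.0, 0.0, 0.0])   # lateral sheet direction
    R = _rot180(axis_dir)

    chain_b = Chain(chain_id="B")
    for res in chain_a:
        atoms = [Atom(a.name, a.element, R @ (a.position - centre) + centre)
                 for a in res.atoms]
        chain_b.residues.append(Residue(res.seq_id, res.insertion_code,
                                        res.name, atoms))
    structure = StructureModel(id=f"synthetic_{spec.topology_preset}",
                               chains=[chain_a, chain_b])
    truth = GroundTruth(preset=spec.topology_preset)
    for (cid, label), ids in base_truth.strand_residues.items():
        truth.strand_residues[("A", label)] = ids
        truth.strand_residues[("B", label)] = ids
        for sid in ids:
            p = base_truth.protodomain_of[(cid, sid)]
            truth.protodomain_of[("A", sid)] = p
            truth.protodomain_of[("B", sid)] = p
    truth.axes["tertiary_A"] = base_truth.axes["tertiary"]
    dir_b, pt_b = base_truth.axes["tertiary"]
    truth.axes["tertiary_B"] = (R @ dir_b, R @ (pt_b - centre) + centre)
    truth.axes["quaternary"] = (axis_dir, centre)
    truth.orientation = ("parallel" if spec.topology_preset == "parallel_dimer"
                         else "inverted")
    truth.residue_map = {r.seq_id: r.seq_id for r in chain_a}
    _finish(structure, spec, truth)
    return structure, truth


def _make_swapped(spec: SandwichSpec) -> tuple[StructureModel, GroundTruth]:
    geoms = {g.label: g for g in _strand_geoms(
        SandwichSpec(topology_preset="V_set",
                     strand_length=spec.strand_length, rise=spec.rise,
                     strand_spacing=spec.strand_spacing,
                     sheet_separation=spec.sheet_separation,
                     sequence_mode=spec.effective_sequence_mode))}

    def site(lbl: str, shift: float) -> _StrandGeom:
        g = geoms[lbl]
        return _StrandGeom(g.label, g.x + shift, g.y, g.direction, g.length,
                           g.z_offset)

    odd, even = ["A", "A'", "B", "C", "C'"], ["D", "E", "F", "G"]
    off = spec.site_offset
    chains = []
    truth = GroundTruth(preset="swapped_dimer", swapped=True)
    for cid, odd_shift, even_shift in (("A", 0.0, off), ("B", off, 0.0)):
        segs = [{"geom": site(l, odd_shift)} for l in odd]
        segs.append({"geom": site(even[0], even_shift),
                     "loop_name": f"{cid}_swap_linker"})
        segs.extend({"geom": site(l, even_shift)} for l in even[1:])
        chain, strand_ids, linkers = _build_chain(cid, segs, spec)
        chains.append(chain)
        truth.linkers.update(linkers)
        for label, ids in strand_ids.items():
            truth.strand_residues[(cid, label)] = ids
            p = 1 if label in _P_ODD else 2
            for sid in ids:
                truth.protodomain_of[(cid, sid)] = p
    structure = StructureModel(id="synthetic_swapped_dimer", chains=chains)
    cx = 1.5 * spec.strand_spacing
    y_mid = spec.sheet_separation / 2
    truth.axes["site1"] = (np.array([0.0, 1.0, 0.0]),
                           np.array([cx, y_mid, 0.0]))
    truth.axes["site2"] = (np.array([0.0, 1.0, 0.0]),
                           np.array([cx + off, y_mid, 0.0]))
    _finish(structure, spec, truth)
    return structure, truth


def _rot180(axis: np.ndarray) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    return 2.0 * np.outer(u, u) - np.eye(3)


def _finish(structure: StructureModel, spec: SandwichSpec,
            truth: GroundTruth) -> None:
    if spec.full_backbone:
        strand_keys: dict[tuple[str, int], int] = {}
        for (cid, label), ids in truth.strand_residues.items():
            phase = 1 if label.startswith("A'") else 0
            for sid in ids:
                strand_keys[(cid, sid)] = phase
        _add_backbone(structure, spec, strand_keys)
    _apply_noise(structure, spec.noise_sigma, spec.seed)
    _check_truth(structure, truth)


def _check_truth(structure: StructureModel, truth: GroundTruth) -> None:
    # construction-time consistency: every ground-truth residue exists
    for (cid, _label), ids in truth.strand_residues.items():
        chain = structure.chain(cid)
        present = {r.seq_id for r in chain}
        missing = set(ids) - present
        assert not missing, f"ground truth references missing residues {missing}"
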