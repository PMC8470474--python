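"""Quaternary analysis of Ig-Ig dimers.

Ig domains dimerize through their sheets -- canonically the GFCC' sheet for
variable domains (VH-VL, CD8aa, VL-VL), the opposite ABED sheet for
constant-domain pairing, and more exotic C''D or A'G/hinge interfaces --
with a quaternary C2 axis relating the two partners.  This module
attributes the interface to a sheet, extracts the quaternary axis by
superposing one domain onto the other under the label-matched
correspondence, classifies the relative orientation (parallel / inverted /
tilted, from the angle between the two G-strand directions), reports the
quasi-D2 geometry (inter-axis angles, centre offset), and detects the
CD2-style protodomain-swapped dimer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import Config, DEFAULT
from .geometry import SymmetryAxis, angle_between_deg, superpose_points, \
    symmetry_axis
from .model import ResidueKey, StructureModel
from .protodomains import decompose, _trim
from .strands import IgAnnotation, Strand

SHEET_GROUPS = {
    "GFCC'": ("G", "F", "C", "C'"),
    "ABED": ("A", "B", "E", "D"),
    "C''D": ("C''", "D"),
    "A'G_hinge": ("A'", "G", "hinge"),
}


@dataclass
class DimerInterface:
    partners: tuple[str, str]                     # chain ids
    contact_residues: dict[str, set[ResidueKey]]  # per chain
    strand_fractions: dict[str, dict[str, float]]  # per chain, per strand
    sheet_attribution: dict[str, str]             # per chain
    n_contacts: int

    @property
    def empty(self) -> bool:
        return self.n_contacts == 0


@dataclass
class DimerGeometry:
    quaternary_axis: Optional[SymmetryAxis]
    orientation: str                              # parallel|inverted|tilted
    tilt_angle: float                             # deg between G directions
    tertiary_axes: dict[str, Optional[SymmetryAxis]]
    d2_report: dict[str, float]
    rmsd: float
    n_pairs: int


@dataclass
class SwapReport:
    swapped: Optional[bool]                       # None = indeterminate
    sequential_closure: dict[str, bool]
    cross_closure: dict[str, bool]
    linkers: dict[str, tuple[ResidueKey, ResidueKey]] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# interface
# ---------------------------------------------------------------------------

def find_interface(structure: StructureModel,
                   annotation_a: IgAnnotation, annotation_b: IgAnnotation,
                   cutoff: Optional[float] = None,
                   config: Config = DEFAULT) -> DimerInterface:
    """Heavy-atom contact interface between two annotated domains.

    Attribution picks the sheet group carrying the majority of the
    strand-resident contacts (>= ``attribution_min_fraction``), testing the
    hinge-mediated A'G group and the C''D group before the two sheets;
    below the majority threshold the interface is "mixed".
    """
    cutoff = config.interface_cutoff if cutoff is None else cutoff
    ca, cb = annotation_a.chain, annotation_b.chain
    atoms_a = _heavy(ca)
    atoms_b = _heavy(cb)
    contacts_a: set[ResidueKey] = set()
    contacts_b: set[ResidueKey] = set()
    pairs = 0
    if len(atoms_a[1]) and len(atoms_b[1]):
        pa, pb = atoms_a[1], atoms_b[1]
        d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
        hit = d2 <= cutoff * cutoff
        pairs = int(hit.sum())
        ia, ib = np.nonzero(hit)
        contacts_a = {atoms_a[0][i] for i in ia}
        contacts_b = {atoms_b[0][i] for i in ib}
    fractions, attribution = {}, {}
    for ann, contacts in ((annotation_a, contacts_a), (annotation_b, contacts_b)):
        cid = ann.chain_id
        frac = _strand_fractions(ann, contacts)
        fractions[cid] = frac
        attribution[cid] = _attribute(frac, config)
    return DimerInterface(
        partners=(annotation_a.chain_id, annotation_b.chain_id),
        contact_residues={annotation_a.chain_id: contacts_a,
                          annotation_b.chain_id: contacts_b},
        strand_fractions=fractions,
        sheet_attribution=attribution,
        n_contacts=pairs,
    )


def _heavy(chain) -> tuple[list[ResidueKey], np.ndarray]:
    keys, pos = [], []
    for r in chain:
        for a in r.heavy_atoms():
            keys.append(r.key)
            pos.append(a.position)
    return keys, (np.array(pos) if pos else np.zeros((0, 3)))


def _strand_fractions(ann: IgAnnotation,
                      contacts: set[ResidueKey]) -> dict[str, float]:
    """Fraction of strand-resident interface contacts per strand label;
    residues past the G strand count as 'hinge'."""
    owner: dict[ResidueKey, str] = {}
    for s in ann.strands:
        if s.label:
            for k in s.residue_keys:
                owner[k] = s.label
    g = ann.strand("G")
    if g is not None:
        keys = [r.key for r in ann.chain]
        after = keys.index(g.residue_keys[-1]) + 1
        for k in keys[after:]:
            owner.setdefault(k, "hinge")
    counts: dict[str, int] = {}
    for k in contacts:
        lbl = owner.get(k)
        if lbl is not None:
            counts[lbl] = counts.get(lbl, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {lbl: n / total for lbl, n in counts.items()}


def _attribute(frac: dict[str, float], config: Config) -> str:
    if not frac:
        return "mixed"
    for group in ("A'G_hinge", "C''D"):
        members = SHEET_GROUPS[group]
        share = sum(frac.get(m, 0.0) for m in members)
        # these narrow interfaces need their defining minor strand present
        anchor = "hinge" if group == "A'G_hinge" else "C''"
        if share >= config.attribution_min_fraction and frac.get(anchor, 0) > 0:
            return group
    shares = {g: sum(frac.get(m, 0.0) for m in SHEET_GROUPS[g])
              for g in ("GFCC'", "ABED")}
    top = max(shares, key=shares.get)
    if shares[top] >= config.attribution_min_fraction:
        return top
    return "mixed"


# ---------------------------------------------------------------------------
# quaternary axis and orientation
# ---------------------------------------------------------------------------

def quaternary_axis_and_orientation(
        annotation_a: IgAnnotation, annotation_b: IgAnnotation,
        config: Config = DEFAULT) -> DimerGeometry:
    """Quaternary C2 from the label-matched cross-domain superposition,
    orientation from the G-strand directions, plus the quasi-D2 report."""
    # cross-domain correspondence: same strand label onto same strand label
    pos_a, pos_b = [], []
    common = sorted(set(annotation_a.labelled) & set(annotation_b.labelled))
    for lbl in common:
        sa, sb = annotation_a.strand(lbl), annotation_b.strand(lbl)
        na, nb = len(sa), len(sb)
        if na >= nb:
            s, e = _trim(na, nb)
            pa, pb = sa.positions[s:e], sb.positions
        else:
            s, e = _trim(nb, na)
            pa, pb = sa.positions, sb.positions[s:e]
        pos_a.append(pa)
        pos_b.append(pb)
    quaternary = None
    rmsd, n_pairs = float("nan"), 0
    if pos_a:
        P, Q = np.vstack(pos_a), np.vstack(pos_b)
        sp = superpose_points(P, Q)
        rmsd, n_pairs = sp.rmsd, sp.n_pairs
        quaternary = symmetry_axis(sp, (P.mean(axis=0), Q.mean(axis=0)),
                                   config.c2_tolerance_deg)

    # orientation from the two G-strand N->C direction vectors
    ga, gb = annotation_a.strand("G"), annotation_b.strand("G")
    if ga is not None and gb is not None:
        tilt = angle_between_deg(ga.direction, gb.direction)
    else:  # fall back on F (always present in an Ig core)
        tilt = angle_between_deg(annotation_a.strand("F").direction,
                                 annotation_b.strand("F").direction)
    if tilt < config.orientation_parallel_max_deg:
        orientation = "parallel"
    elif tilt > config.orientation_inverted_min_deg:
        orientation = "inverted"
    else:
        orientation = "tilted"

    tertiary: dict[str, Optional[SymmetryAxis]] = {}
    for ann in (annotation_a, annotation_b):
        try:
            from .protodomains import analyse_protodomains
            tertiary[ann.chain_id] = analyse_protodomains(
                ann, config=config)["axis"]
        except Exception as exc:  # heterodimer halves may not decompose
            tertiary[ann.chain_id] = None

    d2: dict[str, float] = {}
    ta = tertiary.get(annotation_a.chain_id)
    tb = tertiary.get(annotation_b.chain_id)
    if ta is not None and tb is not None:
        d2["angle_tertiary_tertiary"] = ta.angle_to(tb)
        if quaternary is not None:
            d2["angle_tertiary_A_quaternary"] = ta.angle_to(quaternary)
            d2["angle_tertiary_B_quaternary"] = tb.angle_to(quaternary)
            # how far each tertiary axis misses the quaternary axis: zero
            # when all three C2 axes concur (ideal quasi-D2)
            d2["center_offset"] = max(_line_line_distance(ta, quaternary),
                                      _line_line_distance(tb, quaternary))
    return DimerGeometry(
        quaternary_axis=quaternary,
        orientation=orientation,
        tilt_angle=tilt,
        tertiary_axes=tertiary,
        d2_report=d2,
        rmsd=rmsd,
        n_pairs=n_pairs,
    )


def _line_line_distance(a: SymmetryAxis, b: SymmetryAxis) -> float:
    """Shortest distance between two axis lines."""
    cross = np.cross(a.direction, b.direction)
    norm = np.linalg.norm(cross)
    if norm < 1e-9:  # parallel: point-to-line distance
        return a.distance_to_point(b.point)
    return float(abs(np.dot(b.point - a.point, cross / norm)))


# ---------------------------------------------------------------------------
# protodomain swap
# ---------------------------------------------------------------------------

def _split_units(structure: StructureModel, chain_id: str,
                 config: Config) -> Optional[tuple[list[Strand], list[Strand],
                                                   tuple[ResidueKey, ResidueKey]]]:
    """Split one chain's strands into its two protodomain units at the
    largest inter-strand sequence gap (each unit needs >= 2 strands)."""
    from .strands import detect_strands
    strands, _sm = detect_strands(structure, chain_id, config=config)
    if len(strands) < 4:
        return None
    chain = structure.chain(chain_id)
    keys = [r.key for r in chain]

    def gap(i: int) -> int:
        return (keys.index(strands[i + 1].residue_keys[0])
                - keys.index(strands[i].residue_keys[-1]) - 1)

    order = sorted(range(len(strands) - 1), key=gap, reverse=True)
    for cut in order:
        u1, u2 = strands[:cut + 1], strands[cut + 1:]
        if len(u1) >= 2 and len(u2) >= 2:
            i0 = keys.index(u1[-1].residue_keys[-1]) + 1
            i1 = keys.index(u2[0].residue_keys[0]) - 1
            link = (keys[i0], keys[i1]) if i0 <= i1 else (keys[i0 - 1],
                                                          keys[i0 - 1])
            return u1, u2, link
    return None


def _closes(u: list[Strand], v: list[Strand], config: Config) -> bool:
    """Domain closure of two protodomain units: spatial compactness plus an
    internal C2 between positionally paired strands."""
    cu = np.vstack([s.positions for s in u]).mean(axis=0)
    cv = np.vstack([s.positions for s in v]).mean(axis=0)
    if np.linalg.norm(cu - cv) > config.closure_centroid_max:
        return False
    from .topology import _pd_superpose
    try:
        sp, _P, _Q = _pd_superpose(u, v)
    except Exception:
        return False
    from .geometry import rotation_angle_deg
    ang = rotation_angle_deg(sp.rotation)
    return sp.rmsd <= 3.0 and ang >= 180.0 - config.c2_tolerance_deg


def detect_protodomain_swap(structure: StructureModel,
                            chain_a: str, chain_b: str,
                            config: Config = DEFAULT) -> SwapReport:
    """CD2-style swap: the spatial Ig domains pair p_odd of one chain with
    p_even of the other, while each chain's own units fail domain closure."""
    diags: list[str] = []
    # a chain that annotates as a complete single Ig closes on itself
    from .strands import detect_strands, label_ig_strands
    whole = {}
    for cid in (chain_a, chain_b):
        strands, sm = detect_strands(structure, cid, config=config)
        ann = label_ig_strands(strands, sm, structure.chain(cid),
                               config=config)
        whole[cid] = ann.ig_like
    if whole[chain_a] and whole[chain_b]:
        diags.append("each chain folds as a complete single Ig domain")
        return SwapReport(False,
                          {chain_a: True, chain_b: True}, {}, {}, diags)
    ua = _split_units(structure, chain_a, config)
    ub = _split_units(structure, chain_b, config)
    if ua is None or ub is None:
        diags.append("could not split both chains into protodomain units")
        return SwapReport(None, {}, {}, diagnostics=diags)
    (a1, a2, la), (b1, b2, lb) = ua, ub
    linkers = {chain_a: la, chain_b: lb}
    seq = {chain_a: _closes(a1, a2, config), chain_b: _closes(b1, b2, config)}
    cross = {f"{chain_a}odd+{chain_b}even": _closes(a1, b2, config),
             f"{chain_b}odd+{chain_a}even": _closes(b1, a2, config)}
    if seq[chain_a] and seq[chain_b]:
        return SwapReport(False, seq, cross, linkers, diags)
    if all(cross.values()) and not any(seq.values()):
        diags.append("both cross pairs close as Ig domains; sequential pairs "
                     "do not: protodomain-swapped dimer")
        return SwapReport(True, seq, cross, linkers, diags)
    diags.append(f"closure pattern ambiguous: sequential={seq}, cross={cross}")
    return SwapReport(None, seq, cross, linkers, diags)
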