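"""Topology classification of Ig(-like) domains.

The classifier turns a labelled strand annotation into one of the canonical
topology classes using strand-presence rules, applied in a fixed order:

1. C'' present -> V-set (the C'' strand is unique to the V-set).
2. no C'', short C' (<= 3 residues) and a split A/A' -> I-set
   (VNAR-like is reported only via an optional heuristic flag).
3. no C', A entirely on the ABED sheet -> C1-set.
4. no C', A only on the A'/GFC sheet -> cadherin.
5. no D, A on the A/BE sheet -> C2-set or FN3, discriminated by the
   CCW(L) sequence signature (>= 3 of 4 strict hits -> C2-set), because the
   two topologies are structurally identical.
6. otherwise (core straddle absent) -> not Ig.

The CD19-style double Ig fold -- four protodomains in two parallel-linked
pairs, interdigitated through an inverter segment into two composite
domains with fused beta sheets, one of them an inverse Ig (circular
permutation realised by folding) -- is detected separately on chains with
enough strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import Config, DEFAULT
from .geometry import SymmetryAxis, angle_between_deg, superpose_points
from .model import Chain, ResidueKey, StructureModel
from .protodomains import Protodomain, protodomain_axis
from .strands import IgAnnotation, SheetModel, Strand, detect_strands, \
    label_ig_strands

TOPOLOGY_LABELS = ("V_set", "C1_set", "C2_set", "I_set", "VNAR_like", "FN3",
                   "cadherin", "double_Ig", "inverse_Ig", "not_Ig")


@dataclass
class TopologyClass:
    label: str
    rule_trace: list[str] = field(default_factory=list)
    notes: str = ""

    def __post_init__(self) -> None:
        assert self.label in TOPOLOGY_LABELS


@dataclass
class SignatureHit:
    """CCW(L): cysteines on strands B and F (the intra-domain disulfide),
    tryptophan on C, leucine (conservatively I/V/M) on E."""
    positions: dict[str, Optional[ResidueKey]]
    strict: dict[str, bool]
    complete: bool

    @property
    def n_strict(self) -> int:
        return sum(self.strict.values())


@dataclass
class DoubleIgModel:
    protodomains: list[Protodomain]              # p1..p4 in sequence order
    parallel_pairs: list[tuple[int, int]]        # (1,2), (3,4)
    parallel_linkers: dict[str, tuple[ResidueKey, ResidueKey]]
    inverter: tuple[ResidueKey, ResidueKey]
    inverter_length: int
    composite_regular: tuple[int, int]           # odd-type member first
    composite_inverse: tuple[int, int]
    fused_ladders: dict[str, int]                # "C'|C'" and "D|D" pair counts
    axes: dict[str, Optional[SymmetryAxis]]      # local + central C2
    rmsds: dict[str, float]
    diagnostics: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# CCW(L) signature
# ---------------------------------------------------------------------------

_SIGNATURE = {"B": ("C", ()), "C": ("W", ()), "E": ("L", ("I", "V", "M")),
              "F": ("C", ())}


def detect_ccwl(annotation: IgAnnotation) -> SignatureHit:
    """Search strands B, C, E, F (plus one flanking residue) for the CCW(L)
    residues; fallback matches (I/V/M for L) are recorded as non-strict."""
    positions: dict[str, Optional[ResidueKey]] = {}
    strict: dict[str, bool] = {}
    chain_keys = [r.key for r in annotation.chain]
    for strand_label, (target, fallbacks) in _SIGNATURE.items():
        name = f"{target}_in_{strand_label}"
        positions[name], strict[name] = None, False
        s = annotation.strand(strand_label)
        if s is None:
            continue
        try:
            i0 = chain_keys.index(s.residue_keys[0])
            i1 = chain_keys.index(s.residue_keys[-1])
        except ValueError:
            continue
        window = annotation.chain.residues[max(0, i0 - 1):i1 + 2]
        # prefer the hit nearest the strand centre
        centre = (i0 + i1) / 2.0
        best, best_d, best_strict = None, None, False
        for off, r in enumerate(window, start=max(0, i0 - 1)):
            if r.one_letter == target or r.one_letter in fallbacks:
                d = abs(off - centre)
                if best_d is None or d < best_d or \
                        (r.one_letter == target and not best_strict):
                    best, best_d = r.key, d
                    best_strict = r.one_letter == target
        positions[name] = best
        strict[name] = best_strict
    complete = all(strict.values())
    return SignatureHit(positions=positions, strict=strict, complete=complete)


# ---------------------------------------------------------------------------
# single-domain classification
# ---------------------------------------------------------------------------

def classify_topology(annotation: IgAnnotation,
                      config: Config = DEFAULT,
                      vnar_heuristic: bool = False) -> TopologyClass:
    """Strand-presence rules, in fixed order (total over annotations)."""
    trace: list[str] = []
    if not annotation.ig_like:
        trace.append("core BC/EF straddle absent -> not_Ig")
        return TopologyClass("not_Ig", trace)

    has = annotation.has
    trace.append(f"strands: {sorted(annotation.labelled)}")
    if not has("G"):
        # B, C, E, F and G are required for any Ig class
        trace.append("no G strand -> not_Ig")
        return TopologyClass("not_Ig", trace)

    if has("C''"):
        trace.append("rule 1: C'' present -> V_set")
        return TopologyClass("V_set", trace)
    trace.append("rule 1: no C''")

    c_prime = annotation.strand("C'")
    if c_prime is not None and len(c_prime) <= config.short_c_prime_max \
            and annotation.a_split:
        trace.append(f"rule 2: short C' ({len(c_prime)} residues) and split "
                     "A/A' -> I_set")
        if vnar_heuristic and _hydrophilic_sheet_b(annotation):
            trace.append("heuristic: hydrophilic outward face on sheet B -> "
                         "VNAR_like (heuristic flag, biology not decidable "
                         "from geometry)")
            return TopologyClass("VNAR_like", trace)
        return TopologyClass("I_set", trace)
    trace.append("rule 2: not I-set "
                 f"(C' len {len(c_prime) if c_prime else 'absent'}, "
                 f"a_split={annotation.a_split})")

    if c_prime is None:
        if "A" in annotation.sheet_A:
            trace.append("rule 3: no C', A on the A|BED sheet -> C1_set")
            return TopologyClass("C1_set", trace)
        if "A'" in annotation.sheet_B or "A" in annotation.sheet_B:
            trace.append("rule 4: no C', A only on the A'|GFC sheet -> cadherin")
            return TopologyClass("cadherin", trace)
        trace.append("rules 3-4: no C' and no A strand at all")
    else:
        trace.append("rules 3-4: C' present")

    if not has("D"):
        sig = detect_ccwl(annotation)
        if sig.n_strict >= config.ccwl_strict_min:
            trace.append(f"rule 5: no D, CCW(L) {sig.n_strict}/4 strict -> C2_set")
            return TopologyClass("C2_set", trace)
        trace.append(f"rule 5: no D, CCW(L) {sig.n_strict}/4 strict -> FN3")
        return TopologyClass("FN3", trace)
    trace.append("rule 5: D present")

    trace.append("no rule fired -> not_Ig")
    return TopologyClass("not_Ig", trace,
                         notes="core present but lateral strands match no class")


def _hydrophilic_sheet_b(annotation: IgAnnotation) -> bool:
    """Optional VNAR heuristic: outward-facing positions of the GF|CC' sheet
    more hydrophilic than hydrophobic."""
    polar = set("DEKRNQSTH")
    count = total = 0
    for label in annotation.sheet_B:
        for aa in annotation.sequence_of(label):
            total += 1
            if aa in polar:
                count += 1
    return total > 0 and count / total > 0.5


# ---------------------------------------------------------------------------
# double-Ig detection
# ---------------------------------------------------------------------------

def _seq_gap(chain: Chain, s1: Strand, s2: Strand) -> int:
    """Number of chain residues strictly between two strands."""
    keys = [r.key for r in chain]
    return keys.index(s2.residue_keys[0]) - keys.index(s1.residue_keys[-1]) - 1


def _unit_protodomain(index: int, strands: list[Strand],
                      chain_id: str) -> Protodomain:
    labels = [s.label or f"s{s.index}" for s in strands]
    return Protodomain(index, labels, strands, chain_id)


def _pd_superpose(u: list[Strand], v: list[Strand]):
    """Superpose the last three strands of two protodomain units, paired
    positionally (B<->E, C<->F, C'<->G) with centre trimming."""
    from .protodomains import _trim
    pos_u, pos_v = [], []
    for su, sv in zip(u[-3:], v[-3:]):
        nu, nv = len(su), len(sv)
        if nu >= nv:
            a, b = _trim(nu, nv)
            pu, pv = su.positions[a:b], sv.positions
        else:
            a, b = _trim(nv, nu)
            pu, pv = su.positions, sv.positions[a:b]
        pos_u.append(pu)
        pos_v.append(pv)
    P, Q = np.vstack(pos_u), np.vstack(pos_v)
    return superpose_points(P, Q), P, Q


def detect_double_ig(structure: StructureModel, chain_id: str,
                     config: Config = DEFAULT,
                     detection: Optional[tuple[list[Strand], SheetModel]] = None
                     ) -> tuple[Optional[DoubleIgModel], list[str]]:
    """Detect the interdigitated double Ig architecture on one chain.

    Evidence required: (a) two protodomain pairs each joined by a short
    linker leaving them parallel (B-vs-E strand directions < 90 deg);
    (b) a long inverter segment separating the pairs; (c) lateral ladders
    fusing the C'|C' and D|D strands of the two halves.  Partial evidence
    returns ``None`` plus diagnostics listing what failed.
    """
    diags: list[str] = []
    chain = structure.chain(chain_id)
    if detection is None:
        detection = detect_strands(structure, chain_id, config=config)
    strands, sm = detection
    if len(strands) < 12:
        diags.append(f"only {len(strands)} strands; a double Ig has ~16")
        return None, diags

    # split at the inverter: the largest sequence gap between consecutive
    # strands, which must exceed the inverter threshold
    gaps = [_seq_gap(chain, strands[i], strands[i + 1])
            for i in range(len(strands) - 1)]
    inv_at = int(np.argmax(gaps))
    if gaps[inv_at] <= config.inverter_min:
        diags.append(f"(b) largest inter-strand gap {gaps[inv_at]} residues "
                     f"<= inverter threshold {config.inverter_min}")
        return None, diags
    half1, half2 = strands[:inv_at + 1], strands[inv_at + 1:]
    if len(half1) < 6 or len(half2) < 6:
        diags.append(f"uneven halves around the inverter "
                     f"({len(half1)}/{len(half2)} strands)")
        return None, diags

    units: list[list[Strand]] = []
    linkers: dict[str, tuple[ResidueKey, ResidueKey]] = {}
    ok_parallel = True
    for h, half in enumerate((half1, half2), start=1):
        mid = len(half) // 2
        u1, u2 = half[:mid], half[mid:]
        gap = _seq_gap(chain, u1[-1], u2[0])
        if gap > config.short_linker_max:
            diags.append(f"(a) half {h}: protodomain linker {gap} residues > "
                         f"{config.short_linker_max}")
            ok_parallel = False
        keys = [r.key for r in chain]
        i0 = keys.index(u1[-1].residue_keys[-1]) + 1
        i1 = keys.index(u2[0].residue_keys[0]) - 1
        if i0 <= i1:
            linkers[f"p{2*h-1}-p{2*h}"] = (keys[i0], keys[i1])
        ang = angle_between_deg(u1[-3].direction, u2[-3].direction)
        if ang >= config.parallel_angle_max_deg:
            diags.append(f"(a) half {h}: B-vs-E directions at {ang:.0f} deg "
                         "(not parallel)")
            ok_parallel = False
        units.extend([u1, u2])
    if not ok_parallel:
        return None, diags

    # (c) fused lateral ladders: C'(p1)|C'(p3) and D(p2)|D(p4)
    lad_cc = sm.ladder_between(units[0][-1].index, units[2][-1].index)
    lad_dd = sm.ladder_between(units[1][0].index, units[3][0].index)
    fused = {}
    for name, lad in (("C'|C'", lad_cc), ("D|D", lad_dd)):
        n = len(lad.pairs) if lad else 0
        fused[name] = n
        if n < 2:
            diags.append(f"(c) fused-sheet ladder {name}: {n} pairs (< 2)")
    if any(v < 2 for v in fused.values()):
        return None, diags

    pds = [_unit_protodomain(i + 1, u, chain_id) for i, u in enumerate(units)]

    # composite pairing by compactness; the two parallel pairs (1,2), (3,4)
    # are excluded
    d14 = float(np.linalg.norm(pds[0].centroid - pds[3].centroid))
    d23 = float(np.linalg.norm(pds[1].centroid - pds[2].centroid))
    d13 = float(np.linalg.norm(pds[0].centroid - pds[2].centroid))
    d24 = float(np.linalg.norm(pds[1].centroid - pds[3].centroid))
    if d14 + d23 <= d13 + d24:
        composites = [(1, 4), (2, 3)]
    else:
        composites = [(1, 3), (2, 4)]
        diags.append("unexpected composite pairing (p1+p3 / p2+p4)")

    # odd-type member of a composite: contributes 3 strands to its larger
    # sheet (A'CC' side) and 1 to the BED side; even-type contributes 2+2
    def odd_first(pair: tuple[int, int]) -> tuple[int, int]:
        a, b = pair
        sheets_a = [s.sheet_id for s in units[a - 1]]
        counts = sorted(sheets_a.count(x) for x in set(sheets_a))
        return (a, b) if counts[-1] >= 3 else (b, a)

    comp = [odd_first(p) for p in composites]
    # inverse composite: its DE-FG (even-type) member precedes the AB-CC'
    # member in sequence
    regular = [c for c in comp if c[0] < c[1]]
    inverse = [c for c in comp if c[0] > c[1]]
    if len(regular) != 1 or len(inverse) != 1:
        diags.append(f"composite typing ambiguous: {comp}")
        return None, diags

    # canonical labels, suffixed by composite-domain membership
    comp_of = {}
    for n, (odd, even) in enumerate(comp, start=1):
        comp_of[odd] = (n, ("A'", "B", "C", "C'"))
        comp_of[even] = (n, ("D", "E", "F", "G"))
    for u, unit in enumerate(units, start=1):
        suffix, names = comp_of[u]
        if len(unit) == len(names):
            for s, name in zip(unit, names):
                if s.label is None:
                    s.label = f"{name}{suffix}"

    axes: dict[str, Optional[SymmetryAxis]] = {}
    rmsds: dict[str, float] = {}
    for name, (odd, even) in (("local_" + "p%dp%d" % tuple(sorted(regular[0])),
                               regular[0]),
                              ("local_" + "p%dp%d" % tuple(sorted(inverse[0])),
                               inverse[0])):
        sp, P, Q = _pd_superpose(units[odd - 1], units[even - 1])
        rmsds[name] = sp.rmsd
        axes[name] = protodomain_axis(sp, pds[odd - 1], pds[even - 1], config)
    # central C2: maps half 1 onto half 2 (p1->p3, p2->p4 strand-wise)
    sp_c, P, Q = _central_superpose(units)
    rmsds["central"] = sp_c.rmsd
    c1 = np.vstack([pds[0].positions, pds[1].positions]).mean(axis=0)
    c2 = np.vstack([pds[2].positions, pds[3].positions]).mean(axis=0)
    from .geometry import symmetry_axis as _sym_axis
    axes["central"] = _sym_axis(sp_c, (c1, c2), config.c2_tolerance_deg)

    keys = [r.key for r in chain]
    inv0 = keys.index(units[1][-1].residue_keys[-1]) + 1
    inv1 = keys.index(units[2][0].residue_keys[0]) - 1
    model = DoubleIgModel(
        protodomains=pds,
        parallel_pairs=[(1, 2), (3, 4)],
        parallel_linkers=linkers,
        inverter=(keys[inv0], keys[inv1]),
        inverter_length=inv1 - inv0 + 1,
        composite_regular=regular[0],
        composite_inverse=inverse[0],
        fused_ladders=fused,
        axes=axes,
        rmsds=rmsds,
        diagnostics=diags,
    )
    return model, diags


def _central_superpose(units: list[list[Strand]]):
    """Half 1 (p1+p2) onto half 2 (p3+p4): strand k of p1 pairs strand k of
    p3, strand k of p2 pairs strand k of p4."""
    from .protodomains import _trim
    pos_u, pos_v = [], []
    for a, b in ((0, 2), (1, 3)):
        for su, sv in zip(units[a], units[b]):
            nu, nv = len(su), len(sv)
            if nu >= nv:
                s, e = _trim(nu, nv)
                pu, pv = su.positions[s:e], sv.positions
            else:
                s, e = _trim(nv, nu)
                pu, pv = su.positions, sv.positions[s:e]
            pos_u.append(pu)
            pos_v.append(pv)
    P, Q = np.vstack(pos_u), np.vstack(pos_v)
    return superpose_points(P, Q), P, Q


def align_protodomain_groups(units: list[list[Strand]],
                             group1: list[int], group2: list[int]):
    """Superpose arbitrary protodomain groups (1-based indices), pairing
    strands positionally in group order; exposes both composite-domain
    groupings of a double Ig."""
    from .protodomains import _trim
    pos_u, pos_v = [], []
    for a, b in zip(group1, group2):
        for su, sv in zip(units[a - 1][-3:], units[b - 1][-3:]):
            nu, nv = len(su), len(sv)
            if nu >= nv:
                s, e = _trim(nu, nv)
                pu, pv = su.positions[s:e], sv.positions
            else:
                s, e = _trim(nv, nu)
                pu, pv = su.positions, sv.positions[s:e]
            pos_u.append(pu)
            pos_v.append(pv)
    return superpose_points(np.vstack(pos_u), np.vstack(pos_v))


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    topology: TopologyClass
    annotation: Optional[IgAnnotation]
    signature: Optional[SignatureHit]
    double_ig: Optional[DoubleIgModel]


def classify_structure(structure: StructureModel, chain_id: str,
                       mode: str = "ca_only",
                       override: Optional[dict] = None,
                       config: Config = DEFAULT) -> ClassificationResult:
    """Full single-chain classification: strand detection, double-Ig check
    for strand-rich chains, otherwise canonical labelling + rules."""
    strands, sm = detect_strands(structure, chain_id, mode=mode, config=config)
    chain = structure.chain(chain_id)
    if len(strands) >= 12:
        model, diags = detect_double_ig(structure, chain_id, config=config,
                                        detection=(strands, sm))
        if model is not None:
            trace = [f"{len(strands)} strands on one chain",
                     "double-Ig evidence (a) parallel protodomain pairs, "
                     "(b) inverter segment "
                     f"({model.inverter_length} residues), "
                     f"(c) fused ladders {model.fused_ladders}",
                     f"composite {model.composite_inverse} is an inverse Ig"]
            ann = IgAnnotation(chain_id=chain_id, strands=strands,
                               sheet_model=sm, chain=chain, ig_like=False,
                               diagnostics=["double-Ig chain; strand labels "
                                            "carry composite-domain suffixes"])
            return ClassificationResult(
                TopologyClass("double_Ig", trace), ann, None, model)
    ann = label_ig_strands(strands, sm, chain, override=override,
                           config=config)
    topo = classify_topology(ann, config=config)
    sig = detect_ccwl(ann) if ann.ig_like else None
    return ClassificationResult(topo, ann, sig, None)
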