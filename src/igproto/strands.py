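"""Beta-strand and sheet detection, and canonical Ig strand labelling.

The Ig fold is a two-sheet beta sandwich whose strands carry conventional
labels A, A', B, C, C', C'', D, E, F, G in N-to-C order.  Detection is
geometric: strands are maximal extended runs of residues that participate in
at least one inter-strand ladder; sheets are connected components of the
strand-adjacency (ladder) graph.  Labelling is anchored on the invariant
core -- the four mutually laddered strands B, C, E, F whose BC and EF
connections straddle the two sheets -- and assigns the lateral strands by
sequence position and sheet membership.  Sequence motifs play no role, so
the same rules label synthetic idealized sandwiches and divergent natural
sequences alike.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import Config, DEFAULT
from .geometry import angle_between_deg, strand_direction
from .model import AnnotationError, CaTrace, Chain, ResidueKey, StructureModel

STRAND_LABELS = ("A", "A'", "B", "C", "C'", "C''", "D", "E", "F", "G")


@dataclass
class Strand:
    index: int                       # N->C order among detected strands
    residue_keys: list[ResidueKey]
    positions: np.ndarray            # (n, 3) C-alpha coordinates
    sheet_id: str = ""
    label: Optional[str] = None

    def __len__(self) -> int:
        return len(self.residue_keys)

    @property
    def direction(self) -> np.ndarray:
        return strand_direction(self.positions)

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass
class Ladder:
    strand_i: int
    strand_j: int
    pairs: list[tuple[ResidueKey, ResidueKey]]
    orientation: str                 # "parallel" | "antiparallel"


@dataclass
class SheetModel:
    sheets: dict[str, list[int]] = field(default_factory=dict)  # lateral order
    ladders: list[Ladder] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    def ladder_between(self, i: int, j: int) -> Optional[Ladder]:
        for lad in self.ladders:
            if {lad.strand_i, lad.strand_j} == {i, j}:
                return lad
        return None

    def neighbours(self, i: int) -> list[int]:
        out = []
        for lad in self.ladders:
            if lad.strand_i == i:
                out.append(lad.strand_j)
            elif lad.strand_j == i:
                out.append(lad.strand_i)
        return sorted(set(out))

    def sheet_of(self, strand_index: int) -> Optional[str]:
        for sid, members in self.sheets.items():
            if strand_index in members:
                return sid
        return None


@dataclass
class IgAnnotation:
    """Canonical Ig labelling of one chain's strands."""

    chain_id: str
    strands: list[Strand]            # all detected strands (some labelled)
    sheet_model: SheetModel
    chain: Chain                     # for sequences and loop intervals
    sheet_A: set[str] = field(default_factory=set)   # ABED-side labels
    sheet_B: set[str] = field(default_factory=set)   # A'GFCC'C''-side labels
    loops: dict[str, tuple[ResidueKey, ResidueKey]] = field(default_factory=dict)
    a_split: bool = False
    hinge: Optional[ResidueKey] = None
    ig_like: bool = True
    diagnostics: list[str] = field(default_factory=list)

    def strand(self, label: str) -> Optional[Strand]:
        for s in self.strands:
            if s.label == label:
                return s
        return None

    def has(self, label: str) -> bool:
        return self.strand(label) is not None

    def sequence_of(self, label: str) -> str:
        s = self.strand(label)
        if s is None:
            return ""
        out = []
        for key in s.residue_keys:
            r = self.chain.residue(key)
            out.append(r.one_letter if r else "X")
        return "".join(out)

    @property
    def labelled(self) -> dict[str, Strand]:
        return {s.label: s for s in self.strands if s.label}


# ---------------------------------------------------------------------------
# strand detection
# ---------------------------------------------------------------------------

def _extended_runs(trace: CaTrace, cfg: Config) -> list[tuple[int, int]]:
    """Maximal extended runs as (start, end) inclusive trace indices."""
    pos = trace.positions
    n = len(pos)
    if n == 0:
        return []
    bond_ok = np.zeros(max(n - 1, 0), bool)
    for i in range(n - 1):
        # numbering gaps (missing residues) always break a run
        if trace.residue_keys[i + 1][0] - trace.residue_keys[i][0] > 1:
            continue
        d = np.linalg.norm(pos[i + 1] - pos[i])
        bond_ok[i] = cfg.extended_bond_min <= d <= cfg.extended_bond_max
    corner = np.zeros(n, bool)
    for i in range(1, n - 1):
        if bond_ok[i - 1] and bond_ok[i]:
            a = angle_between_deg(pos[i] - pos[i - 1], pos[i + 1] - pos[i])
            corner[i] = a > cfg.bend_max_deg
    runs: list[tuple[int, int]] = []
    start = 0
    for i in range(n):
        if corner[i]:
            # a sharp corner is isolated as its own (unusable) run
            if start < i:
                runs.append((start, i - 1))
            runs.append((i, i))
            start = i + 1
        elif (i == n - 1) or (not bond_ok[i]):
            runs.append((start, i))
            start = i + 1
    return [r for r in runs if r[1] >= r[0]]


def _merge_bulges(runs: list[tuple[int, int]], trace: CaTrace,
                  cfg: Config) -> list[tuple[int, int]]:
    """One-residue interruptions inside a ladder do not break a strand."""
    if not cfg.bulge_tolerance:
        return runs
    merged = list(runs)
    changed = True
    while changed:
        changed = False
        for k in range(len(merged) - 2):
            a, b, c = merged[k], merged[k + 1], merged[k + 2]
            if b[1] - b[0] == 0 and a[1] + 1 == b[0] and b[1] + 1 == c[0] \
                    and a[1] - a[0] >= 1 and c[1] - c[0] >= 1:
                da = strand_direction(trace.positions[a[0]:a[1] + 1])
                dc = strand_direction(trace.positions[c[0]:c[1] + 1])
                if angle_between_deg(da, dc) < cfg.bend_max_deg:
                    merged[k:k + 3] = [(a[0], c[1])]
                    changed = True
                    break
    return merged


def _ladder_ca(trace: CaTrace, u: tuple[int, int], v: tuple[int, int],
               cfg: Config) -> Optional[tuple[list[tuple[int, int]], str]]:
    """Ca-only ladder between two runs: matched index pairs + orientation."""
    pos = trace.positions
    cand: list[tuple[int, int]] = []
    for i in range(u[0], u[1] + 1):
        d = np.linalg.norm(pos[v[0]:v[1] + 1] - pos[i], axis=1)
        j = int(np.argmin(d))
        if d[j] <= cfg.ca_ladder_max:
            cand.append((i, v[0] + j))
    if len(cand) < cfg.min_ladder_pairs:
        return None
    # heal single-rung gaps: a register (i,j),(i+2,j+-2) with the middle
    # rung jittered past the cutoff keeps the ladder if the middle pair
    # fits at the relaxed distance (real sheets bulge the same way)
    relaxed = cfg.ca_ladder_max * cfg.ladder_extend_factor
    healed: list[tuple[int, int]] = []
    for k, (i0, j0) in enumerate(cand):
        healed.append((i0, j0))
        if k + 1 < len(cand):
            i1, j1 = cand[k + 1]
            if i1 - i0 == 2 and abs(j1 - j0) == 2:
                s = (j1 - j0) // 2
                if np.linalg.norm(pos[i0 + 1] - pos[j0 + s]) <= relaxed:
                    healed.append((i0 + 1, j0 + s))
    cand = healed
    # longest streak of consistent register (j steps +-1 as i steps +1)
    best: list[tuple[int, int]] = []
    for sign in (+1, -1):
        streak = [cand[0]]
        for (i0, j0), (i1, j1) in zip(cand, cand[1:]):
            if i1 - i0 == 1 and j1 - j0 == sign:
                streak.append((i1, j1))
            else:
                if len(streak) > len(best):
                    best = streak
                streak = [(i1, j1)]
        if len(streak) > len(best):
            best = streak
    if len(best) < cfg.min_ladder_pairs:
        return None
    sign = 1 if best[1][1] > best[0][1] else -1
    # continue the register at both ends with a relaxed cutoff: genuine
    # terminal rungs jitter past the strict cutoff, but stay on register
    i0, j0 = best[0]
    while i0 - 1 >= u[0] and v[0] <= j0 - sign <= v[1]:
        if np.linalg.norm(pos[i0 - 1] - pos[j0 - sign]) > relaxed:
            break
        i0, j0 = i0 - 1, j0 - sign
        best.insert(0, (i0, j0))
    i1, j1 = best[-1]
    while i1 + 1 <= u[1] and v[0] <= j1 + sign <= v[1]:
        if np.linalg.norm(pos[i1 + 1] - pos[j1 + sign]) > relaxed:
            break
        i1, j1 = i1 + 1, j1 + sign
        best.append((i1, j1))
    orient = "parallel" if sign > 0 else "antiparallel"
    return best, orient


def _hbond_pairs(chain: Chain, trace: CaTrace, u: tuple[int, int],
                 v: tuple[int, int], cfg: Config) -> list[tuple[int, int]]:
    """Residue index pairs linked by a geometric backbone H-bond."""

    def atoms(i: int):
        r = chain.residue(trace.residue_keys[i])
        if r is None:
            return None, None, None
        get = lambda nm: (r.atom(nm).position if r.atom(nm) else None)
        return get("N"), get("O"), get("CA")

    def h_estimate(i: int):
        n, _, ca = atoms(i)
        if n is None or ca is None:
            return None
        prev = chain.residue(trace.residue_keys[i - 1]) if i > 0 else None
        cprev = prev.atom("C").position if prev and prev.atom("C") else None
        if cprev is None:
            return None
        d = 2 * n - ca - cprev  # direction away from the CA/C(i-1) bisector
        nn = np.linalg.norm(d)
        return n + d / nn if nn > 1e-6 else None

    def bonded(i: int, j: int) -> bool:
        for don, acc in ((i, j), (j, i)):
            n, _, _ = atoms(don)
            _, o, _ = atoms(acc)
            if n is None or o is None:
                continue
            if np.linalg.norm(n - o) > cfg.hbond_no_max:
                continue
            h = h_estimate(don)
            if h is None:
                return True  # chain terminus: accept on distance alone
            ang = angle_between_deg(n - h, o - h)
            if ang >= cfg.hbond_donor_angle_min:
                return True
        return False

    pos = trace.positions
    out = []
    for i in range(u[0], u[1] + 1):
        d = np.linalg.norm(pos[v[0]:v[1] + 1] - pos[i], axis=1)
        j = v[0] + int(np.argmin(d))
        if d.min() > 6.5:
            continue
        # parallel-sheet H-bonds sit on a +-1 shifted register relative to
        # the nearest-Ca rung; scan the neighbouring rungs too
        for jj in (j, j - 1, j + 1):
            if v[0] <= jj <= v[1] and bonded(i, jj):
                out.append((i, jj))
                break
    return out


def detect_strands(structure: StructureModel, chain_id: str,
                   mode: str = "ca_only",
                   config: Config = DEFAULT) -> tuple[list[Strand], SheetModel]:
    """Detect beta strands and sheets in one chain.

    ``mode="ca_only"`` uses Ca-Ca ladder distances (<= ``ca_ladder_max`` over
    at least ``min_ladder_pairs`` consecutive rungs); ``mode="backbone"``
    uses a geometric N...O hydrogen-bond criterion.  Sheets are connected
    components of the ladder graph; each ladder records its paired residues
    and parallel/antiparallel orientation.
    """
    if mode not in ("ca_only", "backbone"):
        raise ValueError(f"unknown mode {mode!r}")
    from .io import extract_ca
    trace = extract_ca(structure, chain_id)
    chain = structure.chain(chain_id)
    if len(trace) < 20:
        raise AnnotationError(
            f"chain {chain_id!r}: only {len(trace)} Ca residues (< 20)")
    runs = _merge_bulges(_extended_runs(trace, config), trace, config)
    runs = [r for r in runs if r[1] - r[0] + 1 >= config.min_strand_len]

    ladders_raw: dict[tuple[int, int], tuple[list[tuple[int, int]], str]] = {}
    for a, b in itertools.combinations(range(len(runs)), 2):
        lad = _ladder_ca(trace, runs[a], runs[b], config)
        if mode == "backbone" and lad is not None:
            hb = _hbond_pairs(chain, trace, runs[a], runs[b], config)
            if len(hb) < config.min_ladder_pairs:
                lad = None
        if lad is not None:
            ladders_raw[(a, b)] = lad

    in_ladder = sorted({i for pair in ladders_raw for i in pair})
    if not in_ladder:
        raise AnnotationError(f"chain {chain_id!r}: no beta strands found")
    # trim run ends to the laddered extent: terminal residues that pair in
    # no ladder are loop fray, not strand
    paired: dict[int, set[int]] = {i: set() for i in in_ladder}
    for (a, b), (prs, _o) in ladders_raw.items():
        for i, j in prs:
            paired[a].add(i)
            paired[b].add(j)
    trimmed: dict[int, tuple[int, int]] = {}
    for old in in_ladder:
        s, e = runs[old]
        while s < e and s not in paired[old]:
            s += 1
        while e > s and e not in paired[old]:
            e -= 1
        trimmed[old] = (s, e)
    in_ladder = [i for i in in_ladder
                 if trimmed[i][1] - trimmed[i][0] + 1 >= config.min_strand_len]
    remap = {old: new for new, old in enumerate(in_ladder)}
    strands = []
    for old in in_ladder:
        s, e = trimmed[old]
        strands.append(Strand(index=remap[old],
                              residue_keys=trace.residue_keys[s:e + 1],
                              positions=trace.positions[s:e + 1]))
    ladders = []
    for (a, b), (pairs, orient) in ladders_raw.items():
        if a not in remap or b not in remap:
            continue
        ladders.append(Ladder(
            strand_i=remap[a], strand_j=remap[b],
            pairs=[(trace.residue_keys[i], trace.residue_keys[j])
                   for i, j in pairs],
            orientation=orient))

    sheet_model = SheetModel(ladders=ladders)
    _assign_sheets(strands, sheet_model)
    if len(sheet_model.sheets) == 1:
        sheet_model.diagnostics.append(
            "single-sheet result: not a two-sheet sandwich as detected")
    return strands, sheet_model


def _assign_sheets(strands: list[Strand], sm: SheetModel) -> None:
    # connected components of the ladder graph
    parent = list(range(len(strands)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for lad in sm.ladders:
        a, b = find(lad.strand_i), find(lad.strand_j)
        if a != b:
            parent[a] = b
    comps: dict[int, list[int]] = {}
    for s in strands:
        comps.setdefault(find(s.index), []).append(s.index)
    sm.sheets = {}
    for n, members in enumerate(sorted(comps.values(), key=min)):
        sid = f"S{n + 1}"
        ordered = _lateral_order(members, sm, strands)
        sm.sheets[sid] = ordered
        for i in ordered:
            strands[i].sheet_id = sid


def _lateral_order(members: list[int], sm: SheetModel,
                   strands: list[Strand]) -> list[int]:
    """Order strands laterally by walking the adjacency path."""
    if len(members) == 1:
        return members
    adj = {m: [n for n in sm.neighbours(m) if n in members] for m in members}
    ends = [m for m in members if len(adj[m]) == 1]
    start = min(ends) if ends else min(members)
    order, seen = [start], {start}
    while True:
        nxt = [n for n in adj[order[-1]] if n not in seen]
        if not nxt:
            break
        # prefer geometric nearest when branched
        nxt.sort(key=lambda n: float(np.linalg.norm(
            strands[n].centroid - strands[order[-1]].centroid)))
        order.append(nxt[0])
        seen.add(nxt[0])
    for m in members:          # disconnected leftovers (should not happen)
        if m not in seen:
            order.append(m)
    return order


# ---------------------------------------------------------------------------
# Ig labelling
# ---------------------------------------------------------------------------

class OverrideValidationError(ValueError):
    pass


def _find_core(strands: list[Strand], sm: SheetModel
               ) -> Optional[tuple[int, int, int, int]]:
    """The B,C,E,F core: four mutually laddered strands in N->C order whose
    BC and EF connections straddle the two sheets."""
    best, best_score = None, -1
    idx = [s.index for s in strands]
    for b, c, e, f in itertools.combinations(idx, 4):
        sb, sc = strands[b].sheet_id, strands[c].sheet_id
        se, sf = strands[e].sheet_id, strands[f].sheet_id
        if not (sb == se and sc == sf and sb != sc):
            continue
        lbe = sm.ladder_between(b, e)
        lcf = sm.ladder_between(c, f)
        if lbe is None or lcf is None:
            continue
        # the B|E and C|F core ladders of the inverted-topology straddle
        # are antiparallel (the A'|G pair, by contrast, is parallel)
        if lbe.orientation != "antiparallel" or lcf.orientation != "antiparallel":
            continue
        score = sum(len(strands[i]) for i in (b, c, e, f))
        if score > best_score:
            best, best_score = (b, c, e, f), score
    return best


def label_ig_strands(strands: list[Strand], sheet_model: SheetModel,
                     chain: Chain, override: Optional[dict] = None,
                     config: Config = DEFAULT) -> IgAnnotation:
    """Assign canonical Ig labels to detected strands.

    Returns an :class:`IgAnnotation`; when the BC/EF core straddle cannot be
    identified the annotation is returned with ``ig_like=False`` (a typed
    verdict, not an exception).  A manual ``override`` mapping label ->
    {start, end} wins over detection after validation.
    """
    ann = IgAnnotation(chain_id=chain.chain_id, strands=strands,
                       sheet_model=sheet_model, chain=chain)
    if override:
        _apply_override(ann, override)
        return _finalise(ann, config)

    if len(sheet_model.sheets) != 2:
        ann.ig_like = False
        ann.diagnostics.append(
            f"{len(sheet_model.sheets)} sheet(s) detected; an Ig sandwich has 2")
        return ann
    core = _find_core(strands, sheet_model)
    if core is None:
        ann.ig_like = False
        ann.diagnostics.append("BC/EF core straddle not identifiable")
        return ann
    b, c, e, f = core
    strands[b].label, strands[c].label = "B", "C"
    strands[e].label, strands[f].label = "E", "F"
    sheet_a, sheet_b = strands[b].sheet_id, strands[c].sheet_id

    # strands between C and E: C' and C'' on the C-side sheet, D on the E side
    between = [s for s in strands if c < s.index < e]
    cb_side = [s for s in between if s.sheet_id == sheet_b]
    if cb_side:
        cb_side[0].label = "C'"
        if len(cb_side) > 1:
            cb_side[1].label = "C''"
        for s in cb_side[2:]:
            ann.diagnostics.append(f"extra strand {s.index} between C'' and D")
    d_side = [s for s in between if s.sheet_id == sheet_a]
    if d_side:
        d_side[-1].label = "D"
        for s in d_side[:-1]:
            ann.diagnostics.append(f"extra strand {s.index} on D-side sheet")

    # first strand after F on the C-side sheet is G
    after = [s for s in strands if s.index > f and s.sheet_id == sheet_b]
    if after:
        after[0].label = "G"
        for s in after[1:]:
            ann.diagnostics.append(f"unassigned strand {s.index} after G")

    # N-terminal strands: A on the B-side sheet, A' on the G-side sheet
    pre = [s for s in strands if s.index < b]
    if pre:
        pre_a = [s for s in pre if s.sheet_id == sheet_a]
        pre_b = [s for s in pre if s.sheet_id == sheet_b]
        if pre_a:
            pre_a[-1].label = "A"
        if pre_b:
            pre_b[-1].label = "A'"
        for s in pre:
            if s.label is None:
                ann.diagnostics.append(f"unassigned N-terminal strand {s.index}")
        ann.a_split = bool(pre_a) and bool(pre_b)
    return _finalise(ann, config)


def _apply_override(ann: IgAnnotation, override: dict) -> None:
    conflicts = []
    seen: set[ResidueKey] = set()
    chain_keys = [r.key for r in ann.chain]
    for label, spec in override.items():
        if label not in STRAND_LABELS:
            conflicts.append(f"unknown strand label {label!r}")
            continue
        start, end = int(spec["start"]), int(spec["end"])
        keys = [k for k in chain_keys if start <= k[0] <= end]
        if not keys:
            conflicts.append(f"{label}: residues {start}-{end} not in chain")
            continue
        overlap = seen.intersection(keys)
        if overlap:
            conflicts.append(f"{label}: overlaps previously assigned "
                             f"residues {sorted(overlap)[:3]}")
            continue
        seen.update(keys)
        matched = None
        for s in ann.strands:
            if set(s.residue_keys) & set(keys):
                matched = s
                break
        if matched is None:
            # build a strand record directly from the override interval
            pos = []
            for k in keys:
                r = ann.chain.residue(k)
                if r and r.ca is not None:
                    pos.append(r.ca.position)
            if len(pos) < 2:
                conflicts.append(f"{label}: fewer than 2 Ca in {start}-{end}")
                continue
            matched = Strand(index=len(ann.strands), residue_keys=keys,
                             positions=np.array(pos))
            ann.strands.append(matched)
        matched.label = label
    if conflicts:
        raise OverrideValidationError("; ".join(conflicts))
    ann.a_split = ann.has("A") and ann.has("A'")


def _finalise(ann: IgAnnotation, config: Config) -> IgAnnotation:
    lab = ann.labelled
    if not all(k in lab for k in ("B", "C", "E", "F")):
        ann.ig_like = False
        ann.diagnostics.append("BCEF core incomplete")
        return ann
    sheet_a_id = lab["B"].sheet_id
    for s in ann.strands:
        if s.label:
            (ann.sheet_A if s.sheet_id == sheet_a_id else ann.sheet_B).add(s.label)
    # on override-built strands the sheet ids may be empty: fall back to the
    # canonical side of each label
    if not lab["C"].sheet_id:
        ann.sheet_A = {l for l in lab if l in ("A", "B", "E", "D")}
        ann.sheet_B = {l for l in lab if l in ("A'", "G", "F", "C", "C'", "C''")}

    ann.loops = {}
    for name, (l1, l2) in (("CDR1", ("B", "C")), ("CDR3", ("F", "G")),
                           ("CDR2", ("C'", "C''")), ("HV4", ("D", "E"))):
        iv = _loop_interval(ann, l1, l2)
        if iv:
            ann.loops[name] = iv
    if "C''" not in lab and "C'" in lab and "D" in lab:
        iv = _loop_interval(ann, "C'", "D")
        if iv:
            ann.loops["HV2"] = iv
    if ann.a_split:
        ann.hinge = _find_hinge(ann)
    return ann


def _loop_interval(ann: IgAnnotation, l1: str, l2: str
                   ) -> Optional[tuple[ResidueKey, ResidueKey]]:
    s1, s2 = ann.strand(l1), ann.strand(l2)
    if s1 is None or s2 is None:
        return None
    keys = [r.key for r in ann.chain]
    try:
        i1 = keys.index(s1.residue_keys[-1])
        i2 = keys.index(s2.residue_keys[0])
    except ValueError:
        return None
    if i2 - i1 < 2:
        return None
    return (keys[i1 + 1], keys[i2 - 1])


def _find_hinge(ann: IgAnnotation) -> Optional[ResidueKey]:
    """Hinge of the split A strand: first proline, else the middle of the
    longest glycine run, else the geometric midpoint of the A->A' gap."""
    a, ap = ann.strand("A"), ann.strand("A'")
    if a is None or ap is None:
        return None
    keys = [r.key for r in ann.chain]
    try:
        i1, i2 = keys.index(a.residue_keys[-1]), keys.index(ap.residue_keys[0])
    except ValueError:
        return None
    gap = ann.chain.residues[i1 + 1:i2]
    if not gap:
        return a.residue_keys[-1]
    for r in gap:
        if r.name == "PRO":
            return r.key
    best_run, run = [], []
    for r in gap:
        if r.name == "GLY":
            run.append(r)
            if len(run) > len(best_run):
                best_run = list(run)
        else:
            run = []
    if best_run:
        return best_run[len(best_run) // 2].key
    return gap[len(gap) // 2].key
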