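"""Topology/sequence maps: 2D renderings of the sandwich sheets.

Each sheet is drawn as rows of strands in lateral order, residues placed by
ladder register (one column per register position), with the protodomain
colour classes of the symmetry decomposition attached per strand: blue for
A/A' and D, green for B and E, yellow for C and F, orange for C' and G, red
for C''.  Output is structured JSON plus a plain-text grid; when registers
are missing, columns fall back to sequential packing and the map is
flagged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

from .strands import IgAnnotation, Strand

COLOR_CLASS = {"A": "blue", "A'": "blue", "D": "blue",
               "B": "green", "E": "green",
               "C": "yellow", "F": "yellow",
               "C'": "orange", "G": "orange",
               "C''": "red"}


@dataclass
class MapStrand:
    label: Optional[str]
    color: Optional[str]
    direction: str                       # "N->C" along +columns or -columns
    residues: list[dict]                 # {seq_id, icode, aa, column}


@dataclass
class MapDocument:
    sheets: dict[str, list[MapStrand]]
    loops: dict[str, list[int]]
    fallback_packing: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sheets": {sid: [asdict(s) for s in row]
                       for sid, row in self.sheets.items()},
            "loops": self.loops,
            "fallback_packing": self.fallback_packing,
            "notes": self.notes,
        }


def topology_map(annotation: IgAnnotation) -> MapDocument:
    """Register-aligned sheet map of one annotated chain (single or double
    Ig: the double fold simply shows its two fused sheets)."""
    sm = annotation.sheet_model
    chain = annotation.chain
    doc = MapDocument(sheets={}, loops={})
    strands = {s.index: s for s in annotation.strands}

    for sid, order in sm.sheets.items():
        placed: dict[int, tuple[int, int]] = {}   # strand -> (col0, step)
        fallback = False
        if order:
            placed[order[0]] = (0, 1)
        for prev, cur in zip(order, order[1:]):
            lad = sm.ladder_between(prev, cur)
            if lad is None or prev not in placed:
                fallback = True
                placed[cur] = (0, 1)
                continue
            c0, st = placed[prev]
            kp, kc = lad.pairs[0]
            # pairs may be stored as (prev,cur) or (cur,prev)
            if kp in strands[cur].residue_keys:
                kp, kc = kc, kp
            mi = strands[prev].residue_keys.index(kp)
            mj = strands[cur].residue_keys.index(kc)
            step = st if lad.orientation == "parallel" else -st
            placed[cur] = (c0 + st * mi - step * mj, step)
        if fallback:
            doc.fallback_packing = True
            doc.notes.append(f"sheet {sid}: register missing, sequential "
                             "packing used for some strands")
        cols = [placed[i][0] + placed[i][1] * m
                for i in order for m in range(len(strands[i]))]
        shift = -min(cols) if cols else 0
        row = []
        for i in order:
            s = strands[i]
            c0, step = placed[i]
            residues = []
            for m, key in enumerate(s.residue_keys):
                r = chain.residue(key)
                residues.append({
                    "seq_id": key[0], "icode": key[1],
                    "aa": r.one_letter if r else "X",
                    "column": c0 + step * m + shift,
                })
            row.append(MapStrand(
                label=s.label,
                color=COLOR_CLASS.get(_base_label(s.label)) if s.label else None,
                direction="N->C" if step > 0 else "C<-N",
                residues=residues))
        doc.sheets[sid] = row

    for name, (k0, k1) in annotation.loops.items():
        doc.loops[name] = [k0[0], k1[0]]
    return doc


def _base_label(label: Optional[str]) -> Optional[str]:
    return label.rstrip("12") if label else None


def render_text(doc: MapDocument) -> str:
    """Plain-text grid: one row per strand, one column per register slot."""
    lines = []
    for sid, row in doc.sheets.items():
        lines.append(f"sheet {sid} "
                     f"({''.join((s.label or '?') for s in row)})")
        width = 1 + max((r["column"] for s in row for r in s.residues),
                        default=0)
        for s in row:
            cells = [" "] * width
            for r in s.residues:
                cells[r["column"]] = r["aa"]
            label = (s.label or "?").ljust(4)
            lines.append(f"  {label} {''.join(cells)}  {s.direction}")
        lines.append("")
    if doc.loops:
        lines.append("loops: " + ", ".join(
            f"{n}={a}-{b}" for n, (a, b) in sorted(doc.loops.items())))
    if doc.fallback_packing:
        lines.append("note: sequential packing used where registers missing")
    return "\n".join(lines) + "\n"
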