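"""Protodomain decomposition and internal C2 pseudosymmetry.

An Ig domain is treated as a covalently linked dimer of two half-domains
("protodomains"): the N-terminal AB-CC' unit and the C-terminal DE-FG unit,
related by an internal ~180 degree (C2) rotation.  This module decomposes a
labelled annotation into protodomains, builds the symmetry correspondence
between their strands (A/A'<->D, B<->E, C<->F, C'<->G), superposes the
paired C-alphas and extracts the symmetry axis.

The residue correspondence is register-free: each mapped strand pair is
aligned at its centre, the longer strand trimmed symmetrically to the
shorter one's length (ties resolved toward the N side), and residues paired
index-by-index reading both strands N->C -- no antiparallel reversal,
because the C2 acts on the whole protodomain unit.  An optional refinement
pass iteratively drops the worst-fitting pairs and re-superposes, emulating
the trimmed alignments of interactive structure-comparison tools; it is off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import Config, DEFAULT
from .geometry import (SuperpositionResult, SymmetryAxis, superpose_points,
                       symmetry_axis as _axis_from_sp)
from .model import ResidueKey
from .strands import IgAnnotation, Strand

#: symmetry-equivalent strand labels, first-protodomain -> second
SYMMETRY_PARTNERS = {"A": "D", "B": "E", "C": "F", "C'": "G"}

P_ODD_LABELS = ("A", "A'", "B", "C", "C'")
P_EVEN_LABELS = ("D", "E", "F", "G")

#: inter-protodomain linker composition per topology class
LINKER_BY_CLASS = {
    "V_set": "CDR2 + C'' + C''D loop",
    "I_set": "C'D linker",
    "VNAR_like": "C'D linker (HV2)",
    "C1_set": "CD linker",
    "cadherin": "CD linker",
    "C2_set": "C'E linker",
    "FN3": "C'E linker",
}


class DecompositionError(ValueError):
    pass


class CorrespondenceError(ValueError):
    pass


@dataclass
class Protodomain:
    index: int                       # 1-based: p1, p2 (p3, p4 for double Ig)
    strand_labels: list[str]         # N->C order
    strands: list[Strand]
    chain_id: str = ""

    @property
    def residue_keys(self) -> list[ResidueKey]:
        return [k for s in self.strands for k in s.residue_keys]

    @property
    def positions(self) -> np.ndarray:
        return np.vstack([s.positions for s in self.strands])

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def strand(self, label: str) -> Optional[Strand]:
        for lbl, s in zip(self.strand_labels, self.strands):
            if lbl == label:
                return s
        return None

    def sequence(self, annotation: IgAnnotation) -> str:
        return "".join(annotation.sequence_of(l) for l in self.strand_labels)


@dataclass
class ResidueCorrespondence:
    pairs: list[tuple[ResidueKey, ResidueKey]]
    strand_map: list[tuple[str, str]]          # per mapped strand pair
    pair_labels: list[tuple[str, str]]         # per residue pair
    positions_i: np.ndarray = field(default=None, repr=False)
    positions_j: np.ndarray = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.pairs)


def decompose(annotation: IgAnnotation,
              config: Config = DEFAULT) -> list[Protodomain]:
    """Split a labelled single-Ig annotation into its two protodomains.

    p1 collects the present members of {A, A', B, C, C'}; p2 collects
    {D, E, F, G}.  (Double-Ig chains are decomposed by the topology module,
    which yields four protodomains.)
    """
    lab = annotation.labelled
    if "E" not in lab or "F" not in lab:
        raise DecompositionError("annotation lacks strand E or F")
    p1 = [l for l in P_ODD_LABELS if l in lab]
    p2 = [l for l in P_EVEN_LABELS if l in lab]
    return [
        Protodomain(1, p1, [lab[l] for l in p1], annotation.chain_id),
        Protodomain(2, p2, [lab[l] for l in p2], annotation.chain_id),
    ]


def protodomain_linker(annotation: IgAnnotation, label: str) -> str:
    """Describe the inter-protodomain linker for a topology class label."""
    return LINKER_BY_CLASS.get(label, "C-to-E region")


def _trim(n_long: int, n_short: int) -> tuple[int, int]:
    """Start offset into the longer strand; tie resolved toward the N side."""
    excess = n_long - n_short
    return excess // 2, excess // 2 + n_short


def build_correspondence(p_i: Protodomain, p_j: Protodomain,
                         strands: Optional[Sequence[str]] = None,
                         include_a: bool = True) -> ResidueCorrespondence:
    """Symmetry correspondence between two protodomains.

    Maps strand B<->E, C<->F, C'<->G and (when both exist and ``include_a``)
    A<->D; ``strands`` optionally restricts the mapped first-protodomain
    labels (e.g. ``["B", "C", "C'"]`` for the BCC' vs EFG mapping used when
    A' strands are not structurally matched to D).
    """
    wanted = dict(SYMMETRY_PARTNERS)
    if not include_a:
        wanted.pop("A")
    if strands is not None:
        wanted = {k: v for k, v in wanted.items() if k in strands}
    pairs, pair_labels, strand_map = [], [], []
    pos_i, pos_j = [], []
    for li, lj in wanted.items():
        si, sj = p_i.strand(li), p_j.strand(lj)
        if si is None and sj is None:
            # also admit the reversed orientation (p_even given first)
            si, sj = p_i.strand(lj), p_j.strand(li)
            if si is None or sj is None:
                continue
            li, lj = lj, li
        if si is None or sj is None:
            continue
        strand_map.append((li, lj))
        ni, nj = len(si), len(sj)
        if ni >= nj:
            a, b = _trim(ni, nj)
            ki, kj = si.residue_keys[a:b], sj.residue_keys
            pi, pj = si.positions[a:b], sj.positions
        else:
            a, b = _trim(nj, ni)
            ki, kj = si.residue_keys, sj.residue_keys[a:b]
            pi, pj = si.positions, sj.positions[a:b]
        pairs.extend(zip(ki, kj))
        pair_labels.extend([(li, lj)] * len(ki))
        pos_i.append(pi)
        pos_j.append(pj)
    if len(strand_map) < 2:
        raise CorrespondenceError(
            f"only {len(strand_map)} mappable strand pair(s) between "
            f"p{p_i.index} and p{p_j.index}")
    return ResidueCorrespondence(
        pairs=pairs, strand_map=strand_map, pair_labels=pair_labels,
        positions_i=np.vstack(pos_i), positions_j=np.vstack(pos_j))


def superpose(correspondence: ResidueCorrespondence,
              refine: bool = False,
              config: Config = DEFAULT
              ) -> tuple[SuperpositionResult, ResidueCorrespondence]:
    """Least-squares rigid superposition over the paired C-alphas.

    With ``refine=True``, pairs farther than ``config.refine_pair_cutoff``
    after superposition are dropped and the fit repeated (at most
    ``config.refine_max_rounds`` rounds), emulating tool-style trimmed
    alignments.  Returns the fit and the (possibly trimmed) correspondence.
    """
    corr = correspondence
    sp = superpose_points(corr.positions_i, corr.positions_j)
    if not refine:
        return sp, corr
    for _ in range(config.refine_max_rounds):
        d = np.linalg.norm(sp.apply(corr.positions_i) - corr.positions_j,
                           axis=1)
        keep = d <= config.refine_pair_cutoff
        if keep.all() or keep.sum() < 3:
            break
        corr = ResidueCorrespondence(
            pairs=[p for p, k in zip(corr.pairs, keep) if k],
            strand_map=corr.strand_map,
            pair_labels=[p for p, k in zip(corr.pair_labels, keep) if k],
            positions_i=corr.positions_i[keep],
            positions_j=corr.positions_j[keep])
        sp = superpose_points(corr.positions_i, corr.positions_j)
    return sp, corr


def protodomain_axis(sp: SuperpositionResult, p_i: Protodomain,
                     p_j: Protodomain,
                     config: Config = DEFAULT) -> Optional[SymmetryAxis]:
    """Internal symmetry axis from the protodomain superposition transform."""
    return _axis_from_sp(sp, (p_i.centroid, p_j.centroid),
                         c2_tolerance_deg=config.c2_tolerance_deg)


def sequence_identity(annotation: IgAnnotation,
                      correspondence: ResidueCorrespondence) -> float:
    """Fraction of identical residues over paired positions (reported only;
    protodomain identity is typically in the twilight zone and is never used
    for classification)."""
    same = total = 0
    for ki, kj in correspondence.pairs:
        ri, rj = annotation.chain.residue(ki), annotation.chain.residue(kj)
        if ri is None or rj is None:
            continue
        total += 1
        if ri.one_letter == rj.one_letter:
            same += 1
    return same / total if total else 0.0


def analyse_protodomains(annotation: IgAnnotation,
                         strands: Optional[Sequence[str]] = None,
                         refine: bool = False,
                         config: Config = DEFAULT) -> dict:
    """One-call tertiary-symmetry report for a labelled single Ig domain."""
    p1, p2 = decompose(annotation, config)
    include_a = _a_maps_to_d(annotation)
    corr = build_correspondence(p1, p2, strands=strands, include_a=include_a)
    sp, corr = superpose(corr, refine=refine, config=config)
    axis = protodomain_axis(sp, p1, p2, config)
    return {
        "protodomains": [p1, p2],
        "correspondence": corr,
        "superposition": sp,
        "axis": axis,
        "rmsd": sp.rmsd,
        "n_pairs": sp.n_pairs,
        "identity": sequence_identity(annotation, corr),
    }


def _a_maps_to_d(annotation: IgAnnotation) -> bool:
    """A<->D is attempted only when both labels exist and A is not a split
    remnant sitting on the G-side sheet (symmetry breaking)."""
    a, d = annotation.strand("A"), annotation.strand("D")
    if a is None or d is None:
        return False
    return "A" in annotation.sheet_A
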