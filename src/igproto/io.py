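"""Structure reading/writing (PDB, mmCIF) on top of gemmi.

Conventions: first model only, waters and non-polymer ligands dropped,
alternate locations resolved to the highest-occupancy atom (ties to the one
listed first), original author numbering kept throughout.  Modified residues
that carry a C-alpha (MSE, SEP, ...) are retained and mapped to their parent
amino acid for sequence purposes.
"""

from __future__ import annotations

import os
from typing import Optional

import gemmi
import numpy as np

from .model import (Atom, CaTrace, Chain, EmptySelectionError, Residue,
                    StructureModel, THREE_TO_ONE)


class StructureParseError(ValueError):
    pass


def read_structure(path: str, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``format`` is one of ``pdb``, ``mmcif``, ``auto``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}[format]
    try:
        st = gemmi.read_structure(path, format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{path}: structure contains no model")
    model = st[0]  # first model for multi-model (NMR) files
    out = StructureModel(id=st.name or os.path.basename(path))
    for ch in model:
        chain = Chain(chain_id=ch.name)
        for res in ch:
            if res.is_water():
                continue
            std = res.name in THREE_TO_ONE
            if res.het_flag == "H" and not std:
                continue  # ligand
            if not std and res.het_flag != "A":
                continue
            chain.residues.append(_convert_residue(res))
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise StructureParseError(f"{path}: no polymer residues found")
    return out


def _convert_residue(res: gemmi.Residue) -> Residue:
    # altloc policy: highest occupancy, ties -> first listed
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    atoms = [Atom(name=a.name, element=a.element.name,
                  position=np.array([a.pos.x, a.pos.y, a.pos.z]))
             for a in best.values()]
    icode = res.seqid.icode.strip()
    return Residue(seq_id=res.seqid.num, insertion_code=icode,
                   name=res.name, atoms=atoms)


def extract_ca(structure: StructureModel, chain_id: str,
               residue_range: Optional[tuple[int, int]] = None) -> CaTrace:
    """C-alpha trace of one chain, optionally restricted to a closed,
    inclusive interval of source-file residue numbers.

    Residues lacking a C-alpha are excluded; gaps are preserved as absent
    keys, never interpolated.
    """
    chain = structure.chain(chain_id)
    keys, pos = [], []
    for r in chain:
        if residue_range is not None:
            lo, hi = residue_range
            if not (lo <= r.seq_id <= hi):
                continue
        ca = r.ca
        if ca is None:
            continue
        keys.append(r.key)
        pos.append(ca.position)
    if not keys:
        raise EmptySelectionError(
            f"no C-alpha residues selected in chain {chain_id!r} "
            f"(range={residue_range})")
    return CaTrace(chain_id=chain_id, residue_keys=keys, positions=np.array(pos))


def to_gemmi(structure: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        ch = gemmi.Chain(chain.chain_id)
        for res in chain:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = 1.0
                gr.add_atom(ga)
            ch.add_residue(gr)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: StructureModel, path: str) -> None:
    to_gemmi(structure).write_pdb(path)


def write_fasta(structure: StructureModel, path: str,
                per_chain: bool = True) -> None:
    with open(path, "w") as fh:
        for chain in structure.chains:
            fh.write(f">{structure.id}_{chain.chain_id}\n")
            seq = chain.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
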