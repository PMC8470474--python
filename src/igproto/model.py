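"""Coordinate model shared by every pipeline stage.

The model mirrors the source file: chains hold residues in file order, and
residues keep their original author numbering (``seq_id`` plus insertion
code).  All geometry downstream works on C-alpha traces extracted from this
model, so residues without a C-alpha are flagged here and excluded from
traces rather than silently interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

#: (seq_id, insertion_code) -- the residue key used everywhere downstream.
ResidueKey = tuple[int, str]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent amino acid
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y",
}


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Residue:
    seq_id: int
    insertion_code: str
    name: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.seq_id, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, key: ResidueKey) -> Optional[Residue]:
        for r in self.residues:
            if r.key == key:
                return r
        return None

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class StructureModel:
    """Chains -> residues -> atoms, in original file order and numbering."""

    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(
            f"chain {chain_id!r} not in structure {self.id!r} "
            f"(has {[c.chain_id for c in self.chains]})"
        )

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def flagged_residues(self, chain_id: str) -> list[ResidueKey]:
        """Residues lacking a C-alpha; excluded from traces."""
        return [r.key for r in self.chain(chain_id) if r.ca is None]


@dataclass
class CaTrace:
    """Index-aligned residue keys and C-alpha positions for one chain."""

    chain_id: str
    residue_keys: list[ResidueKey]
    positions: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.residue_keys) != len(self.positions):
            raise ValueError("residue_keys and positions must be index-aligned")

    def __len__(self) -> int:
        return len(self.residue_keys)

    def index_of(self, key: ResidueKey) -> int:
        return self.residue_keys.index(key)

    def subset(self, keys: Sequence[ResidueKey]) -> "CaTrace":
        idx = [self.index_of(k) for k in keys]
        return CaTrace(self.chain_id, [self.residue_keys[i] for i in idx],
                       self.positions[idx])


class EmptySelectionError(ValueError):
    """A residue selection matched nothing."""


class AnnotationError(ValueError):
    """Strand/sheet annotation could not be established."""
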