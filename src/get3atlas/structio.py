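"""Atomic-coordinate container and a PDB-format subset reader/writer.

Parsing is delegated to gemmi; this module applies the package contracts:
first model only, waters excluded, altlocs resolved to the highest
occupancy (ties to the alphabetically first altloc id), and a fallback to
atom-name element inference when the element column is absent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import gemmi
import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray                 # (3,) in Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")


@dataclass
class Residue:
    name: str
    number: int                     # author residue number, 1-based
    icode: str = ""
    atoms: List[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class Chain:
    id: str
    residues: List[Residue] = field(default_factory=list)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class StructureModel:
    chains: List[Chain] = field(default_factory=list)

    def chain(self, cid: str) -> Chain:
        for c in self.chains:
            if c.id == cid:
                return c
        raise KeyError(f"chain {cid!r} not in structure")

    def atoms(self) -> List[Tuple[Chain, Residue, Atom]]:
        return [(c, r, a) for c in self.chains for r in c.residues for a in r.atoms]

    def coordinates(self) -> np.ndarray:
        ats = self.atoms()
        return (np.stack([a.xyz for _, _, a in ats])
                if ats else np.empty((0, 3)))

    def subset(self, selection: Iterable[Tuple[str, Optional[int]]]) -> "StructureModel":
        """Sub-structure from (chain_id, residue_number-or-None) pairs;
        None selects a whole chain."""
        whole = {c for c, r in selection if r is None}
        pairs = {(c, r) for c, r in selection if r is not None}
        chains = []
        for ch in self.chains:
            keep = [r for r in ch.residues
                    if ch.id in whole or (ch.id, r.number) in pairs]
            if keep:
                chains.append(Chain(ch.id, keep))
        return StructureModel(chains)


def read_pdb_subset(text: str, keep_waters: bool = False) -> StructureModel:
    """Parse ATOM/HETATM records (first model only) into a StructureModel."""
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ValueError("empty structure: no models")
    st.setup_entities()
    model = st[0]
    chains: List[Chain] = []
    n_atoms = 0
    for gch in model:
        residues = []
        for gres in gch:
            if not keep_waters and gres.name in ("HOH", "WAT", "DOD"):
                continue
            # altloc groups: keep the highest-occupancy conformer,
            # ties broken by the alphabetically first altloc id
            groups: Dict[str, List[gemmi.Atom]] = {}
            for ga in gres:
                groups.setdefault(ga.name, []).append(ga)
            atoms = []
            for name in groups:
                cand = sorted(groups[name], key=lambda a: (-a.occ, a.altloc or "~"))
                ga = cand[0]
                elem = ga.element.name if ga.element and ga.element.name != "X" \
                    else _infer_element(ga.name)
                atoms.append(Atom(name, elem,
                                  np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                                  ga.occ, ga.altloc or ""))
            if atoms:
                residues.append(Residue(gres.name, gres.seqid.num,
                                        gres.seqid.icode.strip(), atoms))
                n_atoms += len(atoms)
        if residues:
            chains.append(Chain(gch.name, residues))
    if n_atoms == 0:
        raise ValueError("empty structure: no ATOM records")
    return StructureModel(chains)


def _infer_element(atom_name: str) -> str:
    s = atom_name.strip()
    while s and s[0].isdigit():
        s = s[1:]
    if not s:
        return "C"
    if len(s) >= 2 and s[:2].upper() in ("FE", "ZN", "MG", "MN", "NA", "CL", "BR"):
        return s[:2].capitalize()
    return s[0].upper()


def write_pdb(model: StructureModel) -> str:
    """Minimal ATOM-record serialization (for fixtures and round-trips)."""
    lines = []
    serial = 1
    for ch in model.chains:
        for res in ch.residues:
            for a in res.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{'':1s}{res.name:<3s} "
                    f"{ch.id:1s}{res.number:4d}{res.icode or ' ':1s}   "
                    f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          "
                    f"{a.element:>2s}")
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
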