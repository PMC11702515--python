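"""PDB structure input/output and atom bookkeeping.

Structures are flat, ordered lists of atoms: SAXS computation only needs
element identities and coordinates, so no residue hierarchy is kept beyond
what feature extraction requires.  Coordinates are in Å everywhere.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

SUPPORTED_ELEMENTS = {"H", "C", "N", "O", "P", "S", "MG", "NA", "K", "CL"}

WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD"}
ION_RESNAMES = {"MG"}


class StructureError(ValueError):
    """Raised for unreadable or empty structures."""


@dataclass
class Atom:
    element: str
    coord: np.ndarray
    name: str = ""
    residue_name: str = ""
    residue_id: int = 0
    icode: str = ""
    chain: str = "A"
    is_hetero: bool = False

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name!r}: coordinate must be a finite 3-vector")
        el = self.element.upper()
        self.element = el if el in SUPPORTED_ELEMENTS else "other"


@dataclass
class Structure:
    atoms: list[Atom] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coord for a in self.atoms])

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def translated(self, shift) -> "Structure":
        shift = np.asarray(shift, dtype=float)
        return Structure([replace(a, coord=a.coord + shift) for a in self.atoms], self.label)

    def rotated(self, R) -> "Structure":
        R = np.asarray(R, dtype=float)
        return Structure([replace(a, coord=R @ a.coord) for a in self.atoms], self.label)

    def subset(self, indices) -> "Structure":
        return Structure([self.atoms[i] for i in indices], self.label)


def _element_of(gatom: gemmi.Atom) -> str:
    name = gatom.element.name.upper()
    if name and name != "X":
        return name
    # fall back on the atom-name heuristic: first alphabetic character
    for ch in gatom.name:
        if ch.isalpha():
            return ch.upper()
    return "other"


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one location per atom name: highest occupancy, ties -> altloc 'A'."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        if atom.occ > prev.occ or (atom.occ == prev.occ and atom.altloc < prev.altloc):
            best[atom.name] = atom
    # preserve file order of the kept atoms
    kept = set(id(a) for a in best.values())
    return [a for a in residue if id(a) in kept]


def _model_to_structure(
    model: gemmi.Model,
    label: str,
    include_waters: bool,
    include_ions: bool,
    keep_hydrogens: bool,
) -> Structure:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            resname = residue.name.strip().upper()
            if resname in WATER_RESNAMES and not include_waters:
                continue
            if resname in ION_RESNAMES and not include_ions:
                continue
            for gatom in _resolve_altlocs(residue):
                element = _element_of(gatom)
                if element == "H" and not keep_hydrogens:
                    continue
                atoms.append(
                    Atom(
                        element=element,
                        coord=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        name=gatom.name,
                        residue_name=resname,
                        residue_id=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        chain=chain.name,
                        is_hetero=residue.het_flag == "H",
                    )
                )
    return Structure(atoms, label)


def read_pdb_models(
    path,
    include_waters: bool = False,
    include_ions: bool = True,
    keep_hydrogens: bool = False,
) -> list[Structure]:
    """Read a PDB file; each MODEL becomes one Structure.

    Elements are taken from columns 77-78 when present, otherwise inferred
    from the atom name.  Alternate locations are resolved to the highest
    occupancy (ties keep altloc 'A').  Hydrogens are dropped unless
    ``keep_hydrogens`` (implicit-hydrogen form factors are used downstream).
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, OSError, ValueError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    structures = []
    for i, model in enumerate(st):
        label = str(path) if len(st) == 1 else f"{path}#model{i + 1}"
        s = _model_to_structure(model, label, include_waters, include_ions, keep_hydrogens)
        structures.append(s)
    structures = [s for s in structures if len(s) > 0]
    if not structures:
        raise StructureError(f"{path}: no atoms remain after filtering")
    return structures


def read_pdb(path, include_waters: bool = False, include_ions: bool = True,
             keep_hydrogens: bool = False) -> Structure:
    """Read the first model of a PDB file as a Structure."""
    return read_pdb_models(path, include_waters, include_ions, keep_hydrogens)[0]


_PDB_ELEMENT = {"MG": "MG", "NA": "NA", "CL": "CL", "K": "K"}


def _format_atom_line(i: int, atom: Atom) -> str:
    record = "HETATM" if atom.is_hetero else "ATOM  "
    name = atom.name or atom.element
    # PDB convention: element symbols of width 1 start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    element = _PDB_ELEMENT.get(atom.element, atom.element if atom.element != "other" else "X")
    x, y, z = atom.coord
    return (
        f"{record}{i:5d} {name_field} {atom.residue_name:>3s} {atom.chain[:1]:1s}"
        f"{atom.residue_id:4d}{atom.icode[:1] or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as fixed-width PDB."""
    lines = [_format_atom_line(i + 1, a) for i, a in enumerate(structure.atoms)]
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_pdb_with_ions(structure: Structure, ion_positions, path) -> None:
    """Write the structure plus one Mg2+ HETATM record per ion position."""
    ion_positions = np.atleast_2d(np.asarray(ion_positions, dtype=float)) \
        if len(ion_positions) else np.zeros((0, 3))
    if ion_positions.size and not np.all(np.isfinite(ion_positions)):
        raise StructureError("ion positions must be finite")
    out = structure.copy()
    next_resid = max((a.residue_id for a in structure.atoms), default=0) + 1
    for k, pos in enumerate(ion_positions):
        out.atoms.append(
            Atom(element="MG", coord=pos, name="MG", residue_name="MG",
                 residue_id=next_resid + k, chain="M", is_hetero=True)
        )
    write_pdb(out, path)


def split_components(structure: Structure) -> tuple[Structure, Structure, Structure]:
    """Partition into (rna, ions, waters) by residue name.

    Everything that is not MG or water counts as an RNA scatterer: scattering
    depends on atoms, not on residue chemistry.
    """
    rna, ions, waters = Structure(label=structure.label), Structure(), Structure()
    for atom in structure.atoms:
        if atom.residue_name in ION_RESNAMES:
            ions.atoms.append(atom)
        elif atom.residue_name in WATER_RESNAMES:
            waters.atoms.append(atom)
        else:
            rna.atoms.append(atom)
    return rna, ions, waters
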