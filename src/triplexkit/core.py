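"""Structure data model and multi-model PDB input/output.

The in-memory unit is :class:`StructureModel`: an ordered list of strands,
each an ordered (5'->3') list of residues carrying their atoms with Cartesian
coordinates in Angstrom.  Multi-model PDB files map one MODEL block to one
:class:`StructureModel` (``frame_index`` = block order, 0-based) and one chain
to one strand.

Parsing is delegated to Biopython's PDB parser; writing emits fixed-width PDB
records directly (3-decimal coordinates, 1-based serials).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from . import chem
from .geometry import torsion


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # 3-vector, Angstrom
    residue_index: int = 0  # 0-based, within strand
    strand_id: str = ""

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(),
                    self.residue_index, self.strand_id)


@dataclass
class Residue:
    base: str  # A, G, C, T, U
    chemistry: str  # DNA / RNA
    atoms: list[Atom] = field(default_factory=list)
    protonated_site: str | None = None  # "N3" (C+) or "N1" (A+)
    glycosidic_state: str | None = None  # anti / syn, where known

    def __post_init__(self) -> None:
        if self.base == "U" and self.chemistry == "DNA":
            raise ValueError("no DNA uracil residues")
        if self.base == "T" and self.chemistry == "RNA":
            raise ValueError("no RNA thymine residues")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.base} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def ring_atom_names(self) -> tuple[str, ...]:
        return chem.RING_ATOMS[self.base]

    def ring_coords(self) -> np.ndarray:
        return np.array([self.atom(n).coords for n in self.ring_atom_names])

    @property
    def has_ring(self) -> bool:
        return all(self.has_atom(n) for n in self.ring_atom_names)

    def chi(self) -> float:
        """Glycosidic torsion chi in degrees (requires O4' and C1')."""
        n = chem.GLYCOSIDIC_N[self.base]
        ref = chem.CHI_REFERENCE[self.base]
        return torsion(self.atom("O4'").coords, self.atom("C1'").coords,
                       self.atom(n).coords, self.atom(ref).coords)

    def copy(self) -> "Residue":
        return Residue(self.base, self.chemistry,
                       [a.copy() for a in self.atoms],
                       self.protonated_site, self.glycosidic_state)


@dataclass
class StructureModel:
    """Atoms/residues/strands of one conformation (or trajectory frame)."""

    strands: list[tuple[str, list[Residue]]]
    frame_index: int = 0

    def strand(self, strand_id: str) -> list[Residue]:
        for sid, residues in self.strands:
            if sid == strand_id:
                return residues
        raise KeyError(f"no strand {strand_id!r}")

    @property
    def strand_ids(self) -> list[str]:
        return [sid for sid, _ in self.strands]

    def residues(self):
        for sid, residues in self.strands:
            for i, res in enumerate(residues):
                yield sid, i, res

    def atoms(self):
        for sid, i, res in self.residues():
            for a in res.atoms:
                yield a

    def coordinates(self, heavy_only: bool = False) -> np.ndarray:
        pts = [a.coords for a in self.atoms()
               if not (heavy_only and a.element == "H")]
        return np.array(pts)

    def transform(self, R: np.ndarray, t: np.ndarray) -> "StructureModel":
        """Return a rigidly moved copy (coords @ R.T + t)."""
        out = self.copy()
        for a in out.atoms():
            a.coords = a.coords @ np.asarray(R).T + np.asarray(t)
        return out

    def copy(self) -> "StructureModel":
        return StructureModel(
            [(sid, [r.copy() for r in residues])
             for sid, residues in self.strands],
            self.frame_index,
        )


# -- PDB output -------------------------------------------------------------

def _atom_line(serial: int, atom: Atom, resname: str, chain: str,
               resseq: int) -> str:
    name = atom.name
    # PDB columns 13-16: element right-justified in 13-14 for 1-2 char names
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.coords
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}"
    )


def write_pdb(models, path, protonated_resnames: bool = False) -> None:
    """Write one or more StructureModels as a (multi-model) PDB file.

    Protonated residues keep standard names (DC/DA) plus the extra proton
    atom by default; ``protonated_resnames=True`` emits DCP/DAP instead.
    """
    if isinstance(models, StructureModel):
        models = [models]
    lines: list[str] = []
    multi = len(models) > 1
    for k, model in enumerate(models):
        if multi:
            lines.append(f"MODEL     {k + 1:4d}")
        serial = 1
        for sid, residues in model.strands:
            resseq = 0
            for res in residues:
                resseq += 1
                resname = chem.RESNAME[(res.base, res.chemistry)]
                if protonated_resnames and res.protonated_site:
                    resname = {"C": "DCP", "A": "DAP"}[res.base]
                for atom in res.atoms:
                    lines.append(_atom_line(serial, atom, resname, sid,
                                            resseq))
                    serial += 1
            lines.append(f"TER   {serial:5d}      "
                         f"{chem.RESNAME[(residues[-1].base, residues[-1].chemistry)]:<3s} "
                         f"{sid}{resseq:4d}")
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- PDB input --------------------------------------------------------------

def _convert_residue(bio_res) -> Residue:
    resname = bio_res.get_resname().strip()
    try:
        base, chemistry = chem.RESNAME_TO_BASE[resname]
    except KeyError:
        raise ValueError(f"unknown nucleotide residue name {resname!r}")
    res = Residue(base, chemistry)
    for a in bio_res.get_atoms():
        element = (a.element or a.get_name()[0]).strip().capitalize()
        res.atoms.append(Atom(a.get_name(), element,
                              np.array(a.get_coord(), dtype=float)))
    # protonation is carried by the extra proton atom on standard names
    if base == "C" and res.has_atom("H3"):
        res.protonated_site = "N3"
    if base == "A" and res.has_atom("H1"):
        res.protonated_site = "N1"
    if resname == "DCP":
        res.protonated_site = "N3"
    if resname == "DAP":
        res.protonated_site = "N1"
    return res


def read_pdb(path) -> list[StructureModel]:
    """Read a (multi-model) PDB file into StructureModels.

    Residues missing ring atoms are kept but flagged with a warning; metric
    code skips planes whose residues are unusable.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("m", str(path))
    models: list[StructureModel] = []
    for k, bio_model in enumerate(structure):
        strands: list[tuple[str, list[Residue]]] = []
        for bio_chain in bio_model:
            residues = []
            for bio_res in bio_chain:
                res = _convert_residue(bio_res)
                for atom in res.atoms:
                    atom.strand_id = bio_chain.id
                    atom.residue_index = len(residues)
                if not res.has_ring:
                    warnings.warn(
                        f"residue {res.base} {len(residues)} of strand "
                        f"{bio_chain.id} lacks ring atoms; plane unusable"
                    )
                residues.append(res)
            strands.append((bio_chain.id, residues))
        models.append(StructureModel(strands, frame_index=k))
    return models
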