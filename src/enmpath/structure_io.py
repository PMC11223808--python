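"""Reading, filtering, coarse-graining and writing of macromolecular structures.

Input structures (PDB or mmCIF) are reduced to the atom set the elastic
networks are built on: hydrogens and HETATM/ligand records are discarded,
alternate locations are resolved to the highest-occupancy conformer, and an
optional one-bead-per-residue coarse-graining keeps CA for amino acids,
C3' for DNA and C4' for RNA.  All trajectory output is written as
multi-model mmCIF so that chain identifiers longer than one character
survive a round trip.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, SizeMismatchError, StructureFormatError

logger = logging.getLogger(__name__)

# 3-letter codes of the 20 standard amino acids -> 1-letter.
AMINO3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
DNA_TO_1 = {"DA": "A", "DC": "C", "DG": "G", "DT": "T"}
RNA_TO_1 = {"A": "A", "C": "C", "G": "G", "U": "U"}

#: representative atom kept in one-bead-per-residue mode, per polymer type
REPRESENTATIVE_ATOM = {"protein": "CA", "dna": "C3'", "rna": "C4'"}


def residue_polymer_type(residue_name: str) -> str | None:
    """Classify a residue name as ``protein``/``dna``/``rna`` or None."""
    if residue_name in AMINO3_TO_1:
        return "protein"
    if residue_name in DNA_TO_1:
        return "dna"
    if residue_name in RNA_TO_1:
        return "rna"
    return None


def residue_one_letter(residue_name: str) -> str | None:
    for table in (AMINO3_TO_1, DNA_TO_1, RNA_TO_1):
        if residue_name in table:
            return table[residue_name]
    return None


@dataclass
class Atom:
    """A single retained atom site."""

    chain_id: str
    residue_seq: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    b_factor: float
    model_num: int = 1

    def key(self) -> tuple:
        return (self.model_num, self.chain_id, self.residue_seq,
                self.insertion_code, self.atom_name)


@dataclass
class Residue:
    """Ordered group of atoms sharing one residue identity."""

    chain_id: str
    seq: int
    insertion_code: str
    name: str
    atom_indices: list[int] = field(default_factory=list)

    @property
    def polymer_type(self) -> str | None:
        return residue_polymer_type(self.name)


@dataclass
class Structure:
    """An ordered list of filtered atoms plus derived per-chain views."""

    atoms: list[Atom]
    source_format: str = "pdb"

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in input order."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if len(xyz) != self.n_atoms:
            raise SizeMismatchError(
                f"coordinate array has {len(xyz)} rows for {self.n_atoms} atoms")
        for atom, row in zip(self.atoms, xyz):
            atom.position = row.copy()

    def b_factors(self) -> np.ndarray:
        return np.array([a.b_factor for a in self.atoms], dtype=float)

    def residues(self) -> list[Residue]:
        """Group consecutive atoms into residues, preserving input order."""
        out: list[Residue] = []
        last_key = None
        for i, a in enumerate(self.atoms):
            key = (a.model_num, a.chain_id, a.residue_seq, a.insertion_code,
                   a.residue_name)
            if key != last_key:
                out.append(Residue(a.chain_id, a.residue_seq,
                                   a.insertion_code, a.residue_name))
                last_key = key
            out[-1].atom_indices.append(i)
        return out

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues() if r.chain_id == chain_id]

    def subset(self, indices: Sequence[int]) -> "Structure":
        return Structure([self.atoms[i] for i in indices], self.source_format)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".pdb", ".ent"):
        return "pdb"
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    # content sniffing: mmCIF files start with data_ blocks / category loops
    with open(path, "r", errors="replace") as fh:
        head = fh.read(4096)
    for line in head.splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith("data_") or s.startswith("_") or s.startswith("loop_"):
            return "mmcif"
        return "pdb"
    return "pdb"


def _select_altloc(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Resolve alternate locations: keep highest occupancy, first on tie."""
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = a
            order.append(a.name)
        elif a.occ > by_name[a.name].occ:
            by_name[a.name] = a
    return [by_name[n] for n in order]


def read_structure(path: str, first_model_only: bool = False) -> Structure:
    """Read a PDB/mmCIF file, dropping hydrogens and HETATM records.

    Parameters
    ----------
    path:
        File in PDB or mmCIF format; the dialect is detected from the
        extension, falling back to content sniffing.
    first_model_only:
        Keep only the first model of a multi-model file.

    Raises
    ------
    StructureFormatError
        If the file cannot be parsed.
    EmptyStructureError
        If no atom survives filtering.
    """
    fmt = _detect_format(path)
    try:
        coor = gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif
        st = gemmi.read_structure(path, format=coor)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path!r} as {fmt}: {exc}") from exc

    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                if res.het_flag == "H":
                    continue  # HETATM: ligands, waters, ions
                for ga in _select_altloc(list(res)):
                    el = ga.element.name
                    if el in ("H", "D"):
                        continue
                    atoms.append(Atom(
                        chain_id=chain.name,
                        residue_seq=res.seqid.num,
                        insertion_code=res.seqid.icode.strip(),
                        residue_name=res.name,
                        atom_name=ga.name,
                        element=el,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        b_factor=float(ga.b_iso),
                        model_num=model.num,
                    ))
        if first_model_only:
            break
    if not atoms:
        raise EmptyStructureError(
            f"{path!r}: no atoms left after removing hydrogens and HETATM records")
    return Structure(atoms, source_format=fmt)


# ---------------------------------------------------------------------------
# coarse graining
# ---------------------------------------------------------------------------

def coarse_grain(s: Structure, mode: str = "one_per_residue") -> Structure:
    """Reduce to one bead per residue (CA / C3' / C4') or pass through.

    Residues that lack their representative atom, and residues whose name
    is not a standard amino acid or nucleotide, are dropped with a warning.
    """
    if mode == "all_atom":
        return s
    if mode != "one_per_residue":
        raise ValueError(f"unknown coarse-grain mode {mode!r}")
    keep: list[int] = []
    for res in s.residues():
        ptype = res.polymer_type
        if ptype is None:
            logger.warning("dropping non-standard residue %s %s%s%s",
                           res.name, res.chain_id, res.seq, res.insertion_code)
            continue
        rep = REPRESENTATIVE_ATOM[ptype]
        hit = [i for i in res.atom_indices if s.atoms[i].atom_name == rep]
        if not hit:
            logger.warning("residue %s %s%s%s lacks representative atom %s; dropped",
                           res.name, res.chain_id, res.seq, res.insertion_code, rep)
            continue
        keep.append(hit[0])
    return s.subset(keep)


def mean_bfactor(s: Structure) -> float | None:
    """Mean B-factor of the retained atoms; None when unavailable.

    A structure whose B column is absent or all-zero carries no thermal
    information, so the spring-constant calibration cannot use it.
    """
    if s.n_atoms == 0:
        raise EmptyStructureError("mean B-factor of an empty structure")
    b = s.b_factors()
    if not np.any(b > 0):
        logger.info("B-factors unavailable (column zero or missing)")
        return None
    return float(np.mean(b))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _to_gemmi(frames: Iterable[np.ndarray], template: Structure,
              name: str = "enmpath") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for num, frame in enumerate(frames, start=1):
        xyz = np.asarray(frame, dtype=float).reshape(-1, 3)
        if len(xyz) != template.n_atoms:
            raise SizeMismatchError(
                f"frame {num} has {len(xyz)} atoms, template has {template.n_atoms}")
        model = gemmi.Model(num)
        chain = None
        residue = None
        res_key = None
        for atom, row in zip(template.atoms, xyz):
            if chain is None or chain.name != atom.chain_id:
                chain = gemmi.Chain(atom.chain_id)
                model.add_chain(chain)
                chain = model[len(model) - 1]
                res_key = None
            key = (atom.residue_seq, atom.insertion_code, atom.residue_name)
            if key != res_key:
                residue = gemmi.Residue()
                residue.name = atom.residue_name
                residue.seqid = gemmi.SeqId(atom.residue_seq,
                                            atom.insertion_code or " ")
                residue.het_flag = "A"
                chain.add_residue(residue)
                residue = chain[len(chain) - 1]
                res_key = key
            ga = gemmi.Atom()
            ga.name = atom.atom_name
            ga.element = gemmi.Element(atom.element)
            # 3 decimals: the PDB convention, and the explicit round-trip tol
            ga.pos = gemmi.Position(*(round(v, 3) for v in row))
            ga.occ = 1.0
            ga.b_iso = atom.b_factor
            residue.add_atom(ga)
        st.add_model(model)
    st.setup_entities()
    return st


def to_mmcif_text(s: Structure, name: str = "enmpath") -> str:
    """Render a Structure (possibly multi-model) as mmCIF text."""
    groups: dict[int, list[int]] = {}
    for i, a in enumerate(s.atoms):
        groups.setdefault(a.model_num, []).append(i)
    first = s.subset(groups[min(groups)])
    frames = [s.subset(idx).coords() for idx in groups.values()]
    return _to_gemmi(frames, first, name=name).make_mmcif_document().as_string()


def to_pdb_text(s: Structure) -> str:
    """Render as PDB text (single-character chain IDs only)."""
    for cid in s.chain_ids():
        if len(cid) > 1:
            raise StructureFormatError(
                f"chain id {cid!r} does not fit the PDB format; write mmCIF")
    groups: dict[int, list[int]] = {}
    for i, a in enumerate(s.atoms):
        groups.setdefault(a.model_num, []).append(i)
    first = s.subset(groups[min(groups)])
    frames = [s.subset(idx).coords() for idx in groups.values()]
    return _to_gemmi(frames, first).make_pdb_string()


def write_structure(s: Structure, path: str) -> None:
    """Write a Structure as mmCIF (or PDB when path ends in .pdb)."""
    if path.lower().endswith(".pdb"):
        text = to_pdb_text(s)
    else:
        text = to_mmcif_text(s)
    with open(path, "w") as fh:
        fh.write(text)


def write_trajectory(frames: Sequence[np.ndarray], template: Structure,
                     path: str) -> None:
    """Write an ordered list of coordinate frames as one multi-model mmCIF.

    Model numbers are sequential from 1; atom identities are copied from
    the template structure.
    """
    frames = list(frames)
    if not frames:
        raise SizeMismatchError("trajectory must contain at least one frame")
    st = _to_gemmi(frames, template, name="trajectory")
    with open(path, "w") as fh:
        fh.write(st.make_mmcif_document().as_string())
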