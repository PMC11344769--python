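"""Macromolecular structure I/O.

Reads and writes single protein chains from PDB / mmCIF files (via gemmi)
and exposes clean per-residue backbone coordinates and confidence values.
Only polymer residues are retained (plus the selenium variants MSE/SEC,
which downstream template preparation standardizes); alternate locations
are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenium variants kept as residues; mapped to their standard analogs
    "MSE": "M", "SEC": "C",
}

#: residue names gemmi flags as HETATM that we still keep
_KEPT_HET = {"MSE", "SEC"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class ChainNotFoundError(KeyError):
    """Requested chain is absent from the file."""


class StructureFormatError(ValueError):
    """File could not be parsed as PDB or mmCIF."""


@dataclass
class AtomRecord:
    """One atom after altloc resolution.

    ``xyz`` is in Å, ``bfactor`` in Å² (or plDDT for predicted models),
    ``occupancy`` in [0, 1].
    """

    name: str
    element: str
    xyz: np.ndarray
    bfactor: float
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    """One residue with author numbering preserved alongside a 0-based index."""

    author_number: int
    insertion_code: str
    index: int
    name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)
    plddt: float | None = None

    @property
    def author_id(self) -> str:
        return f"{self.author_number}{self.insertion_code}".strip()

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class StructureModel:
    """A parsed single chain: ordered residues plus derived sequence."""

    id: str
    chain_id: str
    residues: list[Residue]
    source_format: str = "PDB"

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_by_author(self, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.author_number == number and r.insertion_code.strip() == icode.strip():
                return r
        raise KeyError(f"residue {number}{icode} not found in chain {self.chain_id}")

    def author_numbers(self) -> list[int]:
        return [r.author_number for r in self.residues]


def _resolve_altlocs(raw_atoms: Iterable[gemmi.Atom]) -> dict[str, AtomRecord]:
    """Keep one atom per name: highest occupancy, ties -> alphabetically
    first altloc id (blank altloc sorts first)."""
    best: dict[str, AtomRecord] = {}
    for at in raw_atoms:
        rec = AtomRecord(
            name=at.name,
            element=at.element.name,
            xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
            bfactor=at.b_iso,
            occupancy=at.occ,
            altloc=at.altloc if at.altloc != "\x00" else "",
        )
        prev = best.get(at.name)
        if prev is None:
            best[at.name] = rec
        elif rec.occupancy > prev.occupancy or (
            rec.occupancy == prev.occupancy and rec.altloc < prev.altloc
        ):
            best[at.name] = rec
    return best


def read_structure(
    path: str | Path,
    chain: str | None = None,
    model_index: int = 0,
) -> StructureModel:
    """Read one chain of a PDB or mmCIF file.

    HETATM residues are dropped except MSE and SEC; altlocs are resolved to
    the highest-occupancy conformer (ties broken alphabetically by altloc
    id); residues keep file order and get a contiguous 0-based index.

    Raises
    ------
    ChainNotFoundError
        if the requested chain is absent (the message lists available chains).
    StructureFormatError
        if the file cannot be parsed.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models found")
    source_format = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    model = st[model_index]
    names = [ch.name for ch in model]
    if chain is None:
        if len(names) != 1:
            raise ChainNotFoundError(
                f"{path}: chain must be given; available chains: {', '.join(names)}"
            )
        chain = names[0]
    if chain not in names:
        raise ChainNotFoundError(
            f"chain {chain!r} not found in {path}; available chains: {', '.join(names)}"
        )
    gchain = model[chain]

    residues: list[Residue] = []
    for gres in gchain:
        het = gres.het_flag == "H"
        if het and gres.name not in _KEPT_HET:
            continue
        if gres.name == "HOH":
            continue
        atoms = _resolve_altlocs(gres)
        if not atoms:
            continue
        residues.append(
            Residue(
                author_number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                index=len(residues),
                name=gres.name,
                atoms=atoms,
            )
        )
    return StructureModel(
        id=f"{path.stem}:{chain}",
        chain_id=chain,
        residues=residues,
        source_format=source_format,
    )


def extract_plddt(
    model: StructureModel,
    scale: str = "auto",
) -> np.ndarray:
    """Per-residue confidence (plDDT, 0-100 scale) from the CA B-factor column.

    AlphaFold writes plDDT into the B-factor field; some exports use a 0-1
    scale, detected when the chain maximum is ≤ 1.0 (override with
    ``scale='0-100'`` or ``scale='0-1'``). Values are clipped to [0, 100].
    """
    vals = []
    for res in model.residues:
        ca = res.atoms.get("CA")
        if ca is None:
            raise ValueError(
                f"residue {res.name} {res.author_id} has no CA atom; cannot read plDDT"
            )
        vals.append(ca.bfactor)
    arr = np.asarray(vals, dtype=float)
    if scale == "0-1" or (scale == "auto" and arr.size and arr.max() <= 1.0):
        arr = arr * 100.0
    return np.clip(arr, 0.0, 100.0)


def annotate_plddt(model: StructureModel, scale: str = "auto") -> StructureModel:
    """Store extract_plddt values on each residue; returns the same model."""
    for res, v in zip(model.residues, extract_plddt(model, scale=scale)):
        res.plddt = float(v)
    return model


def backbone_coords(
    model: StructureModel,
    atom_set: Sequence[str] = BACKBONE_ATOMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered coordinates of the requested atoms plus a completeness mask.

    Residues missing any requested atom are excluded from the coordinate
    array (and logged); the boolean mask has one entry per residue.
    """
    if not atom_set:
        raise ValueError("atom_set must be nonempty")
    coords: list[np.ndarray] = []
    mask = np.zeros(len(model.residues), dtype=bool)
    for i, res in enumerate(model.residues):
        if all(a in res.atoms for a in atom_set):
            mask[i] = True
            coords.extend(res.atoms[a].xyz for a in atom_set)
        else:
            missing = [a for a in atom_set if a not in res.atoms]
            logger.warning(
                "residue %s %s incomplete (missing %s); excluded",
                res.name, res.author_id, ",".join(missing),
            )
    if coords:
        return np.vstack(coords), mask
    return np.zeros((0, 3)), mask


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")
    gchain = gemmi.Chain(model.chain_id or "A")
    for res in model.residues:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
        gres.het_flag = "H" if res.name in _KEPT_HET else "A"
        for rec in res.atoms.values():
            at = gemmi.Atom()
            at.name = rec.name
            at.element = gemmi.Element(rec.element)
            at.pos = gemmi.Position(*rec.xyz)
            at.b_iso = rec.bfactor
            at.occ = rec.occupancy
            gres.add_atom(at)
        gchain.add_residue(gres)
    gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path, format: str | None = None) -> Path:
    """Write the chain as PDB or mmCIF (format from extension when omitted).

    Round trip through :func:`read_structure` preserves residue names,
    author numbering, coordinates to 3 decimals and B-factors to 2 decimals.
    """
    path = Path(path)
    if format is None:
        format = "mmCIF" if path.suffix.lower() in {".cif", ".mmcif"} else "PDB"
    st = _to_gemmi(model)
    if format.upper() == "PDB":
        st.write_pdb(str(path))
    elif format.lower() in {"mmcif", "cif"}:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical positions between two equal-length sequences
    (gapless, position-wise)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        raise ValueError("empty sequences")
    return sum(x == y for x, y in zip(a, b)) / len(a)
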