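"""Template preparation and composite scoring for fold ranking.

To ask a structure-prediction network which of two conformations it
considers lower-energy, each experimental fold is passed as a sequence-
agnostic template: side chains beyond Cβ are stripped, glycines receive
an ideal Cβ to mask their identity, and selenium variants are
standardized (MSE -> MET, SEC -> CYS).  The network's confidence on the
resulting model is condensed into a composite score of plDDT, pTM and
the TM-score between output and template; the fold with the larger
composite is the preferred (putative ground-state) conformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure_io import AtomRecord, Residue, StructureModel

logger = logging.getLogger(__name__)

TEMPLATE_ATOMS = ("N", "CA", "C", "O", "CB")
CB_BOND_LENGTH = 1.522  # Å, ideal CA-CB

#: local-frame coefficients for the ideal Cβ direction from N, CA, C
_CB_COEFF_A, _CB_COEFF_B, _CB_COEFF_C = -0.58273431, 0.56802827, -0.54067466


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position from backbone N, CA, C.

    The direction comes from the standard local-frame construction
    (linear combination of CA-N, C-CA and their cross product); the atom
    is then placed at exactly 1.522 Å from CA, which makes the bond length
    independent of small deviations in backbone geometry.  The
    construction is equivariant: rigid motion of the backbone moves the
    Cβ with it.
    """
    b = ca - n
    c_vec = c - ca
    a = np.cross(b, c_vec)
    direction = _CB_COEFF_A * a + _CB_COEFF_B * b + _CB_COEFF_C * c_vec
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise ValueError("degenerate backbone geometry; cannot place CB")
    return ca + CB_BOND_LENGTH * direction / norm


@dataclass
class TemplateModel:
    model: StructureModel
    provenance: str = "stripped, Gly-CB-added, standardized"


def strip_to_template(structure: StructureModel) -> TemplateModel:
    """Reduce a chain to a sequence-agnostic template.

    Keeps only {N, CA, C, O, CB}; adds an ideal Cβ to glycine; renames
    MSE -> MET (SE -> SD) and SEC -> CYS (SE -> SG), retyping selenium to
    sulfur.  Residues missing any of N/CA/C are dropped with a warning;
    an empty result is an error.  Idempotent.
    """
    out_res: list[Residue] = []
    for res in structure.residues:
        if not all(a in res.atoms for a in ("N", "CA", "C")):
            logger.warning(
                "residue %s %s missing backbone; dropped from template",
                res.name, res.author_id,
            )
            continue
        name = res.name
        rename: dict[str, tuple[str, str]] = {}
        if name == "MSE":
            name = "MET"
            rename = {"SE": ("SD", "S")}
        elif name == "SEC":
            name = "CYS"
            rename = {"SE": ("SG", "S")}
        atoms: dict[str, AtomRecord] = {}
        for aname, rec in res.atoms.items():
            new_name, new_elem = rename.get(aname, (aname, rec.element))
            if new_name in TEMPLATE_ATOMS:
                atoms[new_name] = AtomRecord(
                    name=new_name, element=new_elem, xyz=rec.xyz.copy(),
                    bfactor=rec.bfactor, occupancy=rec.occupancy,
                )
        if "CB" not in atoms:
            cb_xyz = ideal_cb(
                atoms["N"].xyz, atoms["CA"].xyz, atoms["C"].xyz
            )
            atoms["CB"] = AtomRecord(
                name="CB", element="C", xyz=cb_xyz,
                bfactor=atoms["CA"].bfactor, occupancy=1.0,
            )
        out_res.append(
            Residue(
                author_number=res.author_number,
                insertion_code=res.insertion_code,
                index=len(out_res),
                name=name,
                atoms=atoms,
            )
        )
    if not out_res:
        raise ValueError("no residues with complete backbone; cannot build template")
    return TemplateModel(
        model=StructureModel(
            id=f"{structure.id}|template",
            chain_id=structure.chain_id,
            residues=out_res,
            source_format=structure.source_format,
        )
    )


@dataclass
class CompositeScore:
    plddt: float
    ptm: float
    tm_out_template: float
    composite: float


def composite_score(
    plddt: float,
    ptm: float,
    tm_out_template: float,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CompositeScore:
    """Composite model-quality score (plddt/100)^a · ptm^b · tm^c.

    With default unit weights this is the plain product; it is strictly
    increasing in each ingredient when the others are positive, so a
    higher score means a more confident prediction closer to the template.
    """
    if not (0.0 <= plddt <= 100.0):
        raise ValueError(f"plddt {plddt} outside [0, 100]")
    if not (0.0 <= ptm <= 1.0):
        raise ValueError(f"ptm {ptm} outside [0, 1]")
    if not (0.0 <= tm_out_template <= 1.0):
        raise ValueError(f"tm {tm_out_template} outside [0, 1]")
    a, b, c = weights
    comp = (plddt / 100.0) ** a * ptm**b * tm_out_template**c
    return CompositeScore(plddt, ptm, tm_out_template, comp)


def rank_fold_pair(
    score_ground: CompositeScore,
    score_excited: CompositeScore,
) -> tuple[str, float]:
    """Compare the composite scores of the two folds of one pair.

    Returns ('ground' | 'excited' | 'undecided', margin = ground − excited).
    """
    margin = score_ground.composite - score_excited.composite
    if margin > 0:
        return "ground", margin
    if margin < 0:
        return "excited", margin
    return "undecided", 0.0
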