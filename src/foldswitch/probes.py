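"""Structure probes: flexibility, contact maps, distances, plDDT windows.

Normalized B-factors measure crystallographic flexibility per chain:

    BF_norm = (BF - mu_BF) / sigma_BF

with a residue flagged flexible at BF_norm >= 2.0.  Contact maps support
comparing a predicted conformation against an experimental one (unique
vs common contacts, optionally overlaid with externally computed
coevolution couplings), and simple residue-distance probes track
open/closed-type conformational coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import StructureModel

FLEXIBLE_CUTOFF = 2.0


@dataclass
class FlexibilityProfile:
    author_ids: list[str]
    bf: np.ndarray
    mu: float
    sigma: float
    bf_norm: np.ndarray
    flexible: np.ndarray  # boolean, BF_norm >= 2.0
    sd_convention: str = "sample (n-1)"


def normalize_bfactors(model: StructureModel, atom: str = "CA") -> FlexibilityProfile:
    """Per-residue normalized B-factors over one chain.

    Uses the chosen atom's B-factor (CA by default; ``atom='mean'``
    averages all heavy atoms per residue) and the sample (n-1) standard
    deviation.  Constant B-factors are a degenerate input and an error.
    """
    ids, vals = [], []
    for res in model.residues:
        if atom == "mean":
            bs = [a.bfactor for a in res.atoms.values()]
            if not bs:
                continue
            ids.append(res.author_id)
            vals.append(float(np.mean(bs)))
        else:
            rec = res.atoms.get(atom)
            if rec is not None:
                ids.append(res.author_id)
                vals.append(rec.bfactor)
    if len(vals) < 2:
        raise ValueError("need at least 2 residues with the chosen atom")
    bf = np.asarray(vals)
    mu = float(bf.mean())
    sigma = float(bf.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("constant B-factors: normalization undefined")
    bf_norm = (bf - mu) / sigma
    return FlexibilityProfile(
        author_ids=ids, bf=bf, mu=mu, sigma=sigma,
        bf_norm=bf_norm, flexible=bf_norm >= FLEXIBLE_CUTOFF,
    )


def region_flexibility(
    profile: FlexibilityProfile,
    model: StructureModel,
    region: list[tuple[int, int]],
) -> dict:
    """Flexibility summary of an author-numbered region.

    Reports both readings of "flexible region": whether any residue
    crosses the 2.0 cutoff, and the fraction of residues that do.
    """
    id_to_pos = {rid: i for i, rid in enumerate(profile.author_ids)}
    sel = [
        id_to_pos[r.author_id] for r in model.residues
        if r.author_id in id_to_pos
        and any(lo <= r.author_number <= hi for lo, hi in region)
    ]
    if not sel:
        raise ValueError("region has no residues in the flexibility profile")
    vals = profile.bf_norm[sel]
    return {
        "n_residues": len(sel),
        "max_bf_norm": float(vals.max()),
        "any_flexible": bool((vals >= FLEXIBLE_CUTOFF).any()),
        "fraction_flexible": float((vals >= FLEXIBLE_CUTOFF).mean()),
    }


@dataclass(frozen=True)
class Contact:
    i: int           # author number, chain_i
    j: int
    chain_i: str
    chain_j: str
    kind: str        # intramolecular | intermolecular


@dataclass
class ContactMap:
    contacts: set[Contact]
    cutoff: float
    atom_mode: str
    min_seq_sep: int

    def pairs(self) -> set[tuple[int, int, str, str]]:
        return {(c.i, c.j, c.chain_i, c.chain_j) for c in self.contacts}


def _contact_atoms(res, atom_mode: str) -> np.ndarray:
    if atom_mode == "heavy":
        pts = [a.xyz for a in res.atoms.values() if a.element not in ("H", "D")]
        return np.vstack(pts) if pts else np.zeros((0, 3))
    if atom_mode == "CB":
        rec = res.atoms.get("CB") or res.atoms.get("CA")
    else:
        rec = res.atoms.get(atom_mode)
    return rec.xyz[None, :] if rec is not None else np.zeros((0, 3))


def contact_map(
    models: list[StructureModel] | StructureModel,
    cutoff: float = 8.0,
    atom_mode: str = "CB",
    min_seq_sep: int = 5,
) -> ContactMap:
    """Residue-residue contacts within (and between) one or two chains.

    Intrachain pairs require |i - j| >= min_seq_sep (on chain indices) and
    are canonicalized i < j; interchain pairs are unrestricted and tagged
    intermolecular.  ``atom_mode`` 'CB' uses Cβ (Cα for glycine), 'CA'
    uses Cα, 'heavy' the minimal heavy-atom distance.
    """
    if isinstance(models, StructureModel):
        models = [models]
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    contacts: set[Contact] = set()
    cut2 = cutoff * cutoff
    for mi, ma in enumerate(models):
        for mj in range(mi, len(models)):
            mb = models[mj]
            intra = mi == mj
            for ra in ma.residues:
                pa = _contact_atoms(ra, atom_mode)
                if pa.size == 0:
                    continue
                for rb in mb.residues:
                    if intra:
                        if rb.index - ra.index < min_seq_sep:
                            continue
                    pb = _contact_atoms(rb, atom_mode)
                    if pb.size == 0:
                        continue
                    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
                    if d2.min() <= cut2:
                        i, j = ra.author_number, rb.author_number
                        ci, cj = ma.chain_id, mb.chain_id
                        if intra and j < i:
                            i, j = j, i
                        contacts.add(Contact(
                            i=i, j=j, chain_i=ci, chain_j=cj,
                            kind="intramolecular" if intra else "intermolecular",
                        ))
    return ContactMap(contacts=contacts, cutoff=cutoff,
                      atom_mode=atom_mode, min_seq_sep=min_seq_sep)


def compare_contact_maps(
    A: ContactMap, B: ContactMap
) -> tuple[set[Contact], set[Contact], set[Contact]]:
    """Exact partition (unique_A, unique_B, common) of two contact maps."""
    import logging
    if (A.cutoff, A.atom_mode, A.min_seq_sep) != (B.cutoff, B.atom_mode, B.min_seq_sep):
        logging.getLogger(__name__).warning(
            "comparing contact maps with differing parameters: %s vs %s",
            (A.cutoff, A.atom_mode, A.min_seq_sep),
            (B.cutoff, B.atom_mode, B.min_seq_sep),
        )
    common = A.contacts & B.contacts
    return A.contacts - common, B.contacts - common, common


def load_coevolution_pairs(path: str | Path) -> list[tuple[int, int, float]]:
    """Read a coevolution-coupling TSV of (i, j, score), 1-based residue
    numbers; duplicates are collapsed keeping the maximal score and pairs
    are canonicalized i < j."""
    path = Path(path)
    best: dict[tuple[int, int], float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            i, j, score = int(parts[0]), int(parts[1]), float(parts[2])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
        if j < i:
            i, j = j, i
        key = (i, j)
        if key not in best or score > best[key]:
            best[key] = score
    return [(i, j, s) for (i, j), s in sorted(best.items())]


def residue_distance(
    model: StructureModel,
    res_a: int,
    res_b: int,
    atom: str = "CA",
) -> float:
    """Euclidean distance (Å) between the chosen atom of two author-
    numbered residues — e.g. an Arg–Glu pair tracking domain closure."""
    xyz = []
    for num in (res_a, res_b):
        res = model.residue_by_author(num)
        rec = res.atoms.get(atom)
        if rec is None:
            raise KeyError(f"residue {res.name} {res.author_id} has no atom {atom}")
        xyz.append(rec.xyz)
    return float(np.linalg.norm(xyz[0] - xyz[1]))


def mean_plddt_window(
    model: StructureModel,
    region: list[tuple[int, int]],
) -> float:
    """Mean CA plDDT over an author-numbered window (e.g. the folded core
    of a partly disordered chain)."""
    from .structure_io import extract_plddt

    plddts = extract_plddt(model)
    sel = [
        i for i, r in enumerate(model.residues)
        if any(lo <= r.author_number <= hi for lo, hi in region)
    ]
    if not sel:
        raise ValueError("empty plDDT window")
    return float(np.mean(plddts[sel]))
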