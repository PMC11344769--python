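"""Synthetic fold-switch pairs, prediction ensembles and toy MSAs.

Builds idealized protein backbones from canonical dihedral angles
(helix φ=-57°, ψ=-47°; strand φ=-139°, ψ=+135°; coil randomized within
allowed ranges), pairs of reference structures sharing one sequence but
differing in secondary structure over a fold-switching region, and
prediction ensembles that are mixtures of near-Fold-A, near-Fold-B and
decoy models with controllable coordinate noise and planted per-residue
plDDT profiles.  Everything is deterministic under an explicit seed, so
the whole assessment pipeline is testable without downloads.

What these toys emulate — and what they do not: they reproduce the
*statistical* structure of real benchmark data (mixture fractions,
confidence/correctness correlation, region-restricted structural
differences) with protein-like local geometry, but carry no side chains,
no packing quality and no physical energetics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assessment import FoldSwitchPair
from .structure_io import AtomRecord, Residue, StructureModel
from .superpose import Correspondence, build_correspondence, kabsch, region_restrict, tm_score

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

DIHEDRALS = {"H": (-57.0, -47.0), "E": (-139.0, 135.0)}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from reference atoms A-B-C with given internal
    coordinates (natural extension reference frame)."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + m @ d_local


def _coil_dihedrals(rng: np.random.Generator) -> tuple[float, float]:
    # sample from broad allowed basins of the Ramachandran map
    phi = float(rng.uniform(-160.0, -60.0))
    psi = float(rng.uniform(-70.0, 170.0))
    return phi, psi


def make_ideal_backbone(
    ss: str,
    seed: int = 0,
    sequence: str | None = None,
    start_number: int = 1,
    model_id: str = "toy",
) -> StructureModel:
    """Backbone (N, CA, C, O) built from canonical dihedrals per
    secondary-structure character (H helix, E strand, C coil).

    Deterministic given the seed (which only randomizes coil torsions).
    """
    if not ss:
        raise ValueError("empty secondary-structure string")
    bad = set(ss) - {"H", "E", "C"}
    if bad:
        raise ValueError(f"invalid secondary-structure characters: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    n_res = len(ss)
    if sequence is None:
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n_res))
    if len(sequence) != n_res:
        raise ValueError("sequence length must match ss length")

    torsions = []
    for ch in ss:
        torsions.append(DIHEDRALS.get(ch) or _coil_dihedrals(rng))

    # first residue in a fixed local frame; the φ of residue 1 sets C
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    C = [_nerf(np.array([0.0, 1.0, 0.0]), N[0], CA[0],
               _B_CA_C, _A_N_CA_C, torsions[0][0])]
    O: list[np.ndarray] = []

    for i in range(n_res - 1):
        psi_i = torsions[i][1]
        phi_next = torsions[i + 1][0]
        n_next = _nerf(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, psi_i)
        ca_next = _nerf(CA[i], C[i], n_next, _B_N_CA, _A_C_N_CA, 180.0)
        c_next = _nerf(C[i], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi_next)
        O.append(_nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi_i + 180.0))
        N.append(n_next)
        CA.append(ca_next)
        C.append(c_next)
    O.append(_nerf(N[-1], CA[-1], C[-1], _B_C_O, _A_CA_C_O, torsions[-1][1] + 180.0))

    residues = []
    for i in range(n_res):
        atoms = {
            "N": AtomRecord("N", "N", N[i], 0.0),
            "CA": AtomRecord("CA", "C", CA[i], 0.0),
            "C": AtomRecord("C", "C", C[i], 0.0),
            "O": AtomRecord("O", "O", O[i], 0.0),
        }
        residues.append(Residue(
            author_number=start_number + i,
            insertion_code="",
            index=i,
            name=ONE_TO_THREE[sequence[i]],
            atoms=atoms,
        ))
    return StructureModel(id=model_id, chain_id="A", residues=residues)


@dataclass
class ToyPairSpec:
    """Parameters of a synthetic fold-switch pair.

    The two secondary-structure strings must differ exactly and only
    inside the fold-switching region (author-numbered, inclusive).
    Defaults give an 80-residue chain whose residues 25-60 switch between
    helix (fold A) and strand (fold B) against mixed flanks.
    """

    length: int = 80
    fs_region: tuple[int, int] = (25, 60)
    ss_A: str | None = None
    ss_B: str | None = None
    seed: int = 0

    def resolved_ss(self) -> tuple[str, str]:
        lo, hi = self.fs_region
        if not (1 <= lo <= hi <= self.length):
            raise ValueError("fs_region outside chain")
        if self.ss_A is None or self.ss_B is None:
            # coil linkers flank the region so coordinates vary with seed
            n_left, n_right = lo - 1, self.length - hi
            flank_left = "H" * max(0, n_left - 2) + "C" * min(2, n_left)
            flank_right = "C" * min(2, n_right) + "E" * max(0, n_right - 2)
            ss_a = flank_left + "H" * (hi - lo + 1) + flank_right
            ss_b = flank_left + "E" * (hi - lo + 1) + flank_right
        else:
            ss_a, ss_b = self.ss_A, self.ss_B
        if len(ss_a) != len(ss_b) or len(ss_a) != self.length:
            raise ValueError("secondary-structure strings must match length")
        diff = [i for i, (x, y) in enumerate(zip(ss_a, ss_b)) if x != y]
        if not diff or min(diff) + 1 < lo or max(diff) + 1 > hi:
            raise ValueError("ss strings must differ only inside fs_region")
        return ss_a, ss_b


def _region_tm_between(ref_a: StructureModel, ref_b: StructureModel,
                       region: tuple[int, int]) -> float:
    corr = build_correspondence(ref_a, ref_b)
    corr = region_restrict(corr, [region], "A", ref_a)
    return tm_score(ref_a, ref_b, corr, L_norm=len(corr)).tm


def make_toy_pair(spec: ToyPairSpec, max_attempts: int = 25) -> FoldSwitchPair:
    """Two reference structures sharing one sequence but with distinct
    secondary structure over the fold-switching region.

    The pair is regenerated with fresh coil seeds until the region
    TM-score between the two references falls below 0.5, so the pair
    is Complex-grade different by construction.
    """
    ss_a, ss_b = spec.resolved_ss()
    rng = np.random.default_rng(spec.seed)
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=spec.length))
    for attempt in range(max_attempts):
        sub = int(rng.integers(0, 2**31 - 1))
        ref_a = make_ideal_backbone(ss_a, seed=sub, sequence=sequence,
                                    model_id=f"pair{spec.seed}_refA")
        ref_b = make_ideal_backbone(ss_b, seed=sub + 1, sequence=sequence,
                                    model_id=f"pair{spec.seed}_refB")
        if _region_tm_between(ref_a, ref_b, spec.fs_region) < 0.5:
            return FoldSwitchPair(
                pair_id=f"toy_{spec.seed}",
                ref_A=ref_a,
                ref_B=ref_b,
                fs_region_A=[spec.fs_region],
                fs_region_B=[spec.fs_region],
            )
    raise RuntimeError(
        "could not build references with region TM < 0.5; try a larger region"
    )


def perturb(model: StructureModel, target_rmsd: float, seed: int = 0,
            tol: float = 0.05, model_id: str | None = None) -> StructureModel:
    """Gaussian coordinate noise rescaled so the optimal-superposition
    backbone RMSD to the input lands within ``tol`` (5%) of the target."""
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be >= 0")
    coords = []
    for res in model.residues:
        for rec in res.atoms.values():
            coords.append(rec.xyz)
    P = np.vstack(coords)
    if target_rmsd == 0:
        Q = P.copy()
    else:
        rng = np.random.default_rng(seed)
        noise = rng.normal(size=P.shape)
        scale = target_rmsd / np.sqrt((noise**2).sum() / len(P))
        Q = P + noise * scale
        for _ in range(8):
            _, achieved = kabsch(P, Q)
            if abs(achieved - target_rmsd) <= tol * target_rmsd:
                break
            Q = P + (Q - P) * (target_rmsd / achieved)
    out_res = []
    k = 0
    for res in model.residues:
        atoms = {}
        for name, rec in res.atoms.items():
            atoms[name] = AtomRecord(name, rec.element, Q[k], rec.bfactor,
                                     rec.occupancy)
            k += 1
        out_res.append(Residue(res.author_number, res.insertion_code,
                               res.index, res.name, atoms))
    return StructureModel(
        id=model_id or f"{model.id}|perturbed",
        chain_id=model.chain_id,
        residues=out_res,
    )


@dataclass
class EnsembleSpec:
    """Mixture parameters of a synthetic prediction ensemble.

    Class weights (near-fold-A, near-fold-B, decoy) must sum to 1.
    ``plddt_polarity`` 'aligned' gives correct classes high confidence,
    'against' gives the decoys high confidence (the confident-but-wrong
    regime).  Per-class coordinate noise is the target backbone RMSD to
    the parent reference in Å.
    """

    n_models: int = 100
    weights: tuple[float, float, float] = (0.6, 0.3, 0.1)
    noise: dict[str, float] = field(
        default_factory=lambda: {"A": 0.8, "B": 0.8, "OTHER": 1.5}
    )
    plddt_polarity: str = "aligned"
    plddt_params: dict[str, tuple[float, float]] | None = None
    seed: int = 0

    def resolved_plddt(self) -> dict[str, tuple[float, float]]:
        if self.plddt_params is not None:
            return self.plddt_params
        if self.plddt_polarity == "aligned":
            return {"A": (85.0, 6.0), "B": (82.0, 6.0), "OTHER": (55.0, 8.0)}
        return {"A": (60.0, 6.0), "B": (60.0, 6.0), "OTHER": (88.0, 4.0)}


def _decoy_reference(pair: FoldSwitchPair, spec_region: tuple[int, int],
                     rng: np.random.Generator, sequence: str) -> StructureModel:
    """A protein-like decoy: the fold-A secondary-structure string is
    shuffled and rebuilt, regenerated until the fold-switching region
    TM-score against both references is <= 0.5."""
    ss_len = len(sequence)
    # shuffled mix of H/E/C keeps the decoy protein-like but unrelated
    template = ("H" * (ss_len // 3) + "E" * (ss_len // 3)
                + "C" * (ss_len - 2 * (ss_len // 3)))
    for _ in range(20):
        perm = rng.permutation(list(template))
        ss = "".join(perm)
        decoy = make_ideal_backbone(
            ss, seed=int(rng.integers(0, 2**31 - 1)), sequence=sequence,
            model_id="decoy",
        )
        tm_a = _region_tm_between(pair.ref_A, decoy, spec_region)
        tm_b = _region_tm_between(pair.ref_B, decoy, spec_region)
        if tm_a <= 0.5 and tm_b <= 0.5:
            return decoy
    raise RuntimeError("could not generate a decoy dissimilar to both folds")


def _plant_plddt(model: StructureModel, mean: float, sd: float,
                 rng: np.random.Generator) -> None:
    for res in model.residues:
        v = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
        res.plddt = v
        for rec in res.atoms.values():
            rec.bfactor = v


def make_ensemble(
    pair: FoldSwitchPair,
    spec: EnsembleSpec,
) -> tuple[list[StructureModel], list[str]]:
    """Draw a synthetic prediction ensemble for a pair.

    The class composition (A / B / OTHER) matches the mixture weights
    exactly (largest-remainder rounding) with a seeded random assignment
    order, so planted fractions are sharp ground truth.  Near-
    fold classes are noise-perturbed copies of the corresponding
    reference, decoys are independently generated unrelated folds
    (guaranteed region TM <= 0.5 to both references).  Per-residue plDDT
    values are planted in the B-factor column per class.  Returns the
    models and their ground-truth class labels ('A' | 'B' | 'OTHER').
    """
    w = np.asarray(spec.weights, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must be nonnegative and sum to 1")
    rng = np.random.default_rng(spec.seed)
    plddt_params = spec.resolved_plddt()
    region = pair.fs_region_A[0]
    # plant the mixture composition exactly (largest-remainder rounding),
    # then shuffle the assignment order under the seed; this makes the
    # planted fractions a sharp ground truth for recovery checks instead
    # of an extra layer of sampling noise
    exact = w * spec.n_models
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[: spec.n_models - counts.sum()]:
        counts[i] += 1
    classes = np.repeat(np.array(["A", "B", "OTHER"]), counts)
    rng.shuffle(classes)
    models: list[StructureModel] = []
    labels: list[str] = []
    sequence = pair.sequence
    for k, cls in enumerate(classes):
        sub = int(rng.integers(0, 2**31 - 1))
        if cls == "A":
            m = perturb(pair.ref_A, spec.noise["A"], seed=sub,
                        model_id=f"model_{k:04d}")
        elif cls == "B":
            m = perturb(pair.ref_B, spec.noise["B"], seed=sub,
                        model_id=f"model_{k:04d}")
        else:
            decoy = _decoy_reference(pair, region, rng, sequence)
            m = perturb(decoy, spec.noise["OTHER"], seed=sub,
                        model_id=f"model_{k:04d}")
        mean, sd = plddt_params[cls]
        _plant_plddt(m, mean, sd, rng)
        models.append(m)
        labels.append(str(cls))
    return models, labels


def make_toy_msa(
    target: str,
    n_rows: int = 20,
    mutation_rate: float = 0.1,
    gap_rate: float = 0.02,
    seed: int = 0,
    target_id: str = "target",
) -> "MSA":
    """Toy alignment: homolog rows are copies of the target with i.i.d.
    substitutions at ``mutation_rate`` and occasional gaps; the target row
    is exact.  Deterministic given the seed."""
    from .msa import MSA

    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = [(target_id, target)]
    for r in range(1, n_rows):
        chars = []
        for c in target:
            u = rng.random()
            if u < gap_rate:
                chars.append("-")
            elif u < gap_rate + mutation_rate:
                chars.append(str(rng.choice(list(AMINO_ACIDS.replace(c, "") or AMINO_ACIDS))))
            else:
                chars.append(c)
        rows.append((f"homolog_{r}", "".join(chars)))
    return MSA(
        target_id=target_id,
        target_sequence=target,
        rows=rows,
        column_map={i: i for i in range(len(target))},
        format="a3m",
    )
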