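"""Rigid-body superposition and structure-similarity metrics.

Implements the Kabsch algorithm for optimal rigid superposition, the
TM-score with the standard length-dependent distance scale

    d0(L) = 1.24 (L - 15)^(1/3) - 1.8   (floored at 0.5 Å)

and backbone RMSD over an explicit residue correspondence.  Because a
predicted model and its experimental reference share one sequence, the
correspondence is built by residue identity rather than by
sequence-independent structural alignment; the TM-score then optimizes
only the superposition, seeded from the full correspondence and from
contiguous fragments, each refined by iterative re-superposition on the
residues currently within a distance-inclusion cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_io import StructureModel

logger = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation (rotation proper, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class Correspondence:
    """Ordered residue-index pairs (indexA, indexB), strictly increasing."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        a = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if any(x >= y for x, y in zip(a, a[1:])) or any(
            x >= y for x, y in zip(b, b[1:])
        ):
            raise ValueError("correspondence indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class MetricResult:
    tm: float
    rmsd: float
    n_aligned: int
    L_norm: int
    d0: float
    transform: RigidTransform


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of Q onto P (least-squares, Kabsch/SVD).

    Returns the proper-rotation transform T minimizing RMSD(P, T(Q)) and
    that minimal RMSD.  Collinear/degenerate input still returns a
    minimizing transform (SVD handles rank deficiency).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 points required for superposition")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise ValueError("coordinates must be finite")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    diff = P - (Q @ R.T + t)
    rmsd_val = float(np.sqrt((diff**2).sum() / n))
    return RigidTransform(R, t), rmsd_val


def d0(L: int) -> float:
    """TM-score distance scale for normalization length L, floored at 0.5 Å."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if L <= 15:
        return 0.5
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def _ca_coords(model: StructureModel, indices: list[int]) -> np.ndarray:
    out = []
    for i in indices:
        res = model.residues[i]
        ca = res.atoms.get("CA")
        if ca is None:
            raise ValueError(f"residue {res.name} {res.author_id} lacks CA")
        out.append(ca.xyz)
    return np.vstack(out)


def _fragment_seeds(n: int) -> list[np.ndarray]:
    """Superposition seeds: full set plus contiguous fragments of length
    n/2 and n/4 (minimum 4) starting at the ends and the middle."""
    seeds = [np.arange(n)]
    for frac in (2, 4):
        L = max(4, n // frac)
        if L >= n:
            continue
        starts = sorted({0, (n - L) // 2, n - L})
        for s in starts:
            seeds.append(np.arange(s, s + L))
    # drop duplicates while keeping order
    seen: set[tuple[int, ...]] = set()
    uniq = []
    for s in seeds:
        key = (int(s[0]), int(s[-1]))
        if key not in seen:
            seen.add(key)
            uniq.append(s)
    return uniq


def _refine_seed(
    PA: np.ndarray,
    PB: np.ndarray,
    seed: np.ndarray,
    d0_val: float,
    max_iter: int = 50,
) -> tuple[float, RigidTransform, np.ndarray]:
    """Iteratively re-superpose on residues within an inclusion cutoff.

    The cutoff starts at d0 and is escalated by 1.5x whenever fewer than 4
    residues qualify; iteration stops at a fixed point of the included set.
    Returns (sum of per-residue TM terms, transform, distances).
    """
    included = seed
    prev: set[int] | None = None
    transform = RigidTransform.identity()
    di = np.zeros(len(PA))
    for _ in range(max_iter):
        if len(included) < 3:
            break
        transform, _ = kabsch(PA[included], PB[included])
        di = np.linalg.norm(PA - transform.apply(PB), axis=1)
        cutoff = d0_val
        new = np.flatnonzero(di < cutoff)
        while len(new) < 4 and cutoff < 1e3:
            cutoff *= 1.5
            new = np.flatnonzero(di < cutoff)
        new_set = set(new.tolist())
        if prev is not None and new_set == prev:
            break
        prev = new_set
        included = new
    score = float(np.sum(1.0 / (1.0 + (di / d0_val) ** 2)))
    return score, transform, di


def tm_score(
    A: StructureModel,
    B: StructureModel,
    corr: Correspondence,
    L_norm: int | None = None,
) -> MetricResult:
    """TM-score of B against A over an explicit correspondence.

    score = (1/L_norm) Σ_aligned 1 / (1 + (d_i / d0(L_norm))²), maximized
    over superpositions found by refining several fragment seeds.  By
    default L_norm is the number of aligned residues (pass the reference
    region length to normalize by the reference).  Identical structures
    score exactly 1.
    """
    if len(corr) == 0:
        raise ValueError("empty correspondence")
    idx_a = [p[0] for p in corr.pairs]
    idx_b = [p[1] for p in corr.pairs]
    PA = _ca_coords(A, idx_a)
    PB = _ca_coords(B, idx_b)
    n = len(corr)
    if L_norm is None:
        L_norm = n
    d0_val = d0(L_norm)

    best_score = -1.0
    best_transform = RigidTransform.identity()
    best_di = np.zeros(n)
    if n < 3:
        # too few points to superpose: fall back to direct distances
        di = np.linalg.norm(PA - PB, axis=1)
        best_score = float(np.sum(1.0 / (1.0 + (di / d0_val) ** 2)))
        best_di = di
    else:
        for seed in _fragment_seeds(n):
            score, transform, di = _refine_seed(PA, PB, seed, d0_val)
            if score > best_score + 1e-12:
                best_score, best_transform, best_di = score, transform, di

    _, rmsd_val = kabsch(PA, PB) if n >= 3 else (None, float(np.sqrt((np.linalg.norm(PA - PB, axis=1) ** 2).mean())))
    return MetricResult(
        tm=min(1.0, best_score / L_norm),
        rmsd=rmsd_val,
        n_aligned=n,
        L_norm=L_norm,
        d0=d0_val,
        transform=best_transform,
    )


def rmsd(
    A: StructureModel,
    B: StructureModel,
    corr: Correspondence,
    atom_set: tuple[str, ...] = ("N", "CA", "C", "O"),
) -> float:
    """Kabsch-minimal RMSD over the given backbone atoms of all
    corresponding residues; pairs incomplete for the atom set are dropped
    with a warning."""
    PA, PB = [], []
    for ia, ib in corr.pairs:
        ra, rb = A.residues[ia], B.residues[ib]
        if all(a in ra.atoms for a in atom_set) and all(a in rb.atoms for a in atom_set):
            PA.extend(ra.atoms[a].xyz for a in atom_set)
            PB.extend(rb.atoms[a].xyz for a in atom_set)
        else:
            logger.warning(
                "dropping pair (%s, %s): incomplete for atoms %s",
                ra.author_id, rb.author_id, ",".join(atom_set),
            )
    if len(PA) < 3:
        raise ValueError("fewer than 3 atoms after completeness filtering")
    _, val = kabsch(np.vstack(PA), np.vstack(PB))
    return val


def build_correspondence(A: StructureModel, B: StructureModel) -> Correspondence:
    """Same-sequence residue correspondence.

    If the two chains have identical sequences the mapping is positional;
    otherwise residues are matched by author number (+ insertion code),
    keeping only order-preserving matches.
    """
    if A.sequence == B.sequence and len(A) == len(B):
        return Correspondence([(i, i) for i in range(len(A))])
    bmap = {(r.author_number, r.insertion_code): r.index for r in B.residues}
    pairs: list[tuple[int, int]] = []
    last_b = -1
    for ra in A.residues:
        ib = bmap.get((ra.author_number, ra.insertion_code))
        if ib is not None and ib > last_b:
            pairs.append((ra.index, ib))
            last_b = ib
    return Correspondence(pairs)


def region_restrict(
    corr: Correspondence,
    region: list[tuple[int, int]],
    side: str,
    model: StructureModel,
) -> Correspondence:
    """Keep only pairs whose chosen-side residue lies in the author-numbered
    region (inclusive intervals; insertion codes ignored for membership).

    ``side`` is 'A' or 'B'; ``model`` is the StructureModel of that side.
    """
    if side not in ("A", "B"):
        raise ValueError("side must be 'A' or 'B'")
    col = 0 if side == "A" else 1
    kept = []
    for pair in corr.pairs:
        num = model.residues[pair[col]].author_number
        if any(lo <= num <= hi for lo, hi in region):
            kept.append(pair)
    if not kept:
        raise ValueError("region has no aligned residues")
    return Correspondence(kept)


def parse_region(text: str) -> list[tuple[int, int]]:
    """Parse '11-66' or '11-66,70-80' into inclusive author-number intervals."""
    intervals = []
    for part in str(text).split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part[1:]:  # allow negative start numbers
            lo_s, hi_s = part[1:].split("-", 1)
            lo, hi = int(part[0] + lo_s), int(hi_s)
        else:
            lo = hi = int(part)
        if hi < lo:
            raise ValueError(f"invalid interval {part!r}")
        intervals.append((lo, hi))
    if not intervals:
        raise ValueError(f"empty region spec {text!r}")
    return intervals
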