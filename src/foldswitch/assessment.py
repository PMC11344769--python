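"""Dual-conformation assessment of prediction ensembles.

A fold-switching protein has two experimentally determined conformations
sharing one sequence.  This module orders them into Fold1/Fold2 (the more-
and less-frequently predicted fold, by majority over a designated baseline
run), classifies every predicted model by its fold-switching-region
TM-scores against both references (threshold 0.6), and aggregates
per-pair success, difficulty (Easy/Complex) and confident-but-wrong
(false positive) statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .structure_io import StructureModel, extract_plddt
from .superpose import (
    Correspondence,
    build_correspondence,
    parse_region,
    region_restrict,
    rmsd,
    tm_score,
)

logger = logging.getLogger(__name__)

FOLD1, FOLD2, OTHER = "FOLD1", "FOLD2", "OTHER"
TM_THRESHOLD = 0.6
PLDDT_CONFIDENT = 70.0
WRMSD_COMPLEX = 10.0
FSTM_COMPLEX = 0.5


@dataclass
class FoldSwitchPair:
    """One protein with two experimental reference folds.

    ``fs_region_A`` / ``fs_region_B`` are author-numbered inclusive
    intervals on each reference covering the fold-switching region.
    """

    pair_id: str
    ref_A: StructureModel
    ref_B: StructureModel
    fs_region_A: list[tuple[int, int]]
    fs_region_B: list[tuple[int, int]]
    is_amyloid_or_swap: bool = False
    in_training_roster: tuple[bool, bool] = (False, False)
    ground_state: str = "unknown"  # A | B | isoenergetic | unknown

    @property
    def sequence(self) -> str:
        return self.ref_A.sequence


@dataclass
class ModelAssessment:
    model_id: str
    tm1: float
    tm2: float
    rmsd1: float
    rmsd2: float
    label: str
    mean_plddt: float | None = None
    confidence_fraction: float | None = None


@dataclass
class PairSummary:
    pair_id: str
    fold_order: str  # 'A' or 'B' = which reference is Fold1
    counts: dict[str, int]
    success_fold1: bool
    success_fold2: bool
    success_overall: bool
    difficulty: str
    false_positive_rate: float | None
    n_models: int
    fold_order_tiebreak: bool = False


def classify_model(tm1: float, tm2: float, tau: float = TM_THRESHOLD) -> str:
    """Label a model from its region TM-scores vs Fold1 and Fold2.

    Strictly above tau against exactly one fold assigns that fold; above
    tau against both assigns the larger score (exact ties go to Fold1);
    otherwise (including equality with tau) the model is OTHER, i.e. an
    experimentally unobserved conformation.
    """
    for v, name in ((tm1, "tm1"), (tm2, "tm2")):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    if tm1 > tau and tm2 > tau:
        return FOLD1 if tm1 >= tm2 else FOLD2
    if tm1 > tau:
        return FOLD1
    if tm2 > tau:
        return FOLD2
    return OTHER


def region_tm(model: StructureModel, ref: StructureModel,
              region: list[tuple[int, int]]) -> float:
    """Fold-switching-region TM-score of a model against a reference,
    normalized by the number of reference residues in the region."""
    corr = build_correspondence(ref, model)
    corr = region_restrict(corr, region, "A", ref)
    L_norm = sum(
        1 for r in ref.residues
        if any(lo <= r.author_number <= hi for lo, hi in region)
    )
    return tm_score(ref, model, corr, L_norm=L_norm).tm


def region_rmsd(model: StructureModel, ref: StructureModel,
                region: list[tuple[int, int]],
                atom_set: tuple[str, ...] = ("N", "CA", "C", "O")) -> float:
    corr = build_correspondence(ref, model)
    corr = region_restrict(corr, region, "A", ref)
    return rmsd(ref, model, corr, atom_set=atom_set)


def assign_fold_order(
    baseline_models: Sequence[StructureModel],
    pair: FoldSwitchPair,
) -> tuple[str, bool]:
    """Order the references: the one with the higher region TM-score in a
    majority of baseline models becomes Fold1.

    With the canonical 5-model baseline this is the at-least-3-of-5 rule.
    Ties (possible for even counts) fall back to the larger mean region TM
    over the baseline, flagged in the second return value.
    """
    if not baseline_models:
        raise ValueError(
            "no baseline models given; configure fold_order explicitly"
        )
    wins_a = wins_b = 0
    sum_a = sum_b = 0.0
    for m in baseline_models:
        ta = region_tm(m, pair.ref_A, pair.fs_region_A)
        tb = region_tm(m, pair.ref_B, pair.fs_region_B)
        sum_a += ta
        sum_b += tb
        if ta > tb:
            wins_a += 1
        elif tb > ta:
            wins_b += 1
    if wins_a > wins_b:
        return "A", False
    if wins_b > wins_a:
        return "B", False
    logger.warning(
        "pair %s: baseline fold-order vote tied (%d/%d); using mean region TM",
        pair.pair_id, wins_a, wins_b,
    )
    return ("A", True) if sum_a >= sum_b else ("B", True)


def assess_model(
    model: StructureModel,
    pair: FoldSwitchPair,
    fold_order: str = "A",
    tau: float = TM_THRESHOLD,
    plddt_region: list[tuple[int, int]] | None = None,
) -> ModelAssessment:
    """Score one predicted model against both references and label it.

    ``fold_order`` names the reference serving as Fold1.  plDDT statistics
    come from the model's CA B-factor column; ``plddt_region`` optionally
    restricts the mean to an author-numbered window.
    """
    ref1, reg1 = (pair.ref_A, pair.fs_region_A)
    ref2, reg2 = (pair.ref_B, pair.fs_region_B)
    if fold_order == "B":
        ref1, reg1, ref2, reg2 = ref2, reg2, ref1, reg1
    tm1 = region_tm(model, ref1, reg1)
    tm2 = region_tm(model, ref2, reg2)
    r1 = region_rmsd(model, ref1, reg1)
    r2 = region_rmsd(model, ref2, reg2)
    try:
        plddts = extract_plddt(model)
        if plddt_region is not None:
            sel = [
                i for i, r in enumerate(model.residues)
                if any(lo <= r.author_number <= hi for lo, hi in plddt_region)
            ]
            mean_plddt = float(np.mean(plddts[sel])) if sel else float("nan")
        else:
            mean_plddt = float(plddts.mean())
        conf_frac = 100.0 * float((plddts >= PLDDT_CONFIDENT).mean())
    except ValueError:
        mean_plddt = None
        conf_frac = None
    return ModelAssessment(
        model_id=model.id,
        tm1=tm1, tm2=tm2, rmsd1=r1, rmsd2=r2,
        label=classify_model(tm1, tm2, tau=tau),
        mean_plddt=mean_plddt,
        confidence_fraction=conf_frac,
    )


def pair_success(assessments: Sequence[ModelAssessment]) -> tuple[bool, bool, bool]:
    """A conformation counts as predicted if at least one model is labeled
    with it (N_ij >= 1); overall success requires both conformations."""
    if not assessments:
        raise ValueError("no assessments")
    labels = [a.label for a in assessments]
    s1 = FOLD1 in labels
    s2 = FOLD2 in labels
    return s1, s2, s1 and s2


def success_rate(summaries: Sequence[PairSummary]) -> float:
    """Fraction of pairs for which both folds were predicted."""
    if not summaries:
        raise ValueError("no pair summaries")
    return sum(s.success_overall for s in summaries) / len(summaries)


def label_difficulty(
    wrmsd: float,
    fs_tm: float,
    is_amyloid_or_swap: bool = False,
    wrmsd_cut: float = WRMSD_COMPLEX,
    fstm_cut: float = FSTM_COMPLEX,
) -> str:
    """EASY vs COMPLEX: a pair is COMPLEX if it is an amyloid/domain swap,
    or the whole-structure RMSD between its folds exceeds 10 Å, or the
    region TM-score between its folds is below 0.5."""
    if wrmsd < 0:
        raise ValueError("wRMSD must be >= 0")
    if not (0.0 <= fs_tm <= 1.0):
        raise ValueError("fsTM must be in [0, 1]")
    if is_amyloid_or_swap or wrmsd > wrmsd_cut or fs_tm < fstm_cut:
        return "COMPLEX"
    return "EASY"


def false_positive_rate(assessments: Sequence[ModelAssessment],
                        plddt_cut: float = PLDDT_CONFIDENT) -> float | None:
    """Among confident models (mean plDDT >= 70), the fraction labeled
    OTHER; None when no model is confident."""
    confident = [a for a in assessments if a.mean_plddt is not None
                 and a.mean_plddt >= plddt_cut]
    if not confident:
        return None
    return sum(a.label == OTHER for a in confident) / len(confident)


def pair_structural_change(pair: FoldSwitchPair) -> tuple[float, float]:
    """(wRMSD, fsTM) between the two experimental references: whole-
    structure backbone RMSD and fold-switching-region TM-score."""
    corr = build_correspondence(pair.ref_A, pair.ref_B)
    wrmsd = rmsd(pair.ref_A, pair.ref_B, corr)
    corr_fs = region_restrict(corr, pair.fs_region_A, "A", pair.ref_A)
    L = sum(
        1 for r in pair.ref_A.residues
        if any(lo <= r.author_number <= hi for lo, hi in pair.fs_region_A)
    )
    fs_tm = tm_score(pair.ref_A, pair.ref_B, corr_fs, L_norm=L).tm
    return wrmsd, fs_tm


def summarize_pair(
    pair: FoldSwitchPair,
    assessments: Sequence[ModelAssessment],
    fold_order: str,
    fold_order_tiebreak: bool = False,
) -> PairSummary:
    counts = {FOLD1: 0, FOLD2: 0, OTHER: 0}
    for a in assessments:
        counts[a.label] += 1
    s1, s2, overall = pair_success(assessments)
    wrmsd, fs_tm = pair_structural_change(pair)
    return PairSummary(
        pair_id=pair.pair_id,
        fold_order=fold_order,
        counts=counts,
        success_fold1=s1,
        success_fold2=s2,
        success_overall=overall,
        difficulty=label_difficulty(wrmsd, fs_tm, pair.is_amyloid_or_swap),
        false_positive_rate=false_positive_rate(assessments),
        n_models=len(assessments),
        fold_order_tiebreak=fold_order_tiebreak,
    )


def match_training_roster(
    pdb_chain_ids: Iterable[str],
    roster_path: str | Path,
) -> list[bool]:
    """Match 'pdbid_chain' queries against a whitespace-separated roster
    file (e.g. the OpenFold training-chain list): PDB id case-insensitive,
    chain id case-sensitive."""
    roster_path = Path(roster_path)
    try:
        tokens = roster_path.read_text().split()
    except OSError as exc:
        raise OSError(f"cannot read roster {roster_path}: {exc}") from exc
    roster = set()
    for tok in tokens:
        if "_" in tok:
            pdbid, chain = tok.split("_", 1)
            roster.add((pdbid.lower(), chain))
        else:
            roster.add((tok.lower(), None))
    flags = []
    for q in pdb_chain_ids:
        if "_" in q:
            pdbid, chain = q.split("_", 1)
            flags.append((pdbid.lower(), chain) in roster or (pdbid.lower(), None) in roster)
        else:
            flags.append((q.lower(), None) in roster)
    return flags
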