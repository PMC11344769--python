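"""End-to-end orchestration: registry loading, ensemble assessment,
masking sweeps and probe reports, with deterministic TSV/JSON outputs.

The registry is a TSV with columns
pair_id, pdbA, chainA, pdbB, chainB, fs_region_A, fs_region_B
and optional flag columns (is_amyloid_or_swap, ground_state); regions
use author numbering, inclusive, e.g. "11-66" or "11-40,45-66".
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .assessment import (
    FoldSwitchPair,
    ModelAssessment,
    PairSummary,
    assess_model,
    assign_fold_order,
    success_rate,
    summarize_pair,
)
from .confidence import (
    CategoryTabulation,
    records_from_assessments,
    rerank,
    tabulate,
)
from .structure_io import read_structure
from .superpose import parse_region

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective pipeline configuration; defaults are the thresholds the
    assessment rules quote (TM 0.6, plDDT 70/80/90, flexibility 2.0,
    wRMSD 10, fsTM 0.5; masking w=11, cutoff 4.0 Å, exclusion 4)."""

    registry: str = ""
    model_dir: str = ""
    out_dir: str = "out"
    tau: float = 0.6
    n_baseline: int = 5
    seed: int = 0
    mask_window: int = 11
    mask_cutoff: float = 4.0
    mask_seq_exclusion: int = 4
    contact_cutoff: float = 8.0
    contact_atom_mode: str = "CB"
    contact_min_seq_sep: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a flat key/value YAML config; unknown keys are an error."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_registry(path: str | Path, base_dir: str | Path | None = None) -> list[FoldSwitchPair]:
    """Read the pair registry TSV and parse both reference structures."""
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pair_id", "pdbA", "chainA", "pdbB", "chainB",
                "fs_region_A", "fs_region_B"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry {path} missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"registry {path} is empty")
    pairs = []
    for _, row in df.iterrows():
        ref_a = read_structure(base / row["pdbA"], chain=row["chainA"])
        ref_b = read_structure(base / row["pdbB"], chain=row["chainB"])
        pairs.append(FoldSwitchPair(
            pair_id=row["pair_id"],
            ref_A=ref_a,
            ref_B=ref_b,
            fs_region_A=parse_region(row["fs_region_A"]),
            fs_region_B=parse_region(row["fs_region_B"]),
            is_amyloid_or_swap=str(row.get("is_amyloid_or_swap", "")).lower()
            in {"1", "true", "yes"},
            ground_state=str(row.get("ground_state", "unknown") or "unknown"),
        ))
    return pairs


def assess_ensemble(
    pair: FoldSwitchPair,
    models: Sequence,
    fold_order: str | None = None,
    n_baseline: int = 5,
    tau: float = 0.6,
) -> tuple[list[ModelAssessment], PairSummary, CategoryTabulation]:
    """Assess all models of one pair: fold ordering (from the first
    ``n_baseline`` models unless given), per-model classification,
    pair summary and confidence tabulation."""
    tiebreak = False
    if fold_order is None:
        fold_order, tiebreak = assign_fold_order(models[:n_baseline], pair)
    assessments = [
        assess_model(m, pair, fold_order=fold_order, tau=tau) for m in models
    ]
    summary = summarize_pair(pair, assessments, fold_order,
                             fold_order_tiebreak=tiebreak)
    ranked = rerank(records_from_assessments(assessments))
    tab = tabulate(ranked, assessments)
    return assessments, summary, tab


def _assessments_frame(pair_id: str, assessments: Sequence[ModelAssessment]) -> pd.DataFrame:
    rows = [dict(pair_id=pair_id, **asdict(a)) for a in assessments]
    return pd.DataFrame(rows)


def run_assess(config: RunConfig) -> dict:
    """File-based assessment over a registry + per-pair model directories.

    Models for pair P are all ``*.pdb`` / ``*.cif`` files under
    ``<model_dir>/<pair_id>/``.  Pairs whose models are missing or fail to
    parse are skipped and enumerated in the returned report.  Writes
    per-model TSV, per-pair JSON and an aggregate JSON under ``out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = load_registry(config.registry)
    frames, summaries, skips = [], [], []
    pair_reports = {}
    for pair in pairs:
        mdir = Path(config.model_dir) / pair.pair_id
        paths = sorted(list(mdir.glob("*.pdb")) + list(mdir.glob("*.cif")))
        if not paths:
            skips.append({"pair_id": pair.pair_id, "reason": "no models found"})
            continue
        try:
            models = [read_structure(p) for p in paths]
            assessments, summary, tab = assess_ensemble(
                pair, models, n_baseline=config.n_baseline, tau=config.tau
            )
        except Exception as exc:  # isolate failures per pair
            logger.exception("pair %s failed", pair.pair_id)
            skips.append({"pair_id": pair.pair_id, "reason": str(exc)})
            continue
        frames.append(_assessments_frame(pair.pair_id, assessments))
        summaries.append(summary)
        pair_reports[pair.pair_id] = {
            "summary": _summary_dict(summary),
            "tabulation": {
                "|".join(k): v for k, v in sorted(tab.counts.items())
            },
        }
    report = {
        "version": __version__,
        "config": asdict(config),
        "n_pairs": len(pairs),
        "n_assessed": len(summaries),
        "skips": skips,
        "success_rate": success_rate(summaries) if summaries else None,
        "pairs": pair_reports,
    }
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / "per_model.tsv", sep="\t", index=False
        )
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _summary_dict(s: PairSummary) -> dict:
    d = asdict(s)
    return d


def run_mask(
    msa_path: str | Path,
    structure_path: str | Path,
    chain: str | None,
    region: str,
    out_dir: str | Path,
    w: int = 11,
    cutoff: float = 4.0,
    seq_exclusion: int = 4,
) -> pd.DataFrame:
    """Masking sweep to disk: one A3M per unique masked alignment plus a
    manifest TSV (window, masked positions, output file)."""
    from .msa import generate_masked_msas, read_msa, sliding_windows, write_a3m
    from .msa import contact_positions, dedupe, mask_msa

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    msa = read_msa(msa_path)
    structure = read_structure(structure_path, chain=chain)
    (lo, hi), = parse_region(region)

    masked_all = []
    for win in sliding_windows((lo, hi), w=w):
        positions = contact_positions(structure, win, cutoff=cutoff,
                                      seq_exclusion=seq_exclusion)
        masked_all.append(mask_msa(msa, positions, window=win))
    unique = dedupe(masked_all)
    rows = []
    for m in unique:
        fname = f"mask_{m.mask.window[0]}_{m.mask.window[1]}.a3m"
        write_a3m(m, out_dir / fname)
        rows.append({
            "window_start": m.mask.window[0],
            "window_end": m.mask.window[1],
            "n_masked_positions": len(m.mask.masked_positions),
            "masked_positions": ",".join(map(str, sorted(m.mask.masked_positions))),
            "file": fname,
        })
    manifest = pd.DataFrame(rows)
    manifest.attrs["n_windows"] = len(masked_all)
    manifest.attrs["n_unique"] = len(unique)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def run_probe(
    structure_paths: Sequence[str | Path],
    chains: Sequence[str | None] | None = None,
    region: str | None = None,
    distance_probe: tuple[int, int] | None = None,
    out_path: str | Path | None = None,
) -> dict:
    """Flexibility profile, optional region summary, optional distance
    probe, for each input structure; degenerate inputs (constant
    B-factors) are recorded without aborting the run."""
    from .probes import normalize_bfactors, region_flexibility, residue_distance

    if chains is None:
        chains = [None] * len(structure_paths)
    results = {}
    for path, chain in zip(structure_paths, chains):
        entry: dict = {}
        try:
            model = read_structure(path, chain=chain)
            prof = normalize_bfactors(model)
            entry["n_residues"] = len(prof.bf)
            entry["n_flexible"] = int(prof.flexible.sum())
            entry["sd_convention"] = prof.sd_convention
            if region:
                entry["region"] = region_flexibility(
                    prof, model, parse_region(region)
                )
            if distance_probe:
                entry["distance"] = residue_distance(model, *distance_probe)
        except (ValueError, KeyError) as exc:
            entry["error"] = str(exc)
        results[str(path)] = entry
    if out_path is not None:
        Path(out_path).write_text(json.dumps(results, indent=2, sort_keys=True))
    return results


def write_fixture_dir(
    out_dir: str | Path,
    n_pairs: int = 2,
    n_models: int = 20,
    seed: int = 0,
    weights: tuple[float, float, float] = (0.6, 0.3, 0.1),
    polarity: str = "aligned",
) -> dict:
    """Write a complete synthetic fixture directory: registry TSV,
    reference PDBs, per-pair model PDBs (plDDT in the B-factor column),
    a toy A3M and the ground-truth labels JSON."""
    from .msa import write_a3m
    from .structure_io import write_structure
    from .synthetic import EnsembleSpec, ToyPairSpec, make_ensemble, make_toy_msa, make_toy_pair

    out_dir = Path(out_dir)
    (out_dir / "refs").mkdir(parents=True, exist_ok=True)
    (out_dir / "models").mkdir(exist_ok=True)
    rows, truth = [], {}
    for p in range(n_pairs):
        pair_seed = seed * 1000 + p
        pair = make_toy_pair(ToyPairSpec(seed=pair_seed))
        ra, rb = f"refs/pair{p}_A.pdb", f"refs/pair{p}_B.pdb"
        write_structure(pair.ref_A, out_dir / ra)
        write_structure(pair.ref_B, out_dir / rb)
        models, labels = make_ensemble(
            pair, EnsembleSpec(n_models=n_models, weights=weights,
                               plddt_polarity=polarity, seed=pair_seed + 1)
        )
        mdir = out_dir / "models" / f"pair{p}"
        mdir.mkdir(parents=True, exist_ok=True)
        for m in models:
            write_structure(m, mdir / f"{m.id}.pdb")
        truth[f"pair{p}"] = labels
        lo, hi = pair.fs_region_A[0]
        rows.append({
            "pair_id": f"pair{p}", "pdbA": ra, "chainA": "A",
            "pdbB": rb, "chainB": "A",
            "fs_region_A": f"{lo}-{hi}", "fs_region_B": f"{lo}-{hi}",
        })
        msa = make_toy_msa(pair.sequence, seed=pair_seed + 2)
        write_a3m(msa, out_dir / f"pair{p}.a3m")
    pd.DataFrame(rows).to_csv(out_dir / "registry.tsv", sep="\t", index=False)
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return {"out_dir": str(out_dir), "n_pairs": n_pairs, "n_models": n_models}
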