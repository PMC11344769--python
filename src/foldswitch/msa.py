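"""MSA parsing and alanine-mask generation.

Generates alanine-masked multiple sequence alignments: an 11-residue
window slides over the fold-switching region; residues spatially
contacting the window (any heavy atom within 4 Å) but more than 4
positions away in primary sequence are identified, and in every row
except the target those alignment columns are mutated to alanine,
erasing their coevolutionary signal.  Identically masked alignments from
nearby windows are deduplicated.

A3M conventions: the first record is the target; uppercase letters and
'-' form match columns; lowercase letters are insertions relative to the
target and do not create columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import StructureModel

logger = logging.getLogger(__name__)

GAP_CHARS = {"-", "."}


def _match_indices(aligned: str, format: str = "a3m") -> list[int]:
    """String indices of the match columns of a row.

    A3M: uppercase letters and '-' (lowercase and '.' are insertions).
    Aligned FASTA: every column.
    """
    if format == "fasta":
        return list(range(len(aligned)))
    return [i for i, c in enumerate(aligned) if c.isupper() or c == "-"]


@dataclass
class MSA:
    """Target sequence plus aligned homolog rows.

    ``column_map`` maps 0-based ungapped target positions to match-column
    ordinals (for aligned FASTA every string column is a match column).
    """

    target_id: str
    target_sequence: str
    rows: list[tuple[str, str]]  # first row is the target
    column_map: dict[int, int] = field(default_factory=dict)
    format: str = "a3m"  # 'a3m' or 'fasta'

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row_ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]


@dataclass
class MaskSpec:
    window: tuple[int, int]           # author-numbered inclusive interval
    masked_positions: frozenset[int]  # 0-based target positions


@dataclass
class MaskedMSA:
    parent: MSA
    mask: MaskSpec
    rows: list[tuple[str, str]]


def _read_fasta_records(path: Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    header = None
    seq: list[str] = []
    for line in path.read_text().splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(seq)))
            header = line[1:].split()[0] or line[1:]
            seq = []
        elif header is not None:
            seq.append(line)
    if header is not None:
        records.append((header, "".join(seq)))
    return records


def read_msa(path: str | Path, format: str | None = None) -> MSA:
    """Read an A3M or aligned-FASTA alignment; the first record is the target.

    Format defaults from the extension ('.a3m' -> A3M).  In FASTA mode all
    rows must have equal length; in A3M mode all rows must agree on the
    number of match columns.
    """
    path = Path(path)
    if format is None:
        format = "a3m" if path.suffix.lower() == ".a3m" else "fasta"
    records = _read_fasta_records(path)
    if not records:
        raise ValueError(f"{path}: empty alignment")
    fmt = format.lower()
    if fmt == "fasta":
        lengths = {len(s) for _, s in records}
        if len(lengths) != 1:
            raise ValueError(f"{path}: ragged alignment, row lengths {sorted(lengths)}")
    elif fmt == "a3m":
        ncols = {len(_match_indices(s)) for _, s in records}
        if len(ncols) != 1:
            raise ValueError(
                f"{path}: inconsistent A3M match-column counts {sorted(ncols)}"
            )
    else:
        raise ValueError(f"unknown MSA format {format!r}")

    target_id, target_row = records[0]
    tmatch = _match_indices(target_row, fmt)
    column_map: dict[int, int] = {}
    pos = 0
    for col, si in enumerate(tmatch):
        if target_row[si] not in GAP_CHARS:
            column_map[pos] = col
            pos += 1
    return MSA(
        target_id=target_id,
        target_sequence="".join(c for c in target_row if c not in GAP_CHARS).upper(),
        rows=records,
        column_map=column_map,
        format=fmt,
    )


def sliding_windows(
    region: tuple[int, int], w: int = 11, step: int = 1
) -> list[tuple[int, int]]:
    """All w-residue windows moving by `step` across an author-numbered
    inclusive region; a region shorter than w is an error."""
    lo, hi = region
    length = hi - lo + 1
    if length < w:
        raise ValueError(
            f"region {lo}-{hi} (length {length}) shorter than window {w}; "
            "use a smaller window"
        )
    return [(s, s + w - 1) for s in range(lo, hi - w + 2, step)]


def _heavy_coords(res) -> np.ndarray:
    pts = [a.xyz for a in res.atoms.values() if a.element not in ("H", "D")]
    return np.vstack(pts) if pts else np.zeros((0, 3))


def contact_positions(
    structure: StructureModel,
    window: tuple[int, int],
    cutoff: float = 4.0,
    seq_exclusion: int = 4,
) -> set[int]:
    """0-based chain positions whose residues contact the window.

    A position p qualifies iff some heavy atom of residue p lies within
    ``cutoff`` Å of a heavy atom of any window residue AND p is more than
    ``seq_exclusion`` positions (in primary sequence) from every window
    residue — so window residues themselves are never returned.
    """
    lo, hi = window
    win_idx = [
        r.index for r in structure.residues
        if lo <= r.author_number <= hi
    ]
    if len(win_idx) < hi - lo + 1:
        raise ValueError(
            f"window {lo}-{hi} not fully covered by structure "
            f"{structure.id} (found {len(win_idx)} of {hi - lo + 1} residues)"
        )
    win_coords = np.vstack([
        _heavy_coords(structure.residues[i]) for i in win_idx
    ])
    out: set[int] = set()
    for res in structure.residues:
        p = res.index
        if min(abs(p - q) for q in win_idx) <= seq_exclusion:
            continue
        pts = _heavy_coords(res)
        if pts.size == 0:
            continue
        d2 = ((pts[:, None, :] - win_coords[None, :, :]) ** 2).sum(axis=2)
        if d2.min() <= cutoff * cutoff:
            out.add(p)
    return out


def mask_msa(msa: MSA, positions: set[int],
             window: tuple[int, int] = (0, 0)) -> MaskedMSA:
    """Mutate the given target positions to alanine in every row except the
    target.  Gaps and lowercase insertions are untouched; positions where
    the target row is gapped are skipped with a warning."""
    cols = []
    for p in sorted(positions):
        if p < 0 or p >= len(msa.target_sequence):
            raise ValueError(f"position {p} outside target length")
        col = msa.column_map.get(p)
        if col is None:
            logger.warning("position %d unmapped (target gap); skipped", p)
        else:
            cols.append(col)
    colset = set(cols)
    new_rows: list[tuple[str, str]] = [msa.rows[0]]
    for rid, aligned in msa.rows[1:]:
        midx = _match_indices(aligned, msa.format)
        chars = list(aligned)
        for col in colset:
            si = midx[col]
            if chars[si] not in GAP_CHARS:
                chars[si] = "A"
        new_rows.append((rid, "".join(chars)))
    return MaskedMSA(
        parent=msa,
        mask=MaskSpec(window=window, masked_positions=frozenset(positions)),
        rows=new_rows,
    )


def dedupe(masked: list[MaskedMSA]) -> list[MaskedMSA]:
    """Collapse byte-identical masked alignments, keeping the earliest
    window; output order is stable."""
    seen: set[tuple[tuple[str, str], ...]] = set()
    out: list[MaskedMSA] = []
    for m in masked:
        key = tuple(m.rows)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def write_a3m(msa: MSA | MaskedMSA, path: str | Path) -> Path:
    """Write rows as A3M/FASTA records; read_msa round-trips them exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        for rid, aligned in msa.rows:
            fh.write(f">{rid}\n{aligned}\n")
    return path


def generate_masked_msas(
    msa: MSA,
    structure: StructureModel,
    region: tuple[int, int],
    w: int = 11,
    cutoff: float = 4.0,
    seq_exclusion: int = 4,
) -> list[MaskedMSA]:
    """Full masking sweep: windows -> contacts -> mask -> dedupe."""
    masked = []
    for win in sliding_windows(region, w=w):
        positions = contact_positions(
            structure, win, cutoff=cutoff, seq_exclusion=seq_exclusion
        )
        masked.append(mask_msa(msa, positions, window=win))
    return dedupe(masked)
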