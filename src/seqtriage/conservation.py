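"""MSA-based conservation comparison of generated vs natural sequences.

Takes an externally built multiple sequence alignment (any aligner's aligned
FASTA), trims high-gap columns, and computes per-column Shannon entropy (in
bits, gaps excluded from the distribution) and the residue-frequency matrix
behind a sequence logo. A small deterministic center-star aligner is
included so fixtures need no external MSA tool; it is not a substitute for a
real aligner at scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .align import AlignmentResult, ScoringScheme, global_align, global_score
from .seq_core import ProteinSequence, SequenceError

logger = logging.getLogger(__name__)

_AAS = sorted("ACDEFGHIKLMNPQRSTVWY")
MAX_ENTROPY_BITS = math.log2(20)


@dataclass
class Alignment:
    """Equal-length gapped rows over amino acids + '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise SequenceError("alignment has no rows")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise SequenceError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise SequenceError("ids/rows length mismatch")
        for rid, row in zip(self.ids, self.rows):
            degapped = row.replace("-", "")
            ProteinSequence(id=rid, residues=degapped)  # validates alphabet

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids=ids, rows=rows)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n")
                for i in range(0, len(row), width):
                    fh.write(row[i : i + width] + "\n")


@dataclass
class EntropyProfile:
    """Per-column Shannon entropy (bits; NaN where a column is all-gap) and
    gap fraction."""

    entropy: np.ndarray
    gap_fraction: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.entropy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(1, self.n_columns + 1),
                "entropy_bits": self.entropy,
                "gap_fraction": self.gap_fraction,
            }
        )


def gap_fractions(aln: Alignment) -> np.ndarray:
    return np.array(
        [aln.column(j).count("-") / aln.n_rows for j in range(aln.n_columns)]
    )


def trim_high_gap_columns(
    aln: Alignment, max_gap_fraction: float = 0.5
) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    Returns the trimmed alignment and the 0-based indices of removed
    columns. Removing every column is an error.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    fractions = gap_fractions(aln)
    keep = [j for j, f in enumerate(fractions) if f <= max_gap_fraction]
    removed = [j for j in range(aln.n_columns) if fractions[j] > max_gap_fraction]
    if not keep:
        raise SequenceError("gap trimming removed every column")
    rows = ["".join(row[j] for j in keep) for row in aln.rows]
    if removed:
        logger.info("trimmed %d high-gap columns", len(removed))
    return Alignment(ids=list(aln.ids), rows=rows), removed


def column_entropy(aln: Alignment) -> EntropyProfile:
    """Shannon entropy per column, H = -sum f_a log2 f_a over the 20 residues
    with gaps excluded from the counts. All-gap columns are NaN."""
    ent = np.empty(aln.n_columns)
    for j in range(aln.n_columns):
        col = aln.column(j).replace("-", "")
        if not col:
            ent[j] = np.nan
            continue
        counts = np.array([col.count(a) for a in set(col)], dtype=float)
        f = counts / counts.sum()
        ent[j] = float(-(f * np.log2(f)).sum())
    return EntropyProfile(entropy=ent, gap_fraction=gap_fractions(aln))


def logo_matrix(aln: Alignment, information_content: bool = False) -> pd.DataFrame:
    """Columns x 20 residue frequencies (gaps excluded from the denominator).

    All-gap columns are all-zero (flagged with a warning). With
    ``information_content=True`` frequencies are scaled by the column's
    information content IC = log2(20) - H, the usual logo letter-height
    convention.
    """
    mat = np.zeros((aln.n_columns, len(_AAS)))
    for j in range(aln.n_columns):
        col = aln.column(j).replace("-", "")
        if not col:
            logger.warning("column %d is all-gap; logo row left at zero", j + 1)
            continue
        for i, a in enumerate(_AAS):
            mat[j, i] = col.count(a) / len(col)
    df = pd.DataFrame(mat, columns=_AAS)
    df.index = pd.RangeIndex(1, aln.n_columns + 1, name="column")
    if information_content:
        ent = column_entropy(aln).entropy
        ic = np.where(np.isnan(ent), 0.0, MAX_ENTROPY_BITS - ent)
        df = df.mul(ic, axis=0)
    return df


# ---------------------------------------------------------------------------
# Fixture-scale center-star MSA


def _merge_center_gappings(master: str, new: str) -> tuple[str, list[int], list[int]]:
    """Merge two gappings of the same center sequence into their union.

    Returns the merged center row plus, for each input gapping, the column
    index each of its columns maps to in the merged row.
    """
    i = j = 0
    merged = []
    map_master: list[int] = []
    map_new: list[int] = []
    while i < len(master) or j < len(new):
        a = master[i] if i < len(master) else None
        b = new[j] if j < len(new) else None
        if a == b:  # same residue (or both gaps)
            merged.append(a)
            map_master.append(len(merged) - 1)
            map_new.append(len(merged) - 1)
            i += 1
            j += 1
        elif a == "-":
            merged.append("-")
            map_master.append(len(merged) - 1)
            i += 1
        else:  # b == "-" (or master exhausted)
            merged.append("-" if b == "-" else b)
            map_new.append(len(merged) - 1)
            j += 1
    return "".join(merged), map_master, map_new


def build_small_msa(
    seqs: list[ProteinSequence], scheme: ScoringScheme | None = None
) -> Alignment:
    """Deterministic center-star progressive alignment for small fixtures.

    The center is the sequence with the greatest summed pairwise global
    score to all others (ties by id); every other sequence is pairwise-
    aligned to the center and the gappings are merged ("once a gap, always a
    gap"). Row order follows the input order.
    """
    scheme = scheme or ScoringScheme()
    if not seqs:
        raise SequenceError("cannot align an empty sequence list")
    if len(seqs) == 1:
        return Alignment(ids=[seqs[0].id], rows=[seqs[0].residues])

    totals = {
        s.id: sum(global_score(s, t, scheme) for t in seqs if t is not s) for s in seqs
    }
    center = min(seqs, key=lambda s: (-totals[s.id], s.id))
    others = [s for s in seqs if s is not center]

    pairwise: list[AlignmentResult] = [global_align(o, center, scheme) for o in others]

    master = center.residues
    maps: list[list[int]] = []  # per pairwise alignment: its columns -> master columns
    for res in pairwise:
        master, map_master, map_new = _merge_center_gappings(master, res.aligned_b)
        maps = [[map_master[c] for c in m] for m in maps]
        maps.append(map_new)

    width = len(master)
    rows_by_id = {center.id: master}
    for res, m, other in zip(pairwise, maps, others):
        row = ["-"] * width
        for col, ch in zip(m, res.aligned_a):
            row[col] = ch
        rows_by_id[other.id] = "".join(row)

    ids = [s.id for s in seqs]
    return Alignment(ids=ids, rows=[rows_by_id[i] for i in ids])
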