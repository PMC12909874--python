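"""Pairwise global/local alignment, percent identity, and the composite
ranking score.

Scoring follows the triage pipeline's convention: +1 match, -1 mismatch,
-0.5 for the first residue of a gap run, -0.1 for each subsequent one (a
run of g gap positions costs gap_open + (g-1)*gap_extend). Global alignments
penalize end gaps; local alignments are floored at score 0 (the empty
alignment). The composite Alignment Score used for ranking is a weighted
combination of the mean global and mean local score against the reference
set, with default weights 3 (global) and 8 (local).

Percent identity is matches / alignment columns, end gaps included in the
denominator (pairwise alignments have no column gapped in both rows). An
alternative denominator — the shorter sequence's length — is available via
``denominator="shorter"``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .seq_core import ProteinSequence, ReferenceSet, SequenceError


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters and the global/local ranking weights."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -0.5
    gap_extend: float = -0.1
    w_global: float = 3.0
    w_local: float = 8.0

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if abs(self.gap_extend) > abs(self.gap_open):
            raise ValueError("|gap_extend| must not exceed |gap_open|")


@dataclass(frozen=True)
class AlignmentResult:
    """One pairwise alignment: score, gapped rows, and identity summary."""

    score: float
    aligned_a: str
    aligned_b: str
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        """Fraction of identical aligned pairs over alignment columns."""
        return self.matches / self.columns if self.columns else 0.0


def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def _check_nonempty(a: ProteinSequence, b: ProteinSequence) -> None:
    if not len(a) or not len(b):
        raise SequenceError("cannot align empty sequences")


def _result_from(alignment) -> AlignmentResult:
    row_a, row_b = alignment[0], alignment[1]
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x != "-"
    )
    return AlignmentResult(
        score=float(alignment.score),
        aligned_a=row_a,
        aligned_b=row_b,
        matches=matches,
        columns=len(row_a),
    )


def global_align(
    a: ProteinSequence, b: ProteinSequence, scheme: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal Needleman–Wunsch-style alignment under affine gaps.

    End gaps are penalized. Among co-optimal alignments the first of the
    aligner's deterministic traceback is reported; the score is unaffected.
    """
    scheme = scheme or ScoringScheme()
    _check_nonempty(a, b)
    aligner = _aligner(scheme, "global")
    return _result_from(aligner.align(a.residues, b.residues)[0])


def local_align(
    a: ProteinSequence, b: ProteinSequence, scheme: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal Smith–Waterman-style alignment; the empty alignment (score 0)
    is allowed when no positive-scoring block exists."""
    scheme = scheme or ScoringScheme()
    _check_nonempty(a, b)
    aligner = _aligner(scheme, "local")
    score = float(aligner.score(a.residues, b.residues))
    if score <= 0:
        return AlignmentResult(score=0.0, aligned_a="", aligned_b="", matches=0, columns=0)
    return _result_from(aligner.align(a.residues, b.residues)[0])


def global_score(a: ProteinSequence, b: ProteinSequence, scheme: ScoringScheme) -> float:
    """Global alignment score without traceback (fast path for ranking)."""
    _check_nonempty(a, b)
    return float(_aligner(scheme, "global").score(a.residues, b.residues))


def local_score(a: ProteinSequence, b: ProteinSequence, scheme: ScoringScheme) -> float:
    """Local alignment score without traceback (fast path for ranking)."""
    _check_nonempty(a, b)
    return max(0.0, float(_aligner(scheme, "local").score(a.residues, b.residues)))


def composite_score(
    candidate: ProteinSequence,
    refs: ReferenceSet,
    scheme: ScoringScheme | None = None,
) -> float:
    """The ranking statistic: w_global·mean(global) + w_local·mean(local)
    over the reference set. Higher is better; deterministic."""
    scheme = scheme or ScoringScheme()
    g_aligner = _aligner(scheme, "global")
    l_aligner = _aligner(scheme, "local")
    n = len(refs)
    g_sum = 0.0
    l_sum = 0.0
    for ref in refs:
        g_sum += float(g_aligner.score(candidate.residues, ref.residues))
        l_sum += max(0.0, float(l_aligner.score(candidate.residues, ref.residues)))
    return scheme.w_global * g_sum / n + scheme.w_local * l_sum / n


def pairwise_identity(
    a: ProteinSequence,
    b: ProteinSequence,
    scheme: ScoringScheme | None = None,
    denominator: str = "columns",
) -> float:
    """Global-alignment identity as a fraction in [0, 1].

    ``denominator="columns"`` (default) divides by alignment columns,
    end gaps included; ``"shorter"`` divides by the shorter input's length.
    """
    res = global_align(a, b, scheme)
    if denominator == "columns":
        return res.identity
    if denominator == "shorter":
        return res.matches / min(len(a), len(b))
    raise ValueError(f"unknown identity denominator {denominator!r}")


def max_identity(
    candidate: ProteinSequence,
    refs: ReferenceSet,
    scheme: ScoringScheme | None = None,
    denominator: str = "columns",
) -> tuple[float, str]:
    """MaxID: the candidate's best global-alignment percent identity over the
    reference set, with the best reference's id.

    Ties on identity are broken by reference id order (lexicographically
    smallest id wins). Returns (percent in [0, 100], reference id).
    """
    scheme = scheme or ScoringScheme()
    best_pct = -1.0
    best_id = ""
    for ref in sorted(refs, key=lambda r: r.id):
        pct = 100.0 * pairwise_identity(candidate, ref, scheme, denominator)
        if pct > best_pct:
            best_pct, best_id = pct, ref.id
    return best_pct, best_id
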