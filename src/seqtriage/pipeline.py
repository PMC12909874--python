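"""The ordered candidate-triage pipeline.

Stage order is fixed: start codon -> length -> structure confidence (pLDDT)
-> novelty (MaxID) -> identity binning -> alignment-score ranking -> active
site -> diversity clustering -> stratified quota selection. Filters were
ordered to maximize the novelty and functionality of what survives; every
stage records per-candidate pass/fail with a reason, and the whole pipeline
is deterministic given its inputs.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .align import (
    ScoringScheme,
    composite_score,
    global_align,
    max_identity,
    pairwise_identity,
)
from .seq_core import CodingSequence, ProteinSequence, ReferenceSet, SequenceError

logger = logging.getLogger(__name__)


class IdentityBin(enum.Enum):
    """Percent-MaxID intervals used for stratified selection.

    Intervals are lower-exclusive / upper-inclusive except the lowest, which
    is closed below, so every MaxID in [40, 100] maps to exactly one bin.
    """

    BIN_40_50 = (40.0, 50.0)
    BIN_50_60 = (50.0, 60.0)
    BIN_60_70 = (60.0, 70.0)
    BIN_70_80 = (70.0, 80.0)
    BIN_80_90 = (80.0, 90.0)
    BIN_90_100 = (90.0, 100.0)

    @property
    def label(self) -> str:
        lo, hi = self.value
        return f"{lo:.0f}-{hi:.0f}"

    @classmethod
    def from_maxid(cls, maxid: float) -> "IdentityBin | None":
        """Bin for a MaxID percent, or None below 40%."""
        if 40.0 <= maxid <= 50.0:
            return cls.BIN_40_50
        for b in cls:
            lo, hi = b.value
            if lo < maxid <= hi:
                return b
        return None


@dataclass
class SelectionPlan:
    """Per-bin selection quotas. The defaults take 30 sequences at 80-90%
    MaxID, 40 at 70-80%, 20 at 60-70%, 10 at 50-60% and 5 at 40-50%
    (105 total), and exclude the 90-100% bin outright."""

    quotas: dict[IdentityBin, int] = field(
        default_factory=lambda: {
            IdentityBin.BIN_80_90: 30,
            IdentityBin.BIN_70_80: 40,
            IdentityBin.BIN_60_70: 20,
            IdentityBin.BIN_50_60: 10,
            IdentityBin.BIN_40_50: 5,
        }
    )
    exclude_bins: set[IdentityBin] = field(
        default_factory=lambda: {IdentityBin.BIN_90_100}
    )

    def __post_init__(self) -> None:
        if any(q < 0 for q in self.quotas.values()):
            raise ValueError("selection quotas must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.quotas.values())


@dataclass
class CandidateRecord:
    """One candidate's full triage state; fields fill in as stages run.

    ``seq`` may be None for records rebuilt from a scored table, in which
    case ``candidate_id`` must be set.
    """

    seq: CodingSequence | None
    candidate_id: str | None = None
    protein: ProteinSequence | None = None
    plddt: float | None = None
    maxid: float | None = None
    best_ref: str | None = None
    bin: IdentityBin | None = None
    score: float | None = None
    active_site_ok: bool | None = None
    cluster: int | None = None
    is_representative: bool = False
    selected_rank: int | None = None
    stage_flags: dict[str, str] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return self.candidate_id if self.candidate_id is not None else self.seq.id


@dataclass
class StageReport:
    name: str
    n_in: int
    n_passed: int
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def pass_rate(self) -> float:
        return self.n_passed / self.n_in if self.n_in else 0.0


@dataclass
class FilterReport:
    stages: list[StageReport] = field(default_factory=list)

    def add(self, stage: StageReport) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_passed:
            raise ValueError(
                f"stage {stage.name!r} input ({stage.n_in}) does not equal the "
                f"previous stage's passed count ({self.stages[-1].n_passed})"
            )
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "n_in": s.n_in,
                    "n_passed": s.n_passed,
                    "pass_rate": s.pass_rate,
                }
                for s in self.stages
            ]
        )


def _run_filter(
    name: str,
    cands: Sequence[CandidateRecord],
    predicate: Callable[[CandidateRecord], str | None],
) -> tuple[list[CandidateRecord], StageReport]:
    """Apply a predicate returning None (pass) or a failure reason."""
    passed, failures = [], {}
    for c in cands:
        reason = predicate(c)
        if reason is None:
            c.stage_flags[name] = "pass"
            passed.append(c)
        else:
            c.stage_flags[name] = f"fail: {reason}"
            failures[c.id] = reason
    if not passed:
        logger.warning("stage %r eliminated every candidate", name)
    return passed, StageReport(name=name, n_in=len(cands), n_passed=len(passed), failures=failures)


# ---------------------------------------------------------------------------
# Individual stages


def filter_start_codon(
    cands: Sequence[CandidateRecord],
) -> tuple[list[CandidateRecord], StageReport]:
    """Keep candidates whose first codon is the canonical ATG start."""
    return _run_filter(
        "start_codon",
        cands,
        lambda c: None if c.seq.starts_with_atg else f"first codon {c.seq.dna[:3]} != ATG",
    )


def filter_length(
    cands: Sequence[CandidateRecord],
    refs: ReferenceSet | None = None,
    bounds: tuple[int, int] = (306, 421),
    sd_multiplier: float | None = None,
) -> tuple[list[CandidateRecord], StageReport]:
    """Keep candidates whose protein length lies within ``bounds`` inclusive.

    The default bounds are the pipeline's printed valid range for the TrpB
    family, 306-421 residues. Passing ``sd_multiplier`` m recomputes them
    from the reference set as round(mean ± m·σ) instead.
    """
    if sd_multiplier is not None:
        if refs is None:
            raise ValueError("sd_multiplier requires a reference set")
        bounds = (
            round(refs.length_mean - sd_multiplier * refs.length_sd),
            round(refs.length_mean + sd_multiplier * refs.length_sd),
        )
    lo, hi = bounds

    def pred(c: CandidateRecord) -> str | None:
        n = len(c.protein)
        return None if lo <= n <= hi else f"protein length {n} outside [{lo}, {hi}]"

    return _run_filter("length", cands, pred)


def filter_plddt(
    cands: Sequence[CandidateRecord],
    scores: Mapping[str, float],
    min_plddt: float = 0.80,
) -> tuple[list[CandidateRecord], StageReport]:
    """Keep candidates with structure confidence >= ``min_plddt`` (inclusive).

    Scores on a 0-100 scale are auto-normalized to 0-1 (any value > 1 is
    divided by 100). A candidate without a score is an error.
    """
    for c in cands:
        if c.id not in scores:
            raise SequenceError(f"no pLDDT score supplied for candidate {c.id!r}")
        v = float(scores[c.id])
        c.plddt = v / 100.0 if v > 1.0 else v

    return _run_filter(
        "plddt",
        cands,
        lambda c: None if c.plddt >= min_plddt else f"pLDDT {c.plddt:.3f} < {min_plddt:.2f}",
    )


def compute_novelty(
    cands: Sequence[CandidateRecord],
    refs: ReferenceSet,
    scheme: ScoringScheme,
    denominator: str = "columns",
) -> None:
    """Annotate each candidate with MaxID, best reference and identity bin."""
    for c in cands:
        c.maxid, c.best_ref = max_identity(c.protein, refs, scheme, denominator)
        c.bin = IdentityBin.from_maxid(c.maxid)


def filter_novelty(
    cands: Sequence[CandidateRecord],
    max_maxid: float = 90.0,
) -> tuple[list[CandidateRecord], StageReport]:
    """Exclude candidates with MaxID above ``max_maxid`` percent (exactly 90%
    is kept; the boundary is inclusive-keep)."""
    for c in cands:
        if c.maxid is None:
            raise SequenceError(f"MaxID not computed for candidate {c.id!r}")
    return _run_filter(
        "novelty",
        cands,
        lambda c: None if c.maxid <= max_maxid else f"MaxID {c.maxid:.1f}% > {max_maxid:.0f}%",
    )


def rank_by_score(
    cands: Sequence[CandidateRecord],
    refs: ReferenceSet,
    scheme: ScoringScheme,
) -> None:
    """Annotate each candidate with the composite Alignment Score."""
    for c in cands:
        c.score = composite_score(c.protein, refs, scheme)


def check_active_site(
    cand: ProteinSequence,
    anchor: ProteinSequence,
    anchor_pos: int = 82,
    required: str = "K",
    scheme: ScoringScheme | None = None,
) -> bool:
    """True iff the candidate residue aligned to the anchor's catalytic
    position (1-based) is ``required``; a gap there is False."""
    if not 1 <= anchor_pos <= len(anchor):
        raise ValueError(f"anchor position {anchor_pos} outside anchor (len {len(anchor)})")
    if anchor.residues[anchor_pos - 1] != required:
        raise ValueError(
            f"anchor residue at position {anchor_pos} is "
            f"{anchor.residues[anchor_pos - 1]!r}, expected {required!r}"
        )
    res = global_align(cand, anchor, scheme)
    anchor_i = 0
    for col_a, col_b in zip(res.aligned_a, res.aligned_b):
        if col_b != "-":
            anchor_i += 1
            if anchor_i == anchor_pos:
                return col_a == required
    raise AssertionError("anchor position not reached in alignment")  # pragma: no cover


def filter_active_site(
    cands: Sequence[CandidateRecord],
    anchor: ProteinSequence,
    anchor_pos: int = 82,
    required: str = "K",
    scheme: ScoringScheme | None = None,
) -> tuple[list[CandidateRecord], StageReport]:
    for c in cands:
        c.active_site_ok = check_active_site(c.protein, anchor, anchor_pos, required, scheme)
    return _run_filter(
        "active_site",
        cands,
        lambda c: None
        if c.active_site_ok
        else f"residue aligned to anchor {required}{anchor_pos} is not {required}",
    )


def cluster_by_identity(
    cands: Sequence[CandidateRecord],
    threshold: float = 0.70,
    scheme: ScoringScheme | None = None,
) -> list[CandidateRecord]:
    """Greedy identity clustering for diversity; returns the representatives.

    Candidates are processed in descending composite-score order (ties by
    id); each joins the first existing cluster whose representative it
    matches at >= ``threshold`` pairwise global identity, else founds a new
    cluster. Because of the processing order the founder is the
    highest-scoring member, i.e. the representative.
    """
    for c in cands:
        if c.score is None:
            raise SequenceError(f"composite score not computed for candidate {c.id!r}")
    ordered = sorted(cands, key=lambda c: (-c.score, c.id))
    reps: list[CandidateRecord] = []
    for c in ordered:
        for idx, rep in enumerate(reps):
            if pairwise_identity(c.protein, rep.protein, scheme) >= threshold:
                c.cluster = idx
                c.is_representative = False
                break
        else:
            c.cluster = len(reps)
            c.is_representative = True
            reps.append(c)
    return reps


def select_candidates(
    cands: Sequence[CandidateRecord],
    plan: SelectionPlan | None = None,
) -> tuple[list[CandidateRecord], StageReport]:
    """Stratified final selection: per bin, the top-quota cluster
    representatives by composite score (ties by id). Bins listed in
    ``plan.exclude_bins`` contribute nothing; a bin with fewer eligible
    representatives than its quota yields what it has, with a warning."""
    plan = plan or SelectionPlan()
    eligible = [
        c
        for c in cands
        if c.is_representative and c.bin is not None and c.bin not in plan.exclude_bins
    ]
    selected: list[CandidateRecord] = []
    # highest-identity bins first, matching how the selection is reported
    for b in sorted(plan.quotas, key=lambda b: -b.value[0]):
        quota = plan.quotas[b]
        in_bin = sorted(
            (c for c in eligible if c.bin is b), key=lambda c: (-c.score, c.id)
        )
        if len(in_bin) < quota:
            logger.warning(
                "bin %s: only %d representatives for quota %d", b.label, len(in_bin), quota
            )
        selected.extend(in_bin[:quota])
    for rank, c in enumerate(selected, start=1):
        c.selected_rank = rank
    failures = {c.id: "not selected" for c in cands if c.selected_rank is None}
    report = StageReport(
        name="selection", n_in=len(cands), n_passed=len(selected), failures=failures
    )
    return selected, report


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class TriageConfig:
    """Every tunable of the pipeline, with the defaults it was designed for."""

    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    plan: SelectionPlan = field(default_factory=SelectionPlan)
    length_bounds: tuple[int, int] = (306, 421)
    length_sd_multiplier: float | None = None  # overrides length_bounds via refs
    min_plddt: float = 0.80
    max_maxid: float = 90.0
    identity_denominator: str = "columns"
    anchor_pos: int = 82
    anchor_residue: str = "K"
    enable_active_site: bool = True
    enable_clustering: bool = True
    cluster_threshold: float = 0.70
    # optional per-candidate scalar stability filter (e.g. a folding-energy
    # proxy); returns None to pass or a failure reason. Disabled by default.
    stability_filter: Callable[[CandidateRecord], str | None] | None = None


@dataclass
class PipelineResult:
    records: list[CandidateRecord]
    selected: list[CandidateRecord]
    report: FilterReport

    def to_frame(self) -> pd.DataFrame:
        """One row per input candidate with all triage fields."""
        rows = []
        for c in self.records:
            rows.append(
                {
                    "candidate": c.id,
                    "protein_length": len(c.protein) if c.protein else None,
                    "plddt": c.plddt,
                    "maxid": c.maxid,
                    "best_ref": c.best_ref,
                    "bin": c.bin.label if c.bin else None,
                    "score": c.score,
                    "active_site_ok": c.active_site_ok,
                    "cluster": c.cluster,
                    "representative": c.is_representative,
                    "selected_rank": c.selected_rank,
                    **{f"stage_{k}": v for k, v in c.stage_flags.items()},
                }
            )
        return pd.DataFrame(rows)


def run_pipeline(
    candidates: Iterable[CodingSequence],
    references: ReferenceSet,
    plddt: Mapping[str, float],
    anchor: ProteinSequence | None = None,
    config: TriageConfig | None = None,
) -> PipelineResult:
    """Run the full triage in the fixed stage order and return all state.

    ``anchor`` is required when the active-site stage is enabled. Any stage
    error aborts with the stage name and offending candidate id.
    """
    config = config or TriageConfig()
    records = [CandidateRecord(seq=c) for c in candidates]
    report = FilterReport()

    pool, stage = filter_start_codon(records)
    report.add(stage)

    for c in pool:
        c.protein = ProteinSequence(id=c.id, residues=c.seq.protein)
    pool, stage = filter_length(
        pool, references, bounds=config.length_bounds,
        sd_multiplier=config.length_sd_multiplier,
    )
    report.add(stage)

    pool, stage = filter_plddt(pool, plddt, config.min_plddt)
    report.add(stage)

    if config.stability_filter is not None:
        pool, stage = _run_filter("stability", pool, config.stability_filter)
        report.add(stage)

    compute_novelty(pool, references, config.scheme, config.identity_denominator)
    pool, stage = filter_novelty(pool, config.max_maxid)
    report.add(stage)

    rank_by_score(pool, references, config.scheme)

    if config.enable_active_site:
        if anchor is None:
            raise ValueError("active-site stage enabled but no anchor supplied")
        pool, stage = filter_active_site(
            pool, anchor, config.anchor_pos, config.anchor_residue, config.scheme
        )
        report.add(stage)

    if config.enable_clustering:
        cluster_by_identity(pool, config.cluster_threshold, config.scheme)
    else:
        for i, c in enumerate(pool):
            c.cluster, c.is_representative = i, True

    selected, stage = select_candidates(pool, config.plan)
    report.add(stage)

    return PipelineResult(records=records, selected=selected, report=report)
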