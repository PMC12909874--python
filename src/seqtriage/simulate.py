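"""Synthetic reference families and candidate pools with controlled identity.

The real pipeline was run against tens of thousands of natural tryptophan
synthase β-subunit (TrpB) sequences and thousands of generated candidates.
This module builds desk-scale stand-ins with the properties the pipeline's
stages actually consume:

* a reference set of remote homologs that share a conserved catalytic window
  (a lysine at position 82, as in TrpB, embedded in a reserved 9-residue
  motif) but are otherwise strongly diverged (~20% pairwise identity), and
* candidate pools whose maximum identity to the reference set (MaxID) is
  controlled by construction: a candidate is a substitution-only derivative
  of one parent reference, and is accepted only if its measured global-
  alignment identity to that parent (same aligner and denominator as the
  pipeline's MaxID) lands inside the target bin with a safety margin.
  Measurement-based acceptance is needed because under the affine gap
  parameters a run of adjacent mismatches aligns better as paired gaps, so
  the identity of the optimal alignment sits somewhat below the raw
  substitution fraction.

Candidates aimed at the 80–90% bin each derive from a distinct parent:
two ≥85%-identity derivatives of one parent would be ≥70% identical to each
other and merge at the diversity-clustering threshold.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import pairwise_identity
from .seq_core import (
    AA_ALPHABET,
    CodingSequence,
    CodonUsageTable,
    ProteinSequence,
    ReferenceSet,
    codon_optimize,
)

_AAS = sorted(AA_ALPHABET)

#: 1-based position of the catalytic lysine, as in the TrpB anchor numbering.
CATALYTIC_POS = 82
#: 0-based indices reserved from mutation: the start Met and the catalytic
#: window (positions 78–86, 1-based) shared by all family members.
_WINDOW = range(CATALYTIC_POS - 5, CATALYTIC_POS + 4)  # 0-based 77..85


def _reserved_indices(length: int) -> set[int]:
    return {0} | {i for i in _WINDOW if i < length}


def random_protein(rng: np.random.Generator, length: int, seq_id: str) -> ProteinSequence:
    """Uniform random protein starting with M and carrying K at position 82."""
    residues = [_AAS[i] for i in rng.integers(0, 20, size=length)]
    residues[0] = "M"
    if length >= CATALYTIC_POS:
        residues[CATALYTIC_POS - 1] = "K"
    return ProteinSequence(id=seq_id, residues="".join(residues))


def mutate_protein(
    protein: ProteinSequence,
    n_mutations: int,
    rng: np.random.Generator,
    seq_id: str,
    reserved: set[int] | None = None,
) -> ProteinSequence:
    """Substitute ``n_mutations`` distinct non-reserved positions, each to a
    uniformly chosen different residue."""
    residues = list(protein.residues)
    reserved = _reserved_indices(len(residues)) if reserved is None else reserved
    mutable = [i for i in range(len(residues)) if i not in reserved]
    if n_mutations > len(mutable):
        raise ValueError(
            f"cannot place {n_mutations} substitutions in {len(mutable)} mutable positions"
        )
    positions = rng.choice(len(mutable), size=n_mutations, replace=False)
    for p in positions:
        i = mutable[int(p)]
        choices = [a for a in _AAS if a != residues[i]]
        residues[i] = choices[int(rng.integers(0, len(choices)))]
    return ProteinSequence(id=seq_id, residues="".join(residues))


def make_reference_family(
    seed: int,
    n_refs: int = 40,
    length: int = 100,
    divergence: float = 0.75,
) -> tuple[ProteinSequence, ReferenceSet]:
    """Build an anchor (the family root) and a reference set of remote
    homologs derived from it.

    Each reference substitutes ``divergence`` of the root's non-reserved
    positions, yielding ~20% pairwise identity at the default — distant
    enough that a candidate's designed parent identity dominates its MaxID.
    Returns (anchor, references).
    """
    rng = np.random.default_rng(seed)
    root = random_protein(rng, length, "anchor")
    n_mut = round(divergence * (length - len(_reserved_indices(length))))
    members = [
        mutate_protein(root, n_mut, rng, f"ref{i:03d}") for i in range(n_refs)
    ]
    return root, ReferenceSet.from_members(members)


def derive_at_identity(
    parent: ProteinSequence,
    target: float,
    rng: np.random.Generator,
    seq_id: str,
    margin: float = 1.5,
    max_attempts: int = 60,
) -> tuple[ProteinSequence, float]:
    """Substitution-only derivative of ``parent`` whose measured global-
    alignment percent identity to it lies within ``target ± (5 - margin)``
    and strictly inside the target's 10-point identity bin.

    Proposals start from round(L·(100-target)/100) substitutions and the
    count is then steered by the measurement (the optimal affine alignment
    of a dense-substitution pair uses gap pairs and measures below the raw
    substitution fraction). Returns the accepted derivative and its
    measured identity.
    """
    length = len(parent)
    lo = target - 5 + margin
    hi = target + 5 - margin
    mutable = length - len(_reserved_indices(length))
    k = min(mutable, round(length * (100 - target) / 100))
    for attempt in range(max_attempts):
        cand = mutate_protein(parent, k, rng, seq_id)
        ident = 100.0 * pairwise_identity(cand, parent)
        if lo <= ident <= hi:
            return cand, ident
        # steer the substitution count toward the target, one measurement
        # at a time; fresh random positions each proposal
        step = max(1, round(abs(ident - target) * length / 200))
        k = k - step if ident < target else k + step
        k = max(1, min(mutable, k))
    raise RuntimeError(
        f"could not place a derivative of {parent.id!r} at identity "
        f"{target}% within {max_attempts} attempts"
    )


@dataclass
class SyntheticPool:
    """A candidate pool with per-candidate ground truth."""

    candidates: list[CodingSequence]
    plddt: dict[str, float]
    designed_maxid: dict[str, float]
    designed_parent: dict[str, str]
    anchor: ProteinSequence
    references: ReferenceSet


def make_candidate_pool(
    seed: int,
    per_bin: dict[int, int] | None = None,
    n_refs: int = 40,
    length: int = 100,
    n_bad_start: int = 20,
    n_bad_length: int = 25,
    n_low_plddt: int = 25,
    n_high_identity: int = 8,
    n_active_site_broken: int = 6,
) -> SyntheticPool:
    """Build a triage-ready candidate pool with known per-stage outcomes.

    ``per_bin`` maps a bin-midpoint designed identity (45, 55, 65, 75, 85)
    to the number of clean candidates placed there; the defaults exceed the
    pipeline's default per-bin selection quotas (30/40/20/10/5 for
    80–90/70–80/60–70/50–60/40–50% MaxID) so stratified selection is fully
    subscribed. Chaff candidates exercise the earlier stages: non-ATG starts,
    out-of-range lengths, sub-threshold pLDDT, >90% identity, and a broken
    catalytic lysine.
    """
    if per_bin is None:
        per_bin = {85: 34, 75: 44, 65: 24, 55: 14, 45: 9}
    rng = np.random.default_rng(seed)
    anchor, refs = make_reference_family(seed + 1, n_refs=n_refs, length=length)
    table = CodonUsageTable.ecoli_default()
    members = list(refs)

    candidates: list[CodingSequence] = []
    plddt: dict[str, float] = {}
    designed_maxid: dict[str, float] = {}
    designed_parent: dict[str, str] = {}
    counter = 0

    def add(protein: ProteinSequence, score: float, maxid: float | None, parent: str | None):
        cds = codon_optimize(protein, table)
        candidates.append(cds)
        plddt[cds.id] = score
        if maxid is not None:
            designed_maxid[cds.id] = maxid
            designed_parent[cds.id] = parent

    # clean candidates at bin midpoints; the 80-90 bin gets distinct parents
    high_bin_parents = iter(rng.permutation(n_refs))
    for target, count in sorted(per_bin.items(), reverse=True):
        for _ in range(count):
            if target >= 80:
                parent = members[int(next(high_bin_parents))]
            else:
                parent = members[int(rng.integers(0, n_refs))]
            counter += 1
            prot, ident = derive_at_identity(parent, float(target), rng, f"cand{counter:04d}")
            add(prot, 0.82 + 0.16 * float(rng.random()), ident, parent.id)

    # chaff: fails start-codon filter (first codon rewritten to TTG)
    for _ in range(n_bad_start):
        counter += 1
        parent = members[int(rng.integers(0, n_refs))]
        prot = mutate_protein(parent, round(length * 0.25), rng, f"cand{counter:04d}")
        cds = codon_optimize(prot, table)
        cds = CodingSequence(id=cds.id, dna="TTG" + cds.dna[3:])
        candidates.append(cds)
        plddt[cds.id] = 0.9

    # chaff: out-of-range protein length (truncated / extended derivative)
    for j in range(n_bad_length):
        counter += 1
        parent = members[int(rng.integers(0, n_refs))]
        if j % 2 == 0:
            residues = parent.residues[: length - 15]
        else:
            extra = "".join(_AAS[i] for i in rng.integers(0, 20, size=15))
            residues = parent.residues + extra
        add(ProteinSequence(f"cand{counter:04d}", residues), 0.9, None, None)

    # chaff: low structure confidence
    for _ in range(n_low_plddt):
        counter += 1
        parent = members[int(rng.integers(0, n_refs))]
        prot = mutate_protein(parent, round(length * 0.25), rng, f"cand{counter:04d}")
        add(prot, 0.50 + 0.29 * float(rng.random()), None, None)

    # chaff: too close to a natural reference (95% identity -> excluded)
    for _ in range(n_high_identity):
        counter += 1
        parent = members[int(rng.integers(0, n_refs))]
        prot, ident = derive_at_identity(parent, 95.0, rng, f"cand{counter:04d}")
        add(prot, 0.9, ident, parent.id)

    # chaff: catalytic lysine mutated (fails the active-site check)
    for _ in range(n_active_site_broken):
        counter += 1
        parent = members[int(rng.integers(0, n_refs))]
        prot = mutate_protein(parent, round(length * 0.15), rng, f"cand{counter:04d}")
        residues = list(prot.residues)
        residues[CATALYTIC_POS - 1] = "A"
        add(ProteinSequence(prot.id, "".join(residues)), 0.9, None, None)

    return SyntheticPool(
        candidates=candidates,
        plddt=plddt,
        designed_maxid=designed_maxid,
        designed_parent=designed_parent,
        anchor=anchor,
        references=refs,
    )


def synthetic_codon_corpus(
    seed: int, n: int = 50, length: int = 60
) -> list[CodingSequence]:
    """A small corpus of codon sequences for fitting the stand-in generator:
    a protein family rendered to DNA with usage-weighted synonymous codons."""
    rng = np.random.default_rng(seed)
    root = random_protein(rng, length, "root")
    table = CodonUsageTable.ecoli_default()
    corpus = []
    for i in range(n):
        prot = mutate_protein(root, round(0.2 * length), rng, f"nat{i:03d}")
        codons = []
        for aa in prot.residues:
            opts = sorted(table.usage[aa].items())
            p = np.array([f for _, f in opts])
            codons.append(opts[int(rng.choice(len(opts), p=p / p.sum()))][0])
        codons.append("TAA")
        corpus.append(CodingSequence(id=prot.id, dna="".join(codons)))
    return corpus
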