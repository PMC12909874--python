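"""Core sequence domain types and I/O.

Codon-resolved coding sequences, validated protein sequences, the natural
reference set used by the length and novelty stages, and codon-usage-driven
reverse translation. Coordinates in all user-facing output are 1-based and
inclusive; the reading frame is fixed at 0 from the sequence start (generated
sequences are prompted with ATG, so there is no ORF scanning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, '*' for stop; all 64 codons present.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"


class SequenceError(ValueError):
    """Invalid sequence content (alphabet, structure) or malformed input."""


def _validate_alphabet(s: str, allowed: frozenset, what: str, seq_id: str) -> None:
    for i, ch in enumerate(s):
        if ch not in allowed:
            raise SequenceError(
                f"{what} sequence {seq_id!r}: invalid character {ch!r} "
                f"at position {i + 1}"
            )


@dataclass(frozen=True)
class CodingSequence:
    """A codon-resolved DNA record with its translation.

    ``dna`` must be over {A,C,G,T}; a trailing partial codon is dropped with a
    warning on construction. ``codons`` is the contiguous-triplet view and
    concatenates exactly to ``dna``; ``protein`` is the standard-code
    translation up to (not including) the first in-frame stop codon.
    """

    id: str
    dna: str

    def __post_init__(self) -> None:
        dna = self.dna.upper()
        _validate_alphabet(dna, DNA_ALPHABET, "DNA", self.id)
        if len(dna) < 3:
            raise SequenceError(f"DNA sequence {self.id!r}: fewer than 3 nucleotides")
        if len(dna) % 3:
            logger.warning(
                "sequence %r: dropping trailing partial codon of %d nt",
                self.id, len(dna) % 3,
            )
            dna = dna[: len(dna) - len(dna) % 3]
        object.__setattr__(self, "dna", dna)

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(self.dna[i : i + 3] for i in range(0, len(self.dna), 3))

    @property
    def protein(self) -> str:
        aas = []
        for codon in self.codons:
            aa = CODON_TO_AA[codon]
            if aa == "*":
                break
            aas.append(aa)
        return "".join(aas)

    @property
    def starts_with_atg(self) -> bool:
        return self.dna[:3] == "ATG"

    def __len__(self) -> int:
        return len(self.dna)


@dataclass(frozen=True)
class ProteinSequence:
    """A validated amino-acid sequence over the 20-letter alphabet.

    'X' is permitted but flagged via :attr:`has_ambiguous`.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        if not residues:
            raise SequenceError(f"protein sequence {self.id!r}: empty")
        _validate_alphabet(residues, AA_ALPHABET | {"X"}, "protein", self.id)
        object.__setattr__(self, "residues", residues)
        if "X" in residues:
            logger.warning("protein %r contains ambiguous residue 'X'", self.id)

    @property
    def has_ambiguous(self) -> bool:
        return "X" in self.residues

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass
class ReferenceSet:
    """Natural reference proteins plus the family length statistics.

    The defaults are the length mean/SD of the natural TrpB family the
    triage pipeline was designed around; they matter only when length-filter
    bounds are recomputed as mean ± m·σ instead of the fixed defaults.
    """

    members: list[ProteinSequence]
    length_mean: float = 363.55
    length_sd: float = 57.91

    def __post_init__(self) -> None:
        if not self.members:
            raise SequenceError("reference set must contain at least one member")
        if self.length_mean <= 0 or self.length_sd < 0:
            raise SequenceError("reference length statistics must be positive")

    @classmethod
    def from_members(cls, members: Iterable[ProteinSequence]) -> "ReferenceSet":
        """Build a reference set with length statistics computed from members."""
        members = list(members)
        n = len(members)
        if n == 0:
            raise SequenceError("reference set must contain at least one member")
        lengths = [len(m) for m in members]
        mean = sum(lengths) / n
        var = sum((l - mean) ** 2 for l in lengths) / (n - 1) if n > 1 else 0.0
        return cls(members=members, length_mean=mean, length_sd=var ** 0.5)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CodonUsageTable:
    """Relative synonymous codon usage: amino acid -> {codon: frequency}.

    Frequencies are normalized per amino acid on construction. Every amino
    acid of the standard code (plus stop, keyed '*') must have at least one
    codon with positive frequency.
    """

    usage: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        norm: dict[str, dict[str, float]] = {}
        for aa, codons in self.usage.items():
            total = sum(codons.values())
            if total <= 0:
                raise SequenceError(f"codon usage for {aa!r} has no positive frequency")
            norm[aa] = {c: f / total for c, f in codons.items()}
        required = set(AA_ALPHABET) | {"*"}
        missing = required - set(norm)
        if missing:
            raise SequenceError(f"codon usage table missing amino acids: {sorted(missing)}")
        self.usage = norm

    def best_codon(self, aa: str) -> str:
        """Highest-frequency codon for ``aa``; ties broken alphabetically."""
        if aa not in self.usage:
            raise SequenceError(f"amino acid {aa!r} absent from codon usage table")
        return min(self.usage[aa], key=lambda c: (-self.usage[aa][c], c))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonUsageTable":
        usage: dict[str, dict[str, float]] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.lower().startswith("amino_acid"):
                raise SequenceError(f"{path}: expected header 'amino_acid\\tcodon\\tfrequency'")
            for line in fh:
                if not line.strip():
                    continue
                aa, codon, freq = line.rstrip("\n").split("\t")
                usage.setdefault(aa, {})[codon] = float(freq)
        return cls(usage)

    @classmethod
    def ecoli_default(cls) -> "CodonUsageTable":
        """The packaged E. coli K-12 codon usage table."""
        ref = resources.files("seqtriage").joinpath("data/ecoli_codon_usage.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


# ---------------------------------------------------------------------------
# Operations


def translate(seq: CodingSequence) -> ProteinSequence:
    """Standard-code translation in frame 0, stopping at the first stop codon."""
    protein = seq.protein
    if not protein:
        raise SequenceError(
            f"sequence {seq.id!r} translates to an empty protein "
            "(starts with a stop codon)"
        )
    return ProteinSequence(id=seq.id, residues=protein)


def codon_optimize(
    protein: ProteinSequence,
    table: CodonUsageTable | None = None,
    strategy: str = "max_usage",
) -> CodingSequence:
    """Reverse-translate ``protein`` and append a stop codon.

    ``max_usage`` picks each residue's highest-frequency codon (ties broken
    alphabetically), so the result is deterministic and
    ``translate(codon_optimize(p)) == p``.
    """
    if strategy != "max_usage":
        raise ValueError(f"unknown codon optimization strategy {strategy!r}")
    if table is None:
        table = CodonUsageTable.ecoli_default()
    codons = [table.best_codon(aa) for aa in protein.residues]
    codons.append(table.best_codon("*"))
    return CodingSequence(id=protein.id, dna="".join(codons))


def read_fasta(path: str | Path, alphabet: str) -> list:
    """Read a FASTA file into validated records.

    ``alphabet`` is ``"dna"`` (-> :class:`CodingSequence`) or ``"protein"``
    (-> :class:`ProteinSequence`). Input order is preserved; duplicate ids are
    an error; an empty file yields an empty list with a warning.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        s = str(rec.seq)
        if alphabet == "dna":
            records.append(CodingSequence(id=rec.id, dna=s))
        else:
            records.append(ProteinSequence(id=rec.id, residues=s))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: Sequence, path: str | Path, width: int = 60) -> None:
    """Write records (CodingSequence or ProteinSequence) wrapped at ``width``."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            seq = rec.dna if isinstance(rec, CodingSequence) else rec.residues
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
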