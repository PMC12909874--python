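"""Codon-level Markov stand-in generator.

A small n-gram model over the 64 codons plus an end-of-sequence token that
reproduces the sampling interface of a codon-level autoregressive language
model — ATG prompt, temperature scaling, top-k truncation, nucleus (top-p)
truncation, a maximum token count, and early termination on a stop event —
so the downstream triage pipeline can be exercised without model weights.

Sampling defaults mirror the generation settings the pipeline was designed
for: temperature 1.0, top_k 50, top_p 0.9, at most 512 codon tokens, prompt
"ATG". Truncation order is temperature -> top-k -> top-p -> renormalize;
probability ties are broken by codon lexicographic order so that sampling is
reproducible. Two events terminate a sequence: emission of the dedicated end
token (learned from training sequences that end without an in-frame stop
codon) and emission of an in-frame stop codon, matching translation
semantics. Unseen contexts back off by dropping the oldest codon, down to
the unconditional codon distribution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seq_core import CodingSequence, STOP_CODONS

#: Dedicated end-of-sequence token (sorts before codons; never emitted as DNA).
END_TOKEN = "<end>"

Context = tuple[str, ...]


@dataclass
class CodonMarkovModel:
    """Codon n-gram model: context (tuple of ≤ order codons) -> token counts."""

    order: int
    transition_counts: dict[Context, Counter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("model order must be non-negative")

    def probabilities(self, context: Context) -> dict[str, float]:
        """Normalized next-token distribution for an observed context."""
        counts = self.transition_counts[context]
        total = sum(counts.values())
        return {tok: c / total for tok, c in counts.items()}

    def backoff_context(self, history: Sequence[str]) -> Context:
        """Longest suffix of ``history`` (≤ order) observed in training.

        Backs off by dropping the oldest codon; raises ``KeyError`` naming
        the context if even the empty context is unseen (unfitted model).
        """
        ctx: Context = tuple(history[-self.order:]) if self.order else ()
        while ctx not in self.transition_counts:
            if not ctx:
                raise KeyError(
                    f"context {tuple(history[-self.order:])!r} unseen and no "
                    "back-off distribution available (model not fitted?)"
                )
            ctx = ctx[1:]
        return ctx

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("order\t%d\n" % self.order)
            fh.write("context\tcodon\tcount\n")
            for ctx in sorted(self.transition_counts):
                for tok in sorted(self.transition_counts[ctx]):
                    fh.write(f"{'|'.join(ctx) or '.'}\t{tok}\t{self.transition_counts[ctx][tok]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonMarkovModel":
        with open(path, encoding="utf-8") as fh:
            order = int(fh.readline().split("\t")[1])
            fh.readline()  # header
            counts: dict[Context, Counter] = {}
            for line in fh:
                ctx_s, tok, count = line.rstrip("\n").split("\t")
                ctx = () if ctx_s == "." else tuple(ctx_s.split("|"))
                counts.setdefault(ctx, Counter())[tok] = int(count)
        return cls(order=order, transition_counts=counts)


@dataclass(frozen=True)
class SamplingConfig:
    """Sampling knobs of the stand-in generator (see module docstring)."""

    temperature: float = 1.0
    top_k: int = 50
    top_p: float = 0.9
    max_codons: int = 512
    prompt: str = "ATG"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.top_k < 1 or self.top_k > 65:
            raise ValueError("top_k must be in [1, 65] (64 codons + end token)")
        if not 0 < self.top_p <= 1:
            raise ValueError("top_p must be in (0, 1]")
        if self.max_codons < 1:
            raise ValueError("max_codons must be positive")
        if len(self.prompt) % 3 or not self.prompt:
            raise ValueError("prompt must be a non-empty codon string (length % 3 == 0)")

    @property
    def prompt_codons(self) -> tuple[str, ...]:
        return tuple(self.prompt[i : i + 3] for i in range(0, len(self.prompt), 3))


def fit_codon_markov(
    corpus: Iterable[CodingSequence], order: int
) -> CodonMarkovModel:
    """Fit exact n-gram counts of all context lengths 0..order over a corpus.

    Each sequence contributes one transition per emitted codon, conditioned on
    every context suffix up to ``order`` (the shorter contexts feed back-off).
    A sequence's terminal event is its first in-frame stop codon if present,
    else the dedicated end token.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot fit a codon Markov model on an empty corpus")
    model = CodonMarkovModel(order=order)
    counts = model.transition_counts
    for seq in corpus:
        tokens: list[str] = []
        for codon in seq.codons:
            tokens.append(codon)
            if codon in STOP_CODONS:
                break
        else:
            tokens.append(END_TOKEN)
        if len(tokens) < order + 1:
            raise ValueError(
                f"sequence {seq.id!r} has fewer than order+1 = {order + 1} codon events"
            )
        for i, tok in enumerate(tokens):
            for k in range(0, order + 1):
                if k > i:
                    break
                ctx = tuple(tokens[i - k : i])
                counts.setdefault(ctx, Counter())[tok] += 1
    return model


def _truncated_distribution(
    probs: dict[str, float], cfg: SamplingConfig
) -> tuple[list[str], np.ndarray]:
    """Apply temperature, top-k, then nucleus truncation; renormalize.

    Ties in probability are broken by token lexicographic order (the end
    token '<end>' sorts before all codons). Always keeps at least one token.
    """
    items = sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))
    toks = [t for t, _ in items]
    p = np.array([v for _, v in items], dtype=float)
    if cfg.temperature != 1.0:
        # temperature rescaling preserves the probability ordering
        p = p ** (1.0 / cfg.temperature)
    p /= p.sum()
    k = min(cfg.top_k, len(toks))
    toks, p = toks[:k], p[:k]
    # smallest prefix whose cumulative mass reaches top_p; if the top-k tail
    # was cut below top_p, keep everything that survived top-k
    cum = np.cumsum(p)
    cut = int(np.searchsorted(cum, cfg.top_p - 1e-12, side="left")) + 1
    cut = max(1, min(cut, len(toks)))
    toks, p = toks[:cut], p[:cut]
    p = p / p.sum()
    return toks, p


def sample_sequence(
    model: CodonMarkovModel, cfg: SamplingConfig, seq_id: str = "sample"
) -> CodingSequence:
    """Draw one coding sequence from the model under ``cfg``.

    The output begins with the prompt, has at most ``max_codons`` codons, and
    is byte-identical for identical (model, cfg, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    tokens: list[str] = list(cfg.prompt_codons)
    if any(t in STOP_CODONS for t in tokens):
        raise ValueError("prompt contains a stop codon")
    while len(tokens) < cfg.max_codons:
        ctx = model.backoff_context(tokens)
        toks, p = _truncated_distribution(model.probabilities(ctx), cfg)
        tok = toks[int(rng.choice(len(toks), p=p))]
        if tok == END_TOKEN:
            break
        tokens.append(tok)
        if tok in STOP_CODONS:
            break
    return CodingSequence(id=seq_id, dna="".join(tokens))


def sample_many(
    model: CodonMarkovModel,
    cfg: SamplingConfig,
    n: int,
    id_prefix: str = "gen",
) -> list[CodingSequence]:
    """Sample ``n`` sequences; sequence i uses seed ``cfg.seed + i`` so the
    batch is reproducible and individually re-drawable."""
    out = []
    for i in range(n):
        cfg_i = SamplingConfig(
            temperature=cfg.temperature, top_k=cfg.top_k, top_p=cfg.top_p,
            max_codons=cfg.max_codons, prompt=cfg.prompt, seed=cfg.seed + i,
        )
        out.append(sample_sequence(model, cfg_i, seq_id=f"{id_prefix}-{i}"))
    return out
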