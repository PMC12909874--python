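"""Independent brute-force oracles used only by the tests.

The alignment oracles enumerate every monotone alignment path (no dynamic
programming, no memoization) and score it with the affine convention: a run
of g gap positions costs gap_open + (g-1)*gap_extend, tracked per sequence.
The n-gram oracle tallies codon transitions by direct string scanning.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_global_score(a: str, b: str, scheme) -> float:
    """Max score over all global alignments, by exhaustive path enumeration."""
    best = -math.inf

    def rec(i: int, j: int, last: str | None, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            if score > best:
                best = score
            return
        if i < len(a) and j < len(b):
            s = scheme.match if a[i] == b[j] else scheme.mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):  # gap in b
            g = scheme.gap_extend if last == "U" else scheme.gap_open
            rec(i + 1, j, "U", score + g)
        if j < len(b):  # gap in a
            g = scheme.gap_extend if last == "L" else scheme.gap_open
            rec(i, j + 1, "L", score + g)

    rec(0, 0, None, 0.0)
    return best


def brute_local_score(a: str, b: str, scheme) -> float:
    """Max over the empty alignment (0) and the best global alignment of
    every substring pair."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = brute_global_score(a[i1:i2], b[j1:j2], scheme)
                    if s > best:
                        best = s
    return best


def tally_ngrams(sequences: list[list[str]], order: int) -> dict:
    """Hand tally of context->token counts over token lists, all context
    lengths 0..order."""
    counts: dict[tuple, Counter] = {}
    for tokens in sequences:
        for i, tok in enumerate(tokens):
            for k in range(min(i, order) + 1):
                ctx = tuple(tokens[i - k : i])
                counts.setdefault(ctx, Counter())[tok] += 1
    return counts
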