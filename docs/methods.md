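# Methods

This note records the models, conventions, and numerical choices behind
`seqtriage`, in the order a user meets them.

## Scope and assumptions

The package triages *already generated* candidate coding sequences. It does
not train or run a generative model, predict structures, or compute folding
energies: structure confidence (pLDDT) arrives as an externally supplied
per-candidate scalar, and a stability filter exists only as a pluggable
hook (`TriageConfig.stability_filter`), disabled by default. Sequences are
assumed synthetic and clean: the DNA alphabet is strict {A,C,G,T} (no
ambiguity codes), the reading frame is fixed at 0 because generation is
prompted with ATG, and translation uses the standard genetic code, stopping
at the first in-frame stop codon. All user-facing coordinates are 1-based
and inclusive.

## Alignment model

Both aligners use affine gap penalties in the convention where a run of
`g` gap positions costs `gap_open + (g−1)·gap_extend` — the first gap
residue *is* the opening, so a length-1 gap costs exactly `gap_open`
(−0.5 by default, with −0.1 extensions, +1 match, −1 mismatch). Global
alignments penalize end gaps; local alignment scores are floored at 0 (the
empty alignment). `Bio.Align.PairwiseAligner` provides the dynamic program;
the test suite proves score equality against an independent
exhaustive-enumeration oracle on hundreds of short pairs. Among co-optimal
alignments the first traceback of the aligner is reported deterministically;
co-optimal tracebacks can differ in *identity* (see below) but never in
score.

Percent identity is `matches / alignment columns`, end gaps included in the
denominator; in a pairwise alignment no column is gapped in both rows, so
the denominator is simply the alignment length. For two ~400-residue
proteins this convention yields the familiar "322 of 400 residues" style of
full-length identity. A `denominator="shorter"` switch (matches over the
shorter sequence's length) is available for comparison with
coverage-insensitive tools.

A consequence of these parameters worth knowing: a run of two or more
adjacent mismatches costs more than bridging it with a deletion–insertion
pair (e.g. 2 mismatches = −2 versus two length-1 gaps ≈ −1.2…−1.4), so
optimal alignments of densely substituted pairs contain gap pairs and their
measured identity sits below the raw substitution fraction. The synthetic
pool generator accounts for this by measuring, not assuming (below).

The composite Alignment Score aggregates by the **mean** over references,
`S(c) = w_g·mean_r NW(c,r) + w_l·mean_r SW(c,r)` with weights 3 and 8, so
the statistic does not scale with reference-set size; duplicating a
reference leaves scores unchanged.

## Triage stages

* Length bounds default to the fixed window [306, 421] residues, the
  printed valid range for the TrpB family. The family statistics carried by
  `ReferenceSet` (mean 363.55, SD 57.91) reproduce this window at ±1σ, not
  ±2σ; because the two prescriptions disagree, the pipeline treats the
  printed constants as normative and offers `length_sd_multiplier=m` to
  recompute bounds as `round(mean ± m·σ)` for other families.
* The pLDDT gate is inclusive (`≥ 0.80`); values above 1 are assumed to be
  on the 0–100 scale and divided by 100.
* Novelty keeps MaxID ≤ 90% (a candidate at exactly 90% survives the
  filter and lands in the 80–90 bin). Bins are lower-exclusive /
  upper-inclusive except 40–50, which is closed below; MaxID below 40% is
  unbinned and can never be selected.
* The active-site check aligns each candidate pairwise to the anchor
  (rather than through a joint MSA) and asks whether the column aligned to
  the anchor's catalytic position carries the required residue; a gap
  fails. Pairwise anchoring keeps the check independent per candidate and
  deterministic.
* Diversity clustering is greedy and seeded by rank: candidates are
  processed in descending composite-score order; each joins the first
  cluster whose representative it matches at ≥ 70% identity, else founds a
  new cluster. The founder is by construction the highest-scoring member,
  i.e. the representative. This reproduces the semantics of
  similarity-threshold clustering with a deterministic, dependency-free
  algorithm.
* Selection takes, per bin, the top-quota representatives by score (ties
  broken by candidate id), from the 80–90 bin downward; shortfalls are
  returned as-is with a warning.

## Stand-in generator

`CodonMarkovModel` is an order-`k` n-gram model over the 64 codons plus a
dedicated end-of-sequence token. Fitting tallies exact counts for all
context lengths 0…k (the shorter contexts feed back-off); a training
sequence's terminal event is its first in-frame stop codon if present,
otherwise the end token. Sampling applies temperature scaling, then top-k
truncation, then nucleus (top-p) truncation — keep the smallest
probability-sorted prefix reaching cumulative mass `top_p`, always at least
one token — then renormalizes. Probability ties are broken by codon
lexicographic order, and all randomness flows from one integer seed, so
output is byte-identical across reruns; `top_k=1` degenerates to greedy,
seed-independent decoding. Unseen contexts back off by dropping the oldest
codon down to the unconditional distribution. Defaults (temperature 1.0,
top_k 50, top_p 0.9, 512-codon cap, ATG prompt) mirror the generation
settings the triage pipeline was designed around. The model is a testing
stand-in for a codon language model: it reproduces the sampling *interface*
and local codon statistics, not long-range structure.

## Synthetic pools: what they emulate, and what not

`simulate.make_candidate_pool` builds the desk-scale study conditions: 40
reference proteins of length 100 acting as remote homologs (each derived
from a common root by substituting 75% of non-reserved positions, ~20%
pairwise identity) that share a conserved 9-residue catalytic window around
a lysine at position 82; 125 clean candidates placed at the five bin
midpoints (85/75/65/55/45% target identity, counts 34/44/24/14/9 — each
quota plus margin); and chaff failing each earlier stage (20 non-ATG
starts, 25 length outliers, 25 low-pLDDT, 8 near-duplicates above 90%
identity, 6 catalytic-lysine mutants), 209 candidates in all. Because
measured identity under the affine model sits below the substitution
fraction, candidates are placed by propose-measure-accept: the substitution
count is steered until the *measured* parent identity (same aligner and
denominator as the pipeline) lies within ±3.5 points of the bin midpoint.
Candidates aimed at the 80–90% bin each derive from a distinct parent,
since two ≥85% derivatives of one parent are ≥70% identical to each other
and would merge at the clustering threshold.

What passing on these pools shows: the stage contracts, orderings,
boundary conventions, clustering and quota logic behave exactly as
specified on inputs with known ground truth. What it does not show:
behavior on real families with indels, domain rearrangements, biased amino
acid composition, or reference sets orders of magnitude larger — the
fixtures are substitution-only and length-uniform by design so their
ground truth is exact.

Problem sizes throughout (pool ≈ 200, references 40, length 100, 10,000
generator samples for parameter recovery) are the package's chosen
desk-scale defaults; every size is a parameter.

## Conservation analysis

Entropy is Shannon entropy in bits, `H = −Σ f_a log2 f_a`, computed per
column over the 20 residues with gaps excluded from the counts (not a 21st
symbol); an all-gap column is reported missing (NaN). Information content
is `log2(20) − H`, the conventional logo letter height; the logo matrix
holds gap-excluded residue frequencies (rows sum to 1, or 0 for all-gap
columns). Gap trimming removes columns whose gap fraction is strictly
above `max_gap_fraction` (default 0.5); the threshold is a parameter
because the appropriate value depends on the aligner and family. External
alignments are consumed as aligned FASTA; the built-in center-star builder
(center = sequence with maximal summed pairwise score, "once a gap, always
a gap" merging) exists so tests and examples need no external MSA tool and
should not be used beyond fixture scale.

## Screening statistics

The detection threshold is `mean(control) + 3·sd(control)` with the sample
(n−1) standard deviation, computed per substrate from negative-control
wells; a literal `3·sd` alternative is selectable. Detection is strict
(`area > threshold`), a conservative boundary choice; a present UV yield
always takes precedence as "quantified". Promiscuity is
`100 × accepted / panel size` where accepted = quantified or detectable.
UV-yield calibration itself (isosbestic-point quantification) is out of
scope; yields enter as given numbers.

## Known limitations

* `MaxID` is exact pairwise dynamic programming, not a search heuristic —
  fine for thousands×dozens, quadratic beyond that.
* Greedy clustering is order-dependent by design (rank-seeded); it is a
  deterministic approximation to clique-style clustering, not equal to it.
* The center-star MSA degrades on deeply diverged sets (gap columns
  accumulate across merges); use a real aligner for production MSAs.
* The codon Markov stand-in cannot capture long-range constraints; its
  samples are only length- and composition-plausible.
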