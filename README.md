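# seqtriage

Generative models that write protein-coding DNA can emit thousands of
candidate enzymes in an afternoon; only about a hundred can realistically be
synthesized and screened. `seqtriage` is the bridge between those two
numbers: a deterministic triage pipeline that filters, scores, and
stratifies generated coding sequences against a natural reference family so
that the ordered set is plausible, novel, and diverse. It was built around
the triage of generated tryptophan synthase β-subunits (TrpB) but every
stage is parameterized and family-agnostic.

## What it computes

Given candidate CDSs, a natural reference set `R`, per-candidate structure
confidences, and an anchor with an annotated catalytic residue, the pipeline
applies, in order:

1. **Start codon** — first codon must be `ATG`.
2. **Length** — protein length `L` within a family-typical window
   (default `306 ≤ L ≤ 421` residues; alternatively `mean ± m·σ` from `R`).
3. **Structure confidence** — predicted-structure pLDDT `≥ 0.80`
   (0–1 or 0–100 scales accepted).
4. **Novelty** — MaxID = max over `r ∈ R` of global-alignment percent
   identity; candidates with MaxID > 90% are excluded.
5. **Binning** — MaxID partitioned into 40–50, 50–60, …, 90–100% bins.
6. **Ranking** — the composite Alignment Score
   `S(c) = 3·mean_r NW(c, r) + 8·mean_r SW(c, r)`,
   where NW/SW are global/local affine-gap alignment scores with
   match +1, mismatch −1, gap open −0.5, gap extend −0.1.
7. **Active site** — the candidate column aligned to the anchor's catalytic
   lysine (position 82) must be `K`.
8. **Diversity** — greedy identity clustering at 70%; one representative
   per cluster.
9. **Stratified selection** — per-bin quotas 30/40/20/10/5 from the
   80–90% bin down to 40–50% (105 sequences total).

Around the pipeline the package provides: a codon-level Markov stand-in
generator with the sampling interface of a codon language model
(temperature, top-k, nucleus/top-p, ATG prompt, 512-codon cap); MSA gap
trimming, per-column Shannon entropy and sequence-logo matrices for
comparing generated and natural sets; and plate-screen detection statistics
(mean + 3·SD negative-control thresholds, substrate-promiscuity summaries).

## Worked example

`examples/02_run_triage.py` builds a seeded synthetic pool (209 candidates,
40 references of length ~100 sharing a conserved catalytic window) and runs
the full pipeline:

```
 start_codon:  209 ->  189  (90%)
      length:  189 ->  164  (87%)
       plddt:  164 ->  139  (85%)
     novelty:  139 ->  131  (94%)
 active_site:  131 ->  125  (95%)
   selection:  125 ->  105  (84%)

selected 105 candidates (quota plan 30/40/20/10/5 over the 80-90 ... 40-50 bins):
  80-90% MaxID: 30
  70-80% MaxID: 40
  60-70% MaxID: 20
  50-60% MaxID: 10
  40-50% MaxID: 5

top-ranked: cand0006  MaxID 88.0% (vs ref010), Alignment Score 176.8
```

Each line is one stage's attrition (input → passed). The final 105 are
cluster representatives, ranked by the composite score within their MaxID
bin — a selection deliberately biased toward high-identity candidates
(more likely to be active) while reserving slots for divergent ones.

The same run is available from the shell:

```bash
triage run --candidates candidates.fasta --references references.fasta \
           --plddt plddt.tsv --anchor anchor.fasta --out out/
```

which writes `selected.fasta`, `candidates.tsv` (full per-candidate triage
state), `report.tsv`, and a log. `triage score`, `triage select`, and
`triage report` expose the individual steps. The other example scripts
demonstrate the generator, the conservation profile, and the screening
statistics.

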