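"""Compare positional variability of a generated set against its natural
family: build a small MSA, trim high-gap columns, and compute per-column
Shannon entropy and the sequence-logo frequency matrix."""

import numpy as np

from seqtriage import build_small_msa, column_entropy, logo_matrix, trim_high_gap_columns
from seqtriage.simulate import make_reference_family, mutate_protein

# a close family (~70% pairwise identity) so the star alignment stays compact
anchor, refs = make_reference_family(seed=3, n_refs=12, length=100, divergence=0.2)
rng = np.random.default_rng(4)
generated = [mutate_protein(anchor, 20, rng, f"gen{i}") for i in range(12)]

aln = build_small_msa(list(refs) + generated)
trimmed, removed = trim_high_gap_columns(aln, max_gap_fraction=0.5)
print(f"alignment: {aln.n_rows} rows x {aln.n_columns} columns "
      f"({len(removed)} high-gap columns trimmed -> {trimmed.n_columns})")

profile = column_entropy(trimmed)
print(f"mean column entropy: {np.nanmean(profile.entropy):.2f} bits "
      f"(0 = perfectly conserved, log2(20) ~ 4.32 = uniform)")

mat = logo_matrix(trimmed, information_content=True)
top = mat.sum(axis=1).nlargest(3)
print("most conserved (highest-information) columns:")
for col, ic in top.items():
    residue = mat.loc[col].idxmax()
    print(f"  column {col}: {residue} ({ic:.2f} bits)")
# The reserved catalytic window around the family's K82 shows up as a block
# of near-zero-entropy, high-information columns.
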