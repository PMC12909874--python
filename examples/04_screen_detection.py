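"""Detection calls and substrate promiscuity on a plate screen.

A product is 'quantified' when UV yield at the isosbestic channel exists,
'detectable' when its MS peak area strictly exceeds the negative-control
mean + 3 sample standard deviations, else 'not detected'. Promiscuity is
the percent of the substrate panel accepted."""

import numpy as np
import pandas as pd

from seqtriage import analyze_plate

rng = np.random.default_rng(8)
substrates = ["indole", "5-F-indole", "5-NO2-indole", "7-CN-indole"]
rows = []
for sub in substrates:
    for rep in range(3):  # pUC19 negative-control wells
        rows.append(dict(enzyme="pUC19", substrate=sub, replicate=rep,
                         uv_yield=None, ms_area=float(rng.normal(10, 1)), is_control=True))
profiles = {
    "enz230": [("uv", 92.0), ("uv", 31.0), ("ms", 80.0), ("ms", 45.0)],   # accepts all
    "enzNd":  [("uv", 94.0), ("ms", 60.0), ("bg", 9.0), ("bg", 11.0)],    # accepts half
}
for enz, prof in profiles.items():
    for sub, (kind, val) in zip(substrates, prof):
        rows.append(dict(
            enzyme=enz, substrate=sub, replicate=0,
            uv_yield=val if kind == "uv" else None,
            ms_area=val if kind != "uv" else 500.0,
            is_control=False,
        ))

calls, summary = analyze_plate(pd.DataFrame(rows))
print(calls[["enzyme", "substrate", "call", "threshold"]].to_string(index=False))
print()
for _, r in summary.iterrows():
    print(f"{r['enzyme']}: {r['n_accepted']}/{r['n_substrates']} substrates "
          f"accepted ({r['percent_accepted']:.0f}%)")
# enz230 mirrors a maximally promiscuous enzyme (4/4 accepted, two only by
# MS); enzNd accepts only the easier substrates.
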