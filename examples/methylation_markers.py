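"""Hypermethylation markers and fragment-level tumour scoring.

Builds marker regions from differentially methylated CpGs, classifies
fragments with the 80% rule, curates markers against non-cancer controls
and computes per-marker tumour-fragment fractions.
"""

import pandas as pd

from ctdetect import (
    FragmentObservation,
    build_markers,
    classify_fragment,
    curate_markers,
    region_fractions,
)

cpgs = pd.DataFrame(
    [("chr1", 1000 + 40 * k, "hyper") for k in range(5)]
    + [("chr1", 50_000 + 45 * k, "hyper") for k in range(4)]
    + [("chr1", 90_000, "hypo")],
    columns=["chrom", "pos", "direction"],
)
markers = build_markers(cpgs)
print("markers:", [(m.marker_id, m.start, m.end, m.n_cpgs) for m in markers])

print("\n80% rule (tumour fragment iff >= 80% of callable CpGs modified):")
for n, mod in [(4, 4), (4, 3), (9, 8), (10, 7)]:
    obs = FragmentObservation("marker_0", "frag", n, mod)
    print(f"  {mod}/{n} modified -> tumour = {classify_fragment(obs)}")

# marker_1 shows a tumour-like fragment in a non-cancer control: excluded
controls = [[FragmentObservation("marker_1", "c0", 6, 6)], []]
curated = curate_markers(markers, controls)
print("\ncurated markers:", [m.marker_id for m in curated])

sample = [FragmentObservation("marker_0", f"t{i}", 8, 8) for i in range(2)] + [
    FragmentObservation("marker_0", f"h{i}", 8, 0) for i in range(8)
]
rf = region_fractions(sample, curated)
print(rf.round(4).to_string(index=False))
print("the empirical logit of the tumour-fragment fraction is the feature "
      "scored against the reference cohort.")
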