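"""TAPS strand disambiguation, somatic variant filtering and arm burden.

A TAPS methylation event shows C>T support on one strand only; a variant
shows it on both at matching ratios. After subtracting methylation positions
and germline calls, hard quality filters and a panel of normals leave the
final somatic set, summarised as log10 burden per chromosome arm.
"""

import pandas as pd

from ctdetect import (
    SiteStrandCounts,
    VariantRecord,
    VariantSet,
    arm_mutation_burden,
    classify_site_taps,
    filter_and_denoise,
)

for fwd, rev in [(0.25, 0.0), (0.25, 0.25), (0.6, 0.3)]:
    s = SiteStrandCounts("chr1", 12345, fwd, rev, fwd_depth=60, rev_depth=55)
    print(f"C>T ratio fwd {fwd:.2f} / rev {rev:.2f} -> {classify_site_taps(s)}")


def snv(pos, **kw):
    base = dict(kind="snv", dp=100, vaf=0.1, mq=60.0, mqbz=0.0, rpbz=0.0,
                mq0f=0.0, bqbz=0.0, consequence="missense_variant")
    base.update(kw)
    return VariantRecord("chr1", pos, "A", "T", **base)


candidates = [
    snv(1_000),                 # clean somatic call
    snv(2_000, dp=250),         # too deep (DP > 200)
    snv(3_000, vaf=0.02),       # below the 3% VAF floor
    snv(4_000),                 # shared with the panel of normals
    snv(5_000, consequence="synonymous_variant"),  # not protein-altering
    snv(6_000_000),             # clean, on the q arm
]
pon = [VariantSet("pon0", [snv(4_000)])]
out = filter_and_denoise(candidates, pon=pon)
print("\nfilter provenance:", out.provenance)

arms = pd.DataFrame([
    {"chrom": "chr1", "start": 0, "end": 5_000_000, "arm_id": "1p"},
    {"chrom": "chr1", "start": 5_000_000, "end": 10_000_000, "arm_id": "1q"},
])
print("arm burden (log10(count + 1)):", arm_mutation_burden(out, arms))
print("2 of 6 candidates survive; burdens feed the same reference-cohort "
      "scoring as the coverage signal.")
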