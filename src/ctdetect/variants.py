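"""Somatic variant filtering, TAPS strand disambiguation and arm burden.

TAPS chemistry converts methylated cytosines to thymine on the strand
carrying the CpG, so a true methylation event shows C>T support on one
orientation only; a genuine variant shows the same alternate-allele ratio on
both orientations, and a site carrying both shows support on both
orientations at clearly different ratios. That strand logic lets methylation
calls be removed from candidate somatic variants before quality filtering.

Candidate somatic calls are then cleaned by sequential subtraction (germline
variants, germline methylation positions, cfDNA methylation positions),
hard quality thresholds, panel-of-normals shared-variant removal, and
restriction to non-synonymous consequences. The per-arm burden feature is
log10(count + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "VariantSet",
    "SiteStrandCounts",
    "classify_site_taps",
    "filter_and_denoise",
    "arm_mutation_burden",
    "NONSYNONYMOUS",
]

#: consequence classes retained as non-synonymous (VEP-style terms plus
#: the common short labels)
NONSYNONYMOUS = {
    "missense_variant", "missense",
    "stop_gained", "nonsense",
    "stop_lost", "start_lost", "start_gained",
    "splice_acceptor_variant", "splice_donor_variant", "splice_site",
    "frameshift_variant", "frameshift",
    "inframe_insertion", "inframe_deletion", "inframe_indel",
    "protein_altering_variant",
}


@dataclass(frozen=True)
class VariantRecord:
    """One normalised candidate variant (VCF 1-based convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str = "snv"  # {"snv", "indel"}
    dp: float | None = None
    vaf: float | None = None
    mq: float | None = None
    mqbz: float | None = None
    rpbz: float | None = None
    mq0f: float | None = None
    bqbz: float | None = None
    consequence: str | None = None
    gene: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def is_normalized(self) -> bool:
        """Minimal parsimony check: no shared trailing base when both
        alleles are longer than one base, and a single alternate allele."""
        if "," in self.alt:
            return False
        if min(len(self.ref), len(self.alt)) > 1 and self.ref[-1] == self.alt[-1]:
            return False
        return True


@dataclass
class VariantSet:
    sample_id: str
    records: list[VariantRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return {r.key for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SiteStrandCounts:
    """Orientation-resolved C>T evidence at one genomic position."""

    chrom: str
    pos: int
    fwd_ct_ratio: float
    rev_ct_ratio: float
    fwd_depth: int = 0
    rev_depth: int = 0


def classify_site_taps(
    site: SiteStrandCounts, tol: float = 0.1, min_depth: int = 10
) -> str:
    """Disambiguate TAPS methylation from variants at one site.

    Returns one of ``methylation`` (support on the expected strand only),
    ``variant`` (matching ratios on both strands), ``both`` (support on both
    strands at ratios differing by more than ``tol``), ``none`` (no support),
    or ``low_confidence`` when either orientation's depth is below
    ``min_depth``.
    """
    if site.fwd_depth < min_depth or site.rev_depth < min_depth:
        return "low_confidence"
    f, r = site.fwd_ct_ratio, site.rev_ct_ratio
    if not (0 <= f <= 1 and 0 <= r <= 1):
        raise ValueError("strand ratios must lie in [0, 1]")
    f_pos, r_pos = f > tol / 2, r > tol / 2
    if f_pos and not r_pos:
        return "methylation"
    if not f_pos and not r_pos:
        return "none"
    if abs(f - r) <= tol:
        return "variant"
    return "both"


def _passes_thresholds(r: VariantRecord) -> bool:
    """Exclusion thresholds (strict inequalities, exactly as printed):

    SNV: DP > 200 or DP < 50, MQ < 60, MQBZ < -9, RPBZ outside [-5, 5],
    MQ0F > 0, BQBZ < -4, VAF outside [0.03, 0.3].
    Indel: DP > 200 or DP < 50, VAF outside [0.03, 0.3].
    Missing annotations do not trigger an exclusion.
    """

    def bad(v, lo=None, hi=None):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return False
        return (lo is not None and v < lo) or (hi is not None and v > hi)

    if bad(r.dp, lo=50, hi=200):
        return False
    if bad(r.vaf, lo=0.03, hi=0.3):
        return False
    if r.kind == "snv":
        if bad(r.mq, lo=60):
            return False
        if bad(r.mqbz, lo=-9):
            return False
        if bad(r.rpbz, lo=-5, hi=5):
            return False
        if r.mq0f is not None and not (isinstance(r.mq0f, float) and math.isnan(r.mq0f)) and r.mq0f > 0:
            return False
        if bad(r.bqbz, lo=-4):
            return False
    return True


def _is_nonsynonymous(r: VariantRecord) -> bool:
    if not r.consequence:
        return False
    tokens = {t.strip().lower() for t in r.consequence.replace("&", ",").split(",")}
    return bool(tokens & NONSYNONYMOUS)


def filter_and_denoise(
    candidates: Sequence[VariantRecord],
    germline: VariantSet | None = None,
    germline_meth: Iterable[tuple[str, int]] = (),
    cfdna_meth: Iterable[tuple[str, int]] = (),
    pon: Sequence[VariantSet] = (),
    sample_id: str = "sample",
    require_nonsynonymous: bool = True,
) -> VariantSet:
    """Clean candidate somatic calls into the final variant set.

    Steps, applied in order, with removal counts recorded in provenance:
    germline exact-key subtraction; germline methylation-position
    subtraction; cfDNA methylation-position subtraction; per-kind quality
    thresholds; removal of any record whose (chrom, pos, ref, alt) appears
    in ANY panel-of-normals sample; retention of non-synonymous
    consequences only.
    """
    for r in candidates:
        if not r.is_normalized():
            raise ValueError(
                f"unnormalized variant representation at {r.chrom}:{r.pos} "
                f"{r.ref}>{r.alt}; decompose and left-align first"
            )
    recs = sorted(candidates, key=lambda r: r.key)
    prov: dict[str, int] = {"input": len(recs)}

    if germline is not None:
        gl = germline.keys
        recs = [r for r in recs if r.key not in gl]
    prov["after_germline"] = len(recs)

    gl_meth = set(germline_meth)
    recs = [r for r in recs if (r.chrom, r.pos) not in gl_meth]
    prov["after_germline_methylation"] = len(recs)

    cf_meth = set(cfdna_meth)
    recs = [r for r in recs if (r.chrom, r.pos) not in cf_meth]
    prov["after_cfdna_methylation"] = len(recs)

    recs = [r for r in recs if _passes_thresholds(r)]
    prov["after_quality_filters"] = len(recs)

    pon_keys: set = set()
    for p in pon:
        pon_keys |= p.keys
    recs = [r for r in recs if r.key not in pon_keys]
    prov["after_panel_of_normals"] = len(recs)

    if require_nonsynonymous:
        recs = [r for r in recs if _is_nonsynonymous(r)]
    prov["after_consequence_filter"] = len(recs)

    return VariantSet(sample_id=sample_id, records=recs, provenance=prov)


def arm_mutation_burden(
    variants: VariantSet, arms: pd.DataFrame
) -> dict[str, float]:
    """log10(count + 1) retained variants per chromosome arm.

    ``arms`` has columns (chrom, start, end, arm_id) in 0-based half-open
    coordinates; a 1-based variant position p falls in an arm when
    start <= p - 1 < end. Arms with no variants score 0 (= log10(1)).
    """
    counts = {a: 0 for a in arms["arm_id"]}
    for r in variants.records:
        hit = arms[
            (arms["chrom"] == r.chrom)
            & (arms["start"] <= r.pos - 1)
            & (r.pos - 1 < arms["end"])
        ]
        for a in hit["arm_id"]:
            counts[a] += 1
    return {a: math.log10(c + 1) for a, c in counts.items()}
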