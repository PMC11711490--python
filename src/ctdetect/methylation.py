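"""Hypermethylation marker construction and fragment-level tumour scoring.

Markers are built from lists of differentially methylated CpGs: each
hypermethylated CpG is extended 100 bp in both directions, overlapping
intervals are merged, and merged regions with fewer than three CpGs are
discarded (hypomethylated regions are discarded outright). Baseline
methylation at such markers is near zero in non-cancer plasma, so any
well-converted fragment there is strong evidence of tumour origin.

A cfDNA fragment covering >= 3 callable CpGs in a marker is classified as
tumour-originating when at least 80% of its callable CpGs carry the TAPS
modification; equivalently, up to floor(n/5) of n callable CpGs may be
unconverted. Markers in which any non-cancer control sample contributes a
tumour-classified fragment are excluded. The per-marker feature is the
empirical logit of the tumour-fragment fraction,
log((n_tumour + 0.5) / (n_fragments - n_tumour + 0.5)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MarkerRegion",
    "FragmentObservation",
    "build_markers",
    "classify_fragment",
    "curate_markers",
    "region_fractions",
    "empirical_logit",
]

EXTEND_BP = 100
MIN_CPGS = 3
TUMOUR_THRESHOLD = 0.8


@dataclass(frozen=True)
class MarkerRegion:
    """A merged hypermethylated region (0-based half-open coordinates)."""

    marker_id: str
    chrom: str
    start: int
    end: int
    n_cpgs: int
    cancer_type: str | None = None
    retained: bool = True


@dataclass(frozen=True)
class FragmentObservation:
    """CpG calls of one sequenced fragment within one marker."""

    marker_id: str
    fragment_id: str
    n_callable: int
    n_modified: int

    def __post_init__(self):
        if not (0 <= self.n_modified <= self.n_callable):
            raise ValueError("need 0 <= n_modified <= n_callable")


def build_markers(
    cpgs: pd.DataFrame,
    extend: int = EXTEND_BP,
    min_cpgs: int = MIN_CPGS,
) -> list[MarkerRegion]:
    """Merge extended hypermethylated CpGs into marker regions.

    ``cpgs`` has columns (chrom, pos, direction[, study]); direction is
    ``hyper`` or ``hypo``. Each hyper CpG contributes the half-open interval
    [pos - extend, pos + extend); overlapping intervals are merged and the
    merged region keeps the count of contained hyper CpGs. Regions with
    fewer than ``min_cpgs`` CpGs are discarded, as are all hypomethylated
    regions.
    """
    if cpgs.empty:
        return []
    hyper = cpgs[cpgs["direction"].str.lower() == "hyper"]
    markers: list[MarkerRegion] = []
    idx = 0
    for chrom, grp in hyper.groupby("chrom", sort=True):
        positions = sorted(grp["pos"].astype(int))
        study = grp["study"].iloc[0] if "study" in grp.columns else None
        cur_start = cur_end = None
        cur_pos: list[int] = []
        regions = []
        for p in positions:
            s, e = p - extend, p + extend
            if cur_start is None:
                cur_start, cur_end, cur_pos = s, e, [p]
            elif s < cur_end:  # overlap in half-open coordinates
                cur_end = max(cur_end, e)
                cur_pos.append(p)
            else:
                regions.append((cur_start, cur_end, cur_pos))
                cur_start, cur_end, cur_pos = s, e, [p]
        if cur_start is not None:
            regions.append((cur_start, cur_end, cur_pos))
        for s, e, ps in regions:
            if len(ps) >= min_cpgs:
                markers.append(
                    MarkerRegion(
                        marker_id=f"marker_{idx}",
                        chrom=chrom,
                        start=max(s, 0),
                        end=e,
                        n_cpgs=len(ps),
                        cancer_type=study,
                    )
                )
                idx += 1
    return markers


def classify_fragment(
    obs: FragmentObservation, threshold: float = TUMOUR_THRESHOLD
) -> bool:
    """Tumour-originating iff n_modified / n_callable >= threshold.

    At the default 80% threshold this reproduces the allowance rule: a
    fragment with n callable CpGs may carry at most floor(n/5) unconverted
    CpGs. Fragments covering fewer than 3 callable CpGs are not classifiable
    and must be filtered out beforehand.
    """
    if obs.n_callable < 3:
        raise ValueError(
            f"fragment {obs.fragment_id}: {obs.n_callable} callable CpGs; "
            "classification requires >= 3"
        )
    return obs.n_modified / obs.n_callable >= threshold


def curate_markers(
    markers: Sequence[MarkerRegion],
    control_fragments: Sequence[Sequence[FragmentObservation]],
    threshold: float = TUMOUR_THRESHOLD,
) -> list[MarkerRegion]:
    """Drop markers with any tumour-classified fragment in any control.

    ``control_fragments`` holds one observation list per control sample;
    observations with < 3 callable CpGs are ignored (unclassifiable).
    Adding controls can only shrink the retained set.
    """
    flagged: set[str] = set()
    for sample in control_fragments:
        for obs in sample:
            if obs.n_callable >= 3 and classify_fragment(obs, threshold):
                flagged.add(obs.marker_id)
    return [m for m in markers if m.marker_id not in flagged]


def empirical_logit(n_tumour: int, n_fragments: int) -> float:
    """log((x + 0.5) / (n - x + 0.5)); finite at 0 and n."""
    return math.log((n_tumour + 0.5) / (n_fragments - n_tumour + 0.5))


def region_fractions(
    sample_fragments: Iterable[FragmentObservation],
    markers: Sequence[MarkerRegion],
    threshold: float = TUMOUR_THRESHOLD,
) -> pd.DataFrame:
    """Per-marker tumour-fragment fraction and empirical logit.

    Fragments outside the curated marker set or with < 3 callable CpGs are
    ignored. Markers with zero classifiable fragments are dropped from the
    output with a warning. Returns columns (marker_id, n_fragments,
    n_tumour, fraction, elogit).
    """
    marker_ids = [m.marker_id for m in markers]
    counts = {m: [0, 0] for m in marker_ids}  # [n_fragments, n_tumour]
    for obs in sample_fragments:
        if obs.marker_id not in counts or obs.n_callable < 3:
            continue
        c = counts[obs.marker_id]
        c[0] += 1
        if classify_fragment(obs, threshold):
            c[1] += 1
    rows = []
    empty = []
    for m in marker_ids:
        nf, nt = counts[m]
        if nf == 0:
            empty.append(m)
            continue
        rows.append(
            {
                "marker_id": m,
                "n_fragments": nf,
                "n_tumour": nt,
                "fraction": nt / nf,
                "elogit": empirical_logit(nt, nf),
            }
        )
    if empty:
        warnings.warn(f"{len(empty)} marker(s) with no fragments dropped from scoring")
    return pd.DataFrame(
        rows, columns=["marker_id", "n_fragments", "n_tumour", "fraction", "elogit"]
    )
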