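"""End-to-end drivers chaining the stage modules on on-disk inputs.

Each modality driver consumes the files the fixture generator (or a real
pre-processing run) produces, pushes the sample and its reference cohort
through the identical processing path, and returns the per-feature score
table plus the integrated modality score. ``analyze_sample`` runs all three
and combines them into the sample-level cancer call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .coverage import (
    CoverageTrack,
    aggregate_arms,
    build_noise_basis,
    counts_to_bins,
    denoise_and_smooth,
    normalize_and_debias,
)
from .methylation import FragmentObservation, curate_markers, region_fractions
from .multimodal import MultimodalResult, combine_modalities
from .refstats import ModalityScore, modality_score, score_features
from .variants import arm_mutation_burden, filter_and_denoise

__all__ = [
    "ModalityRun",
    "cna_modality",
    "snv_modality",
    "meth_modality",
    "analyze_sample",
]


@dataclass
class ModalityRun:
    score: ModalityScore
    feature_scores: pd.DataFrame
    sample_features: dict[str, float]
    reference_features: list[dict[str, float]]
    extras: dict = field(default_factory=dict)


def _arm_table(arms: pd.DataFrame) -> pd.DataFrame:
    if "arm_id" not in arms.columns and "name" in arms.columns:
        arms = arms.rename(columns={"name": "arm_id"})
    return arms


def _coverage_arms(
    counts_path,
    gc_track,
    map_track,
    blacklist,
    arms,
    basis,
    gc_range,
    min_mappability,
    sg_order,
    sg_window_bins,
    min_arm_bins,
    use_gam,
) -> dict[str, float]:
    bins = counts_to_bins(
        cio.read_counts(counts_path),
        gc_track=gc_track,
        map_track=map_track,
        blacklist=blacklist,
        gc_range=gc_range,
        min_mappability=min_mappability,
    )
    track = normalize_and_debias(bins, use_gam=use_gam)
    track = denoise_and_smooth(track, basis, sg_order=sg_order, sg_window_bins=sg_window_bins)
    agg = aggregate_arms(track, arms, min_bins=min_arm_bins)
    return dict(zip(agg["arm_id"], agg["value"])), track


def cna_modality(
    sample_counts,
    reference_counts: list,
    panel_counts: list,
    arms: pd.DataFrame,
    gc_track: pd.DataFrame | None = None,
    map_track: pd.DataFrame | None = None,
    blacklist: pd.DataFrame | None = None,
    config: cio.RunConfig | None = None,
    use_gam: bool = True,
) -> ModalityRun:
    """Coverage pipeline: debias, panel-SVD denoise, smooth, arm-score.

    The noise panel, the reference cohort and the sample all travel the
    identical pre-processing path; the panel defines the SVD basis used to
    denoise everyone else.
    """
    cfg = config or cio.RunConfig()
    arms = _arm_table(arms)
    common = dict(
        gc_track=gc_track, map_track=map_track, blacklist=blacklist,
        gc_range=cfg.gc_range, min_mappability=cfg.min_mappability,
    )
    panel_tracks = [
        normalize_and_debias(counts_to_bins(cio.read_counts(p), **common), use_gam=use_gam)
        for p in panel_counts
    ]
    basis = build_noise_basis(panel_tracks)
    stage = dict(
        gc_track=gc_track, map_track=map_track, blacklist=blacklist,
        arms=arms, basis=basis, gc_range=cfg.gc_range,
        min_mappability=cfg.min_mappability, sg_order=cfg.sg_order,
        sg_window_bins=cfg.sg_window_bins, min_arm_bins=cfg.min_arm_bins,
        use_gam=use_gam,
    )
    ref_features = []
    for p in reference_counts:
        feats, _ = _coverage_arms(p, **stage)
        ref_features.append(feats)
    sample_features, sample_track = _coverage_arms(sample_counts, **stage)
    shared = set(sample_features)
    for f in ref_features:
        shared &= set(f)
    sample_features = {k: sample_features[k] for k in sorted(shared)}
    scores = score_features(
        sample_features, [{k: f[k] for k in shared} for f in ref_features],
        alpha=cfg.alpha, sided=cfg.sided_coverage,
    )
    return ModalityRun(
        score=modality_score(scores, alpha=cfg.alpha, modality="cna"),
        feature_scores=scores,
        sample_features=sample_features,
        reference_features=ref_features,
        extras={"track": sample_track, "basis": basis},
    )


def _burden_features(vcf_path, arms, germline, germline_meth, cfdna_meth, pon):
    vs = cio.read_vcf(vcf_path)
    clean = filter_and_denoise(
        vs.records, germline=germline, germline_meth=germline_meth,
        cfdna_meth=cfdna_meth, pon=pon, sample_id=vs.sample_id,
    )
    return arm_mutation_burden(clean, arms), clean


def snv_modality(
    sample_vcf,
    reference_vcfs: list,
    arms: pd.DataFrame,
    germline_vcf=None,
    pon_vcfs: list = (),
    cf_meth=None,
    gl_meth=None,
    config: cio.RunConfig | None = None,
) -> ModalityRun:
    """Somatic-burden pipeline: filter/denoise calls, arm burden, score."""
    cfg = config or cio.RunConfig()
    arms = _arm_table(arms)
    germline = cio.read_vcf(germline_vcf) if germline_vcf else None
    pon = [cio.read_vcf(p) for p in pon_vcfs]
    gl_meth_pos = cio.read_positions(gl_meth) if gl_meth else ()
    cf_meth_pos = cio.read_positions(cf_meth) if cf_meth else ()
    ref_features = []
    for p in reference_vcfs:
        f, _ = _burden_features(p, arms, germline, gl_meth_pos, cf_meth_pos, pon)
        ref_features.append(f)
    sample_features, clean = _burden_features(
        sample_vcf, arms, germline, gl_meth_pos, cf_meth_pos, pon
    )
    scores = score_features(
        sample_features, ref_features, alpha=cfg.alpha, sided=cfg.sided_burden
    )
    return ModalityRun(
        score=modality_score(scores, alpha=cfg.alpha, modality="snv"),
        feature_scores=scores,
        sample_features=sample_features,
        reference_features=ref_features,
        extras={"variants": clean},
    )


def _frag_obs(df: pd.DataFrame) -> list[FragmentObservation]:
    return [
        FragmentObservation(r.marker_id, str(r.fragment_id), int(r.n_callable),
                            int(r.n_modified))
        for r in df.itertuples()
    ]


def meth_modality(
    sample_fragments,
    reference_fragments: list,
    control_fragments: list,
    markers,
    config: cio.RunConfig | None = None,
) -> ModalityRun:
    """Fragment-methylation pipeline: curate markers, fraction, elogit, score.

    ``markers`` is a marker BED path or a list of MarkerRegion. Markers
    flagged by any control sample are excluded before scoring; the feature
    is the empirical logit of the per-marker tumour-fragment fraction.
    """
    from .methylation import MarkerRegion

    cfg = config or cio.RunConfig()
    if not isinstance(markers, (list, tuple)):
        mdf = cio.read_regions(markers)
        markers = [
            MarkerRegion(str(r.name), r.chrom, int(r.start), int(r.end), n_cpgs=3)
            for r in mdf.itertuples()
        ]
    controls = [_frag_obs(cio.read_fragments(p)) for p in control_fragments]
    curated = curate_markers(markers, controls, threshold=cfg.fragment_threshold)

    def elogits(path):
        rf = region_fractions(
            _frag_obs(cio.read_fragments(path)), curated, threshold=cfg.fragment_threshold
        )
        return dict(zip(rf["marker_id"], rf["elogit"]))

    ref_features = [elogits(p) for p in reference_fragments]
    sample_features = elogits(sample_fragments)
    shared = set(sample_features)
    for f in ref_features:
        shared &= set(f)
    sample_features = {k: sample_features[k] for k in sorted(shared)}
    ref_features = [{k: f[k] for k in shared} for f in ref_features]
    scores = score_features(
        sample_features, ref_features, alpha=cfg.alpha, sided=cfg.sided_methylation
    )
    return ModalityRun(
        score=modality_score(scores, alpha=cfg.alpha, modality="meth"),
        feature_scores=scores,
        sample_features=sample_features,
        reference_features=ref_features,
        extras={"curated_markers": curated},
    )


def analyze_sample(
    fixture: dict,
    config: cio.RunConfig | None = None,
    use_gam: bool = True,
    modalities: tuple[str, ...] = ("cna", "snv", "meth"),
) -> tuple[MultimodalResult, dict[str, ModalityRun]]:
    """Run the full multimodal pipeline on a fixture-layout dataset.

    ``fixture`` is the dict returned by ``fixtures.generate_fixture`` (or an
    equivalent mapping of paths). Returns the sample-level call and the
    per-modality runs.
    """
    cfg = config or cio.RunConfig()
    arms = _arm_table(fixture["arms"])
    gc_track = cio.read_counts(fixture["gc"]).rename(columns={"count": "value"})
    map_track = cio.read_counts(fixture["mappability"]).rename(columns={"count": "value"})
    blacklist = cio.read_regions(fixture["blacklist"])
    runs: dict[str, ModalityRun] = {}
    if "cna" in modalities:
        runs["cna"] = cna_modality(
            fixture["sample_counts"], fixture["reference_counts"],
            fixture["panel_counts"], arms, gc_track=gc_track,
            map_track=map_track, blacklist=blacklist, config=cfg, use_gam=use_gam,
        )
    if "snv" in modalities:
        runs["snv"] = snv_modality(
            fixture["candidates_vcf"], fixture["reference_vcfs"], arms,
            germline_vcf=fixture.get("germline_vcf"),
            pon_vcfs=fixture.get("pon_vcfs", ()),
            cf_meth=fixture.get("cf_meth"), gl_meth=fixture.get("gl_meth"),
            config=cfg,
        )
    if "meth" in modalities:
        runs["meth"] = meth_modality(
            fixture["sample_fragments"], fixture["reference_fragments"],
            fixture["control_fragments"], fixture["markers_bed"], config=cfg,
        )
    weights = cfg.weights[: len(runs)]
    result = combine_modalities(
        [r.score for r in runs.values()], weights=weights, method=cfg.method,
        alpha=cfg.alpha,
    )
    return result, runs
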