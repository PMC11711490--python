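"""Seeded synthetic dataset generator for end-to-end runs.

Emits a miniature study on disk in exactly the formats the pipeline reads:
a two-chromosome genome binned at 1 kb with GC and mappability tracks, a
blacklist, per-arm definitions; binned coverage for a reference cohort, a
structured-noise panel and one plasma sample carrying arm-level copy-number
events at a configurable tumour fraction; candidate/germline/panel VCFs with
planted somatic calls and artefacts; and fragment-level methylation tables
with planted tumour-fragment fractions.

Coverage counts are Poisson draws around a per-bin expectation combining a
smooth GC bias, a shared low-rank noise structure (what the SVD panel is
meant to remove), and the copy-number factor (2(1-rho) + rho*c)/2 on
aberrant arms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .methylation import build_markers

__all__ = ["FixtureConfig", "generate_fixture"]


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic fixture.

    Defaults follow a typical diagnostic-cohort layout: 9 negative
    reference samples, a 21-sample noise panel, and one plasma sample with
    arm-level events at 5% tumour fraction.
    """

    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 12_000_000, "chr2": 12_000_000}
    )
    bin_size: int = 1000
    depth: float = 100.0  # mean qualifying alignments per bin
    n_reference: int = 9
    n_panel: int = 21
    noise_rank: int = 3
    noise_scale: float = 0.03  # SD of shared low-rank loadings (log2 units)
    gc_bias_amplitude: float = 0.3  # peak-to-trough log2 GC bias
    tumour_rho: float = 0.05
    # arm_id -> average tumour ploidy c (2 = neutral, 4 = gain, 0 = loss)
    aberrations: dict = field(default_factory=lambda: {"chr1p": 4.0, "chr2q": 0.0})
    # somatic-variant fixture
    burden_arm: str = "chr1q"  # arm with elevated mutation burden
    background_muts_per_arm: float = 5.0
    elevated_muts: int = 60
    n_artifacts: int = 50
    n_pon_samples: int = 3
    n_pon_shared: int = 10
    # methylation fixture
    n_marker_clusters: int = 50
    planted_markers: int = 10
    planted_fraction: float = 0.2
    fragments_per_marker: float = 30.0
    background_mod_rate: float = 0.02
    control_flagged_markers: int = 2

    def arms(self) -> pd.DataFrame:
        rows = []
        for chrom, size in self.chrom_sizes.items():
            mid = (size // (2 * self.bin_size)) * self.bin_size
            rows.append({"chrom": chrom, "start": 0, "end": mid, "arm_id": f"{chrom}p"})
            rows.append({"chrom": chrom, "start": mid, "end": size, "arm_id": f"{chrom}q"})
        return pd.DataFrame(rows)


def _smooth_series(rng: np.random.Generator, n: int, knots: int = 40) -> np.ndarray:
    """Smooth random curve via interpolated coarse noise (unit SD-ish)."""
    k = max(4, knots)
    coarse = rng.standard_normal(k)
    x = np.linspace(0, 1, n)
    xk = np.linspace(0, 1, k)
    return np.interp(x, xk, coarse)


def _write_bed(df: pd.DataFrame, path: Path, cols) -> None:
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def generate_fixture(
    out_dir: str | Path,
    config: FixtureConfig | None = None,
    seed: int = 0,
) -> dict[str, object]:
    """Write the synthetic dataset under ``out_dir`` and return its paths.

    Deterministic for a fixed (config, seed). Returns a dict with the
    config, the arm table and the per-component file paths.
    """
    cfg = config or FixtureConfig()
    if cfg.tumour_rho <= 0 or cfg.tumour_rho > 1:
        raise ValueError("tumour_rho must lie in (0, 1]")
    arms = cfg.arms()
    bad_arms = set(cfg.aberrations) | {cfg.burden_arm}
    if not bad_arms <= set(arms["arm_id"]):
        raise ValueError(f"unknown arm in config: {bad_arms - set(arms['arm_id'])}")
    out = Path(out_dir)
    (out / "counts").mkdir(parents=True, exist_ok=True)
    (out / "variants").mkdir(exist_ok=True)
    (out / "fragments").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    # ---- genome, tracks, masks -------------------------------------------
    bins = []
    for chrom, size in cfg.chrom_sizes.items():
        starts = np.arange(0, size, cfg.bin_size)
        bins.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": np.minimum(starts + cfg.bin_size, size)}
            )
        )
    bins = pd.concat(bins, ignore_index=True)
    n_bins = len(bins)

    gc = 0.5 + 0.08 * _smooth_series(rng, n_bins, knots=60)
    gc = np.clip(gc, 0.25, 0.75)
    mappability = np.ones(n_bins)
    low_map = rng.choice(n_bins, size=n_bins // 100, replace=False)
    mappability[low_map] = rng.uniform(0.0, 0.45, len(low_map))

    gc_df = bins.assign(value=np.round(gc, 4))
    map_df = bins.assign(value=np.round(mappability, 3))
    gc_path, map_path = out / "gc.bedgraph", out / "mappability.bedgraph"
    _write_bed(gc_df, gc_path, ["chrom", "start", "end", "value"])
    _write_bed(map_df, map_path, ["chrom", "start", "end", "value"])

    bl_rows = []
    for chrom, size in cfg.chrom_sizes.items():
        for _ in range(3):
            s = int(rng.integers(0, size - 50_000))
            bl_rows.append({"chrom": chrom, "start": s, "end": s + int(rng.integers(5_000, 50_000))})
    blacklist = pd.DataFrame(bl_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    bl_path = out / "blacklist.bed"
    _write_bed(blacklist, bl_path, ["chrom", "start", "end"])

    arms_path = out / "arms.bed"
    _write_bed(arms, arms_path, ["chrom", "start", "end", "arm_id"])
    genome_path = out / "genome.tsv"
    pd.DataFrame(
        {"chrom": list(cfg.chrom_sizes), "size": list(cfg.chrom_sizes.values())}
    ).to_csv(genome_path, sep="\t", header=False, index=False)

    # ---- coverage counts --------------------------------------------------
    gc_bias = cfg.gc_bias_amplitude * np.sin(2 * np.pi * (gc - 0.3) / 0.4)
    noise_basis = np.column_stack(
        [_smooth_series(rng, n_bins, knots=25 + 10 * j) for j in range(cfg.noise_rank)]
    )
    noise_basis /= np.linalg.norm(noise_basis, axis=0, keepdims=True)

    cn_factor = np.ones(n_bins)
    for arm_id, c in cfg.aberrations.items():
        arm = arms[arms["arm_id"] == arm_id].iloc[0]
        sel = (
            (bins["chrom"] == arm["chrom"]).to_numpy()
            & (bins["start"].to_numpy() >= arm["start"])
            & (bins["start"].to_numpy() < arm["end"])
        )
        cn_factor[sel] = (2.0 * (1 - cfg.tumour_rho) + cfg.tumour_rho * c) / 2.0

    def write_counts(name: str, tumour: bool) -> Path:
        loadings = rng.normal(0.0, cfg.noise_scale, cfg.noise_rank) * np.sqrt(n_bins)
        log2_noise = noise_basis @ loadings
        expect = cfg.depth * 2.0 ** (gc_bias + log2_noise)
        if tumour:
            expect = expect * cn_factor
        counts = rng.poisson(expect)
        path = out / "counts" / f"{name}.tsv"
        bins.assign(count=counts).to_csv(path, sep="\t", header=False, index=False)
        return path

    reference_counts = [write_counts(f"reference_{i}", False) for i in range(cfg.n_reference)]
    panel_counts = [write_counts(f"panel_{i}", False) for i in range(cfg.n_panel)]
    sample_counts = write_counts("sample", True)

    # ---- variants ---------------------------------------------------------
    vcf_header = (
        "##fileformat=VCFv4.2\n"
        + "".join(f"##contig=<ID={c},length={s}>\n" for c, s in cfg.chrom_sizes.items())
        + '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        + '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">\n'
        + '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n'
        + '##INFO=<ID=MQBZ,Number=1,Type=Float,Description="MQ bias Z">\n'
        + '##INFO=<ID=RPBZ,Number=1,Type=Float,Description="Read position bias Z">\n'
        + '##INFO=<ID=MQ0F,Number=1,Type=Float,Description="Fraction MQ0">\n'
        + '##INFO=<ID=BQBZ,Number=1,Type=Float,Description="Base quality bias Z">\n'
        + '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n'
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    bases = np.array(list("ACGT"))

    def vcf_line(chrom, pos, ref, alt, dp=100, vaf=0.1, mq=60.0, mqbz=0.0,
                 rpbz=0.0, mq0f=0.0, bqbz=0.0, csq="missense_variant"):
        info = (
            f"DP={dp};VAF={vaf:.4f};MQ={mq:.1f};MQBZ={mqbz:.2f};RPBZ={rpbz:.2f};"
            f"MQ0F={mq0f:.3f};BQBZ={bqbz:.2f};CSQ={csq}"
        )
        return f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t100\tPASS\t{info}\n"

    def random_snv(arm_row):
        pos = int(rng.integers(arm_row["start"] + 1, arm_row["end"]))
        ref = str(rng.choice(bases))
        alt = str(rng.choice(bases[bases != ref]))
        return arm_row["chrom"], pos + 1, ref, alt

    used: set = set()
    lines = []
    for _, arm_row in arms.iterrows():
        n_mut = (
            cfg.elevated_muts
            if arm_row["arm_id"] == cfg.burden_arm
            else rng.poisson(cfg.background_muts_per_arm)
        )
        for _ in range(n_mut):
            chrom, pos, ref, alt = random_snv(arm_row)
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            lines.append(
                vcf_line(chrom, pos, ref, alt, dp=int(rng.integers(60, 190)),
                         vaf=float(rng.uniform(0.04, 0.28)))
            )
    # artefacts, one broken rule each (cycled)
    breakers = [
        dict(dp=250), dict(dp=30), dict(vaf=0.02), dict(vaf=0.5), dict(mq=40.0),
        dict(mqbz=-12.0), dict(rpbz=8.0), dict(mq0f=0.1), dict(bqbz=-6.0),
        dict(csq="synonymous_variant"),
    ]
    arm_list = arms.to_dict("records")
    for i in range(cfg.n_artifacts):
        arm_row = arm_list[int(rng.integers(len(arm_list)))]
        chrom, pos, ref, alt = random_snv(pd.Series(arm_row))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        lines.append(vcf_line(chrom, pos, ref, alt, **breakers[i % len(breakers)]))
    # panel-of-normals shared variants: present in candidates AND in pon files
    pon_lines: list[list[str]] = [[] for _ in range(cfg.n_pon_samples)]
    for i in range(cfg.n_pon_shared):
        arm_row = arm_list[int(rng.integers(len(arm_list)))]
        chrom, pos, ref, alt = random_snv(pd.Series(arm_row))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        line = vcf_line(chrom, pos, ref, alt)
        lines.append(line)
        pon_lines[i % cfg.n_pon_samples].append(line)

    candidates_path = out / "variants" / "candidates.vcf"
    candidates_path.write_text(vcf_header + "".join(sorted(lines)))
    pon_paths = []
    for i, pl in enumerate(pon_lines):
        p = out / "variants" / f"pon_{i}.vcf"
        p.write_text(vcf_header + "".join(sorted(pl)))
        pon_paths.append(p)
    # germline + methylation position lists (subtracted before filtering)
    gl_lines = []
    for _ in range(20):
        arm_row = arm_list[int(rng.integers(len(arm_list)))]
        chrom, pos, ref, alt = random_snv(pd.Series(arm_row))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        gl_lines.append(vcf_line(chrom, pos, ref, alt))
    germline_path = out / "variants" / "germline.vcf"
    germline_path.write_text(vcf_header + "".join(sorted(gl_lines)))
    meth_positions = []
    for _ in range(20):
        arm_row = arm_list[int(rng.integers(len(arm_list)))]
        chrom, pos, _, _ = random_snv(pd.Series(arm_row))
        meth_positions.append((chrom, pos))
    for name in ("cf_meth.tsv", "gl_meth.tsv"):
        pd.DataFrame(meth_positions[:10] if name.startswith("cf") else meth_positions[10:],
                     columns=["chrom", "pos"]).to_csv(
            out / "variants" / name, sep="\t", header=False, index=False
        )

    # reference-cohort variant burdens: one VCF per reference sample
    reference_vcfs = []
    for i in range(cfg.n_reference):
        ref_lines = []
        for _, arm_row in arms.iterrows():
            for _ in range(rng.poisson(cfg.background_muts_per_arm)):
                chrom, pos, ref, alt = random_snv(arm_row)
                ref_lines.append(vcf_line(chrom, pos, ref, alt))
        p = out / "variants" / f"reference_{i}.vcf"
        p.write_text(vcf_header + "".join(sorted(ref_lines)))
        reference_vcfs.append(p)

    # ---- methylation markers + fragment tables ---------------------------
    chroms = list(cfg.chrom_sizes)
    cpg_rows = []
    for _ in range(cfg.n_marker_clusters):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1_000, cfg.chrom_sizes[chrom] - 1_000))
        for k in range(int(rng.integers(3, 6))):
            cpg_rows.append({"chrom": chrom, "pos": start + 40 * k, "direction": "hyper"})
    cpgs = pd.DataFrame(cpg_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    cpgs_path = out / "cpgs.tsv"
    cpgs.to_csv(cpgs_path, sep="\t", index=False)
    markers = build_markers(cpgs)
    markers_path = out / "markers.bed"
    pd.DataFrame(
        [{"chrom": m.chrom, "start": m.start, "end": m.end, "marker_id": m.marker_id}
         for m in markers]
    ).to_csv(markers_path, sep="\t", header=False, index=False)
    marker_ids = [m.marker_id for m in markers]
    planted = list(rng.choice(marker_ids, size=min(cfg.planted_markers, len(marker_ids)),
                              replace=False))
    flagged = list(rng.choice([m for m in marker_ids if m not in planted],
                              size=cfg.control_flagged_markers, replace=False))

    def write_fragments(name: str, tumour_fraction_markers: dict[str, float],
                        force_tumour_in: set[str] = frozenset()) -> Path:
        rows = []
        for mid in marker_ids:
            nfrag = max(int(rng.poisson(cfg.fragments_per_marker)), 5)
            tf = tumour_fraction_markers.get(mid, 0.0)
            for j in range(nfrag):
                n_call = int(rng.integers(5, 13))
                if rng.uniform() < tf or (mid in force_tumour_in and j == 0):
                    n_mod = n_call - int(rng.integers(0, n_call // 5 + 1))
                else:
                    n_mod = int(rng.binomial(n_call, cfg.background_mod_rate))
                rows.append({"marker_id": mid, "fragment_id": f"{name}_{mid}_{j}",
                             "n_callable": n_call, "n_modified": n_mod})
        path = out / "fragments" / f"{name}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    control_fragments = [
        write_fragments(f"control_{i}", {}, force_tumour_in=set(flagged) if i == 0 else frozenset())
        for i in range(cfg.n_panel)
    ]
    reference_fragments = [
        write_fragments(f"reference_{i}", {}) for i in range(cfg.n_reference)
    ]
    sample_fragments = write_fragments(
        "sample", {m: cfg.planted_fraction for m in planted}
    )

    return {
        "config": cfg,
        "out_dir": out,
        "arms": arms,
        "genome": genome_path,
        "arms_bed": arms_path,
        "blacklist": bl_path,
        "gc": gc_path,
        "mappability": map_path,
        "reference_counts": reference_counts,
        "panel_counts": panel_counts,
        "sample_counts": sample_counts,
        "candidates_vcf": candidates_path,
        "germline_vcf": germline_path,
        "pon_vcfs": pon_paths,
        "reference_vcfs": reference_vcfs,
        "cf_meth": out / "variants" / "cf_meth.tsv",
        "gl_meth": out / "variants" / "gl_meth.tsv",
        "cpgs": cpgs_path,
        "markers_bed": markers_path,
        "planted_markers": planted,
        "flagged_markers": flagged,
        "control_fragments": control_fragments,
        "reference_fragments": reference_fragments,
        "sample_fragments": sample_fragments,
    }
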