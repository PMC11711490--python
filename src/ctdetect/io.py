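"""Format readers/writers and run configuration.

BED and bedGraph intervals are 0-based half-open everywhere inside the
package; VCF positions are 1-based at the boundary only. Variant reading
goes through pysam, decomposing multiallelic records into one record per
alternate allele and excluding records that lack required fields (counted
in provenance rather than failing the run).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .variants import VariantRecord, VariantSet

__all__ = [
    "read_regions",
    "read_counts",
    "read_chrom_sizes",
    "read_positions",
    "read_fragments",
    "read_vcf",
    "write_vcf",
    "RunConfig",
    "write_provenance",
]


def read_regions(
    path: str | Path, dialect: str = "bed", allow_overlap: bool = True
) -> pd.DataFrame:
    """Read a BED/TSV interval file into (chrom, start, end[, name]).

    Output is sorted by (chrom, start). Arm definitions must partition each
    chromosome, so pass ``allow_overlap=False`` for them; blacklists may
    overlap freely.
    """
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from e
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            rows.append(row)
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    if not allow_overlap and len(df):
        for chrom, grp in df.groupby("chrom"):
            ends = grp["end"].to_numpy()
            starts = grp["start"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom} in {path}")
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    """4-column (chrom, start, end, count) TSV/bedGraph of binned coverage."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "count"],
        dtype={"chrom": str},
    )
    return df


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_positions(path: str | Path) -> list[tuple[str, int]]:
    """2-column (chrom, pos) methylation-position list (TSV or BED-like)."""
    df = pd.read_csv(path, sep="\t", header=None)
    return list(zip(df[0].astype(str), df[1].astype(int)))


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Fragment table (marker_id, fragment_id, n_callable, n_modified)."""
    return pd.read_csv(path, sep="\t")


_INFO_FIELDS = {
    "DP": "dp", "VAF": "vaf", "MQ": "mq", "MQBZ": "mqbz",
    "RPBZ": "rpbz", "MQ0F": "mq0f", "BQBZ": "bqbz",
}


def _info_get(rec, key, as_float=True):
    try:
        v = rec.info.get(key)
    except (KeyError, ValueError):  # key absent from the header
        return None
    if isinstance(v, tuple):
        v = v[0]
    if v is None:
        return None
    return float(v) if as_float else v


def read_vcf(
    path: str | Path, sample_id: str | None = None, require_dp: bool = False
) -> VariantSet:
    """Read an (uncompressed or bgzipped) VCF into a VariantSet.

    Multiallelic records are decomposed into one record per alternate
    allele. VAF is computed from FORMAT/AD over DP when absent from INFO.
    Records missing required fields are excluded with a warning and counted
    in provenance.
    """
    vs = VariantSet(sample_id=sample_id or Path(path).stem)
    excluded = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            for alt in alts:
                if alt is None:
                    continue
                dp = _info_get(rec, "DP")
                vaf = _info_get(rec, "VAF")
                if vaf is None and rec.samples:
                    s0 = rec.samples[0]
                    ad = s0.get("AD")
                    sdp = s0.get("DP") or dp
                    if ad is not None and sdp:
                        try:
                            ai = list(rec.alts).index(alt) + 1
                            vaf = float(ad[ai]) / float(sdp)
                        except (IndexError, TypeError, ZeroDivisionError):
                            vaf = None
                if require_dp and dp is None:
                    excluded += 1
                    continue
                csq = _info_get(rec, "CSQ", as_float=False)
                if csq is None:
                    csq = _info_get(rec, "ANN", as_float=False)
                kind = "snv" if len(rec.ref) == 1 and len(alt) == 1 else "indel"
                vs.records.append(
                    VariantRecord(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        kind=kind, dp=dp, vaf=vaf,
                        mq=_info_get(rec, "MQ"), mqbz=_info_get(rec, "MQBZ"),
                        rpbz=_info_get(rec, "RPBZ"), mq0f=_info_get(rec, "MQ0F"),
                        bqbz=_info_get(rec, "BQBZ"),
                        consequence=str(csq) if csq is not None else None,
                    )
                )
    if excluded:
        warnings.warn(f"{path}: excluded {excluded} record(s) missing required fields")
    vs.provenance["excluded_on_read"] = excluded
    vs.provenance["source"] = str(path)
    return vs


def write_vcf(
    variants: VariantSet, path: str | Path, contigs: dict[str, int] | None = None
) -> Path:
    """Write a VariantSet as an uncompressed VCF 4.2 file.

    Round-trips through :func:`read_vcf` to an identical set of records.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for r in variants.records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos + len(r.ref) + 1)
    for c, ln in contigs.items():
        header.contigs.add(c, length=int(ln))
    header.info.add("DP", 1, "Integer", "Depth")
    header.info.add("VAF", 1, "Float", "Variant allele fraction")
    header.info.add("MQ", 1, "Float", "Mapping quality")
    header.info.add("MQBZ", 1, "Float", "MQ bias Z")
    header.info.add("RPBZ", 1, "Float", "Read position bias Z")
    header.info.add("MQ0F", 1, "Float", "Fraction MQ0")
    header.info.add("BQBZ", 1, "Float", "Base quality bias Z")
    header.info.add("CSQ", 1, "String", "Consequence")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in sorted(variants.records, key=lambda x: x.key):
            rec = vf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
            )
            for info_key, attr in _INFO_FIELDS.items():
                v = getattr(r, attr)
                if v is not None:
                    rec.info[info_key] = int(v) if info_key == "DP" else float(v)
            if r.consequence is not None:
                rec.info["CSQ"] = r.consequence
            vf.write(rec)
    return path


@dataclass
class RunConfig:
    """Serializable run configuration with the documented thresholds."""

    alpha: float = 0.05
    sided_coverage: str = "two"
    sided_burden: str = "upper"
    sided_methylation: str = "upper"
    fragment_threshold: float = 0.8
    gc_range: tuple = (0.3, 0.7)
    min_mappability: float = 0.5
    sg_order: int = 3
    sg_window_bins: int = 1001
    min_arm_bins: int = 100
    weights: tuple = (1.0, 1.0, 1.0)
    method: str = "stouffer"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.fragment_threshold <= 1):
            raise ValueError("fragment_threshold must lie in (0, 1]")
        if not (0 <= self.gc_range[0] < self.gc_range[1] <= 1):
            raise ValueError("gc_range must be an increasing pair in [0, 1]")
        if self.sg_window_bins <= self.sg_order:
            raise ValueError("sg_window_bins must exceed sg_order")
        if self.method not in ("stouffer", "fisher"):
            raise ValueError("method must be stouffer or fisher")
        return self

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["gc_range"] = list(self.gc_range)
        d["weights"] = list(self.weights)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "gc_range" in d:
            d["gc_range"] = tuple(d["gc_range"])
        if "weights" in d:
            d["weights"] = tuple(d["weights"])
        return cls(**d).validate()

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def write_provenance(path: str | Path, config: RunConfig, counts: dict) -> None:
    """Machine-readable provenance log for a run."""
    import ctdetect

    payload = {
        "package": "ctdetect",
        "version": getattr(ctdetect, "__version__", "unknown"),
        "config_hash": config.digest(),
        "seed": config.seed,
        "config": asdict(config),
        "stage_counts": counts,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
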