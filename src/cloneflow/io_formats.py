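"""Readers and writers for the formats the pipeline touches.

Variant calls move through VCF v4.2 with per-sample ``FORMAT/AD`` allelic
depths; genomic region annotation through BED; single-cell read counts and
all derived tables through headered TSV.  Coordinate conventions follow the
formats: variant positions are 1-based (VCF), intervals are 0-based
half-open internally (BED).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("cloneflow")

STAGES = ("FA", "MDS", "AML")
REGION_CATEGORIES = ("splicing", "exonic", "other", "intronic", "intergenic")
#: precedence when a position falls in overlapping categories (highest first)
CATEGORY_PRECEDENCE = ("splicing", "exonic", "other", "intronic")


class VcfParseError(ValueError):
    """Raised for a malformed VCF, naming the offending record."""


class ConfigurationError(ValueError):
    """Raised when a manifest or run configuration is inconsistent."""


@dataclass
class SampleMeta:
    """Metadata for one sequenced sample of the longitudinal design.

    Parameters
    ----------
    sample_id : str
        Unique sample key, also the VCF sample column name.
    timepoint_label : str
        Calendar label of the draw, e.g. ``"2016"``.
    stage : str
        Disease stage, one of ``FA``, ``MDS``, ``AML``.
    compartment : str
        ``PB``, ``BM``, ``stem_cell`` or ``sorted:<celltype>``.
    purity : float
        Fraction of sequenced cells that are tumor-derived, in [0, 1].
    """

    sample_id: str
    timepoint_label: str = ""
    stage: str = "MDS"
    compartment: str = "BM"
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ConfigurationError(
                f"purity must be in [0, 1], got {self.purity} for {self.sample_id}"
            )


@dataclass
class VariantRecord:
    """One somatic variant with read-count observations across samples.

    ``observations`` maps sample_id to ``(alt_depth, total_depth)``; a
    sample without an entry was not assayed at this locus (distinct from an
    observed depth of zero).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    observations: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        for sid, (a, d) in self.observations.items():
            if not 0 <= a <= d:
                raise ValueError(
                    f"require 0 <= alt_depth <= total_depth, got ({a}, {d}) "
                    f"for sample {sid} at {self.variant_id}"
                )

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def vaf(self, sample_id: str) -> float:
        """Variant allele frequency alt/total; NaN when unobserved or depth 0."""
        obs = self.observations.get(sample_id)
        if obs is None or obs[1] == 0:
            return float("nan")
        return obs[0] / obs[1]

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class CnvSegment:
    """A copy-number segment with its observed depth ratio.

    ``depth_ratio`` is observed/expected normalized coverage; ``copy_number``
    is the integer total copy number in the aberrant cells (2 is not an
    aberration and is rejected by the fraction estimator).
    """

    chrom: str
    start: int  # 0-based half-open
    end: int
    depth_ratio: float
    copy_number: int
    patient_id: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")
        if self.depth_ratio <= 0:
            raise ValueError(f"depth_ratio must be > 0, got {self.depth_ratio}")
        if self.copy_number < 0:
            raise ValueError(f"copy_number must be >= 0, got {self.copy_number}")

    @property
    def direction(self) -> str:
        return "gain" if self.copy_number > 2 else "loss"


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping/abutting half-open intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class RegionIndex:
    """Genomic region annotation mapping positions to functional categories.

    Categories are ``splicing``, ``exonic``, ``other``, ``intronic`` and the
    implicit ``intergenic`` complement.  Overlaps resolve by precedence
    splicing > exonic > other > intronic > intergenic, so every position maps
    to exactly one category.
    """

    def __init__(self, intervals_by_category: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]]):
        unknown = set(intervals_by_category) - set(CATEGORY_PRECEDENCE)
        if unknown:
            raise ConfigurationError(f"unknown region categories: {sorted(unknown)}")
        self._index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for cat, per_chrom in intervals_by_category.items():
            self._index[cat] = {}
            for chrom, ivals in per_chrom.items():
                for s, e in ivals:
                    if s < 0:
                        raise ValueError(f"negative coordinate in {cat} {chrom}: {s}")
                    if e <= s:
                        raise ValueError(f"empty interval in {cat} {chrom}: [{s}, {e})")
                merged = _merge_intervals(ivals)
                starts = np.array([s for s, _ in merged], dtype=np.int64)
                ends = np.array([e for _, e in merged], dtype=np.int64)
                self._index[cat][chrom] = (starts, ends)

    def intervals(self, category: str, chrom: str) -> list[tuple[int, int]]:
        starts, ends = self._index.get(category, {}).get(chrom, (np.array([]), np.array([])))
        return list(zip(starts.tolist(), ends.tolist()))

    def _contains(self, category: str, chrom: str, pos0: int) -> bool:
        per_chrom = self._index.get(category, {})
        if chrom not in per_chrom:
            return False
        starts, ends = per_chrom[chrom]
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < ends[i]

    def classify(self, chrom: str, pos: int) -> str:
        """Category of a 1-based position; intergenic when in no interval."""
        pos0 = pos - 1
        for cat in CATEGORY_PRECEDENCE:
            if self._contains(cat, chrom, pos0):
                return cat
        return "intergenic"


def read_regions_bed(path_by_category: Mapping[str, str | Path]) -> RegionIndex:
    """Build a :class:`RegionIndex` from one BED file per explicit category.

    ``intergenic`` is defined as the complement of the union of all provided
    categories and must not be supplied.  Unsorted BEDs are sorted; abutting
    intervals merge.
    """
    if "intergenic" in path_by_category:
        raise ConfigurationError("intergenic is the complement; do not supply a BED for it")
    intervals: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for cat, path in path_by_category.items():
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise VcfParseError(f"{path}:{ln}: BED needs >= 3 columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if start < 0:
                    raise ValueError(f"{path}:{ln}: negative coordinate")
                per_chrom.setdefault(chrom, []).append((start, end))
        intervals[cat] = per_chrom
    return RegionIndex(intervals)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variant_vcf(
    path: str | Path, sample_manifest: Sequence[SampleMeta]
) -> list[VariantRecord]:
    """Read somatic variants from a VCF with per-sample AD fields.

    Multi-allelic rows are split into one record per ALT allele.  A sample's
    observation is ``(AD[alt_index], sum(AD))``.  Records with AD missing in
    every manifest sample are dropped (count logged).
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        vcf_samples = list(vcf.header.samples)
        for meta in sample_manifest:
            if meta.sample_id not in vcf_samples:
                raise ConfigurationError(
                    f"manifest sample {meta.sample_id!r} not in VCF (has {vcf_samples})"
                )
        records: list[VariantRecord] = []
        n_dropped = 0
        for rec in vcf:
            if rec.alts is None:
                continue
            for ai, alt in enumerate(rec.alts):
                obs: dict[str, tuple[int, int]] = {}
                for meta in sample_manifest:
                    sdata = rec.samples[meta.sample_id]
                    ad = sdata.get("AD")
                    if ad is None or all(v is None for v in ad):
                        continue
                    depths = [0 if v is None else int(v) for v in ad]
                    if len(depths) <= ai + 1:
                        raise VcfParseError(
                            f"{path}: AD has {len(depths)} values but record "
                            f"{rec.chrom}:{rec.pos} has {len(rec.alts)} ALT alleles"
                        )
                    obs[meta.sample_id] = (depths[ai + 1], sum(depths))
                if not obs:
                    n_dropped += 1
                    continue
                records.append(
                    VariantRecord(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt, observations=obs
                    )
                )
    if n_dropped:
        logger.info("read_variant_vcf: dropped %d allele records lacking AD in all samples", n_dropped)
    logger.info("read_variant_vcf: %d records from %s", len(records), path)
    return records


def write_variant_vcf(
    path: str | Path,
    records: Sequence[VariantRecord],
    sample_manifest: Sequence[SampleMeta],
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write records as a VCF v4.2 with FORMAT/AD (biallelic rows only).

    Samples without an observation at a record get missing AD; alleles other
    than the record's ALT contribute to the reference depth so that
    ``sum(AD) == total_depth`` round-trips exactly.
    """
    header = pysam.VariantHeader()
    chroms: dict[str, int] = dict(contig_lengths or {})
    for rec in records:
        chroms.setdefault(rec.chrom, 0)
        chroms[rec.chrom] = max(chroms[rec.chrom], rec.pos + len(rec.ref) + 1)
    for chrom, ln in chroms.items():
        header.contigs.add(chrom, length=ln)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for meta in sample_manifest:
        header.add_sample(meta.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            row = vcf.new_record(
                contig=rec.chrom, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
            )
            for meta in sample_manifest:
                obs = rec.observations.get(meta.sample_id)
                if obs is None:
                    continue
                alt_d, tot_d = obs
                row.samples[meta.sample_id]["AD"] = (tot_d - alt_d, alt_d)
            vcf.write(row)


# ---------------------------------------------------------------------------
# Single-cell count tables
# ---------------------------------------------------------------------------

def read_cell_counts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cells x loci count table from a long-format TSV.

    The TSV has columns ``cell_id``, ``variant_id``, ``alt_depth``,
    ``total_depth``.  Returns dense ``(alt, total)`` DataFrames indexed by
    cell and locus; absent (cell, locus) pairs densify to depth 0.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "variant_id": str})
    required = {"cell_id", "variant_id", "alt_depth", "total_depth"}
    missing = required - set(df.columns)
    if missing:
        raise VcfParseError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(["cell_id", "variant_id"]).any():
        dup = df[df.duplicated(["cell_id", "variant_id"], keep=False)].iloc[0]
        raise ValueError(f"duplicate (cell, locus) row: {dup['cell_id']}, {dup['variant_id']}")
    if (df["alt_depth"] < 0).any() or (df["total_depth"] < 0).any():
        raise ValueError("negative depths in cell-count table")
    if (df["alt_depth"] > df["total_depth"]).any():
        raise ValueError("alt_depth exceeds total_depth in cell-count table")
    alt = df.pivot(index="cell_id", columns="variant_id", values="alt_depth")
    tot = df.pivot(index="cell_id", columns="variant_id", values="total_depth")
    alt = alt.fillna(0).astype(int)
    tot = tot.fillna(0).astype(int)
    return alt, tot


def write_cell_counts(path: str | Path, alt: pd.DataFrame, total: pd.DataFrame) -> None:
    """Write dense cells x loci counts as the long-format TSV ``read_cell_counts`` reads."""
    if not alt.index.equals(total.index) or not alt.columns.equals(total.columns):
        raise ValueError("alt and total tables must share index and columns")
    long = (
        total.stack()
        .rename("total_depth")
        .to_frame()
        .join(alt.stack().rename("alt_depth"))
        .reset_index()
    )
    long.columns = ["cell_id", "variant_id", "total_depth", "alt_depth"]
    long = long[["cell_id", "variant_id", "alt_depth", "total_depth"]]
    long.to_csv(path, sep="\t", index=False)


def variants_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Long-format DataFrame (variant_id, chrom, pos, ref, alt, sample_id, alt_depth, total_depth)."""
    rows = []
    for rec in records:
        for sid, (a, d) in rec.observations.items():
            rows.append(
                {
                    "variant_id": rec.variant_id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "sample_id": sid,
                    "alt_depth": a,
                    "total_depth": d,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "ref", "alt", "sample_id", "alt_depth", "total_depth",
        ],
    )


def count_matrices(
    records: Sequence[VariantRecord], sample_ids: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variants x samples (alt, total) matrices; unobserved entries get depth 0."""
    vids = [r.variant_id for r in records]
    alt = pd.DataFrame(0, index=vids, columns=list(sample_ids), dtype=int)
    tot = pd.DataFrame(0, index=vids, columns=list(sample_ids), dtype=int)
    for rec in records:
        for sid in sample_ids:
            obs = rec.observations.get(sid)
            if obs is not None:
                alt.at[rec.variant_id, sid] = obs[0]
                tot.at[rec.variant_id, sid] = obs[1]
    return alt, tot


def read_cnv_segments(path: str | Path) -> list[CnvSegment]:
    """Read CNV segments from TSV (chrom, start, end, depth_ratio, copy_number[, patient_id, stage])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    segs = []
    for _, row in df.iterrows():
        segs.append(
            CnvSegment(
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                depth_ratio=float(row["depth_ratio"]),
                copy_number=int(row["copy_number"]),
                patient_id=str(row.get("patient_id", "")),
                stage=str(row.get("stage", "")),
            )
        )
    return segs


def write_cnv_segments(path: str | Path, segments: Sequence[CnvSegment]) -> None:
    pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "depth_ratio": s.depth_ratio,
                "copy_number": s.copy_number,
                "patient_id": s.patient_id,
                "stage": s.stage,
            }
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)
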