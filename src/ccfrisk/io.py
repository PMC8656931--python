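"""Tabular I/O for somatic-variant cohorts.

Readers validate the MAF/SEG-like TSV dialects produced by upstream somatic
pipelines (aligner -> caller -> CNV segmentation) and assemble them into a
:class:`Cohort`. Coordinates are 1-based inclusive throughout (MAF/SEG
convention); VCF input is converted on read. VAF is always recomputed from
alt/total read counts — a stored VAF column is ignored with a log message.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["sample_id", "gene", "chrom", "pos", "ref", "alt",
                   "t_alt_count", "t_depth"]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "total_cn"]


@dataclass(frozen=True)
class VariantCall:
    """One somatic mutation in one sample, with its read-count evidence."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    total_depth: int

    def __post_init__(self):
        if self.total_depth <= 0:
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.pos}: total_depth must be positive")
        if not 0 <= self.alt_reads <= self.total_depth:
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.pos}: "
                f"alt_reads={self.alt_reads} outside [0, depth={self.total_depth}]")

    @property
    def vaf(self) -> float:
        """Variant allele frequency, always recomputed from counts."""
        return self.alt_reads / self.total_depth


@dataclass(frozen=True)
class CopyNumberSegment:
    """Total tumor copy number over a 1-based inclusive genomic interval."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.start}-{self.end}: start > end")
        if self.total_cn < 0:
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                f"negative copy number {self.total_cn}")


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample tumor purity (fraction of tumor cells in the specimen)."""

    sample_id: str
    purity: float

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValidationError(
                f"{self.sample_id}: purity {self.purity} outside (0, 1]")


@dataclass
class ClinicalRecord:
    """Survival outcomes and clinical covariates for one patient.

    ``dfs`` is disease-free survival (time to recurrence or death), ``os``
    overall survival, both in months. OS may be absent (None) when only DFS
    follow-up is available. Unknown covariates are carried through opaquely.
    """

    sample_id: str
    dfs_time: float
    dfs_event: int
    os_time: float | None = None
    os_event: int | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dfs_time <= 0:
            raise ValidationError(f"{self.sample_id}: dfs_time must be > 0")
        if self.dfs_event not in (0, 1):
            raise ValidationError(f"{self.sample_id}: dfs_event must be 0/1")
        if self.os_time is not None:
            if self.os_time <= 0:
                raise ValidationError(f"{self.sample_id}: os_time must be > 0")
            if self.os_event not in (0, 1):
                raise ValidationError(f"{self.sample_id}: os_event must be 0/1")


class GeneCCFMatrix:
    """Samples x genes matrix of per-gene cancer cell fractions.

    Entry (sample, gene) is the CCF of the gene's mutation in that sample
    (the maximum across the gene's mutations) and 0 for wildtype. Values are
    capped to [0, 1].
    """

    def __init__(self, frame: pd.DataFrame):
        values = frame.to_numpy(dtype=float)
        if values.size and (np.nanmin(values) < 0 or np.nanmax(values) > 1 + 1e-9):
            raise ValidationError("gene CCF matrix entries must lie in [0, 1]")
        self.frame = frame.clip(lower=0.0, upper=1.0)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def shape(self):
        return self.frame.shape

    def binarized(self) -> pd.DataFrame:
        """Binary mutation-status matrix: entry > 0 -> 1 else 0."""
        return (self.frame > 0).astype(int)

    def to_tsv(self, path) -> None:
        self.frame.round(6).to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "GeneCCFMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="sample_id")
        frame.index = frame.index.astype(str)
        return cls(frame)

    def __eq__(self, other):
        if not isinstance(other, GeneCCFMatrix):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass
class Cohort:
    """A coherent cohort: variants + copy-number segments + purity + clinical.

    Every variant/segment sample id must resolve to a SampleInfo; variants for
    unknown samples are dropped with a counted warning (panel/clinical
    mismatches are tolerated). Every sample must have a clinical record.
    """

    variants: list[VariantCall]
    segments: list[CopyNumberSegment]
    samples: list[SampleInfo]
    clinical: list[ClinicalRecord]
    n_dropped_variants: int = 0

    @classmethod
    def assemble(cls, variants: Iterable[VariantCall],
                 segments: Iterable[CopyNumberSegment],
                 samples: Iterable[SampleInfo],
                 clinical: Iterable[ClinicalRecord]) -> "Cohort":
        samples = list(samples)
        clinical = list(clinical)
        known = {s.sample_id for s in samples}
        clin_ids = {c.sample_id for c in clinical}
        missing = known - clin_ids
        if missing:
            raise ValidationError(
                f"samples without clinical records: {sorted(missing)[:5]}")
        kept, dropped = [], 0
        for v in variants:
            if v.sample_id in known:
                kept.append(v)
            else:
                dropped += 1
        if dropped:
            logger.warning("dropped %d variants with sample ids not in the "
                           "purity table", dropped)
        segs = [s for s in segments if s.sample_id in known]
        _check_segment_overlaps(segs)
        return cls(kept, segs, samples, clinical, n_dropped_variants=dropped)

    # -- DataFrame views ----------------------------------------------------
    def variants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.sample_id, v.gene, v.chrom, v.pos, v.ref, v.alt,
              v.alt_reads, v.total_depth, v.vaf) for v in self.variants],
            columns=["sample_id", "gene", "chrom", "pos", "ref", "alt",
                     "alt_reads", "total_depth", "vaf"])

    def purity_map(self) -> dict[str, float]:
        return {s.sample_id: s.purity for s in self.samples}

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clinical:
            row = {"sample_id": c.sample_id, "dfs_time": c.dfs_time,
                   "dfs_event": c.dfs_event, "os_time": c.os_time,
                   "os_event": c.os_event}
            row.update(c.covariates)
            rows.append(row)
        return pd.DataFrame(rows).set_index("sample_id")

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


class SegmentIndex:
    """Per-sample, per-chromosome sorted segment lookup (1-based inclusive)."""

    def __init__(self, segments: Sequence[CopyNumberSegment]):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[CopyNumberSegment]]] = {}
        grouped: dict[tuple[str, str], list[CopyNumberSegment]] = {}
        for seg in segments:
            grouped.setdefault((seg.sample_id, str(seg.chrom)), []).append(seg)
        for key, segs in grouped.items():
            segs.sort(key=lambda s: s.start)
            self._by_key[key] = ([s.start for s in segs], segs)

    def lookup(self, sample_id: str, chrom: str, pos: int) -> CopyNumberSegment | None:
        entry = self._by_key.get((sample_id, str(chrom)))
        if entry is None:
            return None
        starts, segs = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and segs[i].start <= pos <= segs[i].end:
            return segs[i]
        return None


def _check_segment_overlaps(segments: Sequence[CopyNumberSegment]) -> None:
    grouped: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for seg in segments:
        grouped.setdefault((seg.sample_id, str(seg.chrom)), []).append(seg)
    for (sid, chrom), segs in grouped.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:  # 1-based inclusive: touching ends overlap
                raise ValidationError(
                    f"overlapping segments for {sid} on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_variants(path, format: str = "maf_tsv") -> list[VariantCall]:
    """Read somatic variant calls from a MAF-like TSV or a VCF.

    The TSV dialect needs columns ``sample_id, gene, chrom, pos, ref, alt,
    t_alt_count, t_depth``. VAF is computed from the counts; a ``vaf`` column,
    if present, is ignored. Multi-allelic VCF records are split per alt allele.
    """
    if format == "maf_tsv":
        return _read_variants_tsv(path)
    if format == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown variant format: {format!r}")


def _read_variants_tsv(path) -> list[VariantCall]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    _require_columns(frame, VARIANT_COLUMNS, path)
    if "vaf" in frame.columns:
        logger.info("%s: stored 'vaf' column ignored; VAF recomputed from counts", path)
    if frame.empty:
        logger.warning("%s: no variant rows (header only)", path)
        return []
    calls = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            calls.append(VariantCall(
                sample_id=str(row.sample_id), gene=str(row.gene),
                chrom=str(row.chrom), pos=int(row.pos),
                ref=str(row.ref), alt=str(row.alt),
                alt_reads=int(row.t_alt_count), total_depth=int(row.t_depth)))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
    _check_variant_uniqueness(calls, path)
    return calls


def _check_variant_uniqueness(calls: Sequence[VariantCall], path) -> None:
    seen = set()
    for c in calls:
        key = (c.sample_id, c.chrom, c.pos, c.alt)
        if key in seen:
            raise ValidationError(
                f"{path}: duplicate variant record for "
                f"{c.sample_id} {c.chrom}:{c.pos} {c.alt}")
        seen.add(key)


def _read_variants_vcf(path) -> list[VariantCall]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise FormatError("VCF input requires the optional cyvcf2 dependency") from exc
    calls = []
    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    for rec in vcf:
        gene = rec.INFO.get("GENE")
        if gene is None:
            raise FormatError(f"{path}: VCF record {rec.CHROM}:{rec.POS} lacks "
                              "a GENE INFO tag")
        ad = rec.format("AD")
        if ad is None:
            raise FormatError(f"{path}: VCF record {rec.CHROM}:{rec.POS} lacks "
                              "FORMAT/AD")
        for si, sample in enumerate(sample_names):
            counts = ad[si]
            depth = int(sum(max(int(c), 0) for c in counts))
            if depth <= 0:
                continue
            for ai, alt in enumerate(rec.ALT, start=1):
                alt_reads = max(int(counts[ai]), 0) if ai < len(counts) else 0
                if alt_reads <= 0:
                    continue
                calls.append(VariantCall(
                    sample_id=sample, gene=str(gene), chrom=str(rec.CHROM),
                    pos=int(rec.POS), ref=str(rec.REF), alt=str(alt),
                    alt_reads=alt_reads, total_depth=depth))
    _check_variant_uniqueness(calls, path)
    return calls


def read_segments(path) -> list[CopyNumberSegment]:
    """Read a SEG-style TSV (sample_id, chrom, start, end, total_cn)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    _require_columns(frame, SEGMENT_COLUMNS, path)
    segs = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            segs.append(CopyNumberSegment(
                sample_id=str(row.sample_id), chrom=str(row.chrom),
                start=int(row.start), end=int(row.end),
                total_cn=float(row.total_cn)))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
    _check_segment_overlaps(segs)
    return segs


def read_samples(path) -> list[SampleInfo]:
    """Read per-sample tumor purity (sample_id, purity)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(frame, ["sample_id", "purity"], path)
    return [SampleInfo(str(r.sample_id), float(r.purity))
            for r in frame.itertuples(index=False)]


_CLINICAL_CORE = ["sample_id", "dfs_time", "dfs_event"]


def read_clinical(path) -> list[ClinicalRecord]:
    """Read the clinical table (DFS required, OS optional, covariates opaque)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(frame, _CLINICAL_CORE, path)
    has_os = "os_time" in frame.columns and "os_event" in frame.columns
    if not has_os:
        logger.warning("%s: OS columns absent; records carry DFS only", path)
    covariate_cols = [c for c in frame.columns
                      if c not in _CLINICAL_CORE + ["os_time", "os_event"]]
    records = []
    for idx, row in frame.iterrows():
        try:
            records.append(ClinicalRecord(
                sample_id=str(row["sample_id"]),
                dfs_time=float(row["dfs_time"]), dfs_event=int(row["dfs_event"]),
                os_time=float(row["os_time"]) if has_os else None,
                os_event=int(row["os_event"]) if has_os else None,
                covariates={c: row[c] for c in covariate_cols}))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx + 1}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Writers (round-trip lossless to 6 decimals on fractions)
# ---------------------------------------------------------------------------

def write_variants(variants: Sequence[VariantCall], path) -> None:
    pd.DataFrame(
        [(v.sample_id, v.gene, v.chrom, v.pos, v.ref, v.alt,
          v.alt_reads, v.total_depth) for v in variants],
        columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_segments(segments: Sequence[CopyNumberSegment], path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.chrom, s.start, s.end, s.total_cn) for s in segments],
        columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_samples(samples: Sequence[SampleInfo], path) -> None:
    pd.DataFrame([(s.sample_id, round(s.purity, 6)) for s in samples],
                 columns=["sample_id", "purity"]).to_csv(path, sep="\t", index=False)


def write_clinical(records: Sequence[ClinicalRecord], path) -> None:
    rows = []
    for c in records:
        row = {"sample_id": c.sample_id,
               "dfs_time": round(c.dfs_time, 6), "dfs_event": c.dfs_event}
        if c.os_time is not None:
            row["os_time"] = round(c.os_time, 6)
            row["os_event"] = c.os_event
        row.update(c.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gene_ccf_matrix(matrix: GeneCCFMatrix, path) -> None:
    """Write the samples x genes CCF matrix as TSV (rows = samples)."""
    matrix.to_tsv(path)


def read_gene_ccf_matrix(path) -> GeneCCFMatrix:
    return GeneCCFMatrix.from_tsv(path)


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write all four cohort tables into a directory; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": outdir / "variants.tsv",
        "segments": outdir / "segments.tsv",
        "purity": outdir / "purity.tsv",
        "clinical": outdir / "clinical.tsv",
    }
    write_variants(cohort.variants, paths["variants"])
    write_segments(cohort.segments, paths["segments"])
    write_samples(cohort.samples, paths["purity"])
    write_clinical(cohort.clinical, paths["clinical"])
    return paths


def read_cohort(variants_path, segments_path, purity_path, clinical_path,
                variant_format: str = "maf_tsv") -> Cohort:
    """Read and assemble a full cohort from its four tables."""
    return Cohort.assemble(
        read_variants(variants_path, format=variant_format),
        read_segments(segments_path),
        read_samples(purity_path),
        read_clinical(clinical_path))
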