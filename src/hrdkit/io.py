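"""Readers, writers and domain records for the HRD classification pipeline.

All downstream modules consume the types defined here. Coordinate
conventions are fixed at the read boundary and never converted again:

* mutations are 1-based (VCF convention; ``pos`` is the first REF base),
* copy-number segments are 1-based inclusive,
* interval sets (exome targets) are 0-based half-open (BED convention).

Chromosome names are stored without a ``chr`` prefix so that mixed-source
inputs compare equal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_DNA = set("ACGT")


class VariantClass(str, Enum):
    SBS = "SBS"
    INS = "INS"
    DEL = "DEL"
    OTHER = "OTHER"


class Assay(str, Enum):
    WGS = "WGS"
    WES = "WES"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix; chromosome comparison is
    prefix-insensitive throughout the package."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """Assign a variant class from REF/ALT using the VCF anchor convention."""
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SBS
    if len(ref) > len(alt) and ref.startswith(alt):
        return VariantClass.DEL
    if len(alt) > len(ref) and alt.startswith(ref):
        return VariantClass.INS
    return VariantClass.OTHER


@dataclass(frozen=True)
class MutationRecord:
    """One somatic substitution or indel.

    ``pos`` is 1-based and points at the first REF base. For indels REF and
    ALT keep the shared VCF anchor base; context classification strips it.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass = field(init=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or set(self.ref) - _DNA or set(self.alt) - _DNA:
            raise ValueError(f"alleles must match [ACGT]+: {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")
        object.__setattr__(self, "variant_class", classify_alleles(self.ref, self.alt))

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive genomic span of the REF allele."""
        return self.pos, self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class SegmentRecord:
    """One allele-specific copy-number segment (ASCAT-style).

    Coordinates are 1-based inclusive; ``major_cn >= minor_cn`` is enforced
    at construction.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} < start {self.start}")
        if self.minor_cn < 0 or self.major_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.major_cn < self.minor_cn:
            raise ValueError("major_cn < minor_cn (swap before constructing)")

    @property
    def tcn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def size(self) -> int:
        """Segment length in bases (1-based inclusive coordinates)."""
        return self.end - self.start + 1


class GenomicIntervalSet:
    """Per-chromosome set of merged, sorted 0-based half-open intervals.

    Touching or overlapping intervals are merged; membership queries are
    binary searches on the merged bounds.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        self._pending: dict[str, list[tuple[int, int]]] = {}
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if end <= start:
            raise ValueError(f"interval end {end} <= start {start}")
        self._pending.setdefault(normalize_chrom(chrom), []).append((int(start), int(end)))

    def merge(self) -> None:
        self._ensure()

    def _ensure(self) -> None:
        for chrom, pairs in self._pending.items():
            if chrom in self._merged:
                starts, ends = self._merged.pop(chrom)
                pairs = pairs + list(zip(starts.tolist(), ends.tolist()))
            pairs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._merged[chrom] = (
                np.array([s for s, _ in merged], dtype=np.int64),
                np.array([e for _, e in merged], dtype=np.int64),
            )
        self._pending.clear()

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) (0-based half-open) hits any interval."""
        self._ensure()
        entry = self._merged.get(normalize_chrom(chrom))
        if entry is None:
            return False
        starts, ends = entry
        i = int(np.searchsorted(starts, end, side="left")) - 1
        return i >= 0 and ends[i] > start

    def covered_length(self) -> int:
        self._ensure()
        return int(sum((e - s).sum() for s, e in self._merged.values()))

    def __len__(self) -> int:
        self._ensure()
        return sum(len(s) for s, _ in self._merged.values())

    def __iter__(self):
        self._ensure()
        for chrom in sorted(self._merged):
            starts, ends = self._merged[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield chrom, s, e


@dataclass
class SampleCatalog:
    """All somatic events of one sample plus the assay resolution."""

    sample_id: str
    mutations: list[MutationRecord] = field(default_factory=list)
    segments: list[SegmentRecord] = field(default_factory=list)
    assay: Assay = Assay.WGS

    def __post_init__(self) -> None:
        for rec in self.mutations:
            if rec.sample_id != self.sample_id:
                raise ValueError("mutation sample_id mismatch")
        for seg in self.segments:
            if seg.sample_id != self.sample_id:
                raise ValueError("segment sample_id mismatch")


@dataclass
class ParseIssue:
    line_number: int
    message: str
    raw: str


@dataclass
class ParseReport:
    """Collected per-row problems; parsers never silently drop rows."""

    issues: list[ParseIssue] = field(default_factory=list)

    def add(self, line_number: int, message: str, raw: str = "") -> None:
        self.issues.append(ParseIssue(line_number, message, raw))

    def __len__(self) -> int:
        return len(self.issues)


# ---------------------------------------------------------------------------
# mutation readers


def read_mutations(
    path, dialect: str = "vcf_minimal", sample_id: str | None = None
) -> tuple[list[MutationRecord], ParseReport]:
    """Read somatic mutations from a minimal VCF or a tabular TSV.

    ``vcf_minimal`` honors columns 1-5 (CHROM/POS/ID/REF/ALT) of a
    single-sample VCF; multi-allelic ALT entries are split into one record
    per allele. ``tabular`` expects a header with columns
    sample/chrom/pos/ref/alt. Malformed rows are collected in the returned
    :class:`ParseReport` with their line numbers.
    """
    if dialect == "vcf_minimal":
        return _read_vcf_minimal(path, sample_id)
    if dialect == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf_minimal(path, sample_id: str | None) -> tuple[list[MutationRecord], ParseReport]:
    records: list[MutationRecord] = []
    report = ParseReport()
    sid = sample_id
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                # header line may carry the sample name in column 10
                cols = line.split("\t")
                if sid is None and len(cols) >= 10:
                    sid = cols[9]
                continue
            n_data += 1
            cols = line.split("\t")
            if len(cols) < 5:
                report.add(lineno, "fewer than 5 columns", line)
                continue
            chrom, pos_s, _, ref, alt_field = cols[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                report.add(lineno, f"non-integer POS {pos_s!r}", line)
                continue
            for alt in alt_field.split(","):
                try:
                    records.append(
                        MutationRecord(
                            sample_id=sid or "sample",
                            chrom=normalize_chrom(chrom),
                            pos=pos,
                            ref=ref.upper(),
                            alt=alt.upper(),
                        )
                    )
                except ValueError as exc:
                    report.add(lineno, str(exc), line)
    if n_data == 0:
        warnings.warn(f"no variant rows in {path}", stacklevel=2)
    return records, report


def _read_tabular(path) -> tuple[list[MutationRecord], ParseReport]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample", "chrom", "pos", "ref", "alt"]
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    records: list[MutationRecord] = []
    report = ParseReport()
    if df.empty:
        warnings.warn(f"no variant rows in {path}", stacklevel=2)
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            pos = int(row[cols["pos"]])
        except (TypeError, ValueError):
            report.add(lineno, f"non-integer pos {row[cols['pos']]!r}")
            continue
        for alt in str(row[cols["alt"]]).split(","):
            try:
                records.append(
                    MutationRecord(
                        sample_id=str(row[cols["sample"]]),
                        chrom=normalize_chrom(str(row[cols["chrom"]])),
                        pos=pos,
                        ref=str(row[cols["ref"]]).upper(),
                        alt=alt.upper(),
                    )
                )
            except ValueError as exc:
                report.add(lineno, str(exc))
    return records, report


# ---------------------------------------------------------------------------
# segment reader

_SEG_SYNONYMS = {
    "sample": {"sample", "sample_id", "samplename"},
    "chrom": {"chrom", "chr", "chromosome"},
    "start": {"start", "startpos", "start_pos"},
    "end": {"end", "endpos", "end_pos"},
    "major_cn": {"major_cn", "nmajor", "nmaj", "major"},
    "minor_cn": {"minor_cn", "nminor", "nmin", "minor"},
}


def read_segments(path) -> tuple[list[SegmentRecord], ParseReport]:
    """Read an ASCAT-style allele-specific copy-number segment TSV.

    Header synonyms (nMajor/nMinor etc.) are resolved case-insensitively.
    Rows with major < minor are swapped with a warning; rows with negative
    or non-integer copy numbers go to the parse report.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for canon, names in _SEG_SYNONYMS.items():
        hit = next((lower[n] for n in names if n in lower), None)
        if hit is None:
            raise ValueError(f"missing required column: {canon}")
        resolved[canon] = hit
    records: list[SegmentRecord] = []
    report = ParseReport()
    n_swapped = 0
    for idx, row in df.iterrows():
        lineno = idx + 2
        try:
            start = int(row[resolved["start"]])
            end = int(row[resolved["end"]])
            major = int(row[resolved["major_cn"]])
            minor = int(row[resolved["minor_cn"]])
        except (TypeError, ValueError):
            report.add(lineno, "non-integer coordinate or copy number")
            continue
        if major < 0 or minor < 0:
            report.add(lineno, "negative copy number")
            continue
        if major < minor:
            major, minor = minor, major
            n_swapped += 1
        try:
            records.append(
                SegmentRecord(
                    sample_id=str(row[resolved["sample"]]),
                    chrom=normalize_chrom(str(row[resolved["chrom"]])),
                    start=start,
                    end=end,
                    major_cn=major,
                    minor_cn=minor,
                )
            )
        except ValueError as exc:
            report.add(lineno, str(exc))
    if n_swapped:
        warnings.warn(f"{n_swapped} segment row(s) had major_cn < minor_cn; swapped", stacklevel=2)
    return records, report


def write_segments(segments: Sequence[SegmentRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample": s.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "major_cn": s.major_cn,
                "minor_cn": s.minor_cn,
            }
            for s in segments
        ],
        columns=["sample", "chrom", "start", "end", "major_cn", "minor_cn"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals


def read_intervals(path) -> tuple[GenomicIntervalSet, ParseReport]:
    """Read a BED3+ file into a merged :class:`GenomicIntervalSet`."""
    ivs = GenomicIntervalSet()
    report = ParseReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                report.add(lineno, "fewer than 3 columns", line)
                continue
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                report.add(lineno, "non-integer coordinates", line)
                continue
            if start >= end:
                report.add(lineno, f"start {start} >= end {end}", line)
                continue
            ivs.add(cols[0], start, end)
    ivs.merge()
    return ivs, report


def write_intervals(intervals: GenomicIntervalSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# context matrices (channel x sample TSV); ContextMatrix lives in contexts.py
# but its (de)serialization is format plumbing and belongs here.


def write_matrix(matrix, path) -> None:
    """Write a ContextMatrix as TSV: channel names first column, one column
    per sample; lossless for integer counts."""
    df = pd.DataFrame(matrix.counts, index=matrix.channels, columns=matrix.sample_ids)
    df.index.name = "MutationType"
    df.to_csv(path, sep="\t")


def read_matrix(path, variant_class: str):
    """Round-trip partner of :func:`write_matrix`; channel names must match
    the canonical schema of ``variant_class`` exactly."""
    from .contexts import CHANNELS, ContextMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    canonical = CHANNELS[variant_class]
    unknown = set(df.index) - set(canonical)
    if unknown:
        raise ValueError(f"unknown channel name(s): {sorted(unknown)[:5]}")
    df = df.reindex(canonical, fill_value=0)
    return ContextMatrix(
        variant_class=variant_class,
        counts=df.to_numpy(dtype=int),
        sample_ids=[str(c) for c in df.columns],
    )
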