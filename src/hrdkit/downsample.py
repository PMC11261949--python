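"""Reduce whole-genome catalogs to whole-exome (dWES) resolution.

Mutations are kept when any base of the REF span overlaps an exome target
interval. Copy-number segments are kept when they overlap at least one
interval and retain their original genomic span and copy numbers (size bins
are computed on the original span, not clipped to exon boundaries — clipped
exonic fragments could never reach the 10-40 Mb / >40 Mb size bins the WES
features rely on). An optional ``clip`` mode intersects segment spans with
the target footprint instead.
"""

from __future__ import annotations

from typing import Sequence

from .io import Assay, GenomicIntervalSet, MutationRecord, SampleCatalog, SegmentRecord


def downsample_mutations(
    catalog: SampleCatalog, exome: GenomicIntervalSet
) -> SampleCatalog:
    """Keep mutations whose REF span overlaps an exome interval; tag WES."""
    kept: list[MutationRecord] = []
    for rec in catalog.mutations:
        start1, end1 = rec.ref_span
        if exome.overlaps(rec.chrom, start1 - 1, end1):  # 1-based -> half-open
            kept.append(rec)
    return SampleCatalog(
        sample_id=catalog.sample_id,
        mutations=kept,
        segments=list(catalog.segments),
        assay=Assay.WES,
    )


def downsample_segments(
    segments: Sequence[SegmentRecord], exome: GenomicIntervalSet, clip: bool = False
) -> list[SegmentRecord]:
    """Keep segments overlapping >= 1 exome interval.

    With ``clip=False`` (default) retained segments keep their original
    start/end; with ``clip=True`` each retained segment is clipped to the
    smallest span covering its overlapped targets.
    """
    kept: list[SegmentRecord] = []
    for seg in segments:
        if not exome.overlaps(seg.chrom, seg.start - 1, seg.end):
            continue
        if not clip:
            kept.append(seg)
            continue
        hits = [
            (b, e)
            for chrom, b, e in exome
            if chrom == seg.chrom and b < seg.end and e > seg.start - 1
        ]
        lo = max(min(b for b, _ in hits) + 1, seg.start)
        hi = min(max(e for _, e in hits), seg.end)
        kept.append(
            SegmentRecord(
                sample_id=seg.sample_id,
                chrom=seg.chrom,
                start=lo,
                end=hi,
                major_cn=seg.major_cn,
                minor_cn=seg.minor_cn,
            )
        )
    return kept


def downsample_catalog(
    catalog: SampleCatalog, exome: GenomicIntervalSet, clip_segments: bool = False
) -> SampleCatalog:
    """Full dWES reduction: mutations and segments, assay tagged WES."""
    reduced = downsample_mutations(catalog, exome)
    return SampleCatalog(
        sample_id=catalog.sample_id,
        mutations=reduced.mutations,
        segments=downsample_segments(catalog.segments, exome, clip=clip_segments),
        assay=Assay.WES,
    )
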