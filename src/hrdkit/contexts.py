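"""SBS-96, ID-83 and CN-48 context classification.

Every somatic event is assigned to exactly one channel of its class:

* SBS-96 — pyrimidine-referenced substitution type x 5'/3' flanking base,
  written ``X[R>A]Y`` with R in {C, T}; purine-reference substitutions are
  reverse-complemented before assignment.
* ID-83 — indels by length, C/T base (1 bp events), flanking repeat-unit
  count, and for >=2 bp deletions without a flanking repeat copy, the
  microhomology length shared with the flank.
* CN-48 — allele-specific copy-number segments by zygosity (homozygous
  deletion / LOH / heterozygous), total copy number bin and segment-size bin.

The canonical channel orders are fixed here as constants and are the
ordering of every matrix the package writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from .io import MutationRecord, SampleCatalog, SegmentRecord, VariantClass, normalize_chrom

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# canonical channel orders

_BASES = "ACGT"
_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in _SUBS for five in _BASES for three in _BASES
)

ID83_CHANNELS: tuple[str, ...] = tuple(
    [f"1:Del:{b}:{n}" for b in "CT" for n in range(6)]
    + [f"1:Ins:{b}:{n}" for b in "CT" for n in range(6)]
    + [f"{l}:Del:R:{n}" for l in range(2, 6) for n in range(6)]
    + [f"{l}:Ins:R:{n}" for l in range(2, 6) for n in range(6)]
    + [f"{l}:Del:M:{m}" for l in range(2, 6) for m in range(1, 6 if l == 5 else l)]
)

_CN_SIZES_FULL = ("0-100kb", "100kb-1Mb", "1Mb-10Mb", "10Mb-40Mb", ">40Mb")
_CN_SIZES_HOMDEL = ("0-100kb", "100kb-1Mb", ">1Mb")
_CN_TCN_LOH = ("1", "2", "3-4", "5-8", "9+")
_CN_TCN_HET = ("2", "3-4", "5-8", "9+")

CN48_CHANNELS: tuple[str, ...] = tuple(
    [f"0:homdel:{s}" for s in _CN_SIZES_HOMDEL]
    + [f"{t}:LOH:{s}" for t in _CN_TCN_LOH for s in _CN_SIZES_FULL]
    + [f"{t}:het:{s}" for t in _CN_TCN_HET for s in _CN_SIZES_FULL]
)

CHANNELS: Mapping[str, tuple[str, ...]] = {
    "SBS96": SBS96_CHANNELS,
    "ID83": ID83_CHANNELS,
    "CN48": CN48_CHANNELS,
}

assert len(SBS96_CHANNELS) == 96 and len(ID83_CHANNELS) == 83 and len(CN48_CHANNELS) == 48


# ---------------------------------------------------------------------------
# reference access


class Reference(Protocol):
    """Anything that can hand back an uppercase reference slice."""

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Return bases of [start0, end0) (0-based half-open)."""
        ...

    def length(self, chrom: str) -> int: ...


class DictReference:
    """In-memory reference: chromosome name -> sequence string."""

    def __init__(self, seqs: Mapping[str, str]) -> None:
        self._seqs = {normalize_chrom(k): v.upper() for k, v in seqs.items()}

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        seq = self._seqs[normalize_chrom(chrom)]
        if start0 < 0 or end0 > len(seq):
            raise IndexError(f"slice [{start0},{end0}) outside {chrom} (len {len(seq)})")
        return seq[start0:end0]

    def length(self, chrom: str) -> int:
        return len(self._seqs[normalize_chrom(chrom)])

    def chroms(self) -> list[str]:
        return list(self._seqs)


class FastaReference:
    """pyfaidx-backed reference for on-disk FASTA files."""

    def __init__(self, path) -> None:
        from pyfaidx import Fasta

        self._fasta = Fasta(str(path), sequence_always_upper=True)
        self._names = {normalize_chrom(n): n for n in self._fasta.keys()}

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        name = self._names[normalize_chrom(chrom)]
        return str(self._fasta[name][start0:end0])

    def length(self, chrom: str) -> int:
        name = self._names[normalize_chrom(chrom)]
        return len(self._fasta[name])


@dataclass(frozen=True)
class ReferenceContext:
    """Local reference sequence around one event.

    For an SBS, ``trimer`` is the 3-mer centered on the mutated base. For an
    indel, ``flank5``/``flank3`` hold at least L bases either side of the
    (anchor-stripped) event, L being the indel length.
    """

    trimer: str = ""
    flank5: str = ""
    flank3: str = ""


def context_for(record: MutationRecord, reference: Reference, flank: int = 10) -> ReferenceContext:
    """Pull the reference context an event needs for classification.

    For indels the VCF anchor base is stripped here: the 5' flank ends at the
    anchor base inclusive, and for deletions the 3' flank starts after the
    last deleted base.
    """
    chrom = record.chrom
    if record.variant_class is VariantClass.SBS:
        start0 = record.pos - 2  # pos is 1-based
        return ReferenceContext(trimer=reference.fetch(chrom, start0, start0 + 3))
    if record.variant_class is VariantClass.DEL:
        event_len = len(record.ref) - len(record.alt)
        width = max(flank, event_len + 1)
        anchor0 = record.pos - 1 + len(record.alt) - 1  # last shared base, 0-based
        f5_start = max(0, anchor0 + 1 - width)
        flank5 = reference.fetch(chrom, f5_start, anchor0 + 1)
        del_end0 = anchor0 + 1 + event_len
        f3_end = min(reference.length(chrom), del_end0 + width)
        flank3 = reference.fetch(chrom, del_end0, f3_end)
        return ReferenceContext(flank5=flank5, flank3=flank3)
    if record.variant_class is VariantClass.INS:
        event_len = len(record.alt) - len(record.ref)
        width = max(flank, event_len + 1)
        anchor0 = record.pos - 1 + len(record.ref) - 1
        f5_start = max(0, anchor0 + 1 - width)
        flank5 = reference.fetch(chrom, f5_start, anchor0 + 1)
        f3_end = min(reference.length(chrom), anchor0 + 1 + width)
        flank3 = reference.fetch(chrom, anchor0 + 1, f3_end)
        return ReferenceContext(flank5=flank5, flank3=flank3)
    return ReferenceContext()


# ---------------------------------------------------------------------------
# SBS-96


class ClassificationError(ValueError):
    """Raised when an event cannot be placed in any channel of its class."""


def classify_sbs(record: MutationRecord, context: ReferenceContext) -> str:
    """Map an SBS to its ``X[R>A]Y`` channel (pyrimidine convention)."""
    if record.variant_class is not VariantClass.SBS:
        raise ClassificationError(f"not an SBS: {record.ref}>{record.alt}")
    trimer = context.trimer.upper()
    if len(trimer) != 3:
        raise ClassificationError(f"need a 3-mer context, got {trimer!r}")
    if trimer[1] != record.ref:
        raise ClassificationError(
            f"context center {trimer[1]!r} does not match ref {record.ref!r}"
        )
    ref, alt = record.ref, record.alt
    if ref in "AG":  # purine reference: flip strand
        trimer = revcomp(trimer)
        ref = trimer[1]
        alt = alt.translate(_COMPLEMENT)
    return f"{trimer[0]}[{ref}>{alt}]{trimer[2]}"


# ---------------------------------------------------------------------------
# ID-83


def microhomology_length(deleted_seq: str, flank5: str, flank3: str) -> int:
    """Length of microhomology shared between a deletion and its flanks.

    The maximum of (longest prefix of the deleted sequence found at the
    start of the 3' flank) and (longest suffix found at the end of the 5'
    flank). A full-length flank copy means the deletion is repeat-mediated,
    not microhomology-mediated, and yields 0.
    """
    n = len(deleted_seq)
    if n == 0:
        return 0
    if flank3.startswith(deleted_seq) or flank5.endswith(deleted_seq):
        return 0  # repeat-mediated; caller routes to the repeat branch
    prefix = 0
    for k in range(min(n - 1, len(flank3)), 0, -1):
        if deleted_seq[:k] == flank3[:k]:
            prefix = k
            break
    suffix = 0
    for k in range(min(n - 1, len(flank5)), 0, -1):
        if deleted_seq[-k:] == flank5[-k:]:
            suffix = k
            break
    return max(prefix, suffix)


def _repeat_units(seq: str, flank5: str, flank3: str) -> int:
    """Number of additional complete copies of ``seq`` adjacent in the
    reference (3' copies plus 5' copies)."""
    n = len(seq)
    units = 0
    i = 0
    while flank3[i : i + n] == seq and i + n <= len(flank3):
        units += 1
        i += n
    j = len(flank5)
    while j - n >= 0 and flank5[j - n : j] == seq:
        units += 1
        j -= n
    return units


def _homopolymer_run(base: str, flank5: str, flank3: str, include_self: bool) -> int:
    run = 1 if include_self else 0
    for b in flank3:
        if b != base:
            break
        run += 1
    for b in reversed(flank5):
        if b != base:
            break
        run += 1
    return run


def classify_indel(record: MutationRecord, context: ReferenceContext) -> str:
    """Map an insertion or deletion to its ID-83 channel.

    The shared VCF anchor base must already be stripped from the flanks
    (``context_for`` does this); classification operates on the inserted or
    deleted sequence itself.
    """
    if record.variant_class is VariantClass.DEL:
        seq = record.ref[len(record.alt) :]
        is_del = True
    elif record.variant_class is VariantClass.INS:
        seq = record.alt[len(record.ref) :]
        is_del = False
    else:
        raise ClassificationError(f"not an indel: {record.ref}>{record.alt}")
    if set(seq) - set("ACGT"):
        raise ClassificationError(f"non-ACGT indel sequence {seq!r}")
    flank5, flank3 = context.flank5.upper(), context.flank3.upper()
    n = len(seq)

    if n == 1:
        base = seq
        run = _homopolymer_run(base, flank5, flank3, include_self=is_del)
        # A/G collapse to the pyrimidine strand label (T/C)
        label = base if base in "CT" else base.translate(_COMPLEMENT)
        if is_del:
            code = min(run, 6) - 1  # run length 1..6+ -> 0..5
        else:
            code = min(run, 5)  # adjacent copies 0..5+
        kind = "Del" if is_del else "Ins"
        return f"1:{kind}:{label}:{code}"

    length_bin = min(n, 5)
    extra = _repeat_units(seq, flank5, flank3)
    if not is_del:
        return f"{length_bin}:Ins:R:{min(extra, 5)}"
    if extra >= 1:
        # deleted copy itself plus `extra` flank copies: units 2..6+ -> 1..5
        return f"{length_bin}:Del:R:{min(extra, 5)}"
    mh = microhomology_length(seq, flank5, flank3)
    if mh >= 1:
        return f"{length_bin}:Del:M:{min(mh, 5)}"
    return f"{length_bin}:Del:R:0"


# ---------------------------------------------------------------------------
# CN-48

_KB100 = 100_000
_MB = 1_000_000


def _size_bin_full(size: int) -> str:
    # upper-inclusive bin edges: 10Mb-40Mb means size > 10Mb and <= 40Mb
    if size <= _KB100:
        return "0-100kb"
    if size <= _MB:
        return "100kb-1Mb"
    if size <= 10 * _MB:
        return "1Mb-10Mb"
    if size <= 40 * _MB:
        return "10Mb-40Mb"
    return ">40Mb"


def _tcn_bin(tcn: int, loh: bool) -> str:
    if loh and tcn == 1:
        return "1"
    if tcn == 2:
        return "2"
    if tcn <= 4:
        return "3-4"
    if tcn <= 8:
        return "5-8"
    return "9+"


def classify_cn_segment(segment: SegmentRecord) -> str:
    """Map an allele-specific copy-number segment to its CN-48 channel."""
    size = segment.size
    tcn = segment.tcn
    if tcn == 0:
        if size <= _KB100:
            return "0:homdel:0-100kb"
        if size <= _MB:
            return "0:homdel:100kb-1Mb"
        return "0:homdel:>1Mb"
    if segment.minor_cn == 0:
        return f"{_tcn_bin(tcn, loh=True)}:LOH:{_size_bin_full(size)}"
    return f"{_tcn_bin(tcn, loh=False)}:het:{_size_bin_full(size)}"


# ---------------------------------------------------------------------------
# matrix construction


@dataclass
class ContextMatrix:
    """Channels x samples count matrix for one variant class."""

    variant_class: str  # "SBS96" | "ID83" | "CN48"
    counts: np.ndarray
    sample_ids: list[str]
    channels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.channels = CHANNELS[self.variant_class]
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.channels), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.channels)}, {len(self.sample_ids)})"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def proportions(self) -> np.ndarray:
        """Per-sample channel proportions; zero-event samples stay all-zero."""
        totals = self.counts.sum(axis=0, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(totals > 0, self.counts / totals, 0.0)
        return props

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.channels), columns=self.sample_ids)


def build_matrix(
    catalogs: Sequence[SampleCatalog],
    variant_class: str,
    reference: Reference | None = None,
) -> tuple[ContextMatrix, list[tuple[str, MutationRecord | SegmentRecord, str]]]:
    """Count every classifiable event of ``variant_class`` per sample.

    Returns the matrix plus an exclusion report of (sample_id, record,
    reason) for events that could not be classified. Column sums equal the
    number of classifiable events; the result is independent of record
    order.
    """
    channels = CHANNELS[variant_class]
    index = {c: i for i, c in enumerate(channels)}
    sample_ids = [c.sample_id for c in catalogs]
    counts = np.zeros((len(channels), len(catalogs)), dtype=int)
    excluded: list[tuple[str, MutationRecord | SegmentRecord, str]] = []

    for j, cat in enumerate(catalogs):
        if variant_class == "CN48":
            for seg in cat.segments:
                counts[index[classify_cn_segment(seg)], j] += 1
            continue
        wanted = (
            (VariantClass.SBS,)
            if variant_class == "SBS96"
            else (VariantClass.INS, VariantClass.DEL)
        )
        for rec in cat.mutations:
            if rec.variant_class not in wanted:
                continue
            if reference is None:
                raise ValueError("a reference is required for mutation classification")
            try:
                ctx = context_for(rec, reference)
                channel = (
                    classify_sbs(rec, ctx)
                    if variant_class == "SBS96"
                    else classify_indel(rec, ctx)
                )
            except (ClassificationError, KeyError, IndexError) as exc:
                excluded.append((cat.sample_id, rec, str(exc)))
                continue
            counts[index[channel], j] += 1

    matrix = ContextMatrix(variant_class=variant_class, counts=counts, sample_ids=sample_ids)
    import warnings as _warnings

    zero = [s for s, tot in zip(sample_ids, counts.sum(axis=0)) if tot == 0]
    if zero:
        _warnings.warn(
            f"{len(zero)} sample(s) with zero classifiable {variant_class} events", stacklevel=2
        )
    return matrix, excluded
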