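"""Context classification against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrdkit.contexts import (
    CN48_CHANNELS,
    ID83_CHANNELS,
    SBS96_CHANNELS,
    ClassificationError,
    DictReference,
    ReferenceContext,
    build_matrix,
    classify_cn_segment,
    classify_indel,
    classify_sbs,
    context_for,
    microhomology_length,
    revcomp,
)
from hrdkit.io import MutationRecord, SampleCatalog, SegmentRecord

_COMP = str.maketrans("ACGT", "TGCA")
_MB = 1_000_000


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)


def oracle_sbs_channel(ref: str, alt: str, trimer: str) -> str:
    if ref in "AG":
        trimer = trimer.translate(_COMP)[::-1]
        ref = ref.translate(_COMP)
        alt = alt.translate(_COMP)
    return f"{trimer[0]}[{ref}>{alt}]{trimer[2]}"


def oracle_mh_length(deleted: str, flank5: str, flank3: str) -> int:
    """Brute force: compare every prefix/suffix length, full match -> 0."""
    n = len(deleted)
    if flank3[:n] == deleted or flank5[-n:] == deleted:
        return 0
    best = 0
    for k in range(1, n):
        if flank3[:k] == deleted[:k]:
            best = max(best, k)
        if flank5[-k:] == deleted[-k:]:
            best = max(best, k)
    return best


def oracle_cn_channel(minor: int, tcn: int, size: int) -> str:
    """Literal transcription of the 48-channel schema listing."""
    kb100, mb1, mb10, mb40 = 100_000, _MB, 10 * _MB, 40 * _MB
    if tcn == 0:
        if size <= kb100:
            return "0:homdel:0-100kb"
        return "0:homdel:100kb-1Mb" if size <= mb1 else "0:homdel:>1Mb"
    if size <= kb100:
        s = "0-100kb"
    elif size <= mb1:
        s = "100kb-1Mb"
    elif size <= mb10:
        s = "1Mb-10Mb"
    elif size <= mb40:
        s = "10Mb-40Mb"
    else:
        s = ">40Mb"
    if minor == 0:
        if tcn == 1:
            t = "1"
        elif tcn == 2:
            t = "2"
        elif tcn in (3, 4):
            t = "3-4"
        elif 5 <= tcn <= 8:
            t = "5-8"
        else:
            t = "9+"
        return f"{t}:LOH:{s}"
    if tcn == 2:
        t = "2"
    elif tcn in (3, 4):
        t = "3-4"
    elif 5 <= tcn <= 8:
        t = "5-8"
    else:
        t = "9+"
    return f"{t}:het:{s}"


# ---------------------------------------------------------------------------
# SBS-96


class TestSbs96:
    def test_pyrimidine_reference_direct(self):
        rec = MutationRecord("s", "1", 2, "C", "T")
        assert classify_sbs(rec, ReferenceContext(trimer="ACG")) == "A[C>T]G"

    def test_purine_reference_reverse_complemented(self):
        rec = MutationRecord("s", "1", 2, "G", "C")
        assert classify_sbs(rec, ReferenceContext(trimer="AGT")) == "A[C>G]T"

    def test_context_mismatch_is_classification_error(self):
        rec = MutationRecord("s", "1", 2, "C", "T")
        with pytest.raises(ClassificationError, match="does not match ref"):
            classify_sbs(rec, ReferenceContext(trimer="ATG"))

    def test_strand_collapse_exhaustive(self):
        """Every (trimer, alt) and its reverse-complement presentation land
        in the same channel, and all 96 channels are reachable."""
        seen = set()
        for five in "ACGT":
            for ref in "ACGT":
                for three in "ACGT":
                    for alt in "ACGT":
                        if alt == ref:
                            continue
                        trimer = five + ref + three
                        fwd = classify_sbs(
                            MutationRecord("s", "1", 2, ref, alt),
                            ReferenceContext(trimer=trimer),
                        )
                        rev = classify_sbs(
                            MutationRecord(
                                "s", "1", 2,
                                ref.translate(_COMP), alt.translate(_COMP),
                            ),
                            ReferenceContext(trimer=revcomp(trimer)),
                        )
                        assert fwd == rev
                        assert fwd == oracle_sbs_channel(ref, alt, trimer)
                        assert fwd in SBS96_CHANNELS
                        seen.add(fwd)
        assert seen == set(SBS96_CHANNELS)


# ---------------------------------------------------------------------------
# microhomology


class TestMicrohomology:
    @pytest.mark.parametrize(
        "deleted,flank5,flank3,expected",
        [
            ("TAGGC", "CCCCC", "TAGTT", 3),  # prefix match TAG
            ("AAAAA", "GGGGG", "AAAAAC", 0),  # full-length copy: repeat, not MH
            ("GATC", "AAAA", "TTTT", 0),
            ("ACGT", "AAACG", "TTTTT", 0),  # suffix of flank5 'ACG' != 'CGT'
            ("ACGTT", "CAGTT", "CCCCC", 3),  # suffix match GTT, not AGTT
        ],
    )
    def test_examples(self, deleted, flank5, flank3, expected):
        assert microhomology_length(deleted, flank5, flank3) == expected

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_bruteforce_oracle(self, data):
        bases = st.sampled_from("ACGT")
        n = data.draw(st.integers(2, 8))
        deleted = "".join(data.draw(st.lists(bases, min_size=n, max_size=n)))
        flank5 = "".join(data.draw(st.lists(bases, min_size=n, max_size=12)))
        flank3 = "".join(data.draw(st.lists(bases, min_size=n, max_size=12)))
        got = microhomology_length(deleted, flank5, flank3)
        assert got == oracle_mh_length(deleted, flank5, flank3)
        assert 0 <= got <= n - 1


# ---------------------------------------------------------------------------
# ID-83


def _del_record_and_context(deleted: str, flank5: str, flank3: str):
    """Build a deletion record plus matching context on a throwaway genome."""
    seq = flank5 + deleted + flank3
    ref = DictReference({"1": seq})
    pos = len(flank5)  # 1-based anchor = last flank5 base
    rec = MutationRecord("s", "1", pos, seq[pos - 1] + deleted, seq[pos - 1])
    return rec, context_for(rec, ref, flank=len(seq))


def _ins_record_and_context(inserted: str, flank5: str, flank3: str):
    seq = flank5 + flank3
    ref = DictReference({"1": seq})
    pos = len(flank5)
    rec = MutationRecord("s", "1", pos, seq[pos - 1], seq[pos - 1] + inserted)
    return rec, context_for(rec, ref, flank=len(seq))


class TestId83:
    @pytest.mark.parametrize(
        "deleted,flank5,flank3,expected",
        [
            # >=5 bp deletion with 2 bp of 3' microhomology
            ("TAGGCAT", "CCGCCGCCC", "TACCCGGGC", "5:Del:M:2"),
            # 6 bp deletion with 5 bp microhomology
            ("TAGGCA", "CCCCCCCC", "TAGGCGGGG", "5:Del:M:5"),
            # deletion of one T inside a 6-T homopolymer
            ("T", "GCTTT", "TTGCA", "1:Del:T:5"),
            # 1 bp deletion of A counts on the pyrimidine strand as T
            ("A", "GCGCG", "CGCGC", "1:Del:T:0"),
            # deleted copy + 2 more flank copies of 'AC' -> repeat channel
            ("AC", "GGGGG", "ACACGTT", "2:Del:R:2"),
            # no repeat copy, no microhomology
            ("GATC", "AAAAA", "TTTTT", "4:Del:R:0"),
            # 7 bp deletion, length bin capped at 5+
            ("GATCGAT", "CCCCCCCC", "TTTTTTTT", "5:Del:R:0"),
        ],
    )
    def test_deletion_channels(self, deleted, flank5, flank3, expected):
        rec, ctx = _del_record_and_context(deleted, flank5, flank3)
        assert classify_indel(rec, ctx) == expected

    @pytest.mark.parametrize(
        "inserted,flank5,flank3,expected",
        [
            ("TAG", "CCCCC", "GGGGG", "3:Ins:R:0"),  # 0 flank repeats
            ("TAG", "CCCCC", "TAGTAGGG", "3:Ins:R:2"),
            ("T", "GCGTT", "TGCAA", "1:Ins:T:3"),  # run of 3 Ts around site
            ("G", "AAAAA", "TTTTT", "1:Ins:C:0"),  # purine collapses to C
        ],
    )
    def test_insertion_channels(self, inserted, flank5, flank3, expected):
        rec, ctx = _ins_record_and_context(inserted, flank5, flank3)
        assert classify_indel(rec, ctx) == expected

    def test_homopolymer_run_counted_on_fixture_flanks(self):
        """Oracle: direct run-length count around the deleted base."""
        for run_len in range(1, 9):
            flank5, flank3 = "GCGCA", "T" * (run_len - 1) + "GCA"
            rec, ctx = _del_record_and_context("T", flank5, flank3)
            expected_code = min(run_len, 6) - 1
            assert classify_indel(rec, ctx) == f"1:Del:T:{expected_code}"

    def test_mh_and_repeat_channels_mutually_exclusive(self):
        """Random deletions never land in an MH channel when a full flank
        copy exists (repeat count >= 2 in schema terms)."""
        rng = np.random.default_rng(5)
        for _ in range(500):
            n = int(rng.integers(2, 7))
            deleted = "".join(rng.choice(list("ACGT"), n))
            flank5 = "".join(rng.choice(list("ACGT"), 10))
            flank3 = "".join(rng.choice(list("ACGT"), 10))
            rec, ctx = _del_record_and_context(deleted, flank5, flank3)
            channel = classify_indel(rec, ctx)
            has_full_copy = flank3.startswith(deleted) or flank5.endswith(deleted)
            if has_full_copy:
                assert ":Del:M:" not in channel
            if ":Del:M:" in channel:
                assert not has_full_copy
                assert oracle_mh_length(deleted, flank5, flank3) >= 1
            assert channel in ID83_CHANNELS


# ---------------------------------------------------------------------------
# CN-48


class TestCn48:
    @pytest.mark.parametrize(
        "major,minor,size,expected",
        [
            (1, 0, 25 * _MB, "1:LOH:10Mb-40Mb"),
            (1, 1, 60 * _MB, "2:het:>40Mb"),
            (0, 0, 50_000, "0:homdel:0-100kb"),
            (2, 0, _MB, "2:LOH:100kb-1Mb"),  # upper edge inclusive
            (2, 0, _MB + 1, "2:LOH:1Mb-10Mb"),
            (8, 1, 15 * _MB, "9+:het:10Mb-40Mb"),  # TCN 9 -> 9+ schema bin
        ],
    )
    def test_examples(self, major, minor, size, expected):
        seg = SegmentRecord("s", "1", 1, size, major, minor)
        assert classify_cn_segment(seg) == expected

    def test_partition_over_randomized_sweep(self):
        """Every valid (minor, TCN, size) triple maps to exactly one of the
        48 channels, matching an independent schema-table oracle."""
        rng = np.random.default_rng(17)
        seen = set()
        for _ in range(10_000):
            minor = int(rng.integers(0, 6))
            major = int(minor + rng.integers(0, 8))
            size = int(10 ** rng.uniform(2, 7.95))
            seg = SegmentRecord("s", "1", 1, size, major, minor)
            channel = classify_cn_segment(seg)
            assert channel in CN48_CHANNELS
            assert channel == oracle_cn_channel(minor, major + minor, size)
            seen.add(channel)
        assert len(seen) > 40  # the sweep exercises nearly the whole schema


# ---------------------------------------------------------------------------
# matrix construction


class TestBuildMatrix:
    def test_conservation_and_order_invariance(self, small_cohort):
        ref = small_cohort.reference.reference
        cat = small_cohort.catalogs[0]
        m, excluded = build_matrix([cat], "SBS96", reference=ref)
        n_sbs = sum(1 for r in cat.mutations if len(r.ref) == len(r.alt) == 1)
        assert m.counts.sum() + sum(1 for e in excluded) == n_sbs

        shuffled = SampleCatalog(
            cat.sample_id,
            list(reversed(cat.mutations)),
            list(cat.segments),
            cat.assay,
        )
        m2, _ = build_matrix([shuffled], "SBS96", reference=ref)
        assert (m.counts == m2.counts).all()

    def test_matches_single_event_oracle(self, small_cohort):
        """Matrix equals a brute-force per-event classification loop."""
        ref = small_cohort.reference.reference
        cats = small_cohort.catalogs[:3]
        m, excluded = build_matrix(cats, "SBS96", reference=ref)
        assert not excluded
        idx = {c: i for i, c in enumerate(SBS96_CHANNELS)}
        expected = np.zeros_like(m.counts)
        for j, cat in enumerate(cats):
            for rec in cat.mutations:
                if len(rec.ref) == len(rec.alt) == 1:
                    start0 = rec.pos - 2
                    trimer = ref.fetch(rec.chrom, start0, start0 + 3)
                    expected[idx[oracle_sbs_channel(rec.ref, rec.alt, trimer)], j] += 1
        assert (m.counts == expected).all()

    def test_zero_event_sample_warns_and_keeps_column(self, toy_reference):
        empty = SampleCatalog("empty")
        with pytest.warns(UserWarning, match="zero classifiable"):
            m, _ = build_matrix([empty], "ID83", reference=toy_reference.reference)
        assert m.counts.shape == (83, 1) and m.counts.sum() == 0

    def test_unclassifiable_context_goes_to_exclusion_report(self):
        ref = DictReference({"1": "ACGTACGTAC"})
        # context center mismatches REF: record claims G at a position with C
        cat = SampleCatalog("s", [MutationRecord("s", "1", 2, "G", "A")])
        m, excluded = build_matrix([cat], "SBS96", reference=ref)
        assert m.counts.sum() == 0 and len(excluded) == 1
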