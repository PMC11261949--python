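"""Seeded toy genomes and HRD/HRP cohorts for end-to-end testing.

The generator emulates the mutational contrasts the classifier relies on:
HRD samples are enriched for C>G substitutions at NpCpT, >=5 bp deletions at
microhomologies, LOH segments of 1-40 Mb and heterozygous TCN 3-9 segments
of 10-40 Mb; HRP samples for CpG C>T transitions and very large (>40 Mb)
heterozygous TCN 2-4 segments. Background channels have identical relative
composition in both classes so only the planted contrasts are enriched.

Copy-number segments at realistic scale need chromosomes longer than 40 Mb,
but sequence is only needed where mutations land. Each toy chromosome
therefore declares a nominal length (default 60 Mb) while random sequence is
synthesized only for a window at its head (default 500 kb) where all
mutations are placed; segments span the full nominal length. Exome targets
are dispersed over the nominal span so both mutations and segments
down-sample realistically.

Every simulated event is constructed at a reference locus that classifies
into its intended channel, and the generator records those intended tallies
so tests can close the loop against the classifier.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .contexts import (
    CN48_CHANNELS,
    SBS96_CHANNELS,
    DictReference,
    revcomp,
)
from .features import DEL5_MH_CHANNELS, NCGT_CHANNELS, NCTG_CHANNELS
from .io import Assay, GenomicIntervalSet, MutationRecord, SampleCatalog, SegmentRecord

_MB = 1_000_000
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration


def _default_sbs_probs(ncgt_mass: float, nctg_mass: float) -> dict[str, float]:
    """96-channel probabilities: planted mass on the N[C>G]T / N[C>T]G
    channel groups, the remainder spread uniformly over the other 88."""
    probs = {}
    rest = 1.0 - ncgt_mass - nctg_mass
    background = rest / (96 - 8)
    for ch in SBS96_CHANNELS:
        if ch in NCGT_CHANNELS:
            probs[ch] = ncgt_mass / 4
        elif ch in NCTG_CHANNELS:
            probs[ch] = nctg_mass / 4
        else:
            probs[ch] = background
    return probs


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults give HRD/HRP contrasts of 3-9x on the planted channel groups
    while background channels keep fold changes below the whole-genome
    volcano threshold; burdens are in the range of whole-genome breast
    cancers (thousands of substitutions, hundreds of indels, tens of
    segments).
    """

    n_hrd: int = 50
    n_hrp: int = 50
    sbs_burden: float = 3000.0  # Poisson mean per sample
    indel_burden: float = 500.0
    n_segments: float = 60.0
    # planted SBS masses per class: (N[C>G]T total, N[C>T]G total)
    sbs_masses: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"HRD": (0.24, 0.08), "HRP": (0.04, 0.28)}
    )
    # indel mixture per class over event plans; backgrounds share one shape
    id_mixture: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "HRD": {"mh_del": 0.25, "del1_T": 0.375, "del1_C": 0.1875, "ins1_T": 0.1875},
            "HRP": {"mh_del": 0.10, "del1_T": 0.45, "del1_C": 0.225, "ins1_T": 0.225},
        }
    )
    # segment mixture per class; the background ("other") mass is identical
    # across classes so only the planted contrasts carry fold change
    segment_mixture: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "HRD": {"loh_1_40mb": 0.38, "het_3_9_10_40mb": 0.20, "het_2_4_gt40mb": 0.07, "other": 0.35},
            "HRP": {"loh_1_40mb": 0.12, "het_3_9_10_40mb": 0.06, "het_2_4_gt40mb": 0.47, "other": 0.35},
        }
    )
    genome: tuple[tuple[str, int], ...] = (
        ("1", 60 * _MB),
        ("2", 60 * _MB),
        ("3", 60 * _MB),
        ("4", 60 * _MB),
    )
    seq_window: int = 500_000  # synthesized sequence per chromosome head
    exome_fraction: float = 0.03
    exon_length: int = 150

    def __post_init__(self) -> None:
        for cls in ("HRD", "HRP"):
            if abs(sum(self.id_mixture[cls].values()) - 1.0) > 1e-9:
                raise ValueError(f"{cls} indel mixture does not sum to 1")
            if abs(sum(self.segment_mixture[cls].values()) - 1.0) > 1e-9:
                raise ValueError(f"{cls} segment mixture does not sum to 1")
            ncgt, nctg = self.sbs_masses[cls]
            if not 0 < ncgt + nctg < 1:
                raise ValueError(f"{cls} SBS masses out of range")
        if self.sbs_burden <= 0 or self.indel_burden <= 0 or self.n_segments <= 0:
            raise ValueError("burdens must be positive")
        if any(length < _MB for _, length in self.genome):
            raise ValueError("chromosome nominal lengths must be >= 1 Mb")

    def sbs_probs(self, cls: str) -> dict[str, float]:
        ncgt, nctg = self.sbs_masses[cls]
        return _default_sbs_probs(ncgt, nctg)


# ---------------------------------------------------------------------------
# toy reference


_MARGIN = 25  # flank room kept free at window edges and around MH sites


class ToyReference:
    """Synthesized sequence windows plus the exome target set.

    Provides the position indexes the samplers draw from: trinucleotide
    sites by 3-mer and candidate loci for microhomology deletions by exact
    MH length.
    """

    def __init__(self, config: SimulationConfig, seed: int) -> None:
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEF]))
        self.windows: dict[str, str] = {}
        self._arrays: dict[str, np.ndarray] = {}
        base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
        for chrom, _ in config.genome:
            codes = rng.integers(0, 4, size=config.seq_window)
            self._arrays[chrom] = codes.astype(np.uint8)
            self.windows[chrom] = base_bytes[codes].tobytes().decode("ascii")
        self.reference = DictReference(self.windows)
        self.exome = self._make_exome(rng)
        self._trimer_index: dict[str, list[tuple[str, np.ndarray]]] | None = None
        self._mh_index: dict[int, list[tuple[str, np.ndarray]]] | None = None

    # -- exome targets

    def _make_exome(self, rng: np.random.Generator) -> GenomicIntervalSet:
        cfg = self.config
        spacing = int(round(cfg.exon_length / cfg.exome_fraction))
        exome = GenomicIntervalSet()
        for chrom, nominal in cfg.genome:
            n_exons = nominal // spacing
            jitter = rng.integers(0, spacing - cfg.exon_length, size=n_exons)
            for k in range(n_exons):
                start = k * spacing + int(jitter[k])
                exome.add(chrom, start, start + cfg.exon_length)
        exome.merge()
        return exome

    # -- trinucleotide index

    def trimer_sites(self, trimer: str) -> list[tuple[str, np.ndarray]]:
        """Center positions (0-based) of every occurrence of a plus-strand
        3-mer, per chromosome, away from window edges."""
        if self._trimer_index is None:
            self._trimer_index = {}
            for chrom, codes in self._arrays.items():
                tri = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
                order = np.argsort(tri, kind="stable")
                sorted_codes = tri[order]
                for code in range(64):
                    lo = np.searchsorted(sorted_codes, code, side="left")
                    hi = np.searchsorted(sorted_codes, code, side="right")
                    centers = order[lo:hi] + 1
                    centers = centers[(centers >= _MARGIN) & (centers < len(codes) - _MARGIN)]
                    name = "".join(
                        _BASES[(code >> s) & 3] for s in (4, 2, 0)
                    )
                    self._trimer_index.setdefault(name, []).append((chrom, centers))
        return self._trimer_index.get(trimer, [])

    # -- microhomology deletion candidates

    def mh_sites(self, mh: int) -> list[tuple[str, np.ndarray]]:
        """Start positions (0-based, first deleted base) of deletion loci
        whose microhomology with the 3' flank is exactly ``mh`` (1-4 for
        5 bp deletions, 5 for 6 bp deletions) and whose 5' microhomology
        does not exceed it; no full flank repeat copy exists."""
        if self._mh_index is None:
            self._mh_index = {m: [] for m in range(1, 6)}
            for chrom, codes in self._arrays.items():
                n = len(codes)
                for m in range(1, 6):
                    L = 5 if m <= 4 else 6
                    eq = codes[: n - L] == codes[L:]
                    # run length of eq ending at j
                    idx = np.arange(len(eq))
                    last_false = np.maximum.accumulate(np.where(~eq, idx, -1))
                    run_end = idx - last_false
                    c = np.concatenate(([0], np.cumsum(eq)))
                    starts = np.arange(_MARGIN, n - L - m - _MARGIN)
                    prefix_all = (c[starts + m] - c[starts]) == m
                    prefix_stop = ~eq[starts + m]
                    suffix_ok = run_end[starts - 1] <= m
                    good = starts[prefix_all & prefix_stop & suffix_ok]
                    self._mh_index[m].append((chrom, good))
        return self._mh_index.get(mh, [])

    def base_at(self, chrom: str, pos0: int) -> str:
        return self.windows[chrom][pos0]


def make_reference(config: SimulationConfig, seed: int) -> ToyReference:
    """Build the seeded toy reference (sequence windows, exome targets,
    site indexes). Same seed, same config: byte-identical output."""
    return ToyReference(config, seed)


def write_reference_fasta(ref: ToyReference, path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ref.windows.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# samplers


def _pick_site(
    rng: np.random.Generator, sites: list[tuple[str, np.ndarray]]
) -> tuple[str, int]:
    counts = np.array([len(p) for _, p in sites])
    total = counts.sum()
    if total == 0:
        raise RuntimeError(
            "no candidate locus in the toy genome for the requested event; "
            "increase seq_window or the number of chromosomes"
        )
    j = rng.choice(len(sites), p=counts / total)
    chrom, positions = sites[j]
    return chrom, int(positions[rng.integers(0, len(positions))])


class _SampleSimulator:
    """Draws one sample's events; keeps the intended channel tallies."""

    def __init__(self, ref: ToyReference, rng: np.random.Generator, sample_id: str):
        self.ref = ref
        self.rng = rng
        self.sample_id = sample_id
        self.mutations: list[MutationRecord] = []
        self.segments: list[SegmentRecord] = []
        self.intended: dict[str, Counter] = {
            "SBS96": Counter(),
            "ID83": Counter(),
            "CN48": Counter(),
        }

    # -- substitutions

    def add_sbs_batch(self, channel: str, count: int) -> None:
        """Place ``count`` substitutions of one channel at loci whose
        plus- or minus-strand 3-mer matches the channel context."""
        if count == 0:
            return
        five, rest = channel[0], channel[2:]
        ref_base, alt_base, three = rest[0], rest[2], rest[4]
        plus = five + ref_base + three
        minus = revcomp(plus)
        comp = str.maketrans("ACGT", "TGCA")
        pools: list[tuple[str, np.ndarray, str, str]] = []
        for chrom, positions in self.ref.trimer_sites(plus):
            pools.append((chrom, positions, ref_base, alt_base))
        for chrom, positions in self.ref.trimer_sites(minus):
            pools.append(
                (chrom, positions, ref_base.translate(comp), alt_base.translate(comp))
            )
        sizes = np.array([len(p) for _, p, _, _ in pools], dtype=np.int64)
        total = int(sizes.sum())
        if total == 0:
            raise RuntimeError(f"no locus for SBS context {plus}; enlarge the toy genome")
        offsets = np.concatenate(([0], np.cumsum(sizes)))
        draws = self.rng.integers(0, total, size=count)
        for d in draws:
            k = int(np.searchsorted(offsets, d, side="right")) - 1
            chrom, positions, ref, alt = pools[k]
            center = int(positions[d - offsets[k]])
            self.mutations.append(
                MutationRecord(self.sample_id, chrom, center + 1, ref, alt)
            )
        self.intended["SBS96"][channel] += count

    # -- indels

    def add_mh_deletion(self, mh: int) -> None:
        sites = self.ref.mh_sites(mh)
        chrom, start0 = _pick_site(self.rng, sites)
        L = 5 if mh <= 4 else 6
        seq = self.ref.windows[chrom]
        anchor = seq[start0 - 1]
        deleted = seq[start0 : start0 + L]
        self.mutations.append(
            MutationRecord(self.sample_id, chrom, start0, anchor + deleted, anchor)
        )
        self.intended["ID83"][f"5:Del:M:{mh}"] += 1

    def _run_around(self, chrom: str, left0: int, right0: int, base: str) -> int:
        """Bases equal to ``base`` ending at left0 (inclusive, scanning left)
        plus starting at right0 (inclusive, scanning right)."""
        seq = self.ref.windows[chrom]
        run = 0
        i = left0
        while i >= 0 and seq[i] == base:
            run += 1
            i -= 1
        i = right0
        while i < len(seq) and seq[i] == base:
            run += 1
            i += 1
        return run

    def add_del1(self, label: str) -> None:
        """Delete one base whose pyrimidine-strand label is ``label`` (C/T)."""
        targets = {"C": "CG", "T": "TA"}[label]
        seq_len = self.ref.config.seq_window
        for _ in range(10_000):
            chrom = self.ref.config.genome[self.rng.integers(0, len(self.ref.config.genome))][0]
            g = int(self.rng.integers(_MARGIN, seq_len - _MARGIN))
            base = self.ref.base_at(chrom, g)
            if base in targets:
                run = 1 + self._run_around(chrom, g - 1, g + 1, base)
                seq = self.ref.windows[chrom]
                self.mutations.append(
                    MutationRecord(self.sample_id, chrom, g, seq[g - 1] + base, seq[g - 1])
                )
                self.intended["ID83"][f"1:Del:{label}:{min(run, 6) - 1}"] += 1
                return
        raise RuntimeError("could not place a 1 bp deletion; enlarge the toy genome")

    def add_ins1(self, label: str) -> None:
        """Insert one base (pyrimidine-strand label C/T) at a random locus."""
        base = label  # insert the pyrimidine itself; label == base
        seq_len = self.ref.config.seq_window
        chrom = self.ref.config.genome[self.rng.integers(0, len(self.ref.config.genome))][0]
        g = int(self.rng.integers(_MARGIN, seq_len - _MARGIN))
        run = self._run_around(chrom, g, g + 1, base)
        seq = self.ref.windows[chrom]
        self.mutations.append(
            MutationRecord(self.sample_id, chrom, g + 1, seq[g], seq[g] + base)
        )
        self.intended["ID83"][f"1:Ins:{label}:{min(run, 5)}"] += 1

    # -- copy-number segments

    def add_segment(self, component: str) -> None:
        rng = self.rng
        if component == "loh_1_40mb":
            size = int(round(math.exp(rng.uniform(math.log(_MB + 1), math.log(40 * _MB)))))
            size = min(max(size, _MB + 1), 40 * _MB)
            major, minor = 1, 0
            channel = f"1:LOH:{'1Mb-10Mb' if size <= 10 * _MB else '10Mb-40Mb'}"
        elif component == "het_3_9_10_40mb":
            tcn = int(rng.integers(3, 10))
            major, minor = tcn - 1, 1
            size = int(rng.integers(10 * _MB + 1, 40 * _MB + 1))
            bin_ = "3-4" if tcn <= 4 else ("5-8" if tcn <= 8 else "9+")
            channel = f"{bin_}:het:10Mb-40Mb"
        elif component == "het_2_4_gt40mb":
            tcn = int(rng.integers(2, 5))
            major, minor = tcn - 1, 1
            size = int(rng.integers(40 * _MB + 1, 55 * _MB + 1))
            channel = f"{'2' if tcn == 2 else '3-4'}:het:>40Mb"
        else:  # background, identical sub-mixture in both classes
            sub = rng.choice(["het_small", "loh_small", "homdel"], p=[0.6, 0.3, 0.1])
            if sub == "het_small":
                major = minor = 1
                size = int(rng.integers(100_000 + 1, _MB + 1))
                channel = "2:het:100kb-1Mb"
            elif sub == "loh_small":
                major, minor = 1, 0
                size = int(rng.integers(5_000, 100_000 + 1))
                channel = "1:LOH:0-100kb"
            else:
                major = minor = 0
                size = int(rng.integers(5_000, 100_000 + 1))
                channel = "0:homdel:0-100kb"
        fitting = [(c, n) for c, n in self.ref.config.genome if n >= size]
        if not fitting:
            raise RuntimeError(f"no chromosome fits a {size} bp segment")
        chrom, nominal = fitting[int(rng.integers(0, len(fitting)))]
        start = int(rng.integers(1, nominal - size + 2))
        self.segments.append(
            SegmentRecord(self.sample_id, chrom, start, start + size - 1, major, minor)
        )
        self.intended["CN48"][channel] += 1


def expected_features(config: SimulationConfig, cls: str) -> dict[str, float]:
    """The generator's intended per-sample feature expectations (WGS
    proportion convention for DEL.5.MH)."""
    ncgt, nctg = config.sbs_masses[cls]
    seg = config.segment_mixture[cls]
    return {
        "loh_1_40mb": seg["loh_1_40mb"],
        "del5_mh": config.id_mixture[cls]["mh_del"],
        "het_3_9_10_40mb": seg["het_3_9_10_40mb"],
        "ncgt": ncgt,
        "nctg": nctg,
        "het_2_4_gt40mb": seg["het_2_4_gt40mb"],
    }


def simulate_sample(
    cls: str,
    config: SimulationConfig,
    reference: ToyReference,
    rng: np.random.Generator,
    sample_id: str,
) -> tuple[SampleCatalog, dict[str, Counter], dict[str, float]]:
    """One sample's catalog, its intended channel tallies and the feature
    expectations of its class."""
    if cls not in ("HRD", "HRP"):
        raise ValueError(f"class must be HRD or HRP, got {cls!r}")
    sim = _SampleSimulator(reference, rng, sample_id)

    sbs_probs = config.sbs_probs(cls)
    channels = list(sbs_probs)
    probs = np.array([sbs_probs[c] for c in channels])
    n_sbs = rng.poisson(config.sbs_burden)
    for idx, count in enumerate(rng.multinomial(n_sbs, probs)):
        sim.add_sbs_batch(channels[idx], int(count))

    mix = config.id_mixture[cls]
    plans = list(mix)
    n_id = rng.poisson(config.indel_burden)
    for idx, count in enumerate(rng.multinomial(n_id, np.array([mix[p] for p in plans]))):
        plan = plans[idx]
        for _ in range(count):
            if plan == "mh_del":
                sim.add_mh_deletion(int(rng.integers(1, 6)))
            elif plan == "del1_T":
                sim.add_del1("T")
            elif plan == "del1_C":
                sim.add_del1("C")
            elif plan == "ins1_T":
                sim.add_ins1("T")
            else:
                raise ValueError(f"unknown indel plan {plan!r}")

    seg_mix = config.segment_mixture[cls]
    components = list(seg_mix)
    n_seg = max(int(rng.poisson(config.n_segments)), 1)
    for idx, count in enumerate(
        rng.multinomial(n_seg, np.array([seg_mix[c] for c in components]))
    ):
        for _ in range(count):
            sim.add_segment(components[idx])

    catalog = SampleCatalog(
        sample_id=sample_id,
        mutations=sim.mutations,
        segments=sim.segments,
        assay=Assay.WGS,
    )
    return catalog, sim.intended, expected_features(config, cls)


@dataclass
class SimulatedCohort:
    catalogs: list[SampleCatalog]
    labels: dict[str, str]  # sample -> HRD/HRP
    expected: dict[str, dict[str, float]]  # sample -> feature expectations
    intended: dict[str, dict[str, Counter]]  # sample -> class tallies
    reference: ToyReference


def simulate_cohort(config: SimulationConfig, seed: int) -> SimulatedCohort:
    """n_hrd + n_hrp samples with independent RNG substreams derived from
    the master seed; same seed yields an identical cohort."""
    reference = make_reference(config, seed)
    streams = np.random.SeedSequence([int(seed), 1]).spawn(config.n_hrd + config.n_hrp)
    catalogs, labels, expected, intended = [], {}, {}, {}
    for i in range(config.n_hrd + config.n_hrp):
        cls = "HRD" if i < config.n_hrd else "HRP"
        sid = f"{cls}_{i if cls == 'HRD' else i - config.n_hrd:03d}"
        catalog, tallies, exp = simulate_sample(
            cls, config, reference, np.random.default_rng(streams[i]), sid
        )
        catalogs.append(catalog)
        labels[sid] = cls
        expected[sid] = exp
        intended[sid] = tallies
    return SimulatedCohort(catalogs, labels, expected, intended, reference)


def simulate_feature_cohort(
    n_hrd: int,
    n_hrp: int,
    seed: int,
    assay: Assay = Assay.WGS,
    config: SimulationConfig | None = None,
) -> tuple[list, dict[str, str]]:
    """Six-feature vectors drawn directly from the class-conditional
    expectations, bypassing event-level simulation.

    Each feature is a binomial proportion at the class expectation with the
    event counts of the configured burdens, so the noise matches what full
    catalogs would produce. For WES, DEL.5.MH becomes an absolute count at
    exome scale. Returns (feature vectors, labels).
    """
    from .features import FeatureVector

    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    vectors: list[FeatureVector] = []
    labels: dict[str, str] = {}
    for i in range(n_hrd + n_hrp):
        cls = "HRD" if i < n_hrd else "HRP"
        sid = f"{cls}_{i if cls == 'HRD' else i - n_hrd:03d}"
        exp = expected_features(config, cls)
        n_sbs = max(int(rng.poisson(config.sbs_burden)), 1)
        n_id = max(int(rng.poisson(config.indel_burden)), 1)
        n_seg = max(int(rng.poisson(config.n_segments)), 1)
        ncgt = rng.binomial(n_sbs, exp["ncgt"]) / n_sbs
        nctg = rng.binomial(n_sbs, exp["nctg"]) / n_sbs
        if assay is Assay.WES:
            n_id_wes = max(int(round(n_id * config.exome_fraction)), 1)
            del5 = float(rng.binomial(n_id_wes, exp["del5_mh"]))
        else:
            del5 = rng.binomial(n_id, exp["del5_mh"]) / n_id
        seg_counts = rng.multinomial(
            n_seg,
            [exp["loh_1_40mb"], exp["het_3_9_10_40mb"], exp["het_2_4_gt40mb"],
             1 - exp["loh_1_40mb"] - exp["het_3_9_10_40mb"] - exp["het_2_4_gt40mb"]],
        )
        vectors.append(
            FeatureVector(
                sample_id=sid,
                assay=assay,
                loh_1_40mb=seg_counts[0] / n_seg,
                del5_mh=del5,
                het_3_9_10_40mb=seg_counts[1] / n_seg,
                ncgt=ncgt,
                nctg=nctg,
                het_2_4_gt40mb=seg_counts[2] / n_seg,
            )
        )
        labels[sid] = cls
    return vectors, labels


# ---------------------------------------------------------------------------
# analytic planted-channel sets


def planted_channels(
    config: SimulationConfig, fc_threshold: float
) -> dict[str, dict[str, set[str]]]:
    """Channels whose configured expected fold change exceeds the volcano
    threshold, per variant class and direction. Derived analytically from
    the configuration, independent of any simulation draw."""
    out: dict[str, dict[str, set[str]]] = {
        vc: {"HRD": set(), "HRP": set()} for vc in ("SBS96", "ID83", "CN48")
    }

    hrd_sbs = config.sbs_probs("HRD")
    hrp_sbs = config.sbs_probs("HRP")
    for ch in SBS96_CHANNELS:
        fc = math.log2((hrd_sbs[ch] + 1e-6) / (hrp_sbs[ch] + 1e-6))
        if abs(fc) > fc_threshold:
            out["SBS96"]["HRD" if fc > 0 else "HRP"].add(ch)

    # indels: the MH group carries the planted mass; every background channel
    # shares one shape so its ratio equals the background-mass ratio
    mh_hrd = config.id_mixture["HRD"]["mh_del"]
    mh_hrp = config.id_mixture["HRP"]["mh_del"]
    fc = math.log2((mh_hrd + 1e-6) / (mh_hrp + 1e-6))
    if abs(fc) > fc_threshold:
        out["ID83"]["HRD" if fc > 0 else "HRP"].update(DEL5_MH_CHANNELS)

    # segments: map each mixture component to its channel split
    loh_split_small = math.log(10) / math.log(40)  # log-uniform mass in (1,10] Mb
    comp_channels = {
        "loh_1_40mb": {
            "1:LOH:1Mb-10Mb": loh_split_small,
            "1:LOH:10Mb-40Mb": 1 - loh_split_small,
        },
        "het_3_9_10_40mb": {
            "3-4:het:10Mb-40Mb": 2 / 7,
            "5-8:het:10Mb-40Mb": 4 / 7,
            "9+:het:10Mb-40Mb": 1 / 7,
        },
        "het_2_4_gt40mb": {"2:het:>40Mb": 1 / 3, "3-4:het:>40Mb": 2 / 3},
        "other": {
            "2:het:100kb-1Mb": 0.6,
            "1:LOH:0-100kb": 0.3,
            "0:homdel:0-100kb": 0.1,
        },
    }
    probs = {"HRD": dict.fromkeys(CN48_CHANNELS, 0.0), "HRP": dict.fromkeys(CN48_CHANNELS, 0.0)}
    for cls in ("HRD", "HRP"):
        for comp, weight in config.segment_mixture[cls].items():
            for ch, share in comp_channels[comp].items():
                probs[cls][ch] += weight * share
    for ch in CN48_CHANNELS:
        a, b = probs["HRD"][ch], probs["HRP"][ch]
        if a == 0 and b == 0:
            continue
        fc = math.log2((a + 1e-6) / (b + 1e-6))
        if abs(fc) > fc_threshold:
            out["CN48"]["HRD" if fc > 0 else "HRP"].add(ch)
    return out
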