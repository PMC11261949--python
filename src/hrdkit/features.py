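"""Channel enrichment screening and the six HRD-predictive features.

The enrichment screen contrasts HRD and HRP cohorts channel by channel:
the effect axis is the log2 ratio of group-mean per-sample channel
proportions (with a small pseudocount), the significance axis a two-sided
Fisher exact test on pooled counts ([channel vs all other channels] x
[HRD vs HRP]) with Benjamini-Hochberg adjustment within each variant class.
A channel is called enriched when |log2 FC| exceeds the fold-change
threshold (0.75 for whole genomes, 0.25 for exomes) and -log10(q) > 3.

The screen's significant channels aggregate into six per-sample features:

==================  =========================================================
N[C>T]G             proportion of SBS that are C>T at NpCpG (CpG transitions)
N[C>G]T             proportion of SBS that are C>G at NpCpT
DEL.5.MH            deletions >= 5 bp at microhomologies (proportion of all
                    indels for WGS, absolute count for WES)
LOH:1-40Mb          proportion of segments with LOH and size in (1, 40] Mb
3-9:HET:10-40Mb     proportion of heterozygous segments, TCN 3-9, (10,40] Mb
2-4:HET:>40Mb       proportion of heterozygous segments, TCN 2-4, > 40 Mb
==================  =========================================================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import CHANNELS, ContextMatrix
from .io import Assay, SegmentRecord

PSEUDOCOUNT = 1e-6

FC_THRESHOLD_WGS = 0.75
FC_THRESHOLD_WES = 0.25
FDR_LOG_THRESHOLD = 3.0

FEATURE_NAMES: tuple[str, ...] = (
    "loh_1_40mb",
    "del5_mh",
    "het_3_9_10_40mb",
    "ncgt",
    "nctg",
    "het_2_4_gt40mb",
)

# display names used in tables and plots, keyed by field name
FEATURE_LABELS: Mapping[str, str] = {
    "loh_1_40mb": "LOH:1-40Mb",
    "del5_mh": "DEL.5.MH",
    "het_3_9_10_40mb": "3-9:HET:10-40Mb",
    "ncgt": "N[C>G]T",
    "nctg": "N[C>T]G",
    "het_2_4_gt40mb": "2-4:HET:>40Mb",
}

NCGT_CHANNELS = tuple(f"{n}[C>G]T" for n in "ACGT")
NCTG_CHANNELS = tuple(f"{n}[C>T]G" for n in "ACGT")
DEL5_MH_CHANNELS = tuple(f"5:Del:M:{m}" for m in range(1, 6))

_MB = 1_000_000


@dataclass(frozen=True)
class EnrichmentResult:
    channel: str
    variant_class: str
    log2_fc: float
    p_value: float
    q_value: float
    enriched_in: str  # "HRD" | "HRP" | "none"


def channel_enrichment(
    matrix: ContextMatrix,
    labels: Mapping[str, str],
    fc_threshold: float,
    fdr_log_threshold: float = FDR_LOG_THRESHOLD,
) -> list[EnrichmentResult]:
    """Volcano-style enrichment screen of one context matrix.

    ``labels`` maps every sample column to "HRD" or "HRP". Fold changes are
    ratios of group means of per-sample proportions (HRD over HRP);
    p-values come from Fisher exact tests on pooled counts and are BH
    adjusted across the channels of this class.
    """
    groups = {s: labels[s] for s in matrix.sample_ids}
    hrd_cols = [j for j, s in enumerate(matrix.sample_ids) if groups[s] == "HRD"]
    hrp_cols = [j for j, s in enumerate(matrix.sample_ids) if groups[s] == "HRP"]
    if not hrd_cols or not hrp_cols:
        raise ValueError("both HRD and HRP groups must be non-empty")

    counts = matrix.counts
    pooled_hrd = counts[:, hrd_cols].sum(axis=1)
    pooled_hrp = counts[:, hrp_cols].sum(axis=1)
    total_hrd = int(pooled_hrd.sum())
    total_hrp = int(pooled_hrp.sum())
    if total_hrd == 0:
        raise ValueError("HRD group has zero events in this variant class")
    if total_hrp == 0:
        raise ValueError("HRP group has zero events in this variant class")

    props = matrix.proportions()
    mean_hrd = props[:, hrd_cols].mean(axis=1)
    mean_hrp = props[:, hrp_cols].mean(axis=1)
    log2_fc = np.log2((mean_hrd + PSEUDOCOUNT) / (mean_hrp + PSEUDOCOUNT))

    p_values = np.ones(len(matrix.channels))
    for i in range(len(matrix.channels)):
        a, b = int(pooled_hrd[i]), int(pooled_hrp[i])
        table = [[a, total_hrd - a], [b, total_hrp - b]]
        p_values[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    q_values = stats.false_discovery_control(p_values, method="bh")

    results = []
    for i, channel in enumerate(matrix.channels):
        significant = (
            abs(log2_fc[i]) > fc_threshold and -math.log10(max(q_values[i], 1e-300)) > fdr_log_threshold
        )
        enriched_in = "none"
        if significant:
            enriched_in = "HRD" if log2_fc[i] > 0 else "HRP"
        results.append(
            EnrichmentResult(
                channel=channel,
                variant_class=matrix.variant_class,
                log2_fc=float(log2_fc[i]),
                p_value=float(p_values[i]),
                q_value=float(q_values[i]),
                enriched_in=enriched_in,
            )
        )
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results into a volcano-plot-ready table."""
    return pd.DataFrame(
        [
            {
                "channel": r.channel,
                "variant_class": r.variant_class,
                "log2_fc": r.log2_fc,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "neg_log10_q": -math.log10(max(r.q_value, 1e-300)),
                "enriched_in": r.enriched_in,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# feature extraction


@dataclass(frozen=True)
class FeatureVector:
    """The six engineered features of one sample plus its assay tag."""

    sample_id: str
    assay: Assay
    loh_1_40mb: float
    del5_mh: float
    het_3_9_10_40mb: float
    ncgt: float
    nctg: float
    het_2_4_gt40mb: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def _segment_features(
    segments: Sequence[SegmentRecord], loh_max_tcn: int | None = None
) -> tuple[float, float, float]:
    """(LOH:1-40Mb, 3-9:HET:10-40Mb, 2-4:HET:>40Mb) as proportions of all
    segments. TCN filters apply to the raw total copy number, not the binned
    channel, so TCN 9 still counts toward the 3-9 heterozygous feature. The
    LOH feature aggregates all TCN >= 1 states unless ``loh_max_tcn`` caps
    them."""
    total = len(segments)
    if total == 0:
        return 0.0, 0.0, 0.0
    loh = het39 = het24 = 0
    for s in segments:
        size, tcn = s.size, s.tcn
        loh_tcn_ok = tcn >= 1 and (loh_max_tcn is None or tcn <= loh_max_tcn)
        if s.minor_cn == 0 and loh_tcn_ok and _MB < size <= 40 * _MB:
            loh += 1
        elif s.minor_cn >= 1 and 3 <= tcn <= 9 and 10 * _MB < size <= 40 * _MB:
            het39 += 1
        elif s.minor_cn >= 1 and 2 <= tcn <= 4 and size > 40 * _MB:
            het24 += 1
    return loh / total, het39 / total, het24 / total


def extract_features(
    sample_id: str,
    assay: Assay,
    sbs_column: np.ndarray,
    id_column: np.ndarray,
    segments: Sequence[SegmentRecord],
    del5_mh_as_count: bool | None = None,
    loh_max_tcn: int | None = None,
) -> FeatureVector:
    """Aggregate one sample's channel counts and segments into the six
    features.

    SBS features and (for WGS) DEL.5.MH are proportions of the sample's
    classifiable events; for WES, DEL.5.MH is the absolute count
    (``del5_mh_as_count`` overrides the assay default). Copy-number features
    are proportions of all segments. Zero denominators yield 0 with a
    warning.
    """
    sbs_channels = CHANNELS["SBS96"]
    id_channels = CHANNELS["ID83"]
    sbs_column = np.asarray(sbs_column)
    id_column = np.asarray(id_column)
    if sbs_column.shape != (96,) or id_column.shape != (83,):
        raise ValueError("expected SBS96 (96,) and ID83 (83,) count columns")

    total_sbs = int(sbs_column.sum())
    if total_sbs > 0:
        sbs_idx = {c: i for i, c in enumerate(sbs_channels)}
        ncgt = sum(int(sbs_column[sbs_idx[c]]) for c in NCGT_CHANNELS) / total_sbs
        nctg = sum(int(sbs_column[sbs_idx[c]]) for c in NCTG_CHANNELS) / total_sbs
    else:
        warnings.warn(f"{sample_id}: zero SBS events, SBS features set to 0", stacklevel=2)
        ncgt = nctg = 0.0

    id_idx = {c: i for i, c in enumerate(id_channels)}
    del5_count = sum(int(id_column[id_idx[c]]) for c in DEL5_MH_CHANNELS)
    as_count = assay is Assay.WES if del5_mh_as_count is None else del5_mh_as_count
    if as_count:
        del5_mh = float(del5_count)
    else:
        total_id = int(id_column.sum())
        if total_id > 0:
            del5_mh = del5_count / total_id
        else:
            warnings.warn(f"{sample_id}: zero indel events, DEL.5.MH set to 0", stacklevel=2)
            del5_mh = 0.0

    if not segments:
        warnings.warn(f"{sample_id}: no segments, CN features set to 0", stacklevel=2)
    loh, het39, het24 = _segment_features(segments, loh_max_tcn=loh_max_tcn)

    return FeatureVector(
        sample_id=sample_id,
        assay=assay,
        loh_1_40mb=loh,
        del5_mh=del5_mh,
        het_3_9_10_40mb=het39,
        ncgt=ncgt,
        nctg=nctg,
        het_2_4_gt40mb=het24,
    )


def extract_feature_table(
    catalogs,
    sbs_matrix: ContextMatrix,
    id_matrix: ContextMatrix,
    del5_mh_as_count: bool | None = None,
) -> list[FeatureVector]:
    """Extract features for every catalog using prebuilt context matrices."""
    vectors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cat in catalogs:
            vectors.append(
                extract_features(
                    cat.sample_id,
                    cat.assay,
                    sbs_matrix.column(cat.sample_id),
                    id_matrix.column(cat.sample_id),
                    cat.segments,
                    del5_mh_as_count=del5_mh_as_count,
                )
            )
    return vectors


def feature_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Sample x feature table (plus assay column) for model fitting and TSV
    export."""
    rows = []
    for v in vectors:
        row = {"sample": v.sample_id, "assay": v.assay.value}
        row.update({n: getattr(v, n) for n in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample", "assay", *FEATURE_NAMES]).set_index("sample")
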