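"""Diagnostic plots: volcano view of the enrichment screen and a PCA
scatter of the six features. Both are sanity views, not modeled components."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np


def volcano_plot(table, ax=None):
    """Volcano plot from an :func:`hrdkit.features.enrichment_table` frame:
    log2 fold change vs -log10(q), enriched channels colored by direction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = {"HRD": "crimson", "HRP": "royalblue", "none": "lightgray"}
    for group, sub in table.groupby("enriched_in"):
        ax.scatter(
            sub["log2_fc"], sub["neg_log10_q"], s=12,
            c=colors.get(group, "lightgray"), label=group,
        )
    ax.set_xlabel("log2 fold change (HRD / HRP)")
    ax.set_ylabel("-log10 FDR-adjusted p")
    ax.legend(frameon=False, fontsize=8)
    return ax


def pca_plot(vectors: Sequence, labels: Mapping[str, str], ax=None):
    """First two principal components of the standardized six-feature
    matrix, colored by HRD/HRP label."""
    import matplotlib.pyplot as plt
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    X = np.vstack([v.as_array() for v in vectors])
    pcs = PCA(n_components=2).fit_transform(StandardScaler().fit_transform(X))
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    colors = {"HRD": "crimson", "HRP": "royalblue"}
    for cls in ("HRD", "HRP"):
        mask = np.array([labels[v.sample_id] == cls for v in vectors])
        ax.scatter(pcs[mask, 0], pcs[mask, 1], s=14, c=colors[cls], label=cls)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    return ax
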