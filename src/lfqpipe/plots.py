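"""Optional figures: volcano plot and PCA scatter."""

from __future__ import annotations

import pandas as pd

from .ordination import OrdinationResult
from .tables_io import SampleDesign

_CLASS_COLORS = {"up": "tab:red", "down": "tab:blue", "not_significant": "0.6"}


def volcano_plot(de_table: pd.DataFrame, ax=None, fc_threshold: float = 1.0,
                 p_axis_threshold: float | None = None):
    """Scatter of log2 fold change vs −log2(p), coloured by volcano class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for cls, sub in de_table.groupby("volcano_class"):
        ax.scatter(sub["log2_fc"], sub["neg_log2_p"], s=8,
                   c=_CLASS_COLORS.get(cls, "k"), label=cls, alpha=0.7)
    ax.axvline(fc_threshold, ls="--", lw=0.8, c="0.4")
    ax.axvline(-fc_threshold, ls="--", lw=0.8, c="0.4")
    if p_axis_threshold is not None:
        ax.axhline(p_axis_threshold, ls="--", lw=0.8, c="0.4")
    ax.set_xlabel("log2 fold change (treated − control)")
    ax.set_ylabel("−log2(p-value)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def pca_plot(result: OrdinationResult, design: SampleDesign, ax=None):
    """PC1/PC2 scatter with isolate colour and treatment marker."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    meta = design.table.set_index("sample_id")
    markers = {"control": "o", "treated": "^"}
    isolates = list(dict.fromkeys(meta["isolate"]))
    cmap = {iso: f"C{i}" for i, iso in enumerate(isolates)}
    for sid, row in result.scores.iterrows():
        iso, trt = meta.loc[sid, "isolate"], meta.loc[sid, "treatment"]
        ax.scatter(row.iloc[0], row.iloc[1], c=cmap[iso], marker=markers[trt],
                   edgecolor="k", linewidth=0.3, s=45)
    ve = result.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    if len(ve) > 1:
        ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    return ax
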