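"""Run summaries and the fold-change heat map."""

from __future__ import annotations

import numpy as np

from .silac import ComplexComparison


def comparison_table(comp: ComplexComparison):
    """Per-protein output table for one comparison, sorted by descending
    log2 fold change (undefined fold changes last)."""
    t = comp.table.copy()
    t["log2_fold_change"] = np.log2(t["fold_change"].where(t["fold_change"] > 0))
    return t.sort_values("log2_fold_change", ascending=False,
                         na_position="last").reset_index(drop=True)


def run_summary(comparisons: dict[str, ComplexComparison],
                dropped_peptides=None) -> dict:
    """JSON-ready summary of a quantification run."""
    out = {}
    for label, comp in comparisons.items():
        t = comp.table
        classes = t["enrichment_class"].value_counts().to_dict()
        out[label] = {
            "numerator": comp.numerator,
            "denominator": comp.denominator,
            "n_proteins": int(len(t)),
            "class_counts": {k: int(v) for k, v in classes.items()},
        }
    summary = {"comparisons": out}
    if dropped_peptides is not None and len(dropped_peptides):
        summary["dropped_peptides"] = {
            k: int(v) for k, v in
            dropped_peptides["reason"].value_counts().to_dict().items()
        }
    return summary


def fold_change_heatmap(comparisons: dict[str, ComplexComparison], path,
                        vmax: float = 3.0) -> None:
    """Protein x comparison heat map of log2 fold changes.

    Green marks enrichment in the numerator state, red in the
    denominator state, yellow no change — one panel per comparison,
    proteins ordered by the first comparison's fold change.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    wide = pd.DataFrame({
        label: comp.table.set_index("protein")["fold_change"]
        for label, comp in comparisons.items()
    })
    wide = np.log2(wide.where(wide > 0))
    wide = wide.sort_values(wide.columns[0], ascending=False)

    fig, ax = plt.subplots(figsize=(2 + 1.2 * len(wide.columns),
                                    max(3, 0.22 * len(wide))))
    im = ax.imshow(wide.to_numpy(), aspect="auto", cmap="RdYlGn",
                   vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(wide.columns)), wide.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(wide)), wide.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
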