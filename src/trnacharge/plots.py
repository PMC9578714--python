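"""Bar plots of mean fraction charged ± SD per isodecoder."""

from __future__ import annotations

import numpy as np
import pandas as pd


def charging_barplot(summary: pd.DataFrame, ax=None, conditions=None):
    """Grouped bar chart of condition means with SD error bars.

    ``summary`` is the output of :func:`trnacharge.stats.summarize_replicates`
    (columns condition, isodecoder, mean, sd, n).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, summary["isodecoder"].nunique()), 3.5))
    conds = conditions or list(dict.fromkeys(summary["condition"]))
    isos = sorted(summary["isodecoder"].unique())
    width = 0.8 / len(conds)
    x = np.arange(len(isos))
    for i, cond in enumerate(conds):
        sub = summary[summary["condition"] == cond].set_index("isodecoder")
        means = [sub["mean"].get(iso, np.nan) for iso in isos]
        sds = [sub["sd"].get(iso, 0.0) for iso in isos]
        ax.bar(x + i * width, means, width, yerr=sds, capsize=2, label=cond)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(isos, rotation=90)
    ax.set_ylabel("fraction charged")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    return ax
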