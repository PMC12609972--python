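"""Diagnostic plots: MA plots, Kaplan-Meier curves, enrichment dot plots."""

from __future__ import annotations

import numpy as np


def ma_plot(records, fit=None, ax=None, title="MA plot"):
    """Scatter M vs A with the fitted LOWESS curve overlaid, if given."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(records["A"], records["M"], s=2, alpha=0.3, color="0.3")
    if fit is not None:
        ax.plot(fit["A"], fit["fitted"], color="crimson", lw=1.5)
    ax.axhline(0.0, color="steelblue", lw=0.8, ls="--")
    ax.set_xlabel("A (average log2 intensity)")
    ax.set_ylabel("M (log2 ratio)")
    ax.set_title(title)
    return ax


def km_plot(result, ax=None, title="Median-split survival"):
    """Step plot of the two Kaplan-Meier curves of a SurvivalResult."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, df in result.km.items():
        ax.step(df["time"], df["survival"], where="post", label=label)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_title(
        f"{title}\nlog-rank p = {result.p_value:.3g}, HR = {result.hr:.3g}"
    )
    ax.legend()
    return ax


def enrichment_dotplot(records, ax=None, top=15, title="Over-representation"):
    """Dot plot: fold enrichment vs term, sized by k, colored by -log10 FDR."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * min(top, len(records)) + 1.5))
    sub = records.nsmallest(top, "fdr")[::-1]
    sc = ax.scatter(
        sub["fold_enrichment"], range(len(sub)),
        s=20 * sub["k"], c=-np.log10(sub["fdr"]), cmap="viridis",
    )
    ax.set_yticks(range(len(sub)))
    ax.set_yticklabels(sub["term_name"])
    ax.set_xlabel("fold enrichment")
    ax.set_title(title)
    plt.colorbar(sc, ax=ax, label="-log10 FDR")
    return ax
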