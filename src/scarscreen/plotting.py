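"""Optional matplotlib plots: concentration-distribution curves and ROC curves.

Requires the ``plot`` extra (matplotlib); the analysis pipeline itself never
imports this module.
"""

from __future__ import annotations

GROUP_STYLES = {
    "normal": {"color": "tab:green", "linestyle": "-"},
    "mild": {"color": "tab:pink", "linestyle": ":"},
    "severe": {"color": "tab:red", "linestyle": "--"},
}


def plot_distribution_curves(histograms, ax=None):
    """Percentage-of-simulations curves, one per outcome group.

    ``histograms``: iterable of :class:`~scarscreen.overlap.HistogramDensity`
    for a single protein and day (each binned over its own range).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    protein = day = None
    for h in histograms:
        centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
        ax.plot(centers, 100.0 * h.fractions, label=h.group,
                **GROUP_STYLES.get(h.group, {}))
        protein, day = h.protein, h.day
    ax.set_xlabel(f"[{protein}] (a.u.)")
    ax.set_ylabel("% of simulations")
    ax.set_title(f"{protein}, day {day}")
    ax.legend()
    return ax


def plot_roc_curves(analyses, ax=None):
    """ROC curves for one or more fitted panels (``RocAnalysis`` objects)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for a in analyses:
        suffix = " (CV)" if a.cross_validated else ""
        ax.plot(a.fpr, a.tpr,
                label=f"{'+'.join(a.panel)}{suffix}: AUC {a.auc:.2f}")
    ax.plot([0, 1], [0, 1], color="grey", linewidth=0.8, linestyle="--")
    ax.set_xlabel("False-positive rate (1 - specificity)")
    ax.set_ylabel("True-positive rate (sensitivity)")
    ax.legend(fontsize="small")
    return ax
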