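"""Small plotting helpers for compartment histograms and reports."""

from __future__ import annotations

import numpy as np

from .quantify import HIST_KS


def plot_compartment_histograms(
    nuclear_counts: np.ndarray,
    cytoplasmic_counts: np.ndarray,
    title: str = "",
    ax=None,
):
    """Overlay the nuclear and cytoplasmic intensity histograms of a cell.

    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.step(HIST_KS, nuclear_counts, where="mid", label="nuclear")
    ax.step(HIST_KS, cytoplasmic_counts, where="mid", label="cytoplasmic")
    ax.set_xlabel("pixel intensity k (8-bit)")
    ax.set_ylabel("H(k)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    return ax


def plot_report(report, metric: str = "mfi", ax=None):
    """Bar chart of per-stratum group medians from a cohort report."""
    import matplotlib.pyplot as plt

    sub = report[report["metric"] == metric]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.2))
    labels = [
        f"{r['marker']}\n{r['cell_type']} {r['compartment'][:3]}"
        for _, r in sub.iterrows()
    ]
    x = np.arange(len(sub))
    width = 0.38
    ax.bar(x - width / 2, sub["median_a"], width, label=sub["group_a"].iloc[0]
           if len(sub) else "a")
    ax.bar(x + width / 2, sub["median_b"], width, label=sub["group_b"].iloc[0]
           if len(sub) else "b")
    for xi, (_, r) in zip(x, sub.iterrows()):
        ax.text(xi, max(r["median_a"], r["median_b"]) * 1.02, r["stars"],
                ha="center", fontsize=8)
    ax.set_xticks(x, labels, fontsize=8)
    ax.set_ylabel(f"median {metric.upper()}")
    ax.legend(frameon=False)
    return ax
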