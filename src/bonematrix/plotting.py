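"""BMDD curve plotting (percent bone area vs wt% Ca).

Renders one or more Ca histograms as continuous curves, optionally over a
normative reference band (mean ± 1 SD curves supplied as a CSV with columns
ca, mean, sd)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .bmdd import CaHistogram


def plot_bmdd(
    histograms: dict[str, CaHistogram],
    reference_csv=None,
    ax=None,
    out_path=None,
):
    """Plot BMDD curves; returns the matplotlib Axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    if reference_csv is not None:
        ref = pd.read_csv(reference_csv)
        ax.fill_between(
            ref["ca"], ref["mean"] - ref["sd"], ref["mean"] + ref["sd"],
            color="0.85", label="reference ± 1 SD",
        )
        ax.plot(ref["ca"], ref["mean"], "k:", lw=1)
    for label, hist in histograms.items():
        ax.plot(hist.bin_centers, hist.frequencies, label=label)
    ax.set_xlabel("Ca (wt%)")
    ax.set_ylabel("bone area (%)")
    ax.legend(frameon=False, fontsize=8)
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
    return ax
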