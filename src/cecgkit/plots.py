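"""Report figures: ERP distribution, Bland–Altman, SQI-vs-ERP scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .evaluation import BlandAltmanResult


def erp_histogram(erps, bins: int = 30):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(np.asarray(list(erps)), bins=bins, color="tab:blue", edgecolor="k")
    ax.set_xlabel("ERP (%)")
    ax.set_ylabel("count")
    ax.set_title("RR duration percentage-error distribution")
    fig.tight_layout()
    return fig


def bland_altman_plot(rr_reference, rr_textile, result: BlandAltmanResult):
    """One dot per recording: mean vs. difference of the paired RR durations."""
    ref = np.asarray(list(rr_reference))
    tex = np.asarray(list(rr_textile))
    mean = (ref + tex) / 2
    diff = ref - tex
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=18, color="tab:blue")
    for y, style in ((result.bias, "-"), (result.loa_low, "--"),
                     (result.loa_high, "--")):
        ax.axhline(y, color="tab:red", linestyle=style, linewidth=1)
    ax.set_xlabel("mean RR (s)")
    ax.set_ylabel("reference − textile RR (s)")
    ax.set_title("Bland–Altman agreement of RR durations")
    fig.tight_layout()
    return fig


def sqi_vs_erp_scatter(sqis, erps):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(np.asarray(list(sqis)), np.asarray(list(erps)),
               s=18, color="tab:blue")
    ax.axvline(1.0, color="gray", linestyle="--", linewidth=1,
               label="SQI = 1 (equal in/out-of-band power)")
    ax.set_xlabel("SQI")
    ax.set_ylabel("ERP (%)")
    ax.set_title("RR error vs. signal quality")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig
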