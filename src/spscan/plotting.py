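"""Advisory visualization: scatter colored by cluster with regression lines.

Visual inspection distinguishes benign clustering (separate clusters,
homogeneous trend) from genuine reversal; this view is diagnostic output
only and its exact appearance is not part of the analysis contract.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .detect import SPReport
from .regress import BivariateSample


def plot_clusters(sample: BivariateSample, report: SPReport, path: str) -> None:
    """Write a PNG/PDF scatter of the sample with group and cluster fits."""
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = report.cluster_labels
    cmap = plt.get_cmap("tab10")
    for i, lab in enumerate(np.unique(labels)):
        m = labels == lab
        ax.scatter(sample.x[m], sample.y[m], s=12, alpha=0.6,
                   color=cmap(i % 10), label=f"cluster {lab}")
    xs = np.linspace(sample.x.min(), sample.x.max(), 50)
    g = report.group_fit
    ax.plot(xs, g.intercept + g.slope * xs, "k-", lw=2, label="group fit")
    for f in report.findings:
        style = "r--" if f.sign_reversed else "b--"
        ax.plot(xs, f.fit.intercept + f.fit.slope * xs, style, lw=1)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
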