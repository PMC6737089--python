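"""Static figure export for pipeline runs (log-binned PDFs, raster overview)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .avalanches import EnsembleCatalog
from .powerlaw_stats import log_bin_pdf

__all__ = ["plot_pdf", "render_report_figures"]


def plot_pdf(ax, values, label: str, **kw):
    """Log-binned probability density on log-log axes."""
    pdf = log_bin_pdf(np.asarray(values))
    keep = pdf.densities > 0
    ax.loglog(pdf.centers[keep], pdf.densities[keep], "o-", label=label, **kw)


def render_report_figures(
    report: dict, catalog: EnsembleCatalog, shuffled: EnsembleCatalog, out: Path
) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, attr, title in zip(axes, ("sizes", "durations"), ("ensemble size", "duration")):
        vals = getattr(catalog, attr)
        if vals.size:
            plot_pdf(ax, vals, "observed")
        sv = getattr(shuffled, attr)
        if sv.size:
            plot_pdf(ax, sv, "shuffled", alpha=0.6)
        ax.set_xlabel(f"{title} (frames)" if attr == "durations" else f"{title} (neuron-frames)")
        ax.set_ylabel("probability density")
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "avalanche_pdfs.png", dpi=150)
    plt.close(fig)
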