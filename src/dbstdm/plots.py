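"""Optional figures: the four-panel method-comparison layout and the MPR boxplot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .comparison import ComparisonReport
from .mpr import MPRTable


def comparison_figure(report: ComparisonReport, path: str | Path) -> None:
    """Deming scatter (raw and converted) over Bland-Altman panels."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    pairs = [
        (axes[0, 0], report.blood, report.deming_raw, "DBS blood conc"),
        (axes[0, 1], report.calculated_plasma, report.deming_converted,
         "calculated plasma conc"),
    ]
    for ax, yvals, fit, label in pairs:
        x = report.measured_plasma
        ax.scatter(x, yvals, s=18, color="tab:blue")
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, fit.intercept + fit.slope * grid, color="black",
                label=f"Deming: y={fit.slope:.3f}x+{fit.intercept:.3f}")
        ax.plot(grid, grid, color="red", lw=0.8, label="identity")
        ax.set_xlabel("measured plasma conc (µg/mL)")
        ax.set_ylabel(f"{label} (µg/mL)")
        ax.legend(fontsize=7)
    bas = [
        (axes[1, 0], report.blood, report.ba_raw, "DBS - plasma"),
        (axes[1, 1], report.calculated_plasma, report.ba_converted,
         "calculated - measured plasma"),
    ]
    for ax, yvals, ba, label in bas:
        mean_ax = (yvals + report.measured_plasma) / 2
        ax.scatter(mean_ax, yvals - report.measured_plasma, s=18)
        for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            ax.axhline(y, color="grey", ls=style, lw=0.9)
        ax.set_xlabel("mean of methods (µg/mL)")
        ax.set_ylabel(f"{label} (µg/mL)")
    fig.suptitle(f"{report.analyte.label}: DBS vs plasma (K={report.k_used:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mpr_boxplot(table: MPRTable, path: str | Path) -> None:
    """Cohort MPR boxplot with Tukey fences and flagged subjects in red."""
    fig, ax = plt.subplots(figsize=(4, 5))
    vals = table.per_subject["mpr"].to_numpy()
    ax.boxplot(vals, whis=1.5)
    jitter = np.random.default_rng(0).uniform(-0.06, 0.06, size=vals.size)
    colors = np.where(table.per_subject["outlier"], "red", "tab:blue")
    ax.scatter(1 + jitter, vals, c=colors, zorder=3)
    for fence in (table.fence_low, table.fence_high):
        ax.axhline(fence, ls="--", color="grey", lw=0.9)
    ax.set_ylabel("metabolite-to-parent ratio")
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
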