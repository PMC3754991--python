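"""Four-panel summary figure for a fitted population: the MDE
trajectory against the data, the joint (t1, t2) posterior, and the two
1D marginals."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .forward_model import PopulationData
from .posterior import PosteriorGrids, PosteriorSummary

__all__ = ["summary_panel"]


def summary_panel(
    summary: PosteriorSummary,
    grids: PosteriorGrids,
    data: PopulationData,
    path,
) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))

    ax = axes[0, 0]
    ax.plot(summary.fitted.ages, summary.fitted.bone, label="bone (MDE)")
    ax.plot(
        summary.fitted.ages,
        summary.fitted.synthesized,
        "--",
        label="diet signal",
    )
    ax.scatter(data.ages, data.d15n, s=18, c="k", zorder=3, label="subadults")
    if data.adult_female_mean is not None:
        ax.axhline(data.adult_female_mean, color="grey", lw=0.8)
    ax.set_xlabel("age at death (yr)")
    ax.set_ylabel(r"$\delta^{15}$N (permil)")
    ax.legend(fontsize=8)

    ax = axes[0, 1]
    j = grids.joint_ages
    ax.contour(j.x_centers, j.y_centers, j.mass.T, levels=8)
    ax.plot(summary.mde.t1, summary.mde.t2, "r+", ms=12)
    ax.set_xlabel("t1 (yr)")
    ax.set_ylabel("t2 (yr)")

    for ax, grid, label in (
        (axes[1, 0], grids.enrichment, "enrichment E (permil)"),
        (axes[1, 1], grids.wnfood, "weaning-food value (permil)"),
    ):
        ax.bar(grid.centers, grid.mass, width=0.09)
        ax.set_xlabel(label)
        ax.set_ylabel("cell probability")

    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
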