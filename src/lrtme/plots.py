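"""Optional figure exports (vector graphics).

Matplotlib is used lazily so the analysis modules stay import-light.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: Display colors for the default phenotypes, following the usual
#: multicolor-IF palette (HRS red, CXCL13+ T cells magenta, CXCR5+ B
#: cells yellow).
PHENOTYPE_COLORS = {
    "HRS": "#d62728",
    "TFH_CXCL13": "#c74fc7",
    "B_CXCR5": "#c7a500",
    "T_CD4": "#2ca02c",
    "B": "#1f77b4",
    "other": "#bbbbbb",
}


def membrane_map(
    cells: pd.DataFrame,
    sample_id: str,
    path: str | Path,
    touching: pd.DataFrame | None = None,
) -> None:
    """Scatter map of one sample's phenotypes; cells participating in a
    touching pair are drawn filled, the rest as open circles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sdf = cells[cells["sample_id"] == sample_id]
    touching_ids: set = set()
    if touching is not None:
        sub = touching[touching["sample_id"] == sample_id]
        touching_ids = set(sub["cell_id_a"]) | set(sub["cell_id_b"])
    fig, ax = plt.subplots(figsize=(6, 6))
    for phen, grp in sdf.groupby("phenotype"):
        color = PHENOTYPE_COLORS.get(phen, "#999999")
        filled = grp["cell_id"].isin(touching_ids)
        ax.scatter(grp.loc[~filled, "x_um"], grp.loc[~filled, "y_um"],
                   s=12, facecolors="none", edgecolors=color, label=phen)
        if filled.any():
            ax.scatter(grp.loc[filled, "x_um"], grp.loc[filled, "y_um"],
                       s=20, color=color)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: origin top-left, y downward
    ax.legend(fontsize=7, loc="upper right")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def km_plot(km_curves: pd.DataFrame, path: str | Path) -> None:
    """Step plot of per-group Kaplan-Meier curves (``group, time,
    survival`` columns, as written by the survival stage)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, grp in km_curves.groupby("group"):
        t = [0.0, *grp["time"]]
        s = [1.0, *grp["survival"]]
        ax.step(t, s, where="post", label=str(group))
    ax.set_xlabel("years")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
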