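"""Static map output: bivariate 3x3 choropleth of the risk matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .indicators import AREA_ID

__all__ = ["risk_matrix_choropleth"]

# 3x3 bivariate palette: rows = vulnerability tercile (light->dark),
# columns = hazard tercile (blue->red family); a standard bivariate scheme.
_PALETTE = {
    (1, 1): "#e8e8e8", (1, 2): "#b5c0da", (1, 3): "#6c83b5",
    (2, 1): "#b8d6be", (2, 2): "#90b2b3", (2, 3): "#567994",
    (3, 1): "#73ae80", (3, 2): "#5a9178", (3, 3): "#2a5a5b",
}


def risk_matrix_choropleth(areas: pd.DataFrame, matrix: pd.DataFrame, title: str, path=None):
    """Draw area polygons coloured by their 3x3 risk-matrix cell.

    ``areas`` needs area_id and geometry columns; ``matrix`` is a
    risk-matrix table with vulnerability_tercile/hazard_tercile.  Returns
    the matplotlib figure; saves a PNG when ``path`` is given.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon, Rectangle

    cells = matrix.set_index(AREA_ID)[["vulnerability_tercile", "hazard_tercile"]]
    fig, (ax, legend_ax) = plt.subplots(
        1, 2, figsize=(9, 7), gridspec_kw={"width_ratios": [4, 1]}
    )
    for _, row in areas.iterrows():
        geom = row["geometry"]
        try:
            v, h = cells.loc[row[AREA_ID]]
            colour = _PALETTE[(int(v), int(h))] if not (pd.isna(v) or pd.isna(h)) else "#ffffff"
        except KeyError:
            colour = "#ffffff"
        for ring in getattr(geom, "geoms", [geom]):
            ax.add_patch(
                MplPolygon(np.asarray(ring.exterior.coords), facecolor=colour,
                           edgecolor="#999999", linewidth=0.2)
            )
    bounds = np.array([g.bounds for g in areas["geometry"]])
    ax.set_xlim(bounds[:, 0].min(), bounds[:, 2].max())
    ax.set_ylim(bounds[:, 1].min(), bounds[:, 3].max())
    ax.set_aspect("equal")
    ax.set_title(title)
    ax.set_axis_off()

    for (v, h), colour in _PALETTE.items():
        legend_ax.add_patch(Rectangle((h - 1, v - 1), 1, 1, facecolor=colour, edgecolor="white"))
    legend_ax.set_xlim(0, 3)
    legend_ax.set_ylim(0, 3)
    legend_ax.set_xticks([0.5, 1.5, 2.5], ["H1", "H2", "H3"])
    legend_ax.set_yticks([0.5, 1.5, 2.5], ["V1", "V2", "V3"])
    legend_ax.set_aspect("equal")
    legend_ax.set_title("risk cell", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
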