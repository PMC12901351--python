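"""Plot helpers (funnel plot, network diagram). Matplotlib, Agg-safe."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

from .model import NetworkMetaAnalysis

__all__ = ["funnel_plot", "network_plot"]


def funnel_plot(points: pd.DataFrame, path: Optional[str | Path] = None):
    """Comparison-adjusted funnel: centred log OR against standard error
    (inverted axis), with the pseudo 95% funnel bounds."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for cmp_label, grp in points.groupby("comparison"):
        ax.scatter(grp["effect"], grp["se"], label=cmp_label, s=28, alpha=0.8)
    se_max = float(points["se"].max()) * 1.05
    ax.plot([0, -1.96 * se_max], [0, se_max], "k--", lw=0.8)
    ax.plot([0, 1.96 * se_max], [0, se_max], "k--", lw=0.8)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.invert_yaxis()
    ax.set_xlabel("centred log odds ratio")
    ax.set_ylabel("standard error")
    ax.legend(fontsize=7, loc="lower left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def network_plot(model: NetworkMetaAnalysis, path: Optional[str | Path] = None):
    """Network geometry: node size by number of studies including the
    treatment, edge width by number of direct studies."""
    geo = model.geometry()
    g = nx.Graph()
    for node in geo["nodes"]:
        g.add_node(node["treatment"], n=node["n_studies"])
    for e in geo["edges"]:
        g.add_edge(e["treat_a"], e["treat_b"], n=e["n_studies"])
    pos = nx.circular_layout(g)
    fig, ax = plt.subplots(figsize=(6, 6))
    sizes = [300 + 300 * g.nodes[n]["n"] for n in g]
    widths = [1.5 * g.edges[e]["n"] for e in g.edges]
    nx.draw_networkx(g, pos, ax=ax, node_size=sizes, width=widths,
                     node_color="#9ecae1", font_size=9)
    nx.draw_networkx_edge_labels(
        g, pos, ax=ax,
        edge_labels={e: g.edges[e]["n"] for e in g.edges}, font_size=8,
    )
    ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
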