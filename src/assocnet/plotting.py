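"""Minimal plotting helpers for reports."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402

from .lmm import FitResult
from .networks import SocialNetwork


def plot_reaction_norms(
    result: FitResult,
    frame,
    path: str,
    n_individuals: int = 30,
    x_range: tuple[float, float] = (-2.0, 2.0),
) -> None:
    """Population prediction line over per-individual BLUP-free spaghetti of
    observed trait values against the standardized covariate."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ids = frame["individual_id"].unique()[:n_individuals]
    for ind in ids:
        sub = frame[frame["individual_id"] == ind].sort_values("x")
        ax.plot(sub["x"], sub["y"], color="grey", alpha=0.3, lw=0.7)
    xs = np.linspace(*x_range, 50)
    b = result.beta
    for sex01, label in ((0.0, "F"), (1.0, "M")):
        ax.plot(
            xs,
            b[0] + b[1] * sex01 + (b[2] + b[3] * sex01) * xs,
            lw=2,
            label=label,
        )
    ax.set_xlabel("standardized covariate")
    ax.set_ylabel(f"{result.spec.transform}({result.spec.trait})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_network(network: SocialNetwork, path: str, seed: int = 0) -> None:
    """Spring-layout drawing of one window's network, edges scaled by SRI."""
    g = nx.Graph()
    g.add_nodes_from(network.ids)
    n = network.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            w = network.weights[i, j]
            if w > 0:
                g.add_edge(network.ids[i], network.ids[j], weight=w)
    pos = nx.spring_layout(g, seed=seed, weight="weight")
    fig, ax = plt.subplots(figsize=(5, 5))
    widths = [3 * g[u][v]["weight"] for u, v in g.edges]
    nx.draw_networkx_edges(g, pos, ax=ax, width=widths, alpha=0.5)
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=30)
    ax.set_axis_off()
    ax.set_title("window " + "-".join(str(v) for v in network.window))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
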