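"""Node-level social traits: strength, weighted clustering, corrected closeness."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .networks import SocialNetwork, WindowLabel
from .simulate import EnvironmentalSeries

__all__ = [
    "strength",
    "clustering_coefficient",
    "closeness",
    "network_metrics",
    "metrics_table",
    "write_metrics_table",
]


def strength(network: SocialNetwork, node: str) -> float:
    """Sum of a node's incident edge weights; 0 for an isolated node."""
    i = network.node_index(node)
    return float(network.weights[i].sum())


def clustering_coefficient(
    network: SocialNetwork, node: str, variant: str = "barrat"
) -> float:
    """Weighted clustering coefficient; NaN when the node has < 2 neighbours.

    "barrat": C_i = 1/(s_i (k_i - 1)) * sum over connected neighbour pairs
    (j, h) of (w_ij + w_ih)/2.  "onnela": geometric-mean triangle intensity
    normalized by k_i (k_i - 1) with weights scaled by the network maximum.
    """
    i = network.node_index(node)
    return float(_clustering_all(network, variant)[i])


def _clustering_all(network: SocialNetwork, variant: str = "barrat") -> np.ndarray:
    W = network.weights
    A = (W > 0).astype(float)
    k = A.sum(axis=1)
    out = np.full(network.n_nodes, np.nan)
    eligible = k >= 2
    if not eligible.any():
        return out
    if variant == "barrat":
        s = W.sum(axis=1)
        # num_i = sum_{j,h} (w_ij + w_ih)/2 * a_ij a_ih a_jh  (ordered pairs)
        #       = sum_j w_ij * (A_j . A_i)   by symmetry in (j, h)
        num = ((W * A) * (A @ A)).sum(axis=1)
        denom = s * (k - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = num / denom
        out[eligible] = vals[eligible]
    elif variant == "onnela":
        wmax = W.max()
        if wmax <= 0:
            return out
        Wh = (W / wmax) ** (1.0 / 3.0)
        num = np.diag(Wh @ Wh @ Wh)
        denom = k * (k - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = num / denom
        out[eligible] = vals[eligible]
    else:
        raise ValueError(f"unknown clustering variant: {variant!r}")
    return out


def closeness(network: SocialNetwork, node: str) -> float:
    """Size-corrected closeness with edge lengths 1/weight.

    With R the set of nodes reachable from i (excluding i), r = |R| and n the
    node count: (r / sum of shortest distances to R) * (r / (n - 1)). An
    isolated node (or a single-node network) scores 0; on a connected graph
    this is the inverse of the mean path length times 1.
    """
    i = network.node_index(node)
    return float(_closeness_all(network)[i])


def _closeness_all(network: SocialNetwork) -> np.ndarray:
    n = network.n_nodes
    if n == 1:
        return np.zeros(1)
    W = network.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    dist = dijkstra(csr_matrix(lengths), directed=False)
    np.fill_diagonal(dist, np.inf)
    reachable = np.isfinite(dist)
    r = reachable.sum(axis=1)
    total = np.where(reachable, dist, 0.0).sum(axis=1)
    out = np.zeros(n)
    pos = r > 0
    out[pos] = (r[pos] / total[pos]) * (r[pos] / (n - 1))
    return out


def network_metrics(
    network: SocialNetwork, clustering_variant: str = "barrat"
) -> pd.DataFrame:
    """All three traits for every node of one network."""
    W = network.weights
    return pd.DataFrame(
        {
            "individual_id": network.ids,
            "strength": W.sum(axis=1),
            "clustering": _clustering_all(network, clustering_variant),
            "closeness": _closeness_all(network),
            "n_sightings": network.sightings.astype(int),
        }
    )


def metrics_table(
    networks: dict[WindowLabel, SocialNetwork],
    metadata: pd.DataFrame,
    env: EnvironmentalSeries,
    clustering_variant: str = "barrat",
) -> pd.DataFrame:
    """Long analysis table: one row per (individual, window).

    Rows of unknown-sex individuals are flagged ``included=False`` (they are
    excluded from model fitting) but their nodes remain in the networks, so
    their associations still shape everyone else's metrics.
    """
    sex = metadata.set_index("individual_id")["sex"]
    monthly = env.monthly_lookup()
    yearly = env.yearly_lookup()
    frames = []
    for label in sorted(networks):
        net = networks[label]
        year = int(label[0])
        month = int(label[1]) if len(label) > 1 else None
        if month is None:
            if year not in yearly:
                raise KeyError(f"window {label} missing from environment series")
            cov = yearly[year]
        else:
            if (year, month) not in monthly:
                raise KeyError(f"window {label} missing from environment series")
            cov = monthly[(year, month)]
        block = network_metrics(net, clustering_variant)
        block["window_year"] = year
        block["window_month"] = month if month is not None else pd.NA
        block["covariate_raw"] = cov
        frames.append(block)
    table = pd.concat(frames, ignore_index=True)
    table["sex"] = table["individual_id"].map(sex).fillna("U")
    table["included"] = table["sex"].isin(["F", "M"])
    raw = table["covariate_raw"].to_numpy(float)
    if np.unique(raw).size > 1:
        table["covariate_std"] = (raw - raw.mean()) / raw.std()
    else:
        table["covariate_std"] = 0.0
    cols = [
        "individual_id",
        "window_year",
        "window_month",
        "strength",
        "clustering",
        "closeness",
        "n_sightings",
        "included",
        "sex",
        "covariate_raw",
        "covariate_std",
    ]
    return table[cols]


def write_metrics_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)
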