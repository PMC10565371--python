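"""Encounter tables to weighted social networks (gambit of the group + SRI).

The sampling unit is the encounter: two individuals are "together" when they
appear in the same encounter and "apart" when they appear in different
encounters within the window. The simple ratio index for a pair is

    sri_ij = x_ij / (n_i + n_j - x_ij)

with n_i the number of encounters containing i and x_ij the number
containing both; it ranges from 0 (never together) to 1 (always together).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SocialNetwork",
    "filter_calves",
    "window_encounters",
    "drop_sparse_windows",
    "group_by_individual",
    "build_network",
    "build_window_networks",
    "mask_rare_individuals",
    "write_edge_list",
    "write_windows_summary",
]

WindowLabel = tuple  # (year,) or (year, month)


@dataclass
class SocialNetwork:
    """Per-window weighted undirected graph with SRI edge weights."""

    window: WindowLabel
    ids: list[str]
    weights: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    sightings: np.ndarray  # n_i per node
    together: np.ndarray  # x_ij per pair
    n_encounters: int = 0
    index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {ind: k for k, ind in enumerate(self.ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def node_index(self, individual_id: str) -> int:
        try:
            return self.index[individual_id]
        except KeyError:
            raise KeyError(f"unknown node: {individual_id!r}") from None


def filter_calves(
    encounters: pd.DataFrame, metadata: pd.DataFrame, min_age: int = 3
) -> pd.DataFrame:
    """Drop observation rows of individuals younger than ``min_age`` years.

    Age in a given encounter year is ``year - birth_year``; individuals with
    unknown birth year are treated as adults and retained.
    """
    if min_age <= 0:
        return encounters.copy()
    by = metadata.set_index("individual_id")["birth_year"]
    birth = encounters["individual_id"].map(by)
    age = encounters["year"] - birth
    keep = birth.isna() | (age >= min_age)
    removed = int((~keep).sum())
    logger.info(
        "age filter (<%d y): removed %d observation rows, retained %d",
        min_age,
        removed,
        int(keep.sum()),
    )
    return encounters.loc[keep].reset_index(drop=True)


def window_encounters(
    encounters: pd.DataFrame, scale: str = "year"
) -> dict[WindowLabel, pd.DataFrame]:
    """Partition encounter rows into calendar-year or calendar-month windows."""
    if scale == "year":
        keys = [(int(y),) for y in encounters["year"]]
    elif scale == "month":
        keys = [
            (int(y), int(m))
            for y, m in zip(encounters["year"], encounters["month"])
        ]
    else:
        raise ValueError(f"unknown scale: {scale!r}")
    out: dict[WindowLabel, pd.DataFrame] = {}
    frame = encounters.assign(_window=keys)
    for label, sub in frame.groupby("_window", sort=True):
        out[label] = sub.drop(columns="_window").reset_index(drop=True)
    return out


def drop_sparse_windows(
    windows: dict[WindowLabel, pd.DataFrame], min_encounters: int = 10
) -> dict[WindowLabel, pd.DataFrame]:
    """Remove windows with fewer than ``min_encounters`` distinct encounters."""
    kept = {
        label: sub
        for label, sub in windows.items()
        if sub["encounter_id"].nunique() >= min_encounters
    }
    logger.info(
        "sparse-window filter (<%d encounters): removed %d windows, retained %d",
        min_encounters,
        len(windows) - len(kept),
        len(kept),
    )
    return kept


def group_by_individual(window: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Binary encounters-by-individuals matrix for one window."""
    if window.empty:
        raise ValueError("empty window")
    ids = sorted(window["individual_id"].unique())
    enc_ids = sorted(window["encounter_id"].unique())
    col = {ind: j for j, ind in enumerate(ids)}
    row = {e: i for i, e in enumerate(enc_ids)}
    gbi = np.zeros((len(enc_ids), len(ids)), dtype=np.int8)
    for e, ind in zip(window["encounter_id"], window["individual_id"]):
        gbi[row[e], col[ind]] = 1
    return gbi, ids


def build_network(window: pd.DataFrame, label: WindowLabel = ()) -> SocialNetwork:
    """Build the SRI network for one window of encounters.

    Every individual sighted in the window appears as a node; masking of
    rarely seen individuals happens downstream and never alters the network.
    """
    gbi, ids = group_by_individual(window)
    gbi_f = gbi.astype(float)
    together = gbi_f.T @ gbi_f  # x_ij; diagonal = n_i
    sightings = np.diag(together).copy()
    denom = sightings[:, None] + sightings[None, :] - together
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(denom > 0, together / denom, 0.0)
    np.fill_diagonal(weights, 0.0)
    np.fill_diagonal(together, 0.0)
    return SocialNetwork(
        window=label,
        ids=ids,
        weights=weights,
        sightings=sightings,
        together=together,
        n_encounters=int(window["encounter_id"].nunique()),
    )


def build_window_networks(
    windows: dict[WindowLabel, pd.DataFrame]
) -> dict[WindowLabel, SocialNetwork]:
    return {label: build_network(sub, label) for label, sub in windows.items()}


def mask_rare_individuals(
    metric_rows: pd.DataFrame, min_sightings: int = 5
) -> pd.DataFrame:
    """Flag metric rows of individuals seen fewer than ``min_sightings`` times
    in their window. Flags exclude rows from model fitting only; the networks
    (and therefore other individuals' metrics) are untouched.
    """
    out = metric_rows.copy()
    enough = out["n_sightings"] >= min_sightings
    out["included"] = out["included"] & enough
    logger.info(
        "sighting mask (<%d): flagged %d rows excluded, %d remain included",
        min_sightings,
        int((~enough).sum()),
        int(out["included"].sum()),
    )
    return out


def write_edge_list(network: SocialNetwork, path: str) -> None:
    rows = []
    n = network.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            if network.weights[i, j] > 0:
                rows.append(
                    (
                        network.ids[i],
                        network.ids[j],
                        int(network.together[i, j]),
                        int(network.sightings[i]),
                        int(network.sightings[j]),
                        network.weights[i, j],
                    )
                )
    pd.DataFrame(rows, columns=["i", "j", "x_ij", "n_i", "n_j", "sri"]).to_csv(
        path, index=False
    )


def write_graphml(network: SocialNetwork, path: str) -> None:
    """GraphML export for interoperability with other network tools."""
    import networkx as nx

    g = nx.Graph()
    for ind, n_i in zip(network.ids, network.sightings):
        g.add_node(ind, sightings=int(n_i))
    n = network.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            if network.weights[i, j] > 0:
                g.add_edge(
                    network.ids[i],
                    network.ids[j],
                    weight=float(network.weights[i, j]),
                    together=int(network.together[i, j]),
                )
    nx.write_graphml(g, path)


def write_windows_summary(
    all_windows: dict[WindowLabel, pd.DataFrame],
    retained: dict[WindowLabel, pd.DataFrame],
    path: str,
) -> None:
    rows = []
    for label, sub in sorted(all_windows.items()):
        rows.append(
            (
                "-".join(f"{v:02d}" if i else f"{v}" for i, v in enumerate(label)),
                int(sub["encounter_id"].nunique()),
                int(sub["individual_id"].nunique()),
                label in retained,
            )
        )
    pd.DataFrame(
        rows, columns=["window", "n_encounters", "n_nodes", "retained"]
    ).to_csv(path, index=False)
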