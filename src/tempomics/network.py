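"""Class-wise weighted expression networks.

Nodes are classified series; the edge weight between two nodes is the
reciprocal Euclidean distance w_ij = 1/(d_ij + 0.0001) (the offset guards
d = 0). Edges are kept when their weight reaches the one-tailed quantile

    q(N) = 0.8            if N < 500
           1 - 100/N      if N >= 500

of the network's weight distribution (upper tail: smallest distances are the
strongest putative associations). Missing values are mean-imputed per series
for the distance computation only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .spectral import ClassifiedSeries

DISTANCE_OFFSET = 0.0001


class NetworkError(ValueError):
    pass


@dataclass
class TrendNetwork:
    """Weighted network for one class: nodes, retained edges, provenance."""

    time_frame: str
    class_label: str
    nodes: list[dict] = field(default_factory=list)
    edges: list[dict] = field(default_factory=list)
    q: float = 0.0
    threshold: float = 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "edges": self.edges,
            "meta": {
                "time_frame": self.time_frame,
                "class": self.class_label,
                "N": self.n_nodes,
                "q": self.q,
                "threshold": self.threshold,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrendNetwork":
        meta = d["meta"]
        return cls(
            time_frame=meta["time_frame"],
            class_label=meta["class"],
            nodes=list(d["nodes"]),
            edges=list(d["edges"]),
            q=meta["q"],
            threshold=meta["threshold"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrendNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))


def mean_impute(values: np.ndarray) -> np.ndarray:
    """Replace each series' missing values with its observed mean."""
    out = np.array(values, dtype=float)
    for i, row in enumerate(out):
        nan = np.isnan(row)
        if nan.all():
            raise NetworkError(f"series {i} is fully missing; cannot impute")
        row[nan] = row[~nan].mean()
    return out


def pairwise_weights(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric weight and distance matrices over complete series.

    w_ij = 1/(d_ij + 0.0001) with Euclidean d_ij; the diagonal is excluded
    (set to 0 weight / NaN distance).
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise NetworkError("pairwise_weights requires imputed (complete) series")
    if x.ndim != 2:
        raise NetworkError("expected a 2-D series matrix")
    d = squareform(pdist(x))
    w = 1.0 / (d + DISTANCE_OFFSET)
    np.fill_diagonal(w, 0.0)
    np.fill_diagonal(d, np.nan)
    return w, d


def edge_quantile(n_nodes: int) -> float:
    """Node-count-dependent one-tailed quantile level for edge filtering."""
    if n_nodes < 2:
        raise NetworkError(f"a network needs >= 2 nodes, got {n_nodes}")
    if n_nodes < 500:
        return 0.8
    return 1.0 - 100.0 / n_nodes


def build_network(
    members: list[ClassifiedSeries], time_frame: str, class_label: str | None = None
) -> TrendNetwork:
    """Impute, weight, and quantile-filter one class into a network.

    The threshold is the empirical q(N) quantile (linear interpolation) of the
    upper-triangle weights; edges with weight >= threshold are retained (ties
    kept). Group/subgroup annotations are carried on the nodes for coloring.
    """
    n = len(members)
    if n < 2:
        raise NetworkError(f"a network needs >= 2 nodes, got {n}")
    class_label = class_label or members[0].class_label
    x = mean_impute(np.vstack([r.values for r in members]))
    w, d = pairwise_weights(x)
    iu, ju = np.triu_indices(n, k=1)
    weights = w[iu, ju]
    q = edge_quantile(n)
    threshold = float(np.quantile(weights, q))
    keep = weights >= threshold
    keys = [f"{r.omic}:{r.analyte_id}" for r in members]
    nodes = [
        {
            "id": keys[i],
            "omic": members[i].omic,
            "class": members[i].class_label,
            "group": members[i].group,
            "subgroup": members[i].subgroup,
        }
        for i in range(n)
    ]
    edges = [
        {
            "source": keys[i],
            "target": keys[j],
            "weight": float(w[i, j]),
            "distance": float(d[i, j]),
        }
        for i, j in zip(iu[keep], ju[keep])
    ]
    return TrendNetwork(
        time_frame=time_frame,
        class_label=class_label,
        nodes=nodes,
        edges=edges,
        q=q,
        threshold=threshold,
    )
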