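"""Two-tier within-class clustering.

Tier one groups series by the shape of their autocorrelation vectors
(lags 1..n); tier two splits each group into subgroups by intensity shape,
which separates phase/sense (x vs -x) that the autocorrelations cannot see.
Agglomerative (average linkage, Euclidean), with the cluster count chosen by
maximum mean silhouette over k = 2..min(max_k, m-1). Labels are ordered by
decreasing size (ties: lexicographically smallest member id) so assignments
depend only on the member set, not input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .config import ClusterSettings
from .spectral import ClassifiedSeries, ClassifiedSet

_ZERO_SPREAD = 1e-12


@dataclass
class GroupAssignment:
    """Group/subgroup membership for one class."""

    class_label: str
    groups: dict[str, list[str]] = field(default_factory=dict)  # G# -> member ids
    subgroups: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        all_members = [m for ms in self.groups.values() for m in ms]
        if len(all_members) != len(set(all_members)):
            raise AssertionError("groups do not partition the class")
        for (g, _s), members in self.subgroups.items():
            if not set(members) <= set(self.groups[g]):
                raise AssertionError(f"subgroup members outside group {g}")
        for g, members in self.groups.items():
            sub = [m for (gg, _s), ms in self.subgroups.items() if gg == g for m in ms]
            if sorted(sub) != sorted(members):
                raise AssertionError(f"subgroups do not partition group {g}")


def _order_clusters(labels: np.ndarray, ids: list[str]) -> list[list[int]]:
    """Cluster index lists ordered by decreasing size, ties by smallest id."""
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    return sorted(
        clusters.values(), key=lambda idx: (-len(idx), min(ids[i] for i in idx))
    )


def _cluster_vectors(
    vectors: np.ndarray, ids: list[str], settings: ClusterSettings
) -> list[list[int]]:
    """Core clustering used by both tiers; returns ordered member-index lists."""
    m = len(ids)
    if m == 0:
        return []
    # sort by id so the outcome is independent of input order
    order = sorted(range(m), key=lambda i: ids[i])
    inv = np.empty(m, dtype=int)
    inv[order] = np.arange(m)
    x = np.asarray(vectors, dtype=float)[order]
    sorted_ids = [ids[i] for i in order]
    if m < 3:
        return [[order[j] for j in range(m)]] if m else []
    d = pdist(x)
    if d.size == 0 or d.max() <= _ZERO_SPREAD * max(1.0, np.abs(x).max()):
        return [list(order)]
    z = linkage(x, method=settings.linkage)
    dmat = squareform(d)
    best_k, best_score, best_labels = 1, -np.inf, None
    for k in range(2, min(settings.max_k, m - 1) + 1):
        labels = fcluster(z, k, criterion="maxclust")
        if np.unique(labels).size < 2:
            continue
        if m > settings.silhouette_subsample:
            sub = np.arange(settings.silhouette_subsample)  # id-sorted: deterministic
            if np.unique(labels[sub]).size < 2:
                continue
            score = silhouette_score(
                dmat[np.ix_(sub, sub)], labels[sub], metric="precomputed"
            )
        else:
            score = silhouette_score(dmat, labels, metric="precomputed")
        if score > best_score + 1e-12:
            best_k, best_score, best_labels = k, score, labels
    if best_labels is None or best_score < settings.min_silhouette:
        return [list(order)]
    ordered = _order_clusters(best_labels, sorted_ids)
    return [[order[j] for j in idx] for idx in ordered]


def group_by_autocorrelation(
    members: list[tuple[str, np.ndarray]], settings: ClusterSettings | None = None
) -> dict[str, list[str]]:
    """Tier one: cluster (id, rho-vector) members on lags 1..n into G# groups."""
    settings = settings or ClusterSettings()
    if not members:
        return {}
    ids = [m[0] for m in members]
    x = np.vstack([np.asarray(m[1], dtype=float)[1:] for m in members])
    clusters = _cluster_vectors(x, ids, settings)
    return {f"G{g + 1}": [ids[i] for i in idx] for g, idx in enumerate(clusters)}


def _impute_for_distance(values: np.ndarray) -> np.ndarray:
    """Per-series mean imputation used only for distance computation."""
    out = np.array(values, dtype=float)
    for row in out:
        nan = np.isnan(row)
        if nan.all():
            raise ValueError("cannot impute a fully-missing series")
        row[nan] = row[~nan].mean()
    return out


def subgroup_by_intensity(
    members: list[tuple[str, np.ndarray]], settings: ClusterSettings | None = None
) -> dict[str, list[str]]:
    """Tier two: cluster (id, series) members on intensities into S# subgroups."""
    settings = settings or ClusterSettings()
    if not members:
        return {}
    ids = [m[0] for m in members]
    x = _impute_for_distance(np.vstack([m[1] for m in members]))
    clusters = _cluster_vectors(x, ids, settings)
    return {f"S{s + 1}": [ids[i] for i in idx] for s, idx in enumerate(clusters)}


def cluster_classified(
    classified: ClassifiedSet, settings: ClusterSettings | None = None
) -> list[GroupAssignment]:
    """Run both tiers on every non-empty class and annotate the records.

    Unclassified series are left unannotated. Deterministic: no randomness is
    involved and member order does not matter.
    """
    settings = settings or ClusterSettings()
    by_id: dict[str, ClassifiedSeries] = {}
    for r in classified.records:
        by_id[f"{r.omic}:{r.analyte_id}"] = r
    assignments = []
    for class_label, recs in sorted(classified.by_class().items()):
        if class_label == "unclassified":
            continue
        ga = GroupAssignment(class_label=class_label)
        keyed = [(f"{r.omic}:{r.analyte_id}", r) for r in recs]
        groups = group_by_autocorrelation([(k, r.rho) for k, r in keyed], settings)
        rec_map = dict(keyed)
        for gname, member_ids in groups.items():
            ga.groups[gname] = member_ids
            subs = subgroup_by_intensity(
                [(k, rec_map[k].values) for k in member_ids], settings
            )
            for sname, sub_ids in subs.items():
                ga.subgroups[(gname, sname)] = sub_ids
                for k in sub_ids:
                    by_id[k].group = gname
                    by_id[k].subgroup = sname
        ga.validate()
        assignments.append(ga)
    return assignments
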