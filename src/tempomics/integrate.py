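"""Cross-omics integration: join classified series across omic layers within
one time frame and re-cluster the combined classes."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import ClusterSettings
from .cluster import GroupAssignment, cluster_classified
from .spectral import ClassifiedSeries, ClassifiedSet


class IntegrationError(ValueError):
    pass


@dataclass
class CombinedClass:
    """One class pooled across omics; member keys are ``omic:analyte``."""

    time_frame: str
    class_label: str
    members: list[ClassifiedSeries] = field(default_factory=list)

    @property
    def member_keys(self) -> list[str]:
        return [f"{r.omic}:{r.analyte_id}" for r in self.members]


def join_omics_classes(classified_sets: list[ClassifiedSet]) -> list[CombinedClass]:
    """Pool same-class members across omics within one time frame.

    Ids are namespaced as ``omic:analyte``; counts are preserved exactly
    (no drops, no duplicates). Mixed time frames or timepoint grids error.
    """
    if not classified_sets:
        return []
    frame = classified_sets[0].time_frame
    times = classified_sets[0].times
    combined: dict[str, CombinedClass] = {}
    seen_keys: set[str] = set()
    for cs in classified_sets:
        if cs.time_frame != frame:
            raise IntegrationError(
                f"cannot join time frames {frame!r} and {cs.time_frame!r}"
            )
        if cs.times.size != times.size or not np.allclose(cs.times, times):
            raise IntegrationError("cannot join sets with different timepoint grids")
        for r in cs.records:
            if r.class_label == "unclassified":
                continue
            key = f"{r.omic}:{r.analyte_id}"
            if key in seen_keys:
                raise IntegrationError(f"duplicate member key {key!r}")
            seen_keys.add(key)
            combined.setdefault(
                r.class_label, CombinedClass(frame, r.class_label)
            ).members.append(r)
    return [combined[k] for k in sorted(combined)]


def cluster_combined(
    combined: list[CombinedClass], settings: ClusterSettings | None = None
) -> tuple[ClassifiedSet, list[GroupAssignment]]:
    """Two-tier clustering of the pooled classes (same procedure as per-omic).

    Returns the merged :class:`ClassifiedSet` (records annotated in place with
    combined group/subgroup labels) and the per-class assignments.
    """
    if not combined:
        return ClassifiedSet(time_frame="", times=np.empty(0)), []
    frame = combined[0].time_frame
    # work on copies so combined labels never clobber the per-omic ones
    records = [replace(r, group=None, subgroup=None) for cc in combined for r in cc.members]
    n_times = records[0].values.size
    merged = ClassifiedSet(
        time_frame=frame, times=np.arange(n_times, dtype=float), records=records
    )
    assignments = cluster_classified(merged, settings)
    return merged, assignments
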