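"""Objective clustering: MOTUs as single-linkage components at a
p-distance threshold.

A pair of specimens links when their p-distance is at or below the
threshold; MOTUs are the connected components of the resulting graph
(transitive closure, so chains of near neighbours merge). Pairs flagged
invalid for low overlap never create links. This linkage rule makes
partitions at increasing thresholds strictly nested, which the
stability classification relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distance import DistanceMatrix


@dataclass(frozen=True)
class Partition:
    """Assignment of every specimen to exactly one MOTU.

    MOTU ids are canonical: each MOTU is named after its
    lexicographically smallest member, so the partition is invariant
    under permutation of the input order.
    """

    method: str
    threshold: float | None
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty partition")

    @property
    def ids(self) -> list[str]:
        return list(self.assignment)

    def clusters(self) -> dict[str, list[str]]:
        """motu_id -> sorted member ids, motus ordered by id."""
        out: dict[str, list[str]] = {}
        for sid, motu in self.assignment.items():
            out.setdefault(motu, []).append(sid)
        return {m: sorted(out[m]) for m in sorted(out)}

    def cluster_sets(self) -> set[frozenset[str]]:
        sets: dict[str, set[str]] = {}
        for sid, motu in self.assignment.items():
            sets.setdefault(motu, set()).add(sid)
        return {frozenset(s) for s in sets.values()}

    @property
    def n_motus(self) -> int:
        return len(set(self.assignment.values()))

    def sizes(self) -> list[int]:
        return sorted(len(m) for m in self.clusters().values())

    def restricted(self, ids: list[str] | set[str]) -> "Partition":
        keep = {sid: m for sid, m in self.assignment.items() if sid in set(ids)}
        if not keep:
            raise ValueError("restriction leaves no specimens")
        return Partition(self.method, self.threshold, _canonicalize(keep))


def _canonicalize(assignment: dict[str, str]) -> dict[str, str]:
    """Rename every MOTU after its lexicographically smallest member."""
    rep: dict[str, str] = {}
    for sid, motu in assignment.items():
        if motu not in rep or sid < rep[motu]:
            rep[motu] = sid
    return {sid: rep[motu] for sid, motu in assignment.items()}


def objective_cluster(matrix: DistanceMatrix, threshold: float) -> Partition:
    """Cluster a distance matrix into MOTUs at one p-distance threshold."""
    if matrix.n == 0:
        raise ValueError("empty distance matrix")
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    adj = matrix.links(threshold)
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    assignment = {sid: str(lab) for sid, lab in zip(matrix.ids, labels)}
    return Partition(
        method="objective_clustering",
        threshold=threshold,
        assignment=_canonicalize(assignment),
    )


@dataclass(frozen=True)
class ThresholdProfile:
    """Per-threshold MOTU / singleton / doubleton counts."""

    rows: list[tuple[float, int, int, int]]  # threshold, n_motus, n_singletons, n_doubletons

    def motu_counts(self) -> list[int]:
        return [r[1] for r in self.rows]


def threshold_profile(
    matrix: DistanceMatrix, thresholds: list[float]
) -> ThresholdProfile:
    """MOTU counts over an ascending threshold grid.

    Counts are non-increasing in the threshold (single-linkage
    nestedness).
    """
    if sorted(thresholds) != list(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        part = objective_cluster(matrix, t)
        sizes = part.sizes()
        rows.append(
            (t, len(sizes), sum(1 for s in sizes if s == 1), sum(1 for s in sizes if s == 2))
        )
    return ThresholdProfile(rows=rows)


def check_nested(finer: Partition, coarser: Partition) -> bool:
    """True iff every cluster of ``finer`` sits inside one cluster of
    ``coarser``."""
    coarse_of = coarser.assignment
    for members in finer.clusters().values():
        if len({coarse_of[sid] for sid in members}) != 1:
            return False
    return True
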