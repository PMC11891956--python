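"""LIT stability screening and the specimen-examination plan.

Large-scale integrative taxonomy (LIT) inverts the classical workflow:
barcodes are clustered first and morphology is then checked only on a
targeted subsample of specimens per MOTU. Which specimens need checking
depends on how trustworthy a MOTU looks:

* ``singleton`` — one specimen; it is examined by necessity.
* ``stable``    — the MOTU's specimen set is identical at every
  threshold of a grid rising to the base threshold AND its maximum
  internal p-distance is at most 1.5%; two specimens representing the
  most distant haplotypes suffice (one if the MOTU is a single
  haplotype).
* ``instable``  — composition changes somewhere on the grid, or the
  maximum internal distance exceeds 1.5%; the most distant pair is
  examined plus one representative of every "main" haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import Partition, check_nested, objective_cluster
from .distance import DistanceMatrix

#: MOTUs whose max internal p-distance exceeds this are flagged instable.
MAX_INTRA_STABLE = 0.015

#: Default grid of thresholds over which composition must be constant.
DEFAULT_STABILITY_GRID = (0.01, 0.015, 0.02, 0.025, 0.03)

SINGLETON = "singleton"
STABLE = "stable"
INSTABLE = "instable"


@dataclass(frozen=True)
class MOTUClass:
    motu_id: str
    members: tuple[str, ...]
    motu_class: str
    max_intra_distance: float
    composition_stable: bool
    stability_index: float  # fraction of grid thresholds with unchanged composition
    n_haplotypes: int


@dataclass(frozen=True)
class MainHaplotypeRule:
    """Which haplotypes of an instable MOTU count as "main".

    Default: every haplotype with at least ``min_count`` members, and
    always the largest haplotype. ``min_frequency`` (fraction of the
    MOTU) may be used instead of, or on top of, the absolute count.
    """

    min_count: int = 2
    min_frequency: float = 0.0
    always_include_largest: bool = True

    def select(self, groups: list[list[str]], motu_size: int) -> list[list[str]]:
        chosen = [
            g
            for g in groups
            if len(g) >= self.min_count and len(g) / motu_size >= self.min_frequency
        ]
        if self.always_include_largest and groups and groups[0] not in chosen:
            chosen.insert(0, groups[0])
        return chosen


def collapse_haplotypes(
    member_ids: list[str], matrix: DistanceMatrix
) -> list[list[str]]:
    """Group a MOTU's members into haplotypes.

    A haplotype is a set of sequences identical on all mutually
    compared sites, i.e. the zero-distance single-linkage components of
    the MOTU's submatrix. Groups are ordered by size (descending) then
    by smallest member id; members within a group are sorted.
    """
    if len(member_ids) == 1:
        return [list(member_ids)]
    sub = matrix.submatrix(sorted(member_ids))
    part = objective_cluster(sub, 0.0)
    groups = list(part.clusters().values())
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def _max_intra(members: list[str], matrix: DistanceMatrix) -> float:
    if len(members) == 1:
        return 0.0
    sub = matrix.submatrix(sorted(members))
    d = sub.distances
    vals = d[np.triu_indices(sub.n, k=1)]
    vals = vals[~np.isnan(vals)]
    return float(vals.max()) if vals.size else 0.0


def classify_stability(
    grid_partitions: list[Partition],
    base_threshold: float,
    matrix: DistanceMatrix,
) -> list[MOTUClass]:
    """Classify every base-threshold MOTU as singleton/stable/instable.

    ``grid_partitions`` must come from objective clustering on one
    matrix with ascending thresholds whose maximum is
    ``base_threshold``; nestedness is verified and a violation is a
    hard error (it indicates foreign partitions were mixed in).
    """
    parts = sorted(grid_partitions, key=lambda p: p.threshold)
    if abs(parts[-1].threshold - base_threshold) > 1e-12:
        raise ValueError("base_threshold must be the maximum of the grid")
    for finer, coarser in zip(parts, parts[1:]):
        if not check_nested(finer, coarser):
            raise ValueError(
                f"partitions at {finer.threshold} and {coarser.threshold} are not nested"
            )
    base = parts[-1]
    out: list[MOTUClass] = []
    grid_sets = [p.cluster_sets() for p in parts]
    for motu_id, members in base.clusters().items():
        mset = frozenset(members)
        unchanged = sum(1 for s in grid_sets if mset in s)
        comp_stable = unchanged == len(parts)
        max_d = _max_intra(members, matrix)
        n_hap = len(collapse_haplotypes(members, matrix))
        if len(members) == 1:
            cls = SINGLETON
        elif not comp_stable or max_d > MAX_INTRA_STABLE + 1e-12:
            cls = INSTABLE
        else:
            cls = STABLE
        out.append(
            MOTUClass(
                motu_id=motu_id,
                members=tuple(members),
                motu_class=cls,
                max_intra_distance=max_d,
                composition_stable=comp_stable,
                stability_index=unchanged / len(parts),
                n_haplotypes=n_hap,
            )
        )
    return out


@dataclass(frozen=True)
class ExaminationPlan:
    """Per-MOTU ordered list of (specimen_id, reason) to examine."""

    entries: dict[str, list[tuple[str, str]]]

    @property
    def n_specimens(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def counts_by_class(self, classes: list[MOTUClass]) -> dict[str, int]:
        cls_of = {c.motu_id: c.motu_class for c in classes}
        out = {SINGLETON: 0, STABLE: 0, INSTABLE: 0}
        for motu_id, plan in self.entries.items():
            out[cls_of[motu_id]] += len(plan)
        return out


def _most_distant_pair(
    members: list[str], matrix: DistanceMatrix
) -> tuple[str, str]:
    """Specimen pair at maximum p-distance; lexicographic tie-break."""
    sub = matrix.submatrix(sorted(members))
    d = sub.distances
    best: tuple[str, str] | None = None
    best_d = -1.0
    for i in range(sub.n):
        for j in range(i + 1, sub.n):
            dij = d[i, j]
            if np.isnan(dij):
                continue
            pair = (sub.ids[i], sub.ids[j])
            if dij > best_d + 1e-15 or (abs(dij - best_d) <= 1e-15 and best and pair < best):
                best_d = dij
                best = pair
    if best is None:  # no informative pair: fall back to two smallest ids
        s = sorted(members)
        return s[0], s[1]
    return best


def examination_plan(
    classes: list[MOTUClass],
    matrix: DistanceMatrix,
    main_haplotype_rule: MainHaplotypeRule | None = None,
) -> ExaminationPlan:
    """Specimens to examine per MOTU, with reason tags.

    * singleton: its one specimen.
    * stable: the most distant specimen pair (one specimen if the MOTU
      is a single haplotype).
    * instable: the most distant pair plus one representative of each
      main haplotype not already represented in the plan.
    """
    rule = main_haplotype_rule or MainHaplotypeRule()
    entries: dict[str, list[tuple[str, str]]] = {}
    for c in classes:
        members = sorted(c.members)
        if c.motu_class == SINGLETON:
            entries[c.motu_id] = [(members[0], "singleton")]
            continue
        groups = collapse_haplotypes(members, matrix)
        if len(groups) == 1:
            plan = [(groups[0][0], "main-haplotype")]
        else:
            a, b = _most_distant_pair(members, matrix)
            plan = [(a, "most-distant-pair"), (b, "most-distant-pair")]
        if c.motu_class == INSTABLE:
            covered_groups = {
                idx
                for idx, g in enumerate(groups)
                if any(sid in g for sid, _ in plan)
            }
            for idx, g in enumerate(groups):
                if g in rule.select(groups, len(members)) and idx not in covered_groups:
                    plan.append((g[0], "main-haplotype"))
                    covered_groups.add(idx)
        entries[c.motu_id] = plan
    return ExaminationPlan(entries=entries)
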