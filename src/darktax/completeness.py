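"""Two-batch faunal-completeness statistics.

When specimens arrive in two batches and the first has been revised
taxonomically, the second batch measures how complete that revision
was: which of its MOTUs (in a combined clustering of both batches)
were already represented in batch 1, and what fraction of its
specimens fall into such shared MOTUs. A randomization null reshuffles
specimens into pseudo-batches of the same sizes to show what coverage
pure sampling noise would produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import Partition


@dataclass(frozen=True)
class AbundanceClasses:
    n_motus: int
    n_singletons: int
    n_doubletons: int

    @property
    def singleton_proportion(self) -> float:
        return self.n_singletons / self.n_motus

    @property
    def doubleton_proportion(self) -> float:
        return self.n_doubletons / self.n_motus


@dataclass(frozen=True)
class CoverageReport:
    threshold: float | None
    n_motus_combined: int
    n_motus_occupied_by_batch2: int
    n_shared: int
    n_new: int
    new_motu_specimen_count: int
    new_motus: tuple[str, ...]
    motu_coverage_pct: float
    specimen_coverage_pct: float
    abundance_combined: AbundanceClasses
    abundance_batch1: AbundanceClasses
    abundance_batch2: AbundanceClasses


def abundance_classes(partition: Partition, scope_ids=None) -> AbundanceClasses:
    """Singleton/doubleton counts; ``scope_ids`` restricts the partition
    (batch-restricted scope) before counting."""
    part = partition if scope_ids is None else partition.restricted(scope_ids)
    sizes = part.sizes()
    return AbundanceClasses(
        n_motus=len(sizes),
        n_singletons=sum(1 for s in sizes if s == 1),
        n_doubletons=sum(1 for s in sizes if s == 2),
    )


def coverage_stats(
    partition: Partition,
    batch_of: dict[str, str],
    batch1: str = "1",
    batch2: str = "2",
) -> CoverageReport:
    """Coverage of batch-2 MOTUs and specimens by batch-1 occupancy.

    ``partition`` must be the combined clustering of both batches; a
    MOTU is *shared* if it holds specimens from both batches, *new* if
    it holds only batch-2 specimens.
    """
    ids1 = [s for s in partition.assignment if batch_of.get(s) == batch1]
    ids2 = [s for s in partition.assignment if batch_of.get(s) == batch2]
    if not ids1 or not ids2:
        raise ValueError(f"both batches {batch1!r} and {batch2!r} must be non-empty")
    motus1 = {partition.assignment[s] for s in ids1}
    motus2 = {partition.assignment[s] for s in ids2}
    shared = motus1 & motus2
    new = sorted(motus2 - motus1)
    n2_in_shared = sum(1 for s in ids2 if partition.assignment[s] in shared)
    n2_in_new = len(ids2) - n2_in_shared
    return CoverageReport(
        threshold=partition.threshold,
        n_motus_combined=partition.n_motus,
        n_motus_occupied_by_batch2=len(motus2),
        n_shared=len(shared),
        n_new=len(new),
        new_motu_specimen_count=n2_in_new,
        new_motus=tuple(new),
        motu_coverage_pct=100.0 * len(shared) / len(motus2),
        specimen_coverage_pct=100.0 * n2_in_shared / len(ids2),
        abundance_combined=abundance_classes(partition),
        abundance_batch1=abundance_classes(partition, ids1),
        abundance_batch2=abundance_classes(partition, ids2),
    )


@dataclass(frozen=True)
class RandomizationResult:
    n_reps: int
    seed: int
    motu_coverage: np.ndarray  # per-rep, percent
    specimen_coverage: np.ndarray  # per-rep, percent

    @property
    def motu_coverage_mean(self) -> float:
        return float(self.motu_coverage.mean())

    @property
    def motu_coverage_sd(self) -> float:
        return float(self.motu_coverage.std(ddof=1))

    @property
    def specimen_coverage_mean(self) -> float:
        return float(self.specimen_coverage.mean())

    @property
    def specimen_coverage_sd(self) -> float:
        return float(self.specimen_coverage.std(ddof=1))


def randomization_test(
    partition: Partition,
    sizes: tuple[int, int],
    n_reps: int = 100,
    seed: int = 0,
) -> RandomizationResult:
    """Coverage null: random reassignment of specimens to two batches.

    Each replicate draws ``sizes[0]`` specimens uniformly without
    replacement as pseudo-batch-1 (the rest form pseudo-batch-2) and
    recomputes both coverage percentages on the fixed combined
    partition — batch labels do not affect distances, so re-clustering
    is unnecessary. Deterministic for a fixed seed.
    """
    n1, n2 = sizes
    ids = list(partition.assignment)
    if n1 + n2 != len(ids):
        raise ValueError(f"sizes {sizes} do not sum to {len(ids)} specimens")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates for a standard deviation")
    motu_labels = sorted(set(partition.assignment.values()))
    motu_idx = {m: i for i, m in enumerate(motu_labels)}
    motu_of = np.array([motu_idx[partition.assignment[s]] for s in ids])
    k = len(motu_labels)
    rng = np.random.default_rng(seed)
    motu_cov = np.empty(n_reps)
    spec_cov = np.empty(n_reps)
    for rep in range(n_reps):
        perm = rng.permutation(len(ids))
        in1 = np.zeros(len(ids), dtype=bool)
        in1[perm[:n1]] = True
        occ1 = np.bincount(motu_of[in1], minlength=k) > 0
        occ2_counts = np.bincount(motu_of[~in1], minlength=k)
        occ2 = occ2_counts > 0
        shared = occ1 & occ2
        motu_cov[rep] = 100.0 * shared.sum() / occ2.sum()
        spec_cov[rep] = 100.0 * occ2_counts[shared].sum() / n2
    return RandomizationResult(
        n_reps=n_reps, seed=seed, motu_coverage=motu_cov, specimen_coverage=spec_cov
    )
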