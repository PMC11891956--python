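"""Morphospecies/MOTU congruence: match ratios, per-species status and
split/fuse conflict resolution across a threshold grid.

Morphology is only available for the examined subsample, so congruence
is judged on examined specimens: a morphospecies is congruent with a
partition when its examined specimens occupy exactly one MOTU and that
MOTU contains no other morphospecies. A morphospecies spread over
several pure MOTUs is *split*; a MOTU holding several morphospecies
marks them as *fused*; a morphospecies that is both is in *conflict*.

The match ratio between two partitions is

    match_ratio = 2 * N_congruent / (N_a + N_b)

where N_congruent counts clusters forming identical specimen sets in
both (an F1-style agreement measure; 1 iff identical partitions).

Resolution follows the LIT rules: a fused MOTU is re-examined at finer
thresholds to see whether it splits into morphospecies-pure clusters; a
split morphospecies is re-examined at coarser thresholds to see whether
its MOTUs fuse into one pure cluster. The nearest threshold restoring
congruence wins (minimal perturbation); if none does, the case is a
genuine conflict and its specimens stay unassigned to species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cluster import Partition

CONGRUENT = "congruent"
SPLIT = "split"
FUSED = "fused"
CONFLICT = "conflict"
UNTESTED = "untested"


def match_ratio_from_counts(n_a: int, n_b: int, n_congruent: int) -> float:
    """2*Nc/(Na+Nb) from pre-tabulated cluster counts."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("cluster counts must be positive")
    if n_congruent > min(n_a, n_b):
        raise ValueError("n_congruent cannot exceed either cluster count")
    return 2 * n_congruent / (n_a + n_b)


@dataclass(frozen=True)
class MatchRatioResult:
    n_a: int
    n_b: int
    n_congruent: int
    ratio: float


def match_ratio(partition_a: Partition, partition_b: Partition) -> MatchRatioResult:
    """Agreement between two partitions on their shared specimen set."""
    shared = set(partition_a.assignment) & set(partition_b.assignment)
    if not shared:
        raise ValueError("partitions share no specimens")
    sets_a = partition_a.restricted(shared).cluster_sets()
    sets_b = partition_b.restricted(shared).cluster_sets()
    n_congruent = len(sets_a & sets_b)
    return MatchRatioResult(
        n_a=len(sets_a),
        n_b=len(sets_b),
        n_congruent=n_congruent,
        ratio=match_ratio_from_counts(len(sets_a), len(sets_b), n_congruent),
    )


@dataclass
class SpeciesStatuses:
    """Per-morphospecies status plus MOTUs with no examined specimen."""

    status: dict[str, str]  # morphospecies -> congruent/split/fused/conflict
    motus_of: dict[str, set[str]]  # morphospecies -> MOTUs holding it
    labels_in_motu: dict[str, set[str]]  # MOTU -> examined labels inside
    untested_motus: list[str]


def classify_species(partition: Partition, morph: dict[str, str]) -> SpeciesStatuses:
    """Status of every morphospecies against one MOTU partition.

    Only examined specimens (those with a morphospecies label) enter
    the evaluation; MOTUs without any examined specimen are reported as
    untested.
    """
    examined = {sid: lab for sid, lab in morph.items() if sid in partition.assignment}
    if not examined:
        raise ValueError("no examined specimens overlap the partition")
    motus_of: dict[str, set[str]] = {}
    labels_in: dict[str, set[str]] = {}
    for sid, lab in examined.items():
        motu = partition.assignment[sid]
        motus_of.setdefault(lab, set()).add(motu)
        labels_in.setdefault(motu, set()).add(lab)
    status: dict[str, str] = {}
    for lab, motus in motus_of.items():
        is_split = len(motus) > 1
        is_fused = any(len(labels_in[m]) > 1 for m in motus)
        if is_split and is_fused:
            status[lab] = CONFLICT
        elif is_split:
            status[lab] = SPLIT
        elif is_fused:
            status[lab] = FUSED
        else:
            status[lab] = CONGRUENT
    untested = [m for m in partition.clusters() if m not in labels_in]
    return SpeciesStatuses(
        status=status,
        motus_of=motus_of,
        labels_in_motu=labels_in,
        untested_motus=untested,
    )


@dataclass(frozen=True)
class ResolutionEvent:
    action: str  # "split" or "fuse"
    morphospecies: tuple[str, ...]
    motus: tuple[str, ...]  # base MOTUs affected
    threshold: float


@dataclass
class CongruenceReport:
    """Outcome of integrating morphospecies with the base partition."""

    base_threshold: float | None
    statuses: SpeciesStatuses
    match: MatchRatioResult | None
    species_of: dict[str, str | None]  # specimen -> accepted species (None = conflict)
    log: list[ResolutionEvent]

    @property
    def n_species(self) -> int:
        return len({s for s in self.species_of.values() if s is not None})

    def status_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.statuses.status.values():
            out[s] = out.get(s, 0) + 1
        return out


def _pure_in(partition: Partition, label: str, morph: dict[str, str]) -> str | None:
    """The single pure MOTU holding ``label``'s examined specimens, or None."""
    examined = {s: l for s, l in morph.items() if s in partition.assignment}
    motus = {partition.assignment[s] for s, l in examined.items() if l == label}
    if len(motus) != 1:
        return None
    motu = next(iter(motus))
    members_labels = {
        examined[s]
        for s, m in partition.assignment.items()
        if m == motu and s in examined
    }
    return motu if members_labels == {label} else None


def resolve_conflicts(
    grid_partitions: list[Partition],
    morph: dict[str, str],
    base: Partition,
) -> CongruenceReport:
    """Resolve split/fused morphospecies against a threshold grid.

    Returns the accepted species partition: congruent morphospecies
    absorb all (examined and unexamined) specimens of their MOTU(s);
    untested MOTUs keep their MOTU id as a putative species; specimens
    of unresolvable conflicts map to ``None``.
    """
    grid = sorted(grid_partitions, key=lambda p: p.threshold)
    finer = [p for p in grid if p.threshold < (base.threshold or 0) - 1e-12]
    coarser = [p for p in grid if p.threshold > (base.threshold or 0) + 1e-12]
    st = classify_species(base, morph)
    species_of: dict[str, str | None] = {}
    log: list[ResolutionEvent] = []
    handled_motus: set[str] = set()
    handled_labels: set[str] = set()

    # Fused MOTUs: seek a finer threshold splitting the MOTU into pure
    # clusters, one per contained morphospecies (nearest threshold first).
    for motu, labels in st.labels_in_motu.items():
        if len(labels) <= 1:
            continue
        members = base.clusters()[motu]
        # A label reaching outside this MOTU cannot be fixed by splitting it.
        fixable = all(st.motus_of[lab] == {motu} for lab in labels)
        resolved = False
        if fixable:
            for part in reversed(finer):  # nearest (coarsest of the finer) first
                sub = part.restricted(members)
                sub_st = classify_species(sub, {s: l for s, l in morph.items() if s in set(members)})
                if all(v == CONGRUENT for v in sub_st.status.values()):
                    for lab in labels:
                        sub_motu = next(iter(sub_st.motus_of[lab]))
                        for sid in sub.clusters()[sub_motu]:
                            species_of[sid] = lab
                    # sub-clusters with no examined specimen: putative species
                    for um in sub_st.untested_motus:
                        for sid in sub.clusters()[um]:
                            species_of[sid] = f"motu:{um}"
                    log.append(
                        ResolutionEvent(
                            action="split",
                            morphospecies=tuple(sorted(labels)),
                            motus=(motu,),
                            threshold=part.threshold,
                        )
                    )
                    resolved = True
                    break
        if not resolved:
            for sid in members:
                species_of[sid] = None
        handled_motus.add(motu)
        handled_labels |= labels

    # Split morphospecies: seek a coarser threshold where the label's
    # MOTUs fuse into one cluster still pure for that label.
    for lab, motus in st.motus_of.items():
        if lab in handled_labels or len(motus) <= 1:
            continue
        resolved = False
        for part in coarser:  # nearest (finest of the coarser) first
            target = _pure_in(part, lab, morph)
            if target is not None:
                fused_members = part.clusters()[target]
                fused_base_motus = sorted({base.assignment[s] for s in fused_members})
                for sid in fused_members:
                    species_of[sid] = lab
                log.append(
                    ResolutionEvent(
                        action="fuse",
                        morphospecies=(lab,),
                        motus=tuple(fused_base_motus),
                        threshold=part.threshold,
                    )
                )
                handled_motus.update(fused_base_motus)
                resolved = True
                break
        if not resolved:
            for m in motus:
                for sid in base.clusters()[m]:
                    species_of[sid] = None
                handled_motus.add(m)
        handled_labels.add(lab)

    # Remaining MOTUs: congruent morphospecies or untested putative species.
    for motu, members in base.clusters().items():
        if motu in handled_motus:
            continue
        labels = st.labels_in_motu.get(motu)
        if labels:
            lab = next(iter(labels))
            name = lab if st.status.get(lab) == CONGRUENT else None
        else:
            name = f"motu:{motu}"
        for sid in members:
            species_of.setdefault(sid, name)

    morph_part = Partition(
        method="morphospecies",
        threshold=None,
        assignment={s: l for s, l in morph.items() if s in base.assignment},
    ) if any(s in base.assignment for s in morph) else None
    match = match_ratio(base, morph_part) if morph_part else None
    return CongruenceReport(
        base_threshold=base.threshold,
        statuses=st,
        match=match,
        species_of=species_of,
        log=log,
    )
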