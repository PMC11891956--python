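import pytest

from darktax import (
    classify_species,
    match_ratio,
    match_ratio_from_counts,
    objective_cluster,
    resolve_conflicts,
)
from darktax.cluster import Partition
from darktax.congruence import CONFLICT, CONGRUENT, FUSED, SPLIT


def part(mapping, threshold=0.03, method="objective_clustering"):
    return Partition(method, threshold, mapping)


class TestMatchRatio:
    def test_formula_from_counts(self):
        assert match_ratio_from_counts(115, 117, 113) == pytest.approx(
            2 * 113 / (115 + 117)
        )

    def test_identical_partitions_ratio_one(self):
        a = part({"x": "m1", "y": "m1", "z": "m2"})
        b = part({"x": "A", "y": "A", "z": "B"}, method="morph")
        r = match_ratio(a, b)
        assert r.ratio == 1.0 and r.n_congruent == 2

    def test_one_big_cluster_vs_singletons_is_zero(self):
        n = 5
        a = part({f"s{i}": "m" for i in range(n)})
        b = part({f"s{i}": f"u{i}" for i in range(n)})
        assert match_ratio(a, b).ratio == 0.0

    def test_symmetric_in_arguments(self):
        a = part({"x": "1", "y": "1", "z": "2", "w": "3"})
        b = part({"x": "a", "y": "b", "z": "b", "w": "c"})
        assert match_ratio(a, b).ratio == match_ratio(b, a).ratio

    def test_restricts_to_shared_specimens(self):
        a = part({"x": "1", "y": "1", "z": "2"})
        b = part({"x": "A", "y": "A"})  # morphology examined only x, y
        r = match_ratio(a, b)
        assert r.n_a == 1 and r.n_b == 1 and r.ratio == 1.0

    def test_disjoint_specimen_sets_error(self):
        with pytest.raises(ValueError, match="share"):
            match_ratio(part({"x": "1"}), part({"y": "A"}))

    def test_congruent_bounded_by_smaller_side(self):
        with pytest.raises(ValueError):
            match_ratio_from_counts(3, 5, 4)


class TestClassifySpecies:
    def test_congruent_pure_single_motu(self):
        st = classify_species(part({"a": "M1", "b": "M1"}), {"a": "X", "b": "X"})
        assert st.status == {"X": CONGRUENT}

    def test_split_label_in_two_motus(self):
        st = classify_species(part({"a": "M1", "b": "M2"}), {"a": "X", "b": "X"})
        assert st.status == {"X": SPLIT}

    def test_fused_two_labels_one_motu(self):
        st = classify_species(part({"a": "M1", "b": "M1"}), {"a": "X", "b": "Y"})
        assert st.status == {"X": FUSED, "Y": FUSED}

    def test_conflict_split_and_fused(self):
        st = classify_species(
            part({"a": "M1", "b": "M1", "c": "M2"}),
            {"a": "X", "b": "Y", "c": "X"},
        )
        assert st.status["X"] == CONFLICT

    def test_unexamined_motu_reported_untested(self):
        st = classify_species(
            part({"a": "M1", "b": "M2"}), {"a": "X"}
        )
        assert st.untested_motus == ["M2"]

    def test_no_examined_overlap_error(self):
        with pytest.raises(ValueError):
            classify_species(part({"a": "M1"}), {"zz": "X"})


def make_grid(assignments):
    """assignments: {threshold: {specimen: motu}} -> list of Partitions."""
    return [part(m, threshold=t) for t, m in sorted(assignments.items())]


class TestResolveConflicts:
    def test_split_morphospecies_resolved_by_fuse(self):
        # X spans two base MOTUs that merge (purely) at 5%
        base = part({"a": "A", "b": "A", "c": "C", "d": "D"}, 0.03)
        grid = make_grid(
            {
                0.01: {"a": "A", "b": "B", "c": "C", "d": "D"},
                0.03: base.assignment,
                0.05: {"a": "A", "b": "A", "c": "A", "d": "D"},
            }
        )
        morph = {"a": "X", "c": "X", "d": "W"}
        rep = resolve_conflicts(grid, morph, base)
        assert rep.statuses.status["X"] == SPLIT
        (event,) = [e for e in rep.log if e.action == "fuse"]
        assert event.threshold == 0.05
        assert set(event.motus) == {"A", "C"}
        # all members of the fused 5% cluster inherit X, examined or not
        assert rep.species_of == {"a": "X", "b": "X", "c": "X", "d": "W"}

    def test_fused_motu_resolved_by_split(self):
        # one 3% MOTU holds two morphospecies that separate at 1%
        base = part({"a": "A", "b": "A", "c": "A", "d": "D"}, 0.03)
        grid = make_grid(
            {
                0.01: {"a": "A", "b": "A", "c": "C", "d": "D"},
                0.03: base.assignment,
                0.05: {"a": "A", "b": "A", "c": "A", "d": "A"},
            }
        )
        morph = {"a": "X", "c": "Y", "d": "W"}
        rep = resolve_conflicts(grid, morph, base)
        assert rep.statuses.status["X"] == FUSED and rep.statuses.status["Y"] == FUSED
        (event,) = [e for e in rep.log if e.action == "split"]
        assert event.threshold == 0.01
        assert rep.species_of == {"a": "X", "b": "X", "c": "Y", "d": "W"}

    def test_interleaved_labels_stay_conflict(self):
        # X and Y co-occur in one cluster at every threshold
        base = part({"a": "A", "b": "A", "c": "A"}, 0.03)
        grid = make_grid(
            {
                0.01: {"a": "A", "b": "A", "c": "A"},
                0.03: base.assignment,
                0.05: {"a": "A", "b": "A", "c": "A"},
            }
        )
        morph = {"a": "X", "b": "Y", "c": "X"}
        rep = resolve_conflicts(grid, morph, base)
        assert rep.log == []
        assert rep.species_of == {"a": None, "b": None, "c": None}

    def test_nearest_threshold_wins(self):
        # fused MOTU splits congruently at both 2% and 1%: adopt 2%
        base = part({"a": "A", "b": "A"}, 0.03)
        grid = make_grid(
            {
                0.01: {"a": "A", "b": "B"},
                0.02: {"a": "A", "b": "B"},
                0.03: base.assignment,
            }
        )
        rep = resolve_conflicts(grid, {"a": "X", "b": "Y"}, base)
        (event,) = rep.log
        assert event.action == "split" and event.threshold == 0.02

    def test_untested_motus_kept_as_putative_species(self):
        base = part({"a": "A", "b": "B", "c": "B"}, 0.03)
        rep = resolve_conflicts([base], {"a": "X"}, base)
        assert rep.species_of == {"a": "X", "b": "motu:B", "c": "motu:B"}

    def test_locality_of_resolution(self):
        # resolving the fused MOTU must not touch the unrelated MOTU E
        base = part({"a": "A", "b": "A", "e": "E", "f": "E"}, 0.03)
        grid = make_grid(
            {
                0.01: {"a": "A", "b": "B", "e": "E", "f": "F"},
                0.03: base.assignment,
            }
        )
        morph = {"a": "X", "b": "Y", "e": "Z", "f": "Z"}
        rep = resolve_conflicts(grid, morph, base)
        assert rep.species_of["e"] == "Z" and rep.species_of["f"] == "Z"
        assert rep.species_of["a"] == "X" and rep.species_of["b"] == "Y"

    def test_clean_community_fully_congruent(self, clean_community, clean_matrix):
        parts = [objective_cluster(clean_matrix, t) for t in (0.01, 0.03, 0.05)]
        rep = resolve_conflicts(parts, clean_community.morphospecies, parts[1])
        assert all(s == CONGRUENT for s in rep.statuses.status.values())
        assert rep.match.ratio == 1.0
        assert rep.n_species == clean_community.spec.n_species
        assert rep.log == []
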