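from itertools import combinations

import pytest

from barcogeo import (
    Partition,
    SpecimenRecord,
    adjusted_rand,
    character_report,
    clusterwise_congruence,
    partition_meet,
    validate_species,
    validation_summary,
)
from barcogeo.errors import IntegrityError
from barcogeo.treecheck import MonophylyReport


def brute_force_ari(p1: Partition, p2: Partition) -> float:
    """Pair-counting adjusted Rand, straight from the definition."""
    ids = sorted(p1.universe)
    a = b = both = 0
    n_pairs = 0
    for x, y in combinations(ids, 2):
        n_pairs += 1
        s1 = p1.assignment[x] == p1.assignment[y]
        s2 = p2.assignment[x] == p2.assignment[y]
        a += s1
        b += s2
        both += s1 and s2
    expected = a * b / n_pairs if n_pairs else 0.0
    maximum = (a + b) / 2
    if maximum == expected:
        return 1.0
    return (both - expected) / (maximum - expected)


def _mono_all(partition, status="monophyletic"):
    return MonophylyReport(
        status={lab: status for lab in partition.groups()},
        support={lab: None for lab in partition.groups()},
    )


class TestPartitionMeet:
    def test_idempotent(self):
        p = Partition({"a": "X", "b": "X", "c": "Y"})
        assert partition_meet(p, p).cluster_sets() == p.cluster_sets()

    def test_crossing_groups_intersect(self):
        p1 = Partition({"a": "X", "b": "X", "c": "Y"})
        p2 = Partition({"a": "1", "b": "2", "c": "2"})
        meet = partition_meet(p1, p2)
        assert meet.cluster_sets() == {frozenset("a"), frozenset("b"), frozenset("c")}

    def test_singletons_absorb(self):
        p = Partition({"a": "X", "b": "X"})
        singles = Partition({"a": "1", "b": "2"})
        assert partition_meet(p, singles).k == 2

    def test_meet_refines_every_input_and_bounds_k(self):
        p1 = Partition({s: g for s, g in zip("abcdef", "XXYYZZ")})
        p2 = Partition({s: g for s, g in zip("abcdef", "112222")})
        meet = partition_meet(p1, p2)
        assert meet.refines(p1) and meet.refines(p2)
        assert meet.k >= max(p1.k, p2.k)

    def test_universe_mismatch_rejected(self):
        with pytest.raises(IntegrityError):
            partition_meet(Partition({"a": "X"}), Partition({"b": "X"}))


class TestAdjustedRand:
    def test_identical_partitions_score_one(self):
        p = Partition({s: g for s, g in zip("abcde", "XXYYZ")})
        assert adjusted_rand(p, p) == 1.0

    def test_singletons_vs_lump_score_zero(self):
        p1 = Partition({s: s for s in "abcd"})
        p2 = Partition({s: "X" for s in "abcd"})
        assert adjusted_rand(p1, p2) == pytest.approx(0.0)

    def test_agrees_with_pair_counting_oracle(self, rng):
        ids = [f"s{i}" for i in range(12)]
        for _ in range(10):
            p1 = Partition({s: f"g{rng.integers(4)}" for s in ids})
            p2 = Partition({s: f"h{rng.integers(3)}" for s in ids})
            assert adjusted_rand(p1, p2) == pytest.approx(brute_force_ari(p1, p2), abs=1e-12)


class TestClusterwiseCongruence:
    def test_identical_partitions_fully_congruent(self):
        p = Partition({s: g for s, g in zip("abcde", "XXYYZ")}, source="ref")
        report = clusterwise_congruence(p, [Partition(p.assignment, source="o")])
        assert report.n_congruent == p.k

    def test_split_cluster_flagged(self):
        ref = Partition({"a": "G", "b": "G", "c": "G"}, source="ref")
        other = Partition({"a": "1", "b": "1", "c": "2"}, source="geo")
        report = clusterwise_congruence(ref, [other])
        assert report.incongruent_labels == ["G"]
        assert report.n_congruent == 0

    def test_order_of_others_irrelevant(self):
        ref = Partition({s: g for s, g in zip("abcd", "XXYY")})
        o1 = Partition({s: g for s, g in zip("abcd", "1122")})
        o2 = Partition({s: g for s, g in zip("abcd", "1123")})
        r_fwd = clusterwise_congruence(ref, [o1, o2])
        r_rev = clusterwise_congruence(ref, [o2, o1])
        assert r_fwd.n_congruent == r_rev.n_congruent


def _records(values_by_cluster, deformed=(), n_per=2):
    """Two specimens per cluster sharing that cluster's character values."""
    out = []
    for lab, chars in values_by_cluster.items():
        for i in range(n_per):
            sid = f"{lab}_{i}"
            out.append(
                SpecimenRecord(
                    specimen_id=sid,
                    site_id="s",
                    latitude=0.0,
                    longitude=0.0,
                    deformed=sid in deformed,
                    characters=dict(chars),
                )
            )
    return out


def _partition_for(values_by_cluster, n_per=2):
    return Partition(
        {f"{lab}_{i}": lab for lab in values_by_cluster for i in range(n_per)}
    )


class TestCharacterReport:
    def test_distinct_values_stable_and_diagnosable(self):
        vals = {"A": {"pso": "32/033"}, "B": {"pso": "33/044"}}
        rep = character_report(_records(vals), _partition_for(vals))
        assert rep.stability["A"]["pso"] == 1.0
        assert rep.diagnosable_pair("A", "B")

    def test_identical_value_sets_are_morphological_stasis(self):
        vals = {"A": {"pso": "32/033"}, "B": {"pso": "32/033"}}
        rep = character_report(_records(vals), _partition_for(vals))
        assert not rep.diagnosable_pair("A", "B")

    def test_deformed_specimen_excluded_from_statistics(self):
        vals = {"A": {"pso": "32/033"}, "B": {"pso": "33/044"}}
        recs = _records(vals)
        part = _partition_for(vals)
        clean = character_report(recs, part)
        # aberrant value on a deformed specimen must not change anything
        aberrant = [
            SpecimenRecord("A_2", "s", 0.0, 0.0, deformed=True, characters={"pso": "99/999"})
        ]
        part2 = Partition({**part.assignment, "A_2": "A"})
        rep = character_report(recs + aberrant, part2)
        assert rep.values["A"] == clean.values["A"]
        assert rep.stability["A"] == clean.stability["A"]

    def test_no_characters_yields_empty_report(self):
        vals = {"A": {}, "B": {}}
        rep = character_report(_records(vals), _partition_for(vals))
        assert rep.characters == []
        assert not rep.diagnosable_pair("A", "B")


class TestValidateSpecies:
    def _run(self, vals, mono_status=None):
        part = _partition_for(vals)
        recs = _records(vals)
        mono = _mono_all(part)
        if mono_status:
            mono.status.update(mono_status)
        cong = clusterwise_congruence(part, [Partition(part.assignment, source="geo")])
        chars = character_report(recs, part)
        return {v.cluster: v.status for v in validate_species(part, mono, cong, chars)}

    def test_all_criteria_met_everywhere(self):
        vals = {"A": {"pso": "1"}, "B": {"pso": "2"}, "C": {"pso": "3"}}
        assert set(self._run(vals).values()) == {"validated_species"}

    def test_undiagnosable_pair_is_cryptic_rest_validated(self):
        vals = {"A": {"pso": "1"}, "B": {"pso": "1"}, "C": {"pso": "3"}}
        statuses = self._run(vals)
        assert statuses == {
            "A": "cryptic_species",
            "B": "cryptic_species",
            "C": "validated_species",
        }

    def test_non_monophyletic_cluster_unresolved(self):
        vals = {"A": {"pso": "1"}, "B": {"pso": "2"}}
        statuses = self._run(vals, mono_status={"A": "non-monophyletic"})
        assert statuses["A"] == "unresolved"
        assert statuses["B"] == "validated_species"

    def test_summary_counts(self):
        vals = {"A": {"pso": "1"}, "B": {"pso": "1"}, "C": {"pso": "3"}}
        part = _partition_for(vals)
        recs = _records(vals)
        cong = clusterwise_congruence(part, [Partition(part.assignment, source="geo")])
        verdicts = validate_species(part, _mono_all(part), cong, character_report(recs, part))
        assert validation_summary(verdicts) == {
            "validated_species": 1,
            "cryptic_species": 2,
            "unresolved": 0,
        }
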