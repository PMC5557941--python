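"""Cross-method congruence and species validation.

A putative species earns formal recognition only when three criteria agree:
(i) it is a monophyletic lineage on the phylogeny, (ii) its exact specimen
set is recovered by every other delimitation compared (molecular and
geographic congruence), and (iii) it carries a reliable morphological
diagnosis — at least one character stable within the cluster and, for every
other cluster, at least one character whose value sets do not overlap.
Lineages meeting (i) and (ii) but morphologically indistinguishable from
another lineage are *cryptic species*; anything else is unresolved.

Congruence is deliberately cluster-wise (exact specimen-set identity across
partitions), not whole-partition identity: a 22-cluster molecular partition
can share 21 clusters with a 26-cluster geographic one, and the report names
the incongruent remainder.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from sklearn.metrics import adjusted_rand_score

from .errors import IntegrityError
from .io_model import Partition, SpecimenRecord
from .treecheck import MonophylyReport


def _check_universe(p1: Partition, p2: Partition) -> None:
    if p1.universe != p2.universe:
        only1 = sorted(p1.universe - p2.universe)[:5]
        only2 = sorted(p2.universe - p1.universe)[:5]
        raise IntegrityError(f"partition universes differ (e.g. {only1} vs {only2})")


def partition_meet(*partitions: Partition) -> Partition:
    """Common refinement: groups are non-empty intersections across inputs."""
    if len(partitions) < 2:
        raise IntegrityError("meet needs at least two partitions")
    first = partitions[0]
    for p in partitions[1:]:
        _check_universe(first, p)
    keys: Dict[str, Tuple[str, ...]] = {
        sid: tuple(p.assignment[sid] for p in partitions) for sid in first.assignment
    }
    label_of: Dict[Tuple[str, ...], str] = {}
    assignment: Dict[str, str] = {}
    for sid in sorted(keys):
        key = keys[sid]
        if key not in label_of:
            label_of[key] = f"M{len(label_of) + 1}"
        assignment[sid] = label_of[key]
    return Partition(assignment, source="meet:" + "+".join(p.source or "?" for p in partitions))


def adjusted_rand(p1: Partition, p2: Partition) -> float:
    """Adjusted Rand index between two partitions of the same specimens."""
    _check_universe(p1, p2)
    ids = sorted(p1.universe)
    return float(
        adjusted_rand_score(
            [p1.assignment[s] for s in ids], [p2.assignment[s] for s in ids]
        )
    )


@dataclass
class CongruenceReport:
    """Cluster-wise agreement of a reference partition with other methods."""

    reference_source: str
    other_sources: List[str]
    #: reference cluster label -> indices (into others) of disagreeing partitions
    disagreements: Dict[str, List[int]]
    pairwise_ari: Dict[Tuple[str, str], float]
    meet: Partition

    def congruent(self, label: str) -> bool:
        return not self.disagreements[label]

    @property
    def n_congruent(self) -> int:
        return sum(1 for v in self.disagreements.values() if not v)

    @property
    def incongruent_labels(self) -> List[str]:
        return sorted(lab for lab, v in self.disagreements.items() if v)


def clusterwise_congruence(
    reference: Partition, others: Sequence[Partition]
) -> CongruenceReport:
    """Which reference clusters are recovered exactly by every other method."""
    if not others:
        raise IntegrityError("need at least one other partition")
    for p in others:
        _check_universe(reference, p)
    other_sets = [p.cluster_sets() for p in others]
    disagreements: Dict[str, List[int]] = {}
    for label, members in reference.groups().items():
        fs = frozenset(members)
        disagreements[label] = [i for i, s in enumerate(other_sets) if fs not in s]
    all_parts = [reference, *others]
    names = [p.source or f"p{i}" for i, p in enumerate(all_parts)]
    pairwise = {}
    for i in range(len(all_parts)):
        for j in range(i + 1, len(all_parts)):
            pairwise[(names[i], names[j])] = adjusted_rand(all_parts[i], all_parts[j])
    return CongruenceReport(
        reference_source=reference.source,
        other_sources=[p.source for p in others],
        disagreements=disagreements,
        pairwise_ari=pairwise,
        meet=partition_meet(reference, *others),
    )


@dataclass
class CharacterReport:
    """Per-cluster character value multisets, stability and diagnosability.

    Deformed specimens contribute to no statistic. Stability of a character
    within a cluster is the fraction of non-missing values equal to the modal
    value; a cluster pair is diagnosable on a character iff both value sets
    are non-empty and disjoint.
    """

    characters: List[str]
    #: cluster -> character -> Counter of values (deformed excluded)
    values: Dict[str, Dict[str, Counter]]
    #: cluster -> character -> stability in [0, 1] (absent if no data)
    stability: Dict[str, Dict[str, float]]

    def diagnosable(self, cluster_a: str, cluster_b: str, character: str) -> bool:
        va = set(self.values[cluster_a].get(character, ()))
        vb = set(self.values[cluster_b].get(character, ()))
        return bool(va) and bool(vb) and not (va & vb)

    def diagnosable_pair(self, cluster_a: str, cluster_b: str) -> bool:
        return any(self.diagnosable(cluster_a, cluster_b, c) for c in self.characters)


def character_report(
    records: Sequence[SpecimenRecord], partition: Partition
) -> CharacterReport:
    """Tabulate character values per cluster, excluding deformed specimens."""
    by_id = {r.specimen_id: r for r in records}
    missing = partition.universe - set(by_id)
    if missing:
        raise IntegrityError(f"partition specimens without records: {sorted(missing)[:5]}")
    characters: List[str] = []
    seen: Set[str] = set()
    for r in records:
        for c in r.characters:
            if c not in seen:
                seen.add(c)
                characters.append(c)
    values: Dict[str, Dict[str, Counter]] = {}
    for label, members in partition.groups().items():
        per_char: Dict[str, Counter] = {}
        for sid in members:
            rec = by_id[sid]
            if rec.deformed:
                continue
            for c, v in rec.characters.items():
                if v != "":
                    per_char.setdefault(c, Counter())[v] += 1
        values[label] = per_char
    stability = {
        label: {
            c: max(cnt.values()) / sum(cnt.values()) for c, cnt in per_char.items()
        }
        for label, per_char in values.items()
    }
    return CharacterReport(characters=characters, values=values, stability=stability)


@dataclass
class SpeciesValidationRecord:
    """One cluster's verdict under the three-criterion validation rule."""

    cluster: str
    monophyly: bool
    congruence: bool
    morphology: bool
    status: str  #: validated_species | cryptic_species | unresolved

    @staticmethod
    def decide(monophyly: bool, congruence: bool, morphology: bool) -> str:
        if monophyly and congruence:
            return "validated_species" if morphology else "cryptic_species"
        return "unresolved"


def validate_species(
    candidate: Partition,
    monophyly_report: MonophylyReport,
    congruence_report: CongruenceReport,
    characters: CharacterReport,
    stability_floor: float = 1.0,
) -> List[SpeciesValidationRecord]:
    """Combine the three criteria into per-cluster species statuses.

    The morphology flag requires at least one character with stability >=
    ``stability_floor`` in the cluster AND diagnosability against every other
    cluster on at least one character. The default floor of 1.0 demands
    characters with no intraspecific variation; lower it to tolerate rare
    aberrant individuals.
    """
    labels = sorted(candidate.groups())
    for name, keys in (
        ("monophyly report", set(monophyly_report.status)),
        ("congruence report", set(congruence_report.disagreements)),
        ("character report", set(characters.values)),
    ):
        if keys != set(labels):
            raise IntegrityError(f"{name} clusters do not match candidate partition")
    out: List[SpeciesValidationRecord] = []
    for label in labels:
        mono = monophyly_report.is_monophyletic(label)
        cong = congruence_report.congruent(label)
        stable = any(
            s >= stability_floor for s in characters.stability[label].values()
        )
        diagnosable = all(
            characters.diagnosable_pair(label, other) for other in labels if other != label
        )
        morph = stable and diagnosable
        out.append(
            SpeciesValidationRecord(
                cluster=label,
                monophyly=mono,
                congruence=cong,
                morphology=morph,
                status=SpeciesValidationRecord.decide(mono, cong, morph),
            )
        )
    return out


def validation_summary(records: Sequence[SpeciesValidationRecord]) -> Dict[str, int]:
    counts = Counter(r.status for r in records)
    return {
        "validated_species": counts.get("validated_species", 0),
        "cryptic_species": counts.get("cryptic_species", 0),
        "unresolved": counts.get("unresolved", 0),
    }
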