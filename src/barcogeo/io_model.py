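"""Domain types and readers/writers for the delimitation pipeline.

The four carriers are:

* :class:`SpecimenRecord` — one barcoded individual with its collection site,
  coordinates, morphospecies hypothesis, deformity flag and discrete
  morphological characters;
* :class:`AlignedMatrix` — the aligned COI (or other barcode) nucleotide
  matrix over ``{A, C, G, T, -, N}``;
* :class:`Partition` — a total, disjoint assignment of specimens to putative
  species groups; the common currency of every delimitation method;
* :class:`TreeModel` — a phylogeny (built here or imported) whose leaves are
  specimen ids.

File formats are the field's plain-text standards: FASTA for alignments
(via Biopython), CSV/TSV for metadata and partitions (via pandas), newick for
trees (via dendropy).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    CoordinateRangeError,
    DuplicateIdError,
    EmptyInputError,
    IntegrityError,
    ParseError,
    PartitionConflictError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Characters kept verbatim in an alignment; anything else becomes N.
ALIGNMENT_ALPHABET = frozenset("ACGT-N")

_METADATA_COLUMNS = {
    "specimen_id",
    "site_id",
    "latitude",
    "longitude",
    "morphospecies",
    "deformed",
    "characters",
}

_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}
_FALSE_STRINGS = {"false", "0", "no", "n", "f", ""}


def _check_coordinates(latitude: float, longitude: float, context: str = "") -> None:
    if not (-90.0 <= latitude <= 90.0):
        raise CoordinateRangeError(f"latitude {latitude!r} outside [-90, 90] {context}")
    if not (-180.0 <= longitude <= 180.0):
        raise CoordinateRangeError(f"longitude {longitude!r} outside [-180, 180] {context}")


@dataclass
class SpecimenRecord:
    """One barcoded individual.

    ``characters`` maps character name -> discrete value string; values are
    opaque and compared only for equality. A specimen flagged ``deformed``
    (bilateral asymmetry in key diagnostic features) is excluded from all
    character-stability computations downstream.
    """

    specimen_id: str
    site_id: str
    latitude: float
    longitude: float
    morphospecies: str = ""
    deformed: bool = False
    characters: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_coordinates(self.latitude, self.longitude, f"(specimen {self.specimen_id})")


class AlignedMatrix:
    """An aligned nucleotide matrix with one row per specimen.

    Rows are upper-case strings over ``{A, C, G, T, -, N}`` of identical
    length; IUPAC ambiguity codes other than N are collapsed to N on
    construction (K2P with pairwise deletion ignores them anyway).
    """

    def __init__(self, specimen_ids: Sequence[str], rows: Sequence[str]):
        ids = list(specimen_ids)
        if len(ids) != len(rows):
            raise AlignmentShapeError("id count and row count differ")
        if not ids:
            raise EmptyInputError("alignment has no sequences")
        if len(set(ids)) != len(ids):
            seen: Set[str] = set()
            dups = sorted({i for i in ids if i in seen or seen.add(i)})
            raise DuplicateIdError(f"duplicate specimen ids: {dups}")
        cleaned: List[str] = []
        n_ambiguous = 0
        for sid, row in zip(ids, rows):
            if not row:
                raise EmptyInputError(f"empty sequence for {sid}")
            up = row.upper()
            if not set(up) <= ALIGNMENT_ALPHABET:
                n_ambiguous += sum(c not in ALIGNMENT_ALPHABET for c in up)
                up = "".join(c if c in ALIGNMENT_ALPHABET else "N" for c in up)
            cleaned.append(up)
        lengths = {len(r) for r in cleaned}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"unequal aligned lengths: {sorted(lengths)}")
        if n_ambiguous:
            logger.warning("collapsed %d ambiguous bases (non-ACGT-N) to N", n_ambiguous)
        self.specimen_ids: List[str] = ids
        self.rows: List[str] = cleaned
        self.length: int = len(cleaned[0])

    def __len__(self) -> int:
        return len(self.specimen_ids)

    def row(self, specimen_id: str) -> str:
        return self.rows[self.specimen_ids.index(specimen_id)]

    def subset(self, specimen_ids: Sequence[str]) -> "AlignedMatrix":
        index = {s: i for i, s in enumerate(self.specimen_ids)}
        return AlignedMatrix(list(specimen_ids), [self.rows[index[s]] for s in specimen_ids])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.specimen_ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


class Partition:
    """A total, disjoint assignment of specimens to group labels.

    ``source`` is a free-text provenance tag (e.g. ``"gapdelim:P=0.01"``,
    ``"geo:50km"``, ``"import:PTP"``, ``"morphospecies"``).
    """

    def __init__(self, assignment: Mapping[str, str], source: str = ""):
        if not assignment:
            raise EmptyInputError("empty partition")
        self.assignment: Dict[str, str] = dict(assignment)
        self.source = source

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def universe(self) -> frozenset:
        return frozenset(self.assignment)

    def groups(self) -> Dict[str, List[str]]:
        """Group label -> sorted member ids."""
        out: Dict[str, List[str]] = {}
        for sid, lab in self.assignment.items():
            out.setdefault(lab, []).append(sid)
        return {lab: sorted(members) for lab, members in out.items()}

    def cluster_sets(self) -> Set[frozenset]:
        out: Dict[str, set] = {}
        for sid, lab in self.assignment.items():
            out.setdefault(lab, set()).add(sid)
        return {frozenset(m) for m in out.values()}

    def refines(self, other: "Partition") -> bool:
        """True iff every group of self lies inside a single group of other."""
        if self.universe != other.universe:
            return False
        rep: Dict[str, str] = {}
        for sid, lab in self.assignment.items():
            o = other.assignment[sid]
            if rep.setdefault(lab, o) != o:
                return False
        return True

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and self.assignment == other.assignment

    def __repr__(self) -> str:
        return f"Partition(k={self.k}, n={len(self.assignment)}, source={self.source!r})"

    @classmethod
    def from_groups(cls, groups: Mapping[str, Iterable[str]], source: str = "") -> "Partition":
        assignment: Dict[str, str] = {}
        for lab, members in groups.items():
            for sid in members:
                if sid in assignment:
                    raise PartitionConflictError(f"{sid} in groups {assignment[sid]} and {lab}")
                assignment[sid] = lab
        return cls(assignment, source=source)


class TreeModel:
    """A phylogeny with specimen-id leaves, wrapping a dendropy tree.

    Branch lengths and per-internal-node numeric support labels are optional.
    ``outgroup`` names leaves used to root the tree for monophyly checks.
    """

    def __init__(self, tree: dendropy.Tree, outgroup: Optional[Set[str]] = None):
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise DuplicateIdError("duplicate leaf labels in tree")
        if outgroup:
            missing = set(outgroup) - set(labels)
            if missing:
                raise IntegrityError(f"declared outgroup leaves not in tree: {sorted(missing)}")
        self.tree = tree
        self.outgroup: Optional[Set[str]] = set(outgroup) if outgroup else None

    @property
    def leaf_labels(self) -> List[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def is_rooted(self) -> bool:
        """Rooted means a degree-2 seed node (bifurcating root)."""
        return len(self.tree.seed_node.child_nodes()) == 2

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", unquoted_underscores=True,
                                   suppress_rooting=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_alignment(path, format: str = "fasta") -> AlignedMatrix:
    """Read an aligned FASTA into an :class:`AlignedMatrix`."""
    if format != "fasta":
        raise SchemaError(f"unsupported alignment format: {format}")
    ids: List[str] = []
    rows: List[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq))
    if not ids:
        raise EmptyInputError(f"no sequences in {path}")
    return AlignedMatrix(ids, rows)


def _parse_deformed(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise SchemaError(f"unparseable deformed flag: {value!r}")


def _parse_characters(cell: str) -> Dict[str, str]:
    """Parse a ``name=value;name=value`` characters cell."""
    out: Dict[str, str] = {}
    for chunk in str(cell).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise SchemaError(f"character entry without '=': {chunk!r}")
        name, value = chunk.split("=", 1)
        out[name.strip()] = value.strip()
    return out


def read_metadata(path) -> List[SpecimenRecord]:
    """Read a specimen metadata table (CSV or TSV, sniffed by header).

    Required columns: ``specimen_id, site_id, latitude, longitude``.
    Optional: ``morphospecies``, ``deformed`` (defaults false), ``characters``
    (semicolon-separated ``name=value`` pairs). Any further column is treated
    as one discrete character named after the column.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    required = ["specimen_id", "site_id", "latitude", "longitude"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata missing required columns: {missing}")
    extra_char_cols = [c for c in df.columns if c not in _METADATA_COLUMNS]
    records: List[SpecimenRecord] = []
    seen: Set[str] = set()
    for _, row in df.iterrows():
        sid = row["specimen_id"]
        if sid in seen:
            raise DuplicateIdError(f"duplicate specimen_id {sid!r} in metadata")
        seen.add(sid)
        try:
            lat = float(row["latitude"])
            lon = float(row["longitude"])
        except ValueError as exc:
            raise SchemaError(f"non-numeric coordinate for {sid!r}") from exc
        characters: Dict[str, str] = {}
        if "characters" in df.columns and row["characters"]:
            characters.update(_parse_characters(row["characters"]))
        for col in extra_char_cols:
            if row[col] != "":
                characters[col] = row[col]
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                site_id=row["site_id"],
                latitude=lat,
                longitude=lon,
                morphospecies=row.get("morphospecies", ""),
                deformed=_parse_deformed(row.get("deformed", False)),
                characters=characters,
            )
        )
    if not records:
        raise EmptyInputError(f"no rows in {path}")
    return records


def write_metadata(records: Sequence[SpecimenRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "site_id": r.site_id,
                "latitude": repr(r.latitude),
                "longitude": repr(r.longitude),
                "morphospecies": r.morphospecies,
                "deformed": str(r.deformed).lower(),
                "characters": ";".join(f"{k}={v}" for k, v in r.characters.items()),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_partition(path, source: Optional[str] = None) -> Partition:
    """Read a two-column (specimen_id, group) TSV into a :class:`Partition`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise SchemaError("partition table needs two columns: specimen_id, group")
    sid_col, grp_col = df.columns[0], df.columns[1]
    assignment: Dict[str, str] = {}
    for _, row in df.iterrows():
        sid, grp = row[sid_col], row[grp_col]
        if sid in assignment and assignment[sid] != grp:
            raise PartitionConflictError(f"{sid!r} assigned to both {assignment[sid]!r} and {grp!r}")
        assignment[sid] = grp
    return Partition(assignment, source=source if source is not None else f"import:{path}")


def write_partition(partition: Partition, path) -> None:
    df = pd.DataFrame(
        sorted(partition.assignment.items()), columns=["specimen_id", "group"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_tree(path, outgroup: Optional[Iterable[str]] = None) -> TreeModel:
    """Read a newick tree; internal-node labels are kept as support values."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several unrelated classes
        raise ParseError(f"malformed newick in {path}: {exc}") from exc
    if not any(tree.leaf_node_iter()):
        raise EmptyInputError(f"tree in {path} has no leaves")
    return TreeModel(tree, outgroup=set(outgroup) if outgroup else None)


def check_integrity(
    alignment: Optional[AlignedMatrix] = None,
    records: Optional[Sequence[SpecimenRecord]] = None,
    tree: Optional[TreeModel] = None,
) -> Dict[str, List[str]]:
    """Cross-check identifier sets between alignment, metadata and tree.

    Returns a report of every mismatch (never silently drops one); an empty
    report means the inputs are mutually consistent. The tree may contain
    extra leaves (e.g. an outgroup), reported separately.
    """
    report: Dict[str, List[str]] = {}
    ids_a = set(alignment.specimen_ids) if alignment is not None else None
    ids_m = {r.specimen_id for r in records} if records is not None else None
    ids_t = set(tree.leaf_labels) if tree is not None else None
    if ids_a is not None and ids_m is not None:
        report["alignment_not_in_metadata"] = sorted(ids_a - ids_m)
        report["metadata_not_in_alignment"] = sorted(ids_m - ids_a)
    base = ids_a if ids_a is not None else ids_m
    if ids_t is not None and base is not None:
        report["tree_not_in_data"] = sorted(ids_t - base)
        report["data_not_in_tree"] = sorted(base - ids_t)
    return {k: v for k, v in report.items() if v}
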