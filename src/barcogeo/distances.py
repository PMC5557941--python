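"""Kimura two-parameter (K2P) distances with pairwise deletion.

For a pair of aligned rows, only *comparable* sites — those where both rows
carry an unambiguous base (A, C, G or T) — enter the computation. Over those
sites let ``p`` be the proportion of transitions (A<->G, C<->T) and ``q`` the
proportion of transversions. The K2P distance is

    d = -1/2 * ln(1 - 2p - q) - 1/4 * ln(1 - 2q)

in expected substitutions per site. Gaps and N are deleted pairwise: a column
is dropped for a pair only, not for the whole matrix. When a log argument is
non-positive the pair is *saturated* and reported as an error (never a silent
infinity); the caller may opt in to capping such pairs at the largest finite
observed distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    AlignmentShapeError,
    EmptyInputError,
    IncomparablePairError,
    IntegrityError,
    ParameterError,
    SaturationError,
)
from .io_model import AlignedMatrix, Partition

# base codes: A=0, C=1, G=2, T=3, missing (gap/N)=4.
# Transitions connect bases of equal parity (A/G even, C/T odd).
_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c


def encode(row: str) -> np.ndarray:
    """Encode an aligned row as uint8 codes (missing = 4)."""
    return _CODE[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]


def encode_matrix(alignment: AlignedMatrix) -> np.ndarray:
    return np.vstack([encode(r) for r in alignment.rows])


def _k2p_from_counts(ts: float, tv: float, m: float) -> float:
    p, q = ts / m, tv / m
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError([])
    return -0.5 * float(np.log(w1)) - 0.25 * float(np.log(w2))


def k2p_distance(row_a: str, row_b: str) -> Tuple[float, int]:
    """K2P distance and comparable-site count for two aligned rows.

    Raises :class:`IncomparablePairError` if no site is comparable and
    :class:`SaturationError` if the distance correction diverges.
    """
    if len(row_a) != len(row_b):
        raise AlignmentShapeError("rows differ in length")
    a, b = encode(row_a.upper()), encode(row_b.upper())
    comp = (a < 4) & (b < 4)
    m = int(comp.sum())
    if m == 0:
        raise IncomparablePairError([("row_a", "row_b")])
    diff = comp & (a != b)
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int(diff.sum()) - ts
    try:
        d = _k2p_from_counts(ts, tv, m)
    except SaturationError:
        raise SaturationError([("row_a", "row_b")]) from None
    return d, m


@dataclass
class DistanceMatrix:
    """Symmetric K2P distances (substitutions/site) among specimens."""

    specimen_ids: List[str]
    d: np.ndarray
    comparable_sites: np.ndarray
    #: pairs (id_a, id_b) whose K2P correction saturated (capped or raised).
    saturated_pairs: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.specimen_ids)
        if self.d.shape != (n, n):
            raise IntegrityError("distance matrix shape does not match id count")

    @property
    def n(self) -> int:
        return len(self.specimen_ids)

    def index(self) -> Dict[str, int]:
        return {s: i for i, s in enumerate(self.specimen_ids)}

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in row-major pair order."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def submatrix(self, specimen_ids: Sequence[str]) -> "DistanceMatrix":
        idx = self.index()
        sel = np.array([idx[s] for s in specimen_ids])
        return DistanceMatrix(
            list(specimen_ids),
            self.d[np.ix_(sel, sel)].copy(),
            self.comparable_sites[np.ix_(sel, sel)].copy(),
        )

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.specimen_ids, columns=self.specimen_ids).to_csv(
            path, sep="\t", float_format="%.8f"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        d = df.to_numpy(dtype=float)
        if not np.allclose(d, d.T):
            raise IntegrityError(f"distance matrix in {path} is not symmetric")
        return cls(ids, d, np.ones_like(d, dtype=np.int64))


def distance_matrix(alignment: AlignedMatrix, on_saturation: str = "raise") -> DistanceMatrix:
    """All-pairs K2P distances with pairwise deletion.

    Per-pair failures are collected over the whole matrix and reported
    together. ``on_saturation='raise'`` (default) raises a
    :class:`SaturationError` listing every saturated pair;
    ``'cap'`` replaces them by the largest finite observed distance and
    records them in ``saturated_pairs``. Incomparable pairs always raise.
    """
    if on_saturation not in ("raise", "cap"):
        raise ParameterError(f"on_saturation must be 'raise' or 'cap', got {on_saturation!r}")
    n = len(alignment)
    if n < 2:
        raise ParameterError("need at least 2 specimens for a distance matrix")
    codes = encode_matrix(alignment)
    valid = codes < 4
    parity = codes & 1
    d = np.zeros((n, n), dtype=float)
    msites = np.zeros((n, n), dtype=np.int64)
    incomparable: List[Tuple[str, str]] = []
    saturated: List[Tuple[str, str]] = []
    for i in range(n - 1):
        comp = valid[i] & valid[i + 1 :]
        m = comp.sum(axis=1)
        diff = comp & (codes[i] != codes[i + 1 :])
        ts = (diff & (parity[i] == parity[i + 1 :])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        msites[i, i + 1 :] = m
        with np.errstate(divide="ignore", invalid="ignore"):
            p = ts / m
            q = tv / m
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            di = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        for j_off in np.nonzero(m == 0)[0]:
            incomparable.append((alignment.specimen_ids[i], alignment.specimen_ids[i + 1 + j_off]))
        bad = (m > 0) & ((w1 <= 0.0) | (w2 <= 0.0))
        for j_off in np.nonzero(bad)[0]:
            saturated.append((alignment.specimen_ids[i], alignment.specimen_ids[i + 1 + j_off]))
        di[bad] = np.nan
        d[i, i + 1 :] = di
    if incomparable:
        raise IncomparablePairError(incomparable)
    if saturated:
        if on_saturation == "raise":
            raise SaturationError(saturated)
        finite_max = np.nanmax(d) if np.isfinite(np.nanmax(d)) else 0.0
        d[np.isnan(d)] = finite_max
    d = d + d.T
    msites = msites + msites.T
    np.fill_diagonal(msites, alignment.length)
    return DistanceMatrix(list(alignment.specimen_ids), d, msites, saturated_pairs=saturated)


@dataclass
class DistanceSummary:
    """Pooled intra-/inter-group distance statistics for one partition.

    Statistics are pooled over all within-group pairs (intra) and all
    between-group pairs (inter); a ``None`` block means no such pairs exist
    (all-singleton or single-group partitions).
    """

    n_intra_pairs: int
    n_inter_pairs: int
    intra: Optional[Dict[str, float]]
    inter: Optional[Dict[str, float]]
    per_group_max: Dict[str, float]

    def _fmt(self, block: Optional[Dict[str, float]]) -> str:
        if block is None:
            return "undefined"
        return f"{block['mean']:.4f} ({block['min']:.4f}-{block['max']:.4f})"

    def __str__(self) -> str:
        return (
            f"intra {self._fmt(self.intra)} [{self.n_intra_pairs} pairs], "
            f"inter {self._fmt(self.inter)} [{self.n_inter_pairs} pairs]"
        )


def summarize_distances(dm: DistanceMatrix, partition: Partition) -> DistanceSummary:
    """Pooled within- vs between-group distance statistics."""
    if partition.universe != frozenset(dm.specimen_ids):
        raise IntegrityError("partition universe does not match distance matrix ids")
    labels = np.array([partition.assignment[s] for s in dm.specimen_ids])
    iu = np.triu_indices(dm.n, k=1)
    vals = dm.d[iu]
    same = labels[iu[0]] == labels[iu[1]]
    intra_vals, inter_vals = vals[same], vals[~same]

    def _stats(v: np.ndarray) -> Optional[Dict[str, float]]:
        if v.size == 0:
            return None
        return {"mean": float(v.mean()), "min": float(v.min()), "max": float(v.max())}

    per_group_max: Dict[str, float] = {}
    for lab, members in partition.groups().items():
        if len(members) >= 2:
            sub = dm.submatrix(members)
            per_group_max[lab] = float(sub.condensed().max())
    return DistanceSummary(
        n_intra_pairs=int(same.sum()),
        n_inter_pairs=int((~same).sum()),
        intra=_stats(intra_vals),
        inter=_stats(inter_vals),
        per_group_max=per_group_max,
    )


def distance_histogram(dm: DistanceMatrix, bins: int = 40) -> Tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of all pairwise distances over [0, max].

    Returns ``(edges, counts)``; counts sum to n(n-1)/2. The 40-bin default
    is the conventional graphic used to eyeball the barcode gap.
    """
    if bins < 1:
        raise ParameterError(f"bins must be >= 1, got {bins}")
    vals = dm.condensed()
    if vals.size == 0:
        raise EmptyInputError("no pairs to histogram")
    top = float(vals.max())
    if top <= 0.0:
        top = 1.0
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, top))
    return edges, counts
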