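"""Recursive barcode-gap partitioning over a prior-divergence scan.

The barcode gap is the discontinuity between intraspecific and interspecific
pairwise distances. Given a prior maximum intraspecific divergence P, the
partitioner sorts all pairwise distances, skips ranks at or below P, and
looks for a rank gap ``g_i = d_(i+1) - d_(i)`` that is large relative to the
local gap scale ``r_i`` (the mean of up to ``w`` preceding rank gaps): a gap
is *significant* when ``g_i > X * r_i`` with relative width ``X``. The
threshold is the midpoint of the chosen gap, and groups are the connected
components of the "distance <= threshold" graph (single-linkage
connectivity). Applying the search once gives the *primary* partition;
re-applying it inside each group until nothing splits gives the *recursive*
partition. Scanning P over a log-spaced grid and selecting the widest
plateau of the primary group count gives the final molecular partition.

By default the *largest* significant gap in the scan range is used (the
barcode gap dominates local quantization noise); ``rule="first"`` selects
the first significant gap instead, which on strongly tied, quantized
distance ladders tends to trigger immediately above P and over-split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .errors import EmptyInputError, ParameterError
from .io_model import Partition


@dataclass
class GapScanConfig:
    """Knobs of the gap partitioner and the prior scan.

    ``p_min``/``p_max`` bound the prior intraspecific divergence grid
    (substitutions/site), ``n_priors`` its log-spaced size. ``relative_gap_width``
    is the significance multiplier X; ``gap_window`` the number of preceding
    rank gaps averaged into the local reference; ``max_recursion_rounds`` caps
    the within-group re-splitting.
    """

    p_min: float = 0.001
    p_max: float = 0.14
    n_priors: int = 20
    relative_gap_width: float = 1.0
    max_recursion_rounds: int = 20
    gap_window: int = 10
    rule: str = "largest"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_min < self.p_max < 0.75):
            raise ParameterError("need 0 < p_min < p_max < 0.75")
        if self.relative_gap_width <= 0:
            raise ParameterError("relative_gap_width must be positive")
        if self.n_priors < 1 or self.max_recursion_rounds < 1 or self.gap_window < 1:
            raise ParameterError("n_priors, max_recursion_rounds, gap_window must be >= 1")
        if self.rule not in ("largest", "first"):
            raise ParameterError(f"rule must be 'largest' or 'first', got {self.rule!r}")

    def priors(self) -> np.ndarray:
        if self.n_priors == 1:
            return np.array([self.p_min])
        return np.geomspace(self.p_min, self.p_max, self.n_priors)


def find_gap_threshold(
    sorted_distances: Sequence[float],
    prior: float,
    relative_gap_width: float = 1.0,
    window: int = 10,
    rule: str = "largest",
) -> Optional[float]:
    """Barcode-gap threshold in an ascending distance list, or None.

    Ranks with distance <= ``prior`` are treated as intraspecific and only
    gaps above them are candidates. A candidate rank gap must be positive and
    strictly exceed ``relative_gap_width`` times the mean of its (up to
    ``window``) preceding rank gaps; ranks with no preceding gap cannot be
    assessed and are skipped. The returned threshold is the midpoint of the
    chosen gap.
    """
    d = np.asarray(sorted_distances, dtype=float)
    m = d.size
    if m == 0:
        raise EmptyInputError("empty distance list")
    if m == 1:
        return None
    gaps = np.diff(d)  # gaps[j] sits between d[j] and d[j+1]
    i0 = int(np.searchsorted(d, prior, side="right"))  # ranks with d <= prior
    start = max(i0 - 1, 0)
    csum = np.concatenate([[0.0], np.cumsum(gaps)])
    best_j: Optional[int] = None
    for j in range(start, m - 1):
        if j == 0:
            continue  # no preceding gap to set the local scale
        lo = max(0, j - window)
        ref = (csum[j] - csum[lo]) / (j - lo)
        g = gaps[j]
        # strict inequality with a relative guard so equal gaps that differ
        # only by floating-point noise never count as significant
        if g > 1e-15 and g > relative_gap_width * ref * (1.0 + 1e-9) + 1e-15:
            if rule == "first":
                best_j = j
                break
            if best_j is None or g > gaps[best_j]:
                best_j = j
    if best_j is None:
        return None
    return float((d[best_j] + d[best_j + 1]) / 2.0)


def partition_at_threshold(dm: DistanceMatrix, threshold: float, source: str = "") -> Partition:
    """Connected components of the ``distance <= threshold`` graph.

    Group labels G1..Gk are assigned by the input order of each component's
    first member, so the result is deterministic.
    """
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    adj = csr_matrix(dm.d <= threshold)
    _, comp = connected_components(adj, directed=False)
    order: Dict[int, int] = {}
    for c in comp:
        if c not in order:
            order[c] = len(order) + 1
    assignment = {
        sid: f"G{order[c]}" for sid, c in zip(dm.specimen_ids, comp)
    }
    return Partition(assignment, source=source or f"gapdelim:t={threshold:.6g}")


def _primary(dm: DistanceMatrix, prior: float, config: GapScanConfig) -> Tuple[Partition, float, bool]:
    """Primary partition plus the threshold used and a fallback flag."""
    t = find_gap_threshold(
        np.sort(dm.condensed()),
        prior,
        relative_gap_width=config.relative_gap_width,
        window=config.gap_window,
        rule=config.rule,
    )
    fallback = t is None
    if fallback:
        t = prior  # no significant gap: split at the prior itself
    part = partition_at_threshold(dm, t, source=f"gapdelim:primary:P={prior:.6g}:t={t:.6g}")
    return part, float(t), fallback


def primary_partition(dm: DistanceMatrix, prior: float, config: Optional[GapScanConfig] = None) -> Partition:
    """One application of the gap search to the full distance list."""
    config = config or GapScanConfig()
    return _primary(dm, prior, config)[0]


def recursive_partition(dm: DistanceMatrix, prior: float, config: Optional[GapScanConfig] = None) -> Partition:
    """Iterated within-group gap splitting; refines the primary partition.

    Each group of size >= 3 is re-searched on its own sorted distances (no
    fallback inside groups: a group without a significant gap is final).
    """
    config = config or GapScanConfig()
    part = _primary(dm, prior, config)[0]
    groups = [members for members in part.groups().values()]
    for _ in range(config.max_recursion_rounds):
        changed = False
        next_groups: List[List[str]] = []
        for members in groups:
            if len(members) < 3:
                next_groups.append(members)
                continue
            sub = dm.submatrix(members)
            t = find_gap_threshold(
                np.sort(sub.condensed()),
                prior,
                relative_gap_width=config.relative_gap_width,
                window=config.gap_window,
                rule=config.rule,
            )
            if t is None:
                next_groups.append(members)
                continue
            sub_part = partition_at_threshold(sub, t)
            if sub_part.k == 1:
                next_groups.append(members)
                continue
            changed = True
            next_groups.extend(sub_part.groups().values())
        groups = next_groups
        if not changed:
            break
    # deterministic relabeling by first member in the matrix's id order
    first_index = {s: i for i, s in enumerate(dm.specimen_ids)}
    groups.sort(key=lambda mem: min(first_index[s] for s in mem))
    assignment = {s: f"G{gi + 1}" for gi, mem in enumerate(groups) for s in mem}
    return Partition(assignment, source=f"gapdelim:recursive:P={prior:.6g}")


@dataclass
class PriorEntry:
    prior: float
    primary: Partition
    recursive: Partition
    threshold: float
    fallback: bool

    @property
    def primary_k(self) -> int:
        return self.primary.k

    @property
    def recursive_k(self) -> int:
        return self.recursive.k


@dataclass
class PriorScanResult:
    """Per-prior partitions, plateau structure and the selected partition."""

    entries: List[PriorEntry]
    plateaus: List[Tuple[int, int, int]]  #: (first index, last index, primary k)
    selected_index: int = field(init=False)
    selected: Partition = field(init=False)

    def __post_init__(self) -> None:
        self.selected_index = _select_plateau(self.plateaus)
        self.selected = self.entries[self.selected_index].primary

    def to_frame(self):
        import pandas as pd

        rows = []
        plateau_of = {}
        for pid, (a, b, _) in enumerate(self.plateaus, start=1):
            for i in range(a, b + 1):
                plateau_of[i] = pid
        for i, e in enumerate(self.entries):
            rows.append(
                {
                    "prior": e.prior,
                    "primary_k": e.primary_k,
                    "recursive_k": e.recursive_k,
                    "threshold": e.threshold,
                    "fallback": e.fallback,
                    "plateau_id": plateau_of[i],
                    "selected": i == self.selected_index,
                }
            )
        return pd.DataFrame(rows)


def _plateaus(ks: Sequence[int]) -> List[Tuple[int, int, int]]:
    """Maximal runs of equal k: disjoint, covering all indices."""
    out: List[Tuple[int, int, int]] = []
    start = 0
    for i in range(1, len(ks) + 1):
        if i == len(ks) or ks[i] != ks[start]:
            out.append((start, i - 1, ks[start]))
            start = i
    return out


def _select_plateau(plateaus: Sequence[Tuple[int, int, int]]) -> int:
    """Index (into the prior grid) of the widest plateau's first entry.

    Ties go to the plateau at larger priors: primary partitions stable over
    a wide prior range are the canonical pick.
    """
    best = max(plateaus, key=lambda p: (p[1] - p[0], p[0]))
    return best[0]


def prior_scan(dm: DistanceMatrix, config: Optional[GapScanConfig] = None) -> PriorScanResult:
    """Primary and recursive partitions over the log-spaced prior grid."""
    config = config or GapScanConfig()
    entries: List[PriorEntry] = []
    for prior in config.priors():
        primary, t, fallback = _primary(dm, float(prior), config)
        recursive = recursive_partition(dm, float(prior), config)
        entries.append(PriorEntry(float(prior), primary, recursive, t, fallback))
    plateaus = _plateaus([e.primary_k for e in entries])
    return PriorScanResult(entries=entries, plateaus=plateaus)
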