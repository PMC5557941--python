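"""Geographic species delimitation.

Collection *sites* within a 5 km single-linkage radius form a *population*.
Within each morphospecies, populations further apart than a hypothetical
dispersal threshold (scanned over 10-500 km) are recognized as distinct
putative species; populations within the threshold are chained together
(single linkage by default, complete linkage as an option). Distances are
great-circle kilometers on a sphere of radius 6371.0088 km.

Geographic delimitation only ever *refines* the morphospecies partition:
populations of different morphospecies are never merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .errors import (
    CoordinateRangeError,
    ParameterError,
    UnassignedMorphospeciesError,
)
from .io_model import Partition, SpecimenRecord

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

#: Threshold grid of the geographic scan (km).
DEFAULT_THRESHOLDS_KM = (10.0, 20.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0)

#: Sites within this single-linkage radius form one population.
POPULATION_LINK_KM = 5.0


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two WGS84 decimal-degree points."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise CoordinateRangeError(f"coordinates out of range: ({lat}, {lon})")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def _pairwise_km(coords: np.ndarray) -> np.ndarray:
    """Dense pairwise haversine matrix for an (n, 2) lat/lon array."""
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    dphi = lat - lat.T
    dlam = lon - lon.T
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class PopulationSite:
    """A population: specimens from sites chained within 5 km of each other."""

    population_id: str
    specimen_ids: List[str]
    sites: Dict[str, Tuple[float, float]]  #: site_id -> (lat, lon)
    morphospecies_labels: Set[str] = field(default_factory=set)

    @property
    def morphospecies(self) -> Optional[str]:
        """The single shared label, or None when the population is mixed."""
        if len(self.morphospecies_labels) == 1:
            return next(iter(self.morphospecies_labels))
        return None

    def site_coords(self) -> np.ndarray:
        return np.array(list(self.sites.values()), dtype=float)


def assemble_populations(
    records: Sequence[SpecimenRecord], link_km: float = POPULATION_LINK_KM
) -> List[PopulationSite]:
    """Single-linkage clustering of distinct sites into populations.

    Specimens without finite coordinates are excluded with a warning.
    Population labels P1..Pn follow the input order of each cluster's first
    site. Mixed-morphospecies populations are reported via
    ``morphospecies_labels``.
    """
    if link_km <= 0:
        raise ParameterError("link_km must be positive")
    site_coord: Dict[str, Tuple[float, float]] = {}
    site_members: Dict[str, List[SpecimenRecord]] = {}
    excluded: List[str] = []
    for r in records:
        if not (np.isfinite(r.latitude) and np.isfinite(r.longitude)):
            excluded.append(r.specimen_id)
            continue
        if r.site_id in site_coord and site_coord[r.site_id] != (r.latitude, r.longitude):
            logger.warning(
                "site %s has conflicting coordinates; keeping first seen", r.site_id
            )
        site_coord.setdefault(r.site_id, (r.latitude, r.longitude))
        site_members.setdefault(r.site_id, []).append(r)
    if excluded:
        logger.warning("excluded %d specimens without coordinates: %s", len(excluded), excluded)
    site_ids = list(site_coord)
    coords = np.array([site_coord[s] for s in site_ids], dtype=float)
    if len(site_ids) == 1:
        comp = np.zeros(1, dtype=int)
    else:
        dkm = _pairwise_km(coords)
        _, comp = connected_components(csr_matrix(dkm <= link_km), directed=False)
    order: Dict[int, int] = {}
    for c in comp:
        if c not in order:
            order[c] = len(order) + 1
    populations: Dict[int, PopulationSite] = {}
    for sid_idx, site_id in enumerate(site_ids):
        c = order[comp[sid_idx]]
        pop = populations.setdefault(
            c, PopulationSite(population_id=f"P{c}", specimen_ids=[], sites={})
        )
        pop.sites[site_id] = site_coord[site_id]
        for rec in site_members[site_id]:
            pop.specimen_ids.append(rec.specimen_id)
            if rec.morphospecies:
                pop.morphospecies_labels.add(rec.morphospecies)
    return [populations[c] for c in sorted(populations)]


def population_distance_km(
    pop_a: PopulationSite, pop_b: PopulationSite, method: str = "min"
) -> float:
    """Inter-population distance: minimum over member-site pairs (default)
    or distance between site centroids."""
    ca, cb = pop_a.site_coords(), pop_b.site_coords()
    if method == "centroid":
        ma, mb = ca.mean(axis=0), cb.mean(axis=0)
        return haversine_km(ma[0], ma[1], mb[0], mb[1])
    if method != "min":
        raise ParameterError(f"method must be 'min' or 'centroid', got {method!r}")
    best = np.inf
    for la, lo in ca:
        for lb, lob in cb:
            best = min(best, haversine_km(la, lo, lb, lob))
    return float(best)


def _cluster_indices(
    dist: np.ndarray, threshold: float, linkage_method: str
) -> np.ndarray:
    n = dist.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    if linkage_method == "single":
        _, comp = connected_components(csr_matrix(dist <= threshold), directed=False)
        return comp
    if linkage_method == "complete":
        z = linkage(squareform(dist, checks=False), method="complete")
        return fcluster(z, t=threshold, criterion="distance")
    raise ParameterError(f"linkage must be 'single' or 'complete', got {linkage_method!r}")


def geo_delimit(
    populations: Sequence[PopulationSite],
    morphospecies: Partition,
    threshold_km: float,
    linkage_method: str = "single",
    distance_method: str = "min",
) -> Partition:
    """Split each morphospecies into putative species at a km threshold.

    Within one morphospecies, populations holding its specimens are clustered
    (joined iff their distance is <= threshold); each cluster is a putative
    species and specimens inherit their population's cluster. Specimens
    without a morphospecies label raise
    :class:`~barcogeo.errors.UnassignedMorphospeciesError`.
    """
    if threshold_km <= 0:
        raise ParameterError("threshold_km must be positive")
    unassigned = [s for s, lab in morphospecies.assignment.items() if not lab]
    if unassigned:
        raise UnassignedMorphospeciesError(
            f"specimens without morphospecies label: {sorted(unassigned)[:10]}"
        )
    pop_of: Dict[str, int] = {}
    for pi, pop in enumerate(populations):
        for sid in pop.specimen_ids:
            pop_of[sid] = pi
    missing = [s for s in morphospecies.assignment if s not in pop_of]
    if missing:
        raise UnassignedMorphospeciesError(
            f"specimens not in any population (missing coordinates?): {sorted(missing)[:10]}"
        )
    assignment: Dict[str, str] = {}
    for morph, members in sorted(morphospecies.groups().items()):
        pop_indices = sorted({pop_of[s] for s in members})
        sub = np.zeros((len(pop_indices), len(pop_indices)))
        for a in range(len(pop_indices)):
            for b in range(a + 1, len(pop_indices)):
                d = population_distance_km(
                    populations[pop_indices[a]], populations[pop_indices[b]], distance_method
                )
                sub[a, b] = sub[b, a] = d
        comp = _cluster_indices(sub, threshold_km, linkage_method)
        order: Dict[int, int] = {}
        for c in comp:
            if c not in order:
                order[c] = len(order) + 1
        cluster_of_pop = {pop_indices[i]: order[c] for i, c in enumerate(comp)}
        for s in members:
            assignment[s] = f"{morph}#g{cluster_of_pop[pop_of[s]]}"
    return Partition(assignment, source=f"geo:{threshold_km:g}km:{linkage_method}")


@dataclass
class GeoScanResult:
    """Per-threshold geographic partitions with plateau structure."""

    thresholds_km: List[float]
    partitions: List[Partition]
    ks: List[int]
    plateaus: List[Tuple[int, int, int]]  #: (first index, last index, k)

    def partition_at(self, threshold_km: float) -> Partition:
        return self.partitions[self.thresholds_km.index(threshold_km)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"threshold_km": self.thresholds_km, "k": self.ks})


def geo_scan(
    populations: Sequence[PopulationSite],
    morphospecies: Partition,
    thresholds_km: Sequence[float] = DEFAULT_THRESHOLDS_KM,
    linkage_method: str = "single",
    distance_method: str = "min",
) -> GeoScanResult:
    """Geographic delimitation across an ascending threshold grid."""
    thresholds = [float(t) for t in thresholds_km]
    if not thresholds or any(t <= 0 for t in thresholds):
        raise ParameterError("thresholds must be positive")
    if sorted(thresholds) != thresholds:
        raise ParameterError("thresholds must be ascending")
    from .gapdelim import _plateaus  # same run-length structure

    partitions = [
        geo_delimit(populations, morphospecies, t, linkage_method, distance_method)
        for t in thresholds
    ]
    ks = [p.k for p in partitions]
    if linkage_method == "single" and any(ks[i + 1] > ks[i] for i in range(len(ks) - 1)):
        raise AssertionError("geographic k increased with threshold; internal error")
    return GeoScanResult(thresholds, partitions, ks, _plateaus(ks))
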