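import math

import numpy as np
import pytest

from barcogeo import (
    Partition,
    SpecimenRecord,
    assemble_populations,
    geo_delimit,
    geo_scan,
    haversine_km,
)
from barcogeo.errors import CoordinateRangeError, ParameterError, UnassignedMorphospeciesError
from barcogeo.geodelim import EARTH_RADIUS_KM, population_distance_km

KM_PER_DEG_LAT = EARTH_RADIUS_KM * math.pi / 180.0


def _records_on_meridian(offsets_km, morph="M1", prefix="s"):
    """Specimens strung along the 0-meridian at given km offsets from equator."""
    out = []
    for i, km in enumerate(offsets_km):
        out.append(
            SpecimenRecord(
                specimen_id=f"{prefix}{i}",
                site_id=f"{prefix}site{i}",
                latitude=km / KM_PER_DEG_LAT,
                longitude=0.0,
                morphospecies=morph,
            )
        )
    return out


class TestHaversine:
    def test_coincident_points_zero(self):
        assert haversine_km(0, 0, 0, 0) == 0.0

    def test_one_degree_of_latitude(self):
        assert haversine_km(0, 0, 1, 0) == pytest.approx(KM_PER_DEG_LAT, abs=1e-3)
        assert haversine_km(0, 0, 1, 0) == pytest.approx(111.195, abs=1e-3)

    def test_antipodal_half_circumference(self):
        assert haversine_km(0, 0, 0, 180) == pytest.approx(math.pi * EARTH_RADIUS_KM, abs=0.1)

    def test_symmetry(self):
        assert haversine_km(10, 20, -30, 40) == pytest.approx(haversine_km(-30, 40, 10, 20))

    def test_out_of_range_rejected(self):
        with pytest.raises(CoordinateRangeError):
            haversine_km(95, 0, 0, 0)


class TestAssemblePopulations:
    def test_single_site_single_population(self):
        pops = assemble_populations(_records_on_meridian([0]))
        assert len(pops) == 1 and pops[0].specimen_ids == ["s0"]

    def test_chaining_links_sites_within_radius(self):
        # 0, 4, 8 km: adjacent pairs within 5 km chain into one population
        pops = assemble_populations(_records_on_meridian([0, 4, 8]))
        assert len(pops) == 1

    def test_distant_sites_stay_separate(self):
        pops = assemble_populations(_records_on_meridian([0, 10]))
        assert len(pops) == 2

    def test_mixed_morphospecies_reported(self):
        recs = _records_on_meridian([0], morph="M1") + _records_on_meridian(
            [1], morph="M2", prefix="t"
        )
        pops = assemble_populations(recs)
        assert len(pops) == 1
        assert pops[0].morphospecies is None
        assert pops[0].morphospecies_labels == {"M1", "M2"}


class TestGeoDelimit:
    def _setup(self, offsets_km, morph_labels=None):
        records = []
        for mi, offs in enumerate(offsets_km):
            morph = morph_labels[mi] if morph_labels else f"M{mi+1}"
            records += _records_on_meridian(offs, morph=morph, prefix=f"m{mi}_")
        pops = assemble_populations(records)
        morpho = Partition({r.specimen_id: r.morphospecies for r in records})
        return records, pops, morpho

    def test_one_population_per_morphospecies(self):
        _, pops, morpho = self._setup([[0], [500]])
        part = geo_delimit(pops, morpho, threshold_km=50)
        assert part.k == 2

    def test_threshold_splits_and_merges(self):
        _, pops, morpho = self._setup([[0, 60]], morph_labels=["M1"])
        assert geo_delimit(pops, morpho, 50).k == 2
        assert geo_delimit(pops, morpho, 100).k == 1

    def test_never_merges_morphospecies(self):
        # two morphospecies 1 km apart stay separate at any threshold
        _, pops, morpho = self._setup([[0], [1]])
        for t in (10, 100, 1000):
            part = geo_delimit(pops, morpho, t)
            assert part.refines(morpho) and part.k == 2

    def test_unassigned_morphospecies_rejected(self):
        records = _records_on_meridian([0], morph="")
        pops = assemble_populations(records)
        morpho = Partition({r.specimen_id: r.morphospecies for r in records})
        with pytest.raises(UnassignedMorphospeciesError):
            geo_delimit(pops, morpho, 50)

def closure(dist, t):
    n = dist.shape[0]
    groups = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(dist[i, j] <= t for i in groups[a] for j in groups[b]):
                    groups[a] |= groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(g) for g in groups}


class TestGeoScan:
    def test_three_population_chain(self):
        records = _records_on_meridian([0, 60, 120], morph="M1")
        pops = assemble_populations(records)
        morpho = Partition({r.specimen_id: r.morphospecies for r in records})
        result = geo_scan(pops, morpho, thresholds_km=[50, 70, 130])
        assert result.ks == [3, 1, 1]  # 70 km chains all through the middle

    def test_k_non_increasing_and_morph_floor(self, rng):
        # random populations in two morphospecies; k must fall to the
        # morphospecies count once the threshold exceeds every distance
        offsets = [sorted(rng.uniform(0, 800, size=4)) for _ in range(2)]
        records = []
        for mi, offs in enumerate(offsets):
            records += _records_on_meridian(offs, morph=f"M{mi+1}", prefix=f"m{mi}_")
        pops = assemble_populations(records)
        morpho = Partition({r.specimen_id: r.morphospecies for r in records})
        result = geo_scan(pops, morpho, thresholds_km=[10, 50, 100, 200, 400, 900])
        assert all(a >= b for a, b in zip(result.ks, result.ks[1:]))
        assert result.ks[-1] == 2

    def test_single_population_constant_k(self):
        records = _records_on_meridian([0, 1])
        pops = assemble_populations(records)
        morpho = Partition({r.specimen_id: "M1" for r in records})
        result = geo_scan(pops, morpho, thresholds_km=[10, 100, 500])
        assert result.ks == [1, 1, 1]

    def test_bad_thresholds_rejected(self):
        records = _records_on_meridian([0])
        pops = assemble_populations(records)
        morpho = Partition({r.specimen_id: "M1" for r in records})
        with pytest.raises(ParameterError):
            geo_scan(pops, morpho, thresholds_km=[100, 50])


class TestPopulationDistance:
    def test_min_vs_centroid(self):
        recs_a = _records_on_meridian([0, 4], prefix="a")
        recs_b = _records_on_meridian([20, 24], prefix="b")
        pops = assemble_populations(recs_a + recs_b)
        assert len(pops) == 2
        d_min = population_distance_km(pops[0], pops[1], "min")
        d_cen = population_distance_km(pops[0], pops[1], "centroid")
        assert d_min == pytest.approx(16.0, rel=1e-3)
        assert d_cen == pytest.approx(20.0, rel=1e-3)

    def test_delimitation_oracle_on_random_populations(self, rng):
        # single-linkage result equals brute-force transitive closure
        offs = sorted(rng.uniform(0, 500, size=7))
        records = _records_on_meridian(offs, morph="M1")
        pops = assemble_populations(records, link_km=1.0)
        morpho = Partition({r.specimen_id: "M1" for r in records})
        n = len(pops)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = population_distance_km(pops[i], pops[j])
        for t in (30, 75, 150, 600):
            part = geo_delimit(pops, morpho, t)
            got = {
                frozenset(
                    i for i, p in enumerate(pops)
                    if part.assignment[p.specimen_ids[0]] == lab
                )
                for lab in set(part.assignment.values())
            }
            assert got == closure(dist, t)
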