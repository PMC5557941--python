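"""Geographic threshold delimitation of a morphospecies.

Builds three populations of one morphospecies strung 60 km apart along a
meridian and scans dispersal thresholds: populations further apart than the
threshold are distinct putative species; chains of populations merge by
single linkage.
"""

from barcogeo import Partition, SpecimenRecord, assemble_populations, geo_scan
from barcogeo.geodelim import EARTH_RADIUS_KM
import math

KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0
records = [
    SpecimenRecord(f"s{i}", f"site{i}", km / KM_PER_DEG, 0.0, morphospecies="M1")
    for i, km in enumerate([0, 60, 120])
]
pops = assemble_populations(records)  # sites > 5 km apart stay separate populations
morpho = Partition({r.specimen_id: r.morphospecies for r in records})

result = geo_scan(pops, morpho, thresholds_km=[50, 70, 130])
for t, k in zip(result.thresholds_km, result.ks):
    print(f"threshold {t:>5.0f} km -> {k} putative species")
# At 50 km no pair is linked (3 species); at 70 km the middle population
# chains its two neighbours into one species even though the ends are
# 120 km apart — the single-linkage reading of the distance rule.
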