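"""Barcode-gap delimitation on a simulated barcode dataset.

Generates 8 species (48 COI-like sequences, ~2% within-species and 12-20%
between-species K2P divergence), scans prior intraspecific divergences, and
selects the partition on the widest plateau of the primary group count.
"""

from barcogeo import adjusted_rand, distance_histogram, distance_matrix, prior_scan
from barcogeo.simulate import simulate_dataset

ds = simulate_dataset(seed=11, n_species=8, total_individuals=48,
                      inter_divergence=(0.12, 0.20))
dm = distance_matrix(ds.alignment)

edges, counts = distance_histogram(dm, bins=40)
first_occupied = next(i for i, c in enumerate(counts) if c > 0)
gap_start = next(i for i in range(first_occupied, len(counts)) if counts[i] == 0)
print(f"{len(ds.alignment)} specimens, {dm.n * (dm.n - 1) // 2} pairwise distances")
print(f"histogram: distances vanish above {edges[gap_start]:.3f} "
      "(the visible barcode gap)")

scan = prior_scan(dm)
print("prior grid primary k:", [e.primary_k for e in scan.entries])
print(f"selected partition: k={scan.selected.k} "
      f"(widest plateau of the primary group count)")
print(f"adjusted Rand vs planted truth: {adjusted_rand(scan.selected, ds.truth.partition):.2f}")
# k equal to the number of simulated species and ARI 1.0 mean the gap
# partitioner recovered every planted species exactly.
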