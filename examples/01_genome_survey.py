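"""Genome survey from a k-mer histogram.

Simulates error-free long reads from a 50-kb random genome, builds the
17-mer histogram, and estimates peak depth, genome size and coverage.
Then applies the same G = volume / peak-depth model to the published
lupin survey inputs (17-mer volume 25,376,847,185 at peak depth 22,
31.001 Gbp sequenced).
"""

import numpy as np

from rilmap import (count_kmers, estimate_coverage, estimate_genome_size,
                    find_peak, genome_size_from_volume)

rng = np.random.default_rng(0)
genome = "".join(rng.choice(list("ACGT"), size=50_000))
reads = [genome[s:s + 1000]
         for s in rng.integers(0, 49_000, size=1_500)]  # ~30x

hist = count_kmers(reads, k=17)
peak = find_peak(hist)
size = estimate_genome_size(hist)
print(f"simulated 50 kb genome at 30x:")
print(f"  k-mer volume      {hist.volume:,}")
print(f"  peak depth        {peak}   (k-mer coverage ~ 30 * 984/1000)")
print(f"  genome size       {size:,.0f} bp  (truth 50,000)")
print(f"  fold coverage     "
      f"{estimate_coverage(sum(map(len, reads)), size):.1f}x")

size = genome_size_from_volume(25_376_847_185, 22)
print("\npublished lupin survey inputs:")
print(f"  genome size       {size / 1e9:.3f} Gb")
print(f"  fold coverage     {estimate_coverage(31.001e9, size):.1f}x")
# The genome size divides the total k-mer volume by the modal k-mer
# depth; coverage is total sequenced bases over that size.
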