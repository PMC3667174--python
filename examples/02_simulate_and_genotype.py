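"""Simulate a small RAD-seq experiment and genotype it.

Builds two founder genomes differing at 30 variants placed on EcoRI
tag windows, advances 40 F8 RILs by single seed descent, sequences
barcoded 100-bp RAD reads, then demultiplexes, clusters tags, calls
parental SNP/indel markers and genotypes every RIL.
"""

import rilmap as rm

cfg = rm.GenomeConfig(chromosomes=[("chr1", 100_000, 100.0)],
                      n_variants=30, indel_fraction=0.1, seed=11)
founders = rm.make_founders(cfg)
pop = rm.simulate_population(founders, rm.PedigreeConfig(40, 8, 12))

samples = {"ParentA": rm.founder_individual(founders, "A"),
           "ParentB": rm.founder_individual(founders, "B"), **pop}
barcodes = rm.simulate.assign_barcodes(list(samples), seed=13)
lib = rm.RadLibraryConfig(mean_depth=12.0, error_rate=0.001, rng_seed=14)
haps = {n: rm.simulate.sample_haplotype_sequences(founders, ind)
        for n, ind in samples.items()}
records, origins = rm.digest_and_sequence(haps, barcodes, lib)
print(f"{len(records):,} reads from {len(samples)} samples "
      f"({founders.seq_a['chr1'].count('GAATTC')} EcoRI sites)")

matrix, markers, log = rm.genotype_fastq(records, barcodes,
                                         "ParentA", "ParentB")
n_snp = sum(m.kind == "SNP" for m in markers)
print(f"called {len(markers)} markers ({n_snp} SNP, "
      f"{len(markers) - n_snp} indel); rejects: {log}")
print("genotype matrix (first 4 markers x 6 samples):")
print(matrix.iloc[:4, :6])
# Codes: A/B = homozygous parental alleles, H = heterozygous (residual
# F8 heterozygosity ~ (1/2)^7), '-' = below the read-depth minimum.
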