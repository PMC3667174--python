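"""rilmap: RAD-seq genotyping and sequence-defined linkage mapping for
biparental recombinant inbred line populations, with a k-mer genome
survey, scaffold anchoring and marker-trait co-segregation scanning.

The package covers the computational path of a medium-depth
genome-survey + RAD-seq mapping study: simulate (or load) barcoded RAD
reads, call SNP/indel markers between two homozygous founders, genotype
the RILs, build a linkage map with Haldane-Waddington-corrected
two-point distances and RECORD-style marker ordering, anchor assembly
scaffolds by unique exact tag match, and scan binary traits for linked
and co-segregating markers.
"""

from importlib.resources import files as _files

import pandas as _pd

from .kmer_profile import (KmerHistogram, count_kmers, estimate_coverage,
                           estimate_genome_size, find_peak,
                           genome_size_from_volume, repeat_volume_fraction)
from .linkage_map import (LinkageGroup, LinkageGroupMap, Locus,
                          TwoPointEstimate, build_groups, build_map,
                          collapse_loci, find_gaps, haldane_cm,
                          haldane_waddington_R, haldane_waddington_r,
                          kosambi_cm, map_statistics, order_group,
                          pairwise_two_point, position_loci, summarize_map,
                          two_point)
from .pipeline import PipelineConfig, run_pipeline
from .rad_genotyping import (MarkerDefinition, RadTag, call_parental_markers,
                             cluster_tags, demultiplex, filter_repetitive,
                             genotype_fastq, genotype_rils, qc_matrix)
from .scaffold_anchor import (Anchor, anchor_markers, coverage_fractions,
                              integrate, locate_tag)
from .simulate import (Chromosome, FounderGenome, GenomeConfig,
                       PedigreeConfig, RadLibraryConfig, RilGenome, Variant,
                       advance_ssd, digest_and_sequence, f1_individual,
                       founder_individual, make_founders, simulate_gamete,
                       simulate_population, truth_genotypes,
                       truth_marker_tags)
from .trait_candidates import (TraitLinkageReport, TraitPhenotype,
                               candidate_scaffolds, cosegregating_markers,
                               map_trait, validate_panel)

__version__ = "0.1.0"


def published_map_summary() -> "_pd.DataFrame":
    """Per-linkage-group summary of the published narrow-leafed lupin
    sequence-defined map (markers, loci, genetic length, anchored
    scaffolds and their span), bundled as reference input."""
    path = _files("rilmap").joinpath("data/lupin_slg_summary.csv")
    return _pd.read_csv(path)
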