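"""End-to-end pipeline driver: simulate -> kmer survey -> genotype ->
map -> anchor -> trait scan, with a single seed and a run manifest.

Every stage writes diff-able CSV artifacts into the output directory;
the manifest records parameters, per-stage counts and the stage list
actually run, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, kmer_profile, linkage_map, rad_genotyping, scaffold_anchor
from . import simulate, trait_candidates

log = logging.getLogger("rilmap")

STAGES = ("simulate", "kmerprof", "genotype", "map", "anchor", "traitscan")


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration for the whole pipeline.

    Defaults mirror the study design the simulator emulates: a
    biparental cross advanced to F8 by single seed descent, 94 RILs,
    EcoRI RAD libraries of 100-bp reads with 8-nt inline barcodes.
    """
    seed: int = 0
    # genome / founders
    n_chromosomes: int = 2
    chromosome_length_bp: int = 150_000
    genetic_length_cm: float = 100.0
    n_variants: int = 40
    indel_fraction: float = 0.08
    cut_site_spacing_bp: int = 1500
    # pedigree
    n_rils: int = 94
    final_generation: int = 8
    # library
    mean_depth: float = 20.0
    depth_distribution: str = "poisson"
    error_rate: float = 0.001
    # genotyping
    min_depth: int = 3
    max_tag_reads: int = 100
    # survey
    kmer_k: int = 17
    # mapping
    lod_start: float = 6.0
    target_groups: int = 0       # 0 -> number of simulated chromosomes
    lod_floor: float = 3.0
    mapping_function: str = "kosambi"
    gap_threshold_cm: float = 20.0
    # anchoring / traits
    scaffold_length_bp: int = 30_000
    trait_window_cm: float = 5.0


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return (config.seed * 1000 + STAGES.index(stage)) % (2 ** 31 - 1)


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run a stage prefix of the pipeline; returns the manifest dict."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="[%(name)s] %(message)s")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "stages": list(stages),
                      "counts": {}}
    state: dict = {}
    for stage in STAGES:
        if stage not in stages:
            break
        log.info("stage %s", stage)
        try:
            _RUNNERS[stage](config, out, state, manifest)
        except Exception as exc:
            io.write_manifest(out / "manifest.json", manifest)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    io.write_manifest(out / "manifest.json", manifest)
    return manifest


def _run_simulate(config, out, state, manifest):
    seed = _stage_seed(config, "simulate")
    genome_cfg = simulate.GenomeConfig(
        chromosomes=[(f"chr{i + 1}", config.chromosome_length_bp,
                      config.genetic_length_cm)
                     for i in range(config.n_chromosomes)],
        n_variants=config.n_variants,
        indel_fraction=config.indel_fraction,
        cut_site_spacing_bp=config.cut_site_spacing_bp,
        seed=seed)
    founders = simulate.make_founders(genome_cfg)
    rils = simulate.simulate_population(
        founders, simulate.PedigreeConfig(config.n_rils,
                                          config.final_generation, seed + 1))
    samples = {"ParentA": simulate.founder_individual(founders, "A"),
               "ParentB": simulate.founder_individual(founders, "B"), **rils}
    barcodes = simulate.assign_barcodes(list(samples), seed=seed + 2)
    lib = simulate.RadLibraryConfig(mean_depth=config.mean_depth,
                                    depth_distribution=config.depth_distribution,
                                    error_rate=config.error_rate,
                                    rng_seed=seed + 3)
    haplotype_sets = {name: simulate.sample_haplotype_sequences(founders, ind)
                      for name, ind in samples.items()}
    records, origins = simulate.digest_and_sequence(haplotype_sets, barcodes,
                                                    lib)
    io.write_fastq(out / "reads.fastq", records)
    pd.DataFrame(sorted(barcodes.items()), columns=["sample", "barcode"]
                 ).to_csv(out / "barcodes.csv", index=False)
    simulate.variant_table(founders).to_csv(out / "truth_variants.csv",
                                            index=False)
    simulate.segment_table(rils).to_csv(out / "truth_segments.csv", index=False)
    origins.to_csv(out / "truth_read_origins.csv", index=False)
    io.write_fasta(out / "founder_a.fasta",
                   sorted(founders.seq_a.items()))
    state.update(founders=founders, rils=rils, samples=samples,
                 barcodes=barcodes, records=records, lib=lib)
    manifest["counts"]["simulate"] = {
        "n_variants": len(founders.variants), "n_samples": len(samples),
        "n_reads": len(records)}


def _run_kmerprof(config, out, state, manifest):
    reads = (seq[8:] for _, seq, _ in state["records"])
    hist = kmer_profile.count_kmers(reads, k=config.kmer_k)
    hist.to_csv(out / "kmer_histogram.csv")
    peak = kmer_profile.find_peak(hist)
    size = kmer_profile.estimate_genome_size(hist)
    manifest["counts"]["kmerprof"] = {
        "peak_depth": peak, "kmer_volume": hist.volume,
        "genome_size_bp": round(size)}
    state["hist"] = hist


def _run_genotype(config, out, state, manifest):
    matrix, markers, gt_log = rad_genotyping.genotype_fastq(
        state["records"], state["barcodes"], "ParentA", "ParentB",
        min_depth=config.min_depth, max_reads=config.max_tag_reads)
    matrix.to_csv(out / "genotype_matrix.csv")
    pd.DataFrame([(m.marker_id, m.kind, m.tag_a, m.tag_b, m.variant_offset,
                   m.allele_a, m.allele_b) for m in markers],
                 columns=["marker_id", "kind", "tag_a", "tag_b",
                          "variant_offset", "allele_a", "allele_b"]
                 ).to_csv(out / "markers.csv", index=False)
    ril_cols = [c for c in matrix.columns if c.startswith("RIL")]
    rad_genotyping.qc_matrix(matrix, ril_cols).to_csv(out / "marker_qc.csv")
    state.update(matrix=matrix, markers=markers, ril_cols=ril_cols)
    manifest["counts"]["genotype"] = {
        "n_markers": len(markers), **gt_log}


def _run_map(config, out, state, manifest):
    target = config.target_groups or config.n_chromosomes
    lmap = linkage_map.build_map(
        state["matrix"][state["ril_cols"]],
        lod_start=config.lod_start, target_groups=target,
        lod_floor=config.lod_floor,
        mapping_function=config.mapping_function,
        seed=_stage_seed(config, "map"))
    lmap.to_frame().to_csv(out / "linkage_map.csv", index=False)
    gaps = linkage_map.find_gaps(lmap, config.gap_threshold_cm)
    gaps.to_csv(out / "map_gaps.csv", index=False)
    state["lmap"] = lmap
    manifest["counts"]["map"] = {
        "n_groups": len(lmap.groups), "n_loci": lmap.n_loci,
        "total_length_cm": round(lmap.total_length_cm, 1),
        "n_gaps": len(gaps)}


def _run_anchor(config, out, state, manifest):
    founders = state["founders"]
    scaffolds = {}
    for chrom, seq in sorted(founders.seq_a.items()):
        for i in range(0, len(seq), config.scaffold_length_bp):
            piece = seq[i:i + config.scaffold_length_bp]
            scaffolds[f"scaffold{len(scaffolds) + 1}"] = piece
    io.write_fasta(out / "scaffolds.fasta", sorted(scaffolds.items()))
    anchors, rejects = scaffold_anchor.anchor_markers(state["markers"],
                                                      scaffolds)
    anchors.to_csv(out / "anchors.csv", index=False)
    lengths = {s: len(seq) for s, seq in scaffolds.items()}
    per_group, conflicts = scaffold_anchor.integrate(anchors, state["lmap"],
                                                     lengths)
    summary = linkage_map.summarize_map(state["lmap"], per_group)
    summary.to_csv(out / "map_summary.csv", index=False)
    state.update(anchors=anchors, scaffolds=scaffolds,
                 scaffold_lengths=lengths)
    manifest["counts"]["anchor"] = {
        "n_anchored": len(anchors), "n_conflicts": len(conflicts), **rejects}


def _run_traitscan(config, out, state, manifest):
    # simulated monogenic trait: a causal variant drawn among the
    # anchored markers; donor parent B carries the resistant allele
    rng = np.random.default_rng(_stage_seed(config, "traitscan"))
    anchored = sorted(set(state["anchors"]["marker_id"]))
    causal = anchored[int(rng.integers(len(anchored)))]
    truth_codes = state["matrix"].loc[causal, state["ril_cols"]]
    codes = {s: ("R" if c in ("B", "H") else "S")
             for s, c in truth_codes.items() if c != "-"}
    pheno = trait_candidates.TraitPhenotype("resistance", codes, "S", "R")
    report = trait_candidates.map_trait(state["matrix"][state["ril_cols"]],
                                        pheno, state["lmap"])
    coseg = report.cosegregating_markers()
    candidates = trait_candidates.candidate_scaffolds(
        coseg, state["anchors"], state["scaffold_lengths"])
    report.per_marker.reset_index(names="marker_id").to_csv(
        out / "trait_scan.csv", index=False)
    candidates.to_csv(out / "trait_candidate_scaffolds.csv", index=False)
    pd.DataFrame(sorted(codes.items()), columns=["sample", "code"]
                 ).to_csv(out / "trait_phenotypes.csv", index=False)
    manifest["counts"]["traitscan"] = {
        "causal_marker": causal, "placed_group": report.group,
        "n_linked": len(report.linked_markers(config.trait_window_cm)),
        "n_cosegregating": len(coseg),
        "n_candidate_scaffolds": len(candidates)}


_RUNNERS = {"simulate": _run_simulate, "kmerprof": _run_kmerprof,
            "genotype": _run_genotype, "map": _run_map,
            "anchor": _run_anchor, "traitscan": _run_traitscan}
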