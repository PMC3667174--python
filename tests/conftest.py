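"""Shared simulated datasets.

Two session-scoped datasets back most integration tests:

* ``e2e`` — an error-free RAD-seq run (2 chromosomes, 94 RILs, fixed
  read depth) carried through demultiplexing, marker calling, mapping,
  anchoring and a trait scan, with full ground truth.
* ``recovery`` — a genotype-level simulation at the parameter-recovery
  scale (5 chromosomes, 500 markers, 94 RILs) with its built map.

All seeds are fixed constants so the suite is deterministic.
"""

import numpy as np
import pandas as pd
import pytest

import rilmap as rm
from rilmap import linkage_map, scaffold_anchor, trait_candidates


@pytest.fixture(scope="session")
def e2e():
    cfg = rm.GenomeConfig(
        chromosomes=[("chr1", 150_000, 100.0), ("chr2", 150_000, 100.0)],
        n_variants=40, indel_fraction=0.1, cut_site_spacing_bp=1500,
        seed=101)
    founders = rm.make_founders(cfg)
    pop = rm.simulate_population(founders, rm.PedigreeConfig(94, 8, 102))
    samples = {"ParentA": rm.founder_individual(founders, "A"),
               "ParentB": rm.founder_individual(founders, "B"), **pop}
    barcodes = rm.simulate.assign_barcodes(list(samples), seed=103)
    lib = rm.RadLibraryConfig(mean_depth=6.0, depth_distribution="fixed",
                              error_rate=0.0, rng_seed=104)
    haplotype_sets = {
        name: rm.simulate.sample_haplotype_sequences(founders, ind)
        for name, ind in samples.items()}
    records, origins = rm.digest_and_sequence(haplotype_sets, barcodes, lib)

    matrix, markers, log = rm.genotype_fastq(records, barcodes,
                                             "ParentA", "ParentB")
    ril_cols = [c for c in matrix.columns if c.startswith("RIL")]
    lmap = rm.build_map(matrix[ril_cols], target_groups=2, seed=105)

    scaffolds = {}
    scaffold_origin = {}
    for chrom, seq in sorted(founders.seq_a.items()):
        for i in range(0, len(seq), 30_000):
            sid = f"scaffold{len(scaffolds) + 1}"
            scaffolds[sid] = seq[i:i + 30_000]
            scaffold_origin[sid] = (chrom, i)
    anchors, anchor_rejects = rm.anchor_markers(markers, scaffolds)

    rng = np.random.default_rng(106)
    anchored_ids = sorted(set(anchors["marker_id"]))
    causal = anchored_ids[int(rng.integers(len(anchored_ids)))]
    codes = {s: ("R" if c in ("B", "H") else "S")
             for s, c in matrix.loc[causal, ril_cols].items() if c != "-"}
    pheno = trait_candidates.TraitPhenotype("resistance", codes, "S", "R")
    report = rm.map_trait(matrix[ril_cols], pheno, lmap)

    return dict(founders=founders, pop=pop, samples=samples,
                barcodes=barcodes, lib=lib, records=records,
                origins=origins, matrix=matrix, markers=markers, log=log,
                ril_cols=ril_cols, lmap=lmap, scaffolds=scaffolds,
                scaffold_origin=scaffold_origin, anchors=anchors,
                anchor_rejects=anchor_rejects,
                truth_tags=rm.truth_marker_tags(founders),
                truth_geno=rm.truth_genotypes(founders, pop),
                causal=causal, pheno=pheno, report=report)


@pytest.fixture(scope="session")
def recovery():
    cfg = rm.GenomeConfig(
        chromosomes=[(f"chr{i + 1}", 100_000, 100.0) for i in range(5)],
        n_variants=500, at_cut_sites=False, seed=1234)
    founders = rm.make_founders(cfg)
    pop = rm.simulate_population(founders, rm.PedigreeConfig(94, 8, 1235))
    matrix = rm.truth_genotypes(founders, pop)
    lmap = rm.build_map(matrix, target_groups=5, seed=1236)
    truth_pos = {f"{v.chrom}:{v.pos}": (v.chrom, v.pos)
                 for v in founders.variants}
    spans = {}
    for v in founders.variants:
        spans.setdefault(v.chrom, []).append(v.pos)
    truth_length_cm = sum(
        (max(p) - min(p)) / 100_000 * 100.0 for p in spans.values())
    return dict(founders=founders, matrix=matrix, lmap=lmap,
                truth_pos=truth_pos, truth_length_cm=truth_length_cm)
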