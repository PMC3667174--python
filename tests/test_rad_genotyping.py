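"""Demultiplexing, tag clustering, marker calling and RIL genotyping."""

import numpy as np
import pandas as pd
import pytest

import rilmap as rm
from rilmap.rad_genotyping import (MISSING, _hamming1_offset, _single_gap,
                                   call_parental_markers, cluster_tags,
                                   demultiplex, filter_repetitive,
                                   genotype_rils, load_barcode_map, qc_matrix)


def _random_tag(rng, n=92):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestDemultiplex:
    BARCODES = {"s1": "AAAACCCC", "s2": "GGGGTTTT"}

    def test_exact_match_assigns_and_trims(self):
        tag = "A" * 92
        assigned, unassigned = demultiplex(["GGGGTTTT" + tag], self.BARCODES)
        assert assigned["s2"] == [tag] and unassigned == 0

    def test_one_mismatch_goes_unassigned(self):
        assigned, unassigned = demultiplex(["GGGGTTTA" + "A" * 92],
                                           self.BARCODES)
        assert unassigned == 1 and not assigned["s2"]

    def test_read_partition_is_exact(self):
        rng = np.random.default_rng(31)
        reads = []
        for _ in range(500):
            bc = rng.choice(["AAAACCCC", "GGGGTTTT", "ACGTACGT"])
            reads.append(bc + _random_tag(rng))
        assigned, unassigned = demultiplex(reads, self.BARCODES)
        assert sum(map(len, assigned.values())) + unassigned == 500

    def test_duplicate_barcodes_rejected_at_load(self, tmp_path):
        df = pd.DataFrame({"sample": ["a", "b"],
                           "barcode": ["AAAACCCC", "AAAACCCC"]})
        path = tmp_path / "barcodes.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError):
            load_barcode_map(path)

    def test_error_free_simulated_library_fully_assigned(self, e2e):
        assert e2e["log"]["unassigned_reads"] == 0


class TestClusterAndFilter:
    def test_identical_reads_one_tag(self):
        assert cluster_tags(["A" * 92] * 5) == {"A" * 92: 5}

    def test_one_base_difference_two_tags(self):
        a = "A" * 92
        b = "C" + "A" * 91
        assert cluster_tags([a, b]) == {a: 1, b: 1}

    def test_repeat_filter_boundary(self):
        tags = {"A" * 92: 100, "C" * 92: 101}
        kept, removed = filter_repetitive(tags)
        assert "A" * 92 in kept and "C" * 92 not in kept and removed == 1

    def test_empty_input(self):
        assert filter_repetitive({}) == ({}, 0)

    def test_repetitive_tag_from_multicopy_region_removed(self):
        # a 10-copy repeat at 20x depth yields a 200-read tag
        tags = {_random_tag(np.random.default_rng(32)): 200}
        kept, removed = filter_repetitive(tags)
        assert kept == {} and removed == 1


class TestMarkerCalling:
    def test_identical_parents_no_markers(self):
        rng = np.random.default_rng(33)
        tags = {_random_tag(rng): 10 for _ in range(5)}
        markers, rejects = call_parental_markers(tags, dict(tags))
        assert markers == [] and rejects["monomorphic"] == len(tags)

    def test_snp_pair_offset_and_alleles(self):
        rng = np.random.default_rng(34)
        a = _random_tag(rng)
        b = a[:30] + ("C" if a[30] != "C" else "T") + a[31:]
        markers, _ = call_parental_markers({a: 10}, {b: 10})
        (m,) = markers
        assert m.kind == "SNP" and m.variant_offset == 31
        assert m.allele_a == a[30] and m.allele_b == b[30]
        assert m.marker_id.startswith("DAFWA")

    def test_indel_pair_called_with_gap(self):
        rng = np.random.default_rng(35)
        genome = _random_tag(rng, 200)
        a = genome[:92]
        b = (genome[:40] + genome[43:95])  # 3-bp deletion in parent B
        markers, _ = call_parental_markers({a: 10}, {b: 10})
        (m,) = markers
        assert m.kind == "indel" and m.marker_id.startswith("iDAFWA")
        assert len(m.allele_a) - len(m.allele_b) == 3

    def test_ambiguous_trio_all_discarded(self):
        rng = np.random.default_rng(36)
        a = _random_tag(rng)
        b1 = a[:10] + ("C" if a[10] != "C" else "T") + a[11:]
        b2 = a[:50] + ("C" if a[50] != "C" else "T") + a[51:]
        markers, rejects = call_parental_markers({a: 10}, {b1: 10, b2: 10})
        assert markers == [] and rejects["ambiguous"] >= 1

    def test_low_depth_tags_not_called(self):
        rng = np.random.default_rng(37)
        a = _random_tag(rng)
        b = a[:5] + ("C" if a[5] != "C" else "T") + a[6:]
        markers, _ = call_parental_markers({a: 2}, {b: 10}, min_depth=3)
        assert markers == []

    def test_pairing_matches_bruteforce_oracle(self):
        # exhaustive pairwise-comparison oracle on random tag sets with
        # planted SNP pairs
        rng = np.random.default_rng(38)
        for _ in range(20):
            a_tags, b_tags = {}, {}
            planted = []
            for i in range(rng.integers(1, 6)):
                t = _random_tag(rng)
                off = int(rng.integers(0, 92))
                alt = t[:off] + ("A" if t[off] != "A" else "G") + t[off + 1:]
                a_tags[t] = 10
                b_tags[alt] = 10
                planted.append((t, alt))
            for _ in range(rng.integers(0, 4)):
                a_tags[_random_tag(rng)] = 10
            markers, _ = call_parental_markers(a_tags, b_tags)
            # oracle: all cross pairs at Hamming distance exactly 1
            oracle = set()
            for a in a_tags:
                for b in b_tags:
                    if _hamming1_offset(a, b) is not None:
                        oracle.add((a, b))
            called = {(m.tag_a, m.tag_b) for m in markers}
            # with unique pairing the called set equals the oracle minus
            # ambiguous members
            counts_a = {a: sum(1 for x, _ in oracle if x == a) for a in a_tags}
            counts_b = {b: sum(1 for _, y in oracle if y == b) for b in b_tags}
            expected = {(a, b) for a, b in oracle
                        if counts_a[a] == 1 and counts_b[b] == 1}
            assert called == expected


class TestSingleGap:
    def test_shifted_pair_aligns(self):
        rng = np.random.default_rng(39)
        g = _random_tag(rng, 200)
        a, b = g[:92], g[5:97]
        hit = _single_gap(a, b)
        assert hit is not None and hit[0] == 5

    def test_unrelated_tags_do_not_align(self):
        rng = np.random.default_rng(40)
        assert _single_gap(_random_tag(rng), _random_tag(rng)) is None


class TestGenotyping:
    MARKER = rm.MarkerDefinition("DAFWA1", "SNP", "A" * 92, "C" + "A" * 91,
                                 1, "A", "C")

    def test_only_tag_a_seen(self):
        codes = genotype_rils([self.MARKER], {"r1": {"A" * 92: 10}})
        assert codes.loc["DAFWA1", "r1"] == "A"

    def test_below_min_depth_is_missing(self):
        codes = genotype_rils([self.MARKER], {"r1": {"A" * 92: 2}})
        assert codes.loc["DAFWA1", "r1"] == MISSING

    def test_both_tags_heterozygous(self):
        codes = genotype_rils([self.MARKER],
                              {"r1": {"A" * 92: 4, "C" + "A" * 91: 3}})
        assert codes.loc["DAFWA1", "r1"] == "H"

    def test_parent_codes_are_pure(self, e2e):
        matrix = e2e["matrix"]
        assert (matrix["ParentA"] == "A").all()
        assert (matrix["ParentB"] == "B").all()

    def test_parent_swap_symmetry(self, e2e):
        """Swapping the parental tag orientation swaps every A/B call."""
        markers = e2e["markers"]
        swapped = [rm.MarkerDefinition(m.marker_id, m.kind, m.tag_b, m.tag_a,
                                       m.variant_offset, m.allele_b,
                                       m.allele_a) for m in markers]
        per_sample, _ = demultiplex(e2e["records"], e2e["barcodes"])
        some = dict(list(per_sample.items())[:5])
        tags = {s: cluster_tags(seqs) for s, seqs in some.items()}
        direct = genotype_rils(markers, tags)
        flipped = genotype_rils(swapped, tags)
        swap = {"A": "B", "B": "A", "H": "H", MISSING: MISSING}
        assert (direct.map(swap.get) == flipped).all().all()

    def test_error_free_calls_match_truth(self, e2e):
        """Non-missing RIL calls agree with the simulated truth."""
        matrix, markers = e2e["matrix"], e2e["markers"]
        truth_tags = e2e["truth_tags"]
        truth_geno = e2e["truth_geno"]
        founders = e2e["founders"]
        # marker id -> truth variant key via the tag pair
        by_tag = {(r.tag_a, r.tag_b): (r.chrom, r.site_pos, r.flank)
                  for r in truth_tags.itertuples()}
        variant_of = {}
        for m in markers:
            chrom, site, flank = by_tag[(m.tag_a, m.tag_b)]
            hits = [v for v in founders.variants
                    if v.chrom == chrom and abs(v.pos - site) <= 100]
            variant_of[m.marker_id] = f"{hits[0].chrom}:{hits[0].pos}"
        agree = total = 0
        for m in markers:
            for ril in e2e["ril_cols"]:
                call = matrix.loc[m.marker_id, ril]
                if call == MISSING:
                    continue
                total += 1
                agree += call == truth_geno.loc[variant_of[m.marker_id], ril]
        assert total > 0 and agree / total >= 0.99


class TestNoisyPanelAccuracy:
    def test_noisy_calls_against_truth(self):
        """20x Poisson depth with 0.1% error keeps non-missing accuracy
        at or above 99%."""
        cfg = rm.GenomeConfig(chromosomes=[("chr1", 75_000, 50.0)],
                              n_variants=10, indel_fraction=0.1, seed=41)
        founders = rm.make_founders(cfg)
        pop = rm.simulate_population(founders, rm.PedigreeConfig(30, 8, 42))
        samples = {"ParentA": rm.founder_individual(founders, "A"),
                   "ParentB": rm.founder_individual(founders, "B"), **pop}
        barcodes = rm.simulate.assign_barcodes(list(samples), seed=43)
        lib = rm.RadLibraryConfig(mean_depth=20.0, error_rate=0.001,
                                  rng_seed=44)
        hsets = {n: rm.simulate.sample_haplotype_sequences(founders, i)
                 for n, i in samples.items()}
        records, _ = rm.digest_and_sequence(hsets, barcodes, lib)
        matrix, markers, _ = rm.genotype_fastq(records, barcodes,
                                               "ParentA", "ParentB")
        truth_tags = rm.truth_marker_tags(founders)
        truth_geno = rm.truth_genotypes(founders, pop)
        by_tag = {(r.tag_a, r.tag_b): r.site_pos
                  for r in truth_tags.itertuples()}
        agree = total = 0
        for m in markers:
            site = by_tag.get((m.tag_a, m.tag_b))
            if site is None:
                continue
            vkey = min((f"{v.chrom}:{v.pos}" for v in founders.variants
                        if abs(v.pos - site) <= 100),
                       key=lambda k: abs(int(k.split(":")[1]) - site))
            for ril in pop:
                call = matrix.loc[m.marker_id, ril]
                if call == MISSING:
                    continue
                total += 1
                agree += call == truth_geno.loc[vkey, ril]
        assert total > 100 and agree / total >= 0.99


class TestQc:
    def test_balanced_marker_zero_chi2(self):
        row = ["A"] * 47 + ["B"] * 47
        matrix = pd.DataFrame([row], index=["m1"],
                              columns=[f"r{i}" for i in range(94)])
        report = qc_matrix(matrix)
        assert report.loc["m1", "seg_chi2"] == 0.0
        assert report.loc["m1", "missing_rate"] == 0.0

    def test_fully_distorted_marker_chi2(self):
        row = ["A"] * 94
        matrix = pd.DataFrame([row], index=["m1"],
                              columns=[f"r{i}" for i in range(94)])
        assert qc_matrix(matrix).loc["m1", "seg_chi2"] == 94.0

    def test_simulated_panel_rarely_distorted(self, recovery):
        report = qc_matrix(recovery["matrix"])
        from scipy.stats import chi2
        crit = chi2.ppf(0.999, df=1)
        assert (report["seg_chi2"] > crit).mean() < 0.01
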