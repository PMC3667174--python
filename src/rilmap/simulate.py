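"""Forward simulation of a biparental F8 RIL RAD-seq experiment.

The simulator produces the study design end to end with known ground
truth: two fully homozygous founder genomes differing by SNPs and short
indels, F1 hybrids advanced to F_g recombinant inbred lines by single
seed descent (Poisson crossovers, no interference, so the Haldane map
function is exact for the simulated meiosis), and single-end EcoRI RAD
libraries with inline 8-nt barcodes, per-tag read depths and
substitution sequencing errors.

Coordinates are 1-based in truth tables and 0-based internally; variant
positions always refer to the founder-A ("reference") genome.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DNA = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

ECORI_SITE = "GAATTC"  # cut after the leading G (5'-G/AATTC-3')
TAG_LENGTH = 92        # 100-bp read minus the 8-nt inline barcode


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# founder genomes


@dataclass(frozen=True)
class Chromosome:
    id: str
    length_bp: int
    genetic_length_cm: float


@dataclass(frozen=True)
class Variant:
    """A founder-polymorphic site, in founder-A coordinates (1-based).

    For SNPs the alleles are single differing bases.  For indels the
    alleles are VCF-style anchored strings: the base at ``pos`` plus, on
    one side, the 1-10 bp that are inserted/deleted in founder B.
    """
    chrom: str
    pos: int
    kind: str            # 'SNP' | 'indel'
    allele_a: str
    allele_b: str

    def __post_init__(self):
        if self.kind == "SNP":
            assert len(self.allele_a) == len(self.allele_b) == 1
            assert self.allele_a != self.allele_b
        else:
            diff = abs(len(self.allele_a) - len(self.allele_b))
            assert 1 <= diff <= 10


@dataclass
class FounderGenome:
    chromosomes: list[Chromosome]
    seq_a: dict[str, str]
    seq_b: dict[str, str]
    variants: list[Variant]

    def chromosome(self, cid: str) -> Chromosome:
        return next(c for c in self.chromosomes if c.id == cid)


@dataclass
class GenomeConfig:
    """Specification of the founder pair handed to :func:`make_founders`.

    chromosomes: (id, length_bp, genetic_length_cm) triples.
    n_variants: total founder-polymorphic sites across the genome.
    at_cut_sites: place every variant inside a RAD tag window (the
        default; makes every variant discoverable by the genotyper).
        When False, variants are placed uniformly and no restriction
        sites are planted -- useful for genotype-level simulations.
    """
    chromosomes: Sequence[tuple[str, int, float]]
    n_variants: int
    indel_fraction: float = 0.08
    cut_site_spacing_bp: int = 1500
    min_variant_spacing: int = TAG_LENGTH
    at_cut_sites: bool = True
    allow_multi_variant_tags: bool = False
    seed: int = 0


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(DNA), size=length))


def _scrub_site(seq: list[str], rng: np.random.Generator,
                site: str = ECORI_SITE) -> None:
    """Mutate away every occurrence of ``site`` in place."""
    text = "".join(seq)
    start = 0
    while True:
        i = text.find(site, start)
        if i < 0:
            break
        j = i + len(site) // 2
        old = seq[j]
        seq[j] = rng.choice([b for b in DNA if b != old])
        text = "".join(seq)
        start = max(0, i - len(site))


def make_founders(config: GenomeConfig) -> FounderGenome:
    """Generate a homozygous founder pair plus its variant truth set.

    Raises ValueError when the requested variant count cannot be placed
    at the configured spacing (never silently truncates).
    """
    rng = np.random.default_rng(config.seed)
    chroms = [Chromosome(*c) for c in config.chromosomes]
    seq_a: dict[str, str] = {}
    sites: dict[str, list[int]] = {}
    margin = 200

    for chrom in chroms:
        seq = _random_sequence(rng, chrom.length_bp)
        _scrub_site(seq, rng)
        planted: list[int] = []
        if config.at_cut_sites:
            pos = margin
            while pos + len(ECORI_SITE) + margin <= chrom.length_bp:
                seq[pos:pos + len(ECORI_SITE)] = list(ECORI_SITE)
                planted.append(pos)
                pos += config.cut_site_spacing_bp
            # planting can create chance sites across the written edges;
            # mutate a base of each accidental site, outside planted sites
            planted_set = set(planted)
            text = "".join(seq)
            for i in _find_all(text, ECORI_SITE):
                if i in planted_set:
                    continue
                for off in range(len(ECORI_SITE)):
                    if all(not (p <= i + off < p + len(ECORI_SITE))
                           for p in planted):
                        old = seq[i + off]
                        seq[i + off] = rng.choice([b for b in DNA if b != old])
                        break
        seq_a[chrom.id] = "".join(seq)
        sites[chrom.id] = sorted(planted)

    variants = _place_variants(rng, config, chroms, seq_a, sites)
    seq_b = {c.id: _apply_variants(seq_a[c.id],
                                   [v for v in variants if v.chrom == c.id])
             for c in chroms}
    return FounderGenome(chroms, seq_a, seq_b, sorted(
        variants, key=lambda v: (v.chrom, v.pos)))


def _find_all(text: str, pat: str) -> list[int]:
    out, i = [], text.find(pat)
    while i >= 0:
        out.append(i)
        i = text.find(pat, i + 1)
    return out


def _place_variants(rng, config: GenomeConfig, chroms, seq_a, sites):
    n_indels = int(round(config.n_variants * config.indel_fraction))
    kinds = ["indel"] * n_indels + ["SNP"] * (config.n_variants - n_indels)
    rng.shuffle(kinds)

    if config.at_cut_sites:
        # one variant per tag window; by default at most one flank per site
        # so the 92-bp spacing invariant holds between variants
        windows = []
        for chrom in chroms:
            for i in sites[chrom.id]:
                flank = rng.choice(["down", "up"])
                windows.append((chrom.id, i, flank))
                if config.allow_multi_variant_tags:
                    windows.append((chrom.id, i, "up" if flank == "down" else "down"))
        if config.n_variants > len(windows):
            raise ValueError(
                f"cannot place {config.n_variants} variants in "
                f"{len(windows)} tag windows; lower the variant count or "
                "the cut-site spacing")
        chosen = [windows[i] for i in
                  rng.choice(len(windows), size=config.n_variants, replace=False)]
        variants = [_variant_in_window(rng, seq_a[c], c, i, flank, kind)
                    for (c, i, flank), kind in zip(chosen, kinds)]
    else:
        variants = []
        for chrom in chroms:
            n_here = int(round(config.n_variants * chrom.length_bp /
                               sum(c.length_bp for c in chroms)))
            span = chrom.length_bp - 2 * 200
            if n_here * config.min_variant_spacing > span:
                raise ValueError(
                    f"variant density infeasible on {chrom.id}: "
                    f"{n_here} variants need more than {span} bp at "
                    f"{config.min_variant_spacing} bp spacing")
            pos = np.sort(rng.choice(span - n_here * config.min_variant_spacing,
                                     size=n_here, replace=False))
            pos = pos + 200 + np.arange(n_here) * config.min_variant_spacing
            for p, kind in zip(pos, kinds[:n_here]):
                variants.append(_make_variant(rng, seq_a[chrom.id], chrom.id,
                                              int(p), kind))
            kinds = kinds[n_here:]
        while len(variants) > config.n_variants:
            variants.pop()
    return variants


def _variant_in_window(rng, seq, chrom_id, site0, flank, kind):
    """Pick a variant position inside one 92-bp tag window of a cut site."""
    for _ in range(50):
        glen = int(rng.integers(1, 11)) if kind == "indel" else 0
        # tag offsets 1..5 are the AATTC overhang; keep a safety margin
        lo, hi = 8, TAG_LENGTH - 7 - glen
        t = int(rng.integers(lo, hi + 1))
        if flank == "down":
            g = site0 + t          # 0-based genome position of tag offset t
        else:
            g = site0 + 5 - t
            if kind == "indel" and g + glen >= site0:
                continue
        var = _make_variant(rng, seq, chrom_id, g, kind, glen)
        if var is not None and not _touches_site(seq, var):
            return var
    raise RuntimeError("could not place a site-preserving variant")


def _make_variant(rng, seq, chrom_id, g0, kind, glen=None):
    if kind == "SNP":
        ref = seq[g0]
        alt = rng.choice([b for b in DNA if b != ref])
        return Variant(chrom_id, g0 + 1, "SNP", ref, str(alt))
    glen = glen or int(rng.integers(1, 11))
    if rng.random() < 0.5:  # deletion in founder B
        if g0 + 1 + glen > len(seq):
            return None
        return Variant(chrom_id, g0 + 1, "indel",
                       seq[g0:g0 + 1 + glen], seq[g0])
    ins = "".join(rng.choice(list(DNA), size=glen))
    return Variant(chrom_id, g0 + 1, "indel", seq[g0], seq[g0] + ins)


def _touches_site(seq, var: Variant) -> bool:
    """True when applying the variant creates or destroys an EcoRI site."""
    g0 = var.pos - 1
    lo = max(0, g0 - 12)
    hi = min(len(seq), g0 + len(var.allele_a) + 12)
    before = seq[lo:hi]
    after = before[:g0 - lo] + var.allele_b + seq[g0 + len(var.allele_a):hi]
    return before.count(ECORI_SITE) != after.count(ECORI_SITE)


def _apply_variants(seq: str, variants: list[Variant]) -> str:
    out = seq
    for v in sorted(variants, key=lambda v: -v.pos):
        g0 = v.pos - 1
        assert out[g0:g0 + len(v.allele_a)] == v.allele_a
        out = out[:g0] + v.allele_b + out[g0 + len(v.allele_a):]
    return out


def variant_table(founders: FounderGenome) -> pd.DataFrame:
    return pd.DataFrame(
        [(v.chrom, v.pos, v.kind, v.allele_a, v.allele_b)
         for v in founders.variants],
        columns=["chrom", "pos", "kind", "allele_a", "allele_b"])


# ---------------------------------------------------------------------------
# meiosis and single-seed descent

Segment = tuple[str, int, int]  # (founder label 'A'|'B', start0, end0) half-open


@dataclass
class RilGenome:
    """Two haplotypes per chromosome, each a tiling of founder segments."""
    haplotypes: dict[str, tuple[list[Segment], list[Segment]]]

    def heterozygosity(self, founders: FounderGenome) -> float:
        calls = [self.genotype_at(v.chrom, v.pos) for v in founders.variants]
        return sum(c == "H" for c in calls) / max(len(calls), 1)

    def genotype_at(self, chrom: str, pos: int) -> str:
        h1, h2 = self.haplotypes[chrom]
        a = _label_at(h1, pos - 1)
        b = _label_at(h2, pos - 1)
        return a if a == b else "H"


def _label_at(segs: list[Segment], g0: int) -> str:
    for label, s, e in segs:
        if s <= g0 < e:
            return label
    raise ValueError(f"position {g0} not covered by segments")


@dataclass
class PedigreeConfig:
    n_rils: int = 94
    final_generation: int = 8
    rng_seed: int = 0

    def __post_init__(self):
        if self.final_generation < 2:
            raise ValueError("final_generation must be >= 2")
        if self.n_rils < 1:
            raise ValueError("n_rils must be >= 1")


def founder_individual(founders: FounderGenome, label: str) -> RilGenome:
    return RilGenome({c.id: ([(label, 0, c.length_bp)], [(label, 0, c.length_bp)])
                      for c in founders.chromosomes})


def f1_individual(founders: FounderGenome) -> RilGenome:
    return RilGenome({c.id: ([("A", 0, c.length_bp)], [("B", 0, c.length_bp)])
                      for c in founders.chromosomes})


def simulate_gamete(parent: RilGenome, founders: FounderGenome,
                    rng: np.random.Generator) -> dict[str, list[Segment]]:
    """One meiotic product: Poisson(L_cM/100) crossovers, breakpoints
    uniform in genetic coordinates (uniform recombination rate)."""
    gamete = {}
    for chrom in founders.chromosomes:
        h = parent.haplotypes[chrom.id]
        n_co = rng.poisson(chrom.genetic_length_cm / 100.0)
        breaks = sorted(int(f * chrom.length_bp)
                        for f in rng.uniform(size=n_co))
        breaks = [b for b in breaks if 0 < b < chrom.length_bp]
        cur = int(rng.integers(2))
        segs: list[Segment] = []
        prev = 0
        for b in breaks + [chrom.length_bp]:
            if b > prev:
                segs.extend(_slice_segments(h[cur], prev, b))
            prev = b
            cur = 1 - cur
        gamete[chrom.id] = _merge_segments(segs)
    return gamete


def _slice_segments(segs: list[Segment], a: int, b: int) -> list[Segment]:
    out = []
    for label, s, e in segs:
        lo, hi = max(s, a), min(e, b)
        if lo < hi:
            out.append((label, lo, hi))
    return out


def _merge_segments(segs: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in segs:
        if out and out[-1][0] == seg[0] and out[-1][2] == seg[1]:
            out[-1] = (seg[0], out[-1][1], seg[2])
        else:
            out.append(seg)
    return out


def self_cross(parent: RilGenome, founders: FounderGenome,
               rng: np.random.Generator) -> RilGenome:
    g1 = simulate_gamete(parent, founders, rng)
    g2 = simulate_gamete(parent, founders, rng)
    return RilGenome({c: (g1[c], g2[c]) for c in g1})


def advance_ssd(f1: RilGenome, founders: FounderGenome, generations: int,
                rng: np.random.Generator) -> RilGenome:
    """Advance an F1 to generation F_g by single seed descent (selfing,
    one offspring kept per generation)."""
    if generations < 2:
        raise ValueError("generations must be >= 2")
    ind = f1
    for _ in range(generations - 1):
        ind = self_cross(ind, founders, rng)
    return ind


def simulate_population(founders: FounderGenome,
                        pedigree: PedigreeConfig) -> dict[str, RilGenome]:
    rng = np.random.default_rng(pedigree.rng_seed)
    f1 = f1_individual(founders)
    return {f"RIL{i + 1:03d}": advance_ssd(f1, founders,
                                           pedigree.final_generation, rng)
            for i in range(pedigree.n_rils)}


def truth_genotypes(founders: FounderGenome,
                    rils: dict[str, RilGenome]) -> pd.DataFrame:
    """Marker x sample truth codes {A,B,H} keyed '<chrom>:<pos>'."""
    index = [f"{v.chrom}:{v.pos}" for v in founders.variants]
    data = {name: [ind.genotype_at(v.chrom, v.pos) for v in founders.variants]
            for name, ind in rils.items()}
    return pd.DataFrame(data, index=index)


def segment_table(rils: dict[str, RilGenome]) -> pd.DataFrame:
    rows = []
    for name, ind in rils.items():
        for chrom, (h1, h2) in ind.haplotypes.items():
            for hap, segs in ((1, h1), (2, h2)):
                for label, s, e in segs:
                    rows.append((name, chrom, hap, label, s + 1, e))
    return pd.DataFrame(rows, columns=["sample", "chrom", "haplotype",
                                       "founder", "start", "end"])


# ---------------------------------------------------------------------------
# RAD library construction


@dataclass
class RadLibraryConfig:
    recognition_site: str = ECORI_SITE
    read_length: int = 100
    barcode_length: int = 8
    mean_depth: float = 20.0
    depth_distribution: str = "poisson"   # 'poisson' | 'fixed'
    error_rate: float = 0.001
    barcode_error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.read_length - self.barcode_length != TAG_LENGTH:
            raise ValueError("read_length - barcode_length must equal 92")

    @property
    def tag_length(self) -> int:
        return self.read_length - self.barcode_length


def find_cut_sites(seq: str, site: str = ECORI_SITE) -> list[int]:
    return _find_all(seq, site)


def flank_tags(seq: str, site0: int, tag_len: int = TAG_LENGTH) -> list[tuple[str, str]]:
    """The two 92-bp tags flanking one cut site, both starting 'AATTC'.

    The downstream tag reads the forward strand from the cut; the
    upstream tag reads the reverse strand from the cut on the other
    side of the overhang.  Flanks that run off the sequence are skipped.
    """
    tags = []
    if site0 + 1 + tag_len <= len(seq):
        tags.append(("down", seq[site0 + 1:site0 + 1 + tag_len]))
    if site0 + 5 - tag_len >= 0:
        tags.append(("up", revcomp(seq[site0 + 5 - tag_len:site0 + 5])))
    return tags


def assign_barcodes(samples: Sequence[str], seed: int = 0,
                    length: int = 8) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    barcodes: dict[str, str] = {}
    used = set()
    for name in samples:
        while True:
            bc = "".join(rng.choice(list(DNA), size=length))
            if bc not in used:
                used.add(bc)
                barcodes[name] = bc
                break
    return barcodes


def sample_haplotype_sequences(founders: FounderGenome,
                               ind: RilGenome) -> list[dict[str, str]]:
    """Realize the two haplotype nucleotide sequences of an individual.

    Founders differ only at the listed variants, so a haplotype is the
    founder-A backbone with the B allele applied wherever the haplotype
    carries a B segment.
    """
    out = []
    for hap in (0, 1):
        seqs = {}
        for chrom in founders.chromosomes:
            segs = ind.haplotypes[chrom.id][hap]
            b_vars = [v for v in founders.variants if v.chrom == chrom.id
                      and _label_at(segs, v.pos - 1) == "B"]
            seqs[chrom.id] = _apply_variants(founders.seq_a[chrom.id], b_vars)
        out.append(seqs)
    return out


def digest_and_sequence(haplotype_sets: dict[str, list[dict[str, str]]],
                        barcodes: dict[str, str],
                        config: RadLibraryConfig,
                        ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Emit barcoded 100-bp reads for every cut-site flank of every sample.

    haplotype_sets maps sample -> list of haplotype genomes (dict of
    chromosome sequences); read depth is drawn per (site, flank,
    haplotype) with per-haplotype mean mean_depth / n_haplotypes.
    Returns the FASTQ records (id, seq, qual) and a truth read-origin
    table.
    """
    rng = np.random.default_rng(config.rng_seed)
    tag_len = config.tag_length
    qual = chr(35 + 33) * config.read_length      # fixed Q35 placeholder
    records: list[tuple[str, str, str]] = []
    origins = []
    for sample, haplotypes in haplotype_sets.items():
        barcode = barcodes[sample]
        n_copies = len(haplotypes)
        mean = config.mean_depth / n_copies
        for hap_i, genome in enumerate(haplotypes):
            for chrom, seq in genome.items():
                for site0 in find_cut_sites(seq, config.recognition_site):
                    for flank, tag in flank_tags(seq, site0, tag_len):
                        if config.depth_distribution == "fixed":
                            depth = int(round(mean))
                        else:
                            depth = int(rng.poisson(mean))
                        for j in range(depth):
                            read_tag = _with_errors(tag, config.error_rate, rng)
                            read_bc = _with_errors(barcode,
                                                   config.barcode_error_rate, rng)
                            rid = (f"{sample}:{chrom}:{site0 + 1}:{flank}"
                                   f":h{hap_i + 1}:{j}")
                            records.append((rid, read_bc + read_tag, qual))
                            origins.append((rid, sample, chrom, site0 + 1,
                                            flank, hap_i + 1))
    origin_df = pd.DataFrame(origins, columns=["read_id", "sample", "chrom",
                                               "site_pos", "flank", "haplotype"])
    return records, origin_df


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        out[pos] = rng.choice([b for b in DNA if b != out[pos]])
    return "".join(out)


def truth_marker_tags(founders: FounderGenome,
                      tag_len: int = TAG_LENGTH,
                      site: str = ECORI_SITE) -> pd.DataFrame:
    """Ground-truth polymorphic tag pairs: for each (cut site, flank)
    the founder-A and founder-B tags, restricted to windows where they
    differ.  This is exactly the marker set a perfect genotyper should
    recover from error-free reads."""
    rows = []
    for chrom in founders.chromosomes:
        sites_a = find_cut_sites(founders.seq_a[chrom.id], site)
        sites_b = find_cut_sites(founders.seq_b[chrom.id], site)
        if len(sites_a) != len(sites_b):
            raise ValueError(f"{chrom.id}: founders have unequal cut-site "
                             "counts; variants disturbed a recognition site")
        for (sa, sb) in zip(sites_a, sites_b):
            tags_a = dict(flank_tags(founders.seq_a[chrom.id], sa, tag_len))
            tags_b = dict(flank_tags(founders.seq_b[chrom.id], sb, tag_len))
            for flank in tags_a:
                if flank in tags_b and tags_a[flank] != tags_b[flank]:
                    rows.append((chrom.id, sa + 1, flank,
                                 tags_a[flank], tags_b[flank]))
    return pd.DataFrame(rows, columns=["chrom", "site_pos", "flank",
                                       "tag_a", "tag_b"])
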