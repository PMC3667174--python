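"""Barcoded RAD FASTQ -> marker x sample genotype matrix.

Stages: exact-prefix demultiplexing on the 8-nt inline barcode, trim to
the 92-bp tag, identity clustering of tags within each sample,
repeat filtering (tags backed by more than 100 reads are presumed
repetitive and dropped), parental marker calling (SNP = unique
cross-parent tag pair at Hamming distance exactly 1; indel = unique
single-gap alignment with gap 1-10 bp and no mismatches), and RIL
genotyping by tag presence at a minimum read depth.

Genotype codes: 'A' and 'B' for the two parental alleles, 'H' for
heterozygous (both tags seen), '-' for missing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

TAG_LENGTH = 92
MISSING = "-"


@dataclass(frozen=True)
class RadTag:
    sample: str
    sequence: str
    read_count: int

    def __post_init__(self):
        assert len(self.sequence) == TAG_LENGTH
        assert self.read_count >= 1


@dataclass(frozen=True)
class MarkerDefinition:
    """A parent-polymorphic tag pair.

    SNP markers carry the 1-based offset of the variant base within the
    tag and the two bases; indel markers carry the inserted/deleted
    string in the allele of the longer tag and '' in the other, with
    variant_offset pointing at the first divergent tag position.
    """
    marker_id: str
    kind: str          # 'SNP' | 'indel'
    tag_a: str
    tag_b: str
    variant_offset: int
    allele_a: str
    allele_b: str


def load_barcode_map(source: str | Path | Mapping[str, str]) -> dict[str, str]:
    """sample -> barcode map from a two-column CSV or a mapping.

    Duplicate barcodes or non-8-nt barcodes are load-time errors.
    """
    if isinstance(source, Mapping):
        items = list(source.items())
    else:
        df = pd.read_csv(source)
        items = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    barcodes = [bc for _, bc in items]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcode map")
    lengths = {len(bc) for bc in barcodes}
    if lengths and lengths != {len(barcodes[0])}:
        raise ValueError("barcodes must all have the same length")
    return dict(items)


def demultiplex(reads: Iterable, barcode_map: Mapping[str, str],
                tag_length: int = TAG_LENGTH,
                ) -> tuple[dict[str, list[str]], int]:
    """Assign reads to samples by exact barcode prefix match.

    Accepts either raw sequence strings or (id, seq, qual) records.
    Reads whose prefix matches no barcode (including single-mismatch
    barcodes) are routed to the unassigned sink and counted.
    Returns ({sample: [92-bp tag, ...]}, n_unassigned).
    """
    barcode_map = load_barcode_map(barcode_map)
    bc_len = len(next(iter(barcode_map.values()))) if barcode_map else 0
    lookup = {bc: sample for sample, bc in barcode_map.items()}
    assigned: dict[str, list[str]] = {s: [] for s in barcode_map}
    unassigned = 0
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        sample = lookup.get(seq[:bc_len])
        if sample is None:
            unassigned += 1
        else:
            assigned[sample].append(seq[bc_len:bc_len + tag_length])
    return assigned, unassigned


def cluster_tags(tag_seqs: Iterable[str]) -> dict[str, int]:
    """Identity clustering: one tag per distinct sequence, count =
    multiplicity.  Sequencing errors stay as separate low-count tags."""
    return dict(Counter(tag_seqs))


def filter_repetitive(tags: Mapping[str, int],
                      max_reads: int = 100) -> tuple[dict[str, int], int]:
    """Drop tags backed by more than ``max_reads`` reads (repetitive
    regions collapse many copies into one tag).  Boundary: a tag at
    exactly max_reads is kept."""
    kept = {seq: n for seq, n in tags.items() if n <= max_reads}
    return kept, len(tags) - len(kept)


# ---------------------------------------------------------------------------
# parental marker calling


def _hamming1_offset(a: str, b: str) -> int | None:
    """1-based offset of the single mismatch, or None if distance != 1."""
    off = -1
    for i in range(len(a)):
        if a[i] != b[i]:
            if off >= 0:
                return None
            off = i
    return off + 1 if off >= 0 else None


def _snp_candidate_pairs(tags_a: Iterable[str],
                         tags_b: Iterable[str]) -> list[tuple[str, str, int]]:
    """All cross-parent pairs at Hamming distance exactly 1.

    A distance-1 pair agrees on at least one half of the tag, so
    bucketing on both halves finds every pair without the full
    quadratic scan.
    """
    half = TAG_LENGTH // 2
    buckets: dict[tuple[int, str], list[str]] = {}
    for b in tags_b:
        buckets.setdefault((0, b[:half]), []).append(b)
        buckets.setdefault((1, b[half:]), []).append(b)
    pairs = []
    seen = set()
    for a in tags_a:
        for key in ((0, a[:half]), (1, a[half:])):
            for b in buckets.get(key, ()):
                if (a, b) in seen:
                    continue
                seen.add((a, b))
                off = _hamming1_offset(a, b)
                if off is not None:
                    pairs.append((a, b, off))
    return pairs


def _single_gap(a: str, b: str, max_gap: int = 10, min_anchor: int = 3):
    """Align two equal-length tags allowing exactly one internal gap of
    1..max_gap bases and zero mismatches (free end overhang).

    Returns (gap_len, gap_pos_1based, side) where side is 'A' when the
    extra bases sit in tag a, else 'B'; None when no such alignment
    exists.  The gap is placed at the end of the longest common prefix;
    if several gap lengths fit (repeat runs), the smallest wins.  At
    least ``min_anchor`` bases must match beyond the gap, so a gap
    hanging off the tag end (which any near-identical pair would
    "align" to) does not count.
    """
    if a == b:
        return None
    p = 0
    n = len(a)
    while p < n and a[p] == b[p]:
        p += 1
    for g in range(1, max_gap + 1):
        if n - p - g < min_anchor:
            break
        if a[p + g:] == b[p:n - g]:
            return g, p + 1, "A"
        if b[p + g:] == a[p:n - g]:
            return g, p + 1, "B"
    return None


def call_parental_markers(tags_parent_a: Mapping[str, int],
                          tags_parent_b: Mapping[str, int],
                          min_depth: int = 3,
                          max_gap: int = 10,
                          ) -> tuple[list[MarkerDefinition], dict[str, int]]:
    """Call SNP/indel markers from the two parents' clustered tag sets.

    Tags identical across parents are monomorphic and removed.  A SNP
    marker requires a unique cross-parent pairing at Hamming distance
    exactly 1; an indel marker a unique single-gap alignment.  Tags
    with two or more candidate partners are discarded as ambiguous
    (possible paralogs).  All rejection counts are returned by reason.
    """
    rejects = Counter()
    shared = set(tags_parent_a) & set(tags_parent_b)
    rejects["monomorphic"] = len(shared)
    a_only = {s: c for s, c in tags_parent_a.items()
              if s not in shared and c >= min_depth}
    b_only = {s: c for s, c in tags_parent_b.items()
              if s not in shared and c >= min_depth}
    rejects["low_depth"] = (len(tags_parent_a) + len(tags_parent_b)
                            - 2 * len(shared) - len(a_only) - len(b_only))

    partners_a: dict[str, list[tuple]] = {a: [] for a in a_only}
    partners_b: dict[str, list[tuple]] = {b: [] for b in b_only}
    snp_pairs = set()
    for a, b, off in _snp_candidate_pairs(a_only, b_only):
        partners_a[a].append(("SNP", b, off))
        partners_b[b].append(("SNP", a, off))
        snp_pairs.add((a, b))
    for a in a_only:
        for b in b_only:
            if (a, b) in snp_pairs:
                # a Hamming-1 pair is a SNP pair by definition; a gapped
                # alignment of the same pair would be a spurious duplicate
                continue
            hit = _single_gap(a, b, max_gap)
            if hit is not None:
                partners_a[a].append(("indel", b, hit))
                partners_b[b].append(("indel", a, hit))

    markers = []
    for a in sorted(a_only):
        plist = partners_a[a]
        if not plist:
            rejects["unpaired"] += 1
            continue
        if len(plist) > 1:
            rejects["ambiguous"] += 1
            continue
        kind, b, info = plist[0]
        if len(partners_b[b]) != 1:
            rejects["ambiguous"] += 1
            continue
        if kind == "SNP":
            off = info
            markers.append(("SNP", a, b, off, a[off - 1], b[off - 1]))
        else:
            g, pos, side = info
            if side == "A":
                allele_a, allele_b = a[pos - 1:pos - 1 + g], ""
            else:
                allele_a, allele_b = "", b[pos - 1:pos - 1 + g]
            markers.append(("indel", a, b, pos, allele_a, allele_b))

    out = []
    counters = {"SNP": 0, "indel": 0}
    for kind, a, b, off, al_a, al_b in markers:
        counters[kind] += 1
        prefix = "DAFWA" if kind == "SNP" else "iDAFWA"
        out.append(MarkerDefinition(f"{prefix}{counters[kind]}", kind,
                                    a, b, off, al_a, al_b))
    return out, dict(rejects)


def genotype_rils(markers: list[MarkerDefinition],
                  sample_tags: Mapping[str, Mapping[str, int]],
                  min_depth: int = 3) -> pd.DataFrame:
    """Score each sample at each marker by parental-tag presence.

    'A' when only tag_a is present at depth >= min_depth, 'B'
    symmetric, 'H' when both reach min_depth, '-' otherwise.
    Returns a marker x sample DataFrame of codes.
    """
    data = {}
    for sample, tags in sample_tags.items():
        col = []
        for m in markers:
            da = tags.get(m.tag_a, 0)
            db = tags.get(m.tag_b, 0)
            has_a, has_b = da >= min_depth, db >= min_depth
            if has_a and has_b:
                col.append("H")
            elif has_a:
                col.append("A")
            elif has_b:
                col.append("B")
            else:
                col.append(MISSING)
        data[sample] = col
    return pd.DataFrame(data, index=[m.marker_id for m in markers])


def qc_matrix(matrix: pd.DataFrame, ril_samples: list[str] | None = None,
              missing_cutoff: float = 0.2) -> pd.DataFrame:
    """Per-marker QC over the RIL columns: missing rate, founder-A
    allele frequency, and a 1:1 segregation chi-square over A/B calls.
    Markers above the missing-rate cutoff are flagged, not removed."""
    cols = ril_samples if ril_samples is not None else list(matrix.columns)
    sub = matrix[cols]
    n_a = (sub == "A").sum(axis=1)
    n_b = (sub == "B").sum(axis=1)
    n_called = n_a + n_b
    missing = (sub == MISSING).sum(axis=1) / len(cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq_a = np.where(n_called > 0, n_a / n_called, np.nan)
        chi2 = np.where(n_called > 0,
                        (n_a - n_b) ** 2 / n_called, np.nan)
    report = pd.DataFrame({
        "missing_rate": missing,
        "freq_a": freq_a,
        "seg_chi2": chi2,
        "seg_p": stats.chi2.sf(chi2, df=1),
        "flag_missing": missing > missing_cutoff,
    }, index=matrix.index)
    return report


def genotype_fastq(fastq_reads: Iterable, barcode_map: Mapping[str, str],
                   parent_a: str, parent_b: str,
                   min_depth: int = 3, max_reads: int = 100,
                   max_gap: int = 10):
    """End-to-end convenience: reads -> (matrix, markers, log)."""
    per_sample, unassigned = demultiplex(fastq_reads, barcode_map)
    tags = {s: filter_repetitive(cluster_tags(seqs), max_reads)[0]
            for s, seqs in per_sample.items()}
    markers, rejects = call_parental_markers(tags[parent_a], tags[parent_b],
                                             min_depth=min_depth,
                                             max_gap=max_gap)
    matrix = genotype_rils(markers, tags, min_depth=min_depth)
    log = {"unassigned_reads": unassigned, **rejects}
    return matrix, markers, log
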