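"""k-mer genome survey: histogram, peak depth, genome size, coverage.

The survey model is the classic one used for short-read genome sizing:
count canonical k-mers (default k=17) across all reads, locate the
modal depth p of the histogram after excluding the low-depth error
bump, and estimate the genome size as

    G = (total k-mer volume) / p

where the volume is sum_d d*c_d over the depth->count histogram.  The
peak depth estimates *k-mer* coverage, which is lower than per-base
coverage by the edge factor (L - k + 1)/L for read length L; sequencing
coverage is therefore reported separately as total sequenced bases over
the estimated genome size.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class KmerHistogram:
    """Depth -> number of distinct k-mers observed at that depth."""
    k: int
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def volume(self) -> int:
        """Total k-mer instances counted (the survey's "K-number")."""
        return sum(d * c for d, c in self.counts.items())

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(sorted(self.counts.items()), columns=["depth", "count"])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, k: int = 17) -> "KmerHistogram":
        df = pd.read_csv(path)
        return cls(k=k, counts=dict(zip(df["depth"].astype(int),
                                        df["count"].astype(int))))


def count_kmers(reads: Iterable[str], k: int = 17) -> KmerHistogram:
    """Count canonical k-mers (lexicographic min of a k-mer and its
    reverse complement) over a read collection.

    k must be odd and in (1, 31]; odd k rules out self-reverse-
    complementary k-mers, keeping canonicalization unambiguous.
    Windows containing non-ACGT characters are skipped; reads shorter
    than k contribute nothing (warned once).
    """
    if not (1 < k <= 31) or k % 2 == 0:
        raise ValueError("k must be odd and in (1, 31]")
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    kmer_counts: Counter[int] = Counter()
    short = 0
    for read in reads:
        read = read.upper()
        if len(read) < k:
            short += 1
            continue
        fwd = rev = run = 0
        for ch in read:
            code = _CODE.get(ch, -1)
            if code < 0:
                run = fwd = rev = 0
                continue
            fwd = ((fwd << 2) | code) & mask
            rev = (rev >> 2) | ((3 - code) << shift)
            run += 1
            if run >= k:
                kmer_counts[fwd if fwd <= rev else rev] += 1
    if short:
        warnings.warn(f"{short} reads shorter than k={k} were skipped")
    hist = Counter(kmer_counts.values())
    return KmerHistogram(k=k, counts=dict(hist))


def find_peak(hist: KmerHistogram, min_peak_depth: int = 4) -> int:
    """Modal depth of the histogram at depth >= min_peak_depth.

    The cutoff excludes the error bump at depth 1-3.  Ties between
    depths are broken toward the smaller depth.
    """
    candidates = {d: c for d, c in hist.counts.items() if d >= min_peak_depth}
    if not candidates:
        raise ValueError(
            f"no k-mer depth >= {min_peak_depth}; histogram holds only the "
            "low-depth error region")
    best = max(candidates.values())
    return min(d for d, c in candidates.items() if c == best)


def genome_size_from_volume(volume: float, peak_depth: float) -> float:
    """G = K-number / peak depth, in bp."""
    if peak_depth <= 0:
        raise ValueError("peak depth must be positive")
    return volume / peak_depth


def estimate_genome_size(hist: KmerHistogram, min_peak_depth: int = 4) -> float:
    return genome_size_from_volume(hist.volume, find_peak(hist, min_peak_depth))


def estimate_coverage(total_sequenced_bp: float, genome_size: float) -> float:
    """Fold coverage of the genome by the sequencing data."""
    if total_sequenced_bp <= 0 or genome_size <= 0:
        raise ValueError("inputs must be positive")
    return total_sequenced_bp / genome_size


@dataclass(frozen=True)
class RepeatShares:
    """Share of k-mer volume at and above the repeat threshold.

    This is a k-mer-volume statistic (how much of the counted k-mer
    mass sits at repeat-like depth), not a genome-fraction estimate.
    """
    high_fraction: float
    low_fraction: float
    threshold: int


def repeat_volume_fraction(hist: KmerHistogram, min_peak_depth: int = 4,
                           threshold: int | None = None) -> RepeatShares:
    """Split the k-mer volume at ``threshold`` (default 2 * peak depth)."""
    if threshold is None:
        threshold = 2 * find_peak(hist, min_peak_depth)
    vol = hist.volume
    if vol == 0:
        return RepeatShares(0.0, 1.0, threshold)
    high = sum(d * c for d, c in hist.counts.items() if d >= threshold)
    return RepeatShares(high / vol, 1.0 - high / vol, threshold)
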