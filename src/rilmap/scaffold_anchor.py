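"""Anchor markers onto assembly scaffolds by unique exact tag match.

A marker anchors when its reference-parent tag (tag_a) occurs, on
either strand, at exactly one site on exactly one scaffold — a strict
reading of the "one unique scaffold with a 100% match" rule: full
length, no mismatches, no gaps.  Anchors carry the 1-based variant
position on the scaffold forward strand, following the supplementary
":" coordinate convention of sequence-defined maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .rad_genotyping import MarkerDefinition
from .simulate import revcomp


@dataclass(frozen=True)
class Anchor:
    marker_id: str
    scaffold_id: str
    position: int      # 1-based variant position on the forward strand
    strand: str        # '+' or '-' (strand of the tag match)


def _find_all(text: str, pat: str) -> list[int]:
    out, i = [], text.find(pat)
    while i >= 0:
        out.append(i)
        i = text.find(pat, i + 1)
    return out


def locate_tag(marker: MarkerDefinition,
               scaffolds: Mapping[str, str]) -> tuple[Anchor | None, str]:
    """Exact search of tag_a and its reverse complement over scaffolds.

    Returns (anchor, reason); reason is 'ok', 'no_hit', or 'ambiguous'
    (several scaffolds, or several sites on one scaffold).
    """
    tag = marker.tag_a
    rc = revcomp(tag)
    hits: list[tuple[str, int, str]] = []
    for sid, seq in scaffolds.items():
        for pos in _find_all(seq, tag):
            hits.append((sid, pos, "+"))
        if rc != tag:
            for pos in _find_all(seq, rc):
                hits.append((sid, pos, "-"))
        if len(hits) > 1:
            return None, "ambiguous"
    if not hits:
        return None, "no_hit"
    sid, start0, strand = hits[0]
    offset = marker.variant_offset or 1
    if strand == "+":
        pos = start0 + offset
    else:
        pos = start0 + (len(tag) - offset) + 1
    return Anchor(marker.marker_id, sid, pos, strand), "ok"


def anchor_markers(markers: list[MarkerDefinition],
                   scaffolds: Mapping[str, str],
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Anchor every marker; returns the anchor table and reject counts."""
    rows = []
    rejects = {"no_hit": 0, "ambiguous": 0}
    for m in markers:
        anchor, reason = locate_tag(m, scaffolds)
        if anchor is None:
            rejects[reason] += 1
        else:
            rows.append((anchor.marker_id, anchor.scaffold_id,
                         anchor.position, anchor.strand))
    df = pd.DataFrame(rows, columns=["marker_id", "scaffold", "position",
                                     "strand"])
    return df, rejects


def integrate(anchors: pd.DataFrame, lmap,
              scaffold_lengths: Mapping[str, int],
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach anchored scaffolds to the map groups of their markers.

    Returns (per-group table with distinct scaffold counts and summed
    length spans, conflict table).  A scaffold whose markers land in
    two or more groups is a conflict and excluded from the counts; a
    scaffold is counted once per group however many markers it carries.
    """
    rows = []
    for _, rec in anchors.iterrows():
        located = lmap.locus_of(rec["marker_id"])
        if located is None:
            continue
        group, locus = located
        rows.append((rec["scaffold"], group, locus.id, rec["marker_id"]))
    placed = pd.DataFrame(rows, columns=["scaffold", "group", "locus",
                                         "marker_id"])
    if placed.empty:
        empty = pd.DataFrame(columns=["group", "n_scaffolds",
                                      "scaffold_span_bp"])
        return empty, pd.DataFrame(columns=["scaffold", "groups"])

    groups_per_scaffold = placed.groupby("scaffold")["group"].nunique()
    conflicted = groups_per_scaffold[groups_per_scaffold > 1].index
    conflicts = pd.DataFrame(
        [(s, sorted(placed.loc[placed["scaffold"] == s, "group"].unique()))
         for s in conflicted], columns=["scaffold", "groups"])
    clean = placed[~placed["scaffold"].isin(conflicted)]

    per_group = (clean.drop_duplicates(["scaffold", "group"])
                 .groupby("group")["scaffold"]
                 .agg(list).reset_index())
    per_group["n_scaffolds"] = per_group["scaffold"].map(len)
    per_group["scaffold_span_bp"] = per_group["scaffold"].map(
        lambda ss: sum(scaffold_lengths[s] for s in ss))
    return per_group[["group", "n_scaffolds", "scaffold_span_bp"]], conflicts


def coverage_fractions(integrated_span_bp: float, assembly_span_bp: float,
                       genome_size_bp: float) -> tuple[float, float]:
    """Anchored span as a percentage of the assembly and of the genome."""
    if min(integrated_span_bp, assembly_span_bp, genome_size_bp) <= 0:
        raise ValueError("spans must be positive")
    return (100.0 * integrated_span_bp / assembly_span_bp,
            100.0 * integrated_span_bp / genome_size_bp)
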