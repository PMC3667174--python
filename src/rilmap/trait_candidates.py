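"""Trait mapping by co-segregation with sequence-defined markers.

A binary monogenic trait scored on near-homozygous RILs behaves as one
extra two-class marker: the resistant/dark class maps to the donor
parent's allele.  The trait is placed on the linkage group of its
best-linked marker, at the locus of its co-segregating markers when any
exist; linked markers fall within a cM window (default 5), and
co-segregating markers show zero recombinants over the informative
RILs.  Candidate scaffolds are the anchored scaffolds carrying
co-segregating markers.  A validation panel of independent samples
measures genotype-phenotype concordance for a chosen marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .linkage_map import LinkageGroupMap, MISSING_CODES, _lod


@dataclass
class TraitPhenotype:
    """Binary phenotype codes per sample (e.g. R/S, dark/white)."""
    name: str
    codes: dict[str, str]
    parent_a_code: str
    parent_b_code: str

    def __post_init__(self):
        if self.parent_a_code == self.parent_b_code:
            raise ValueError("parents must differ in phenotype")
        classes = set(self.codes.values())
        if not {self.parent_a_code, self.parent_b_code} <= classes:
            raise ValueError("both phenotype classes must be present "
                             "among the scored samples")

    def as_genotype_codes(self) -> dict[str, str]:
        """Phenotype classes mapped to parental-origin codes A/B."""
        lookup = {self.parent_a_code: "A", self.parent_b_code: "B"}
        return {s: lookup[c] for s, c in self.codes.items() if c in lookup}


def _trait_two_point(matrix: pd.DataFrame,
                     pheno: TraitPhenotype) -> pd.DataFrame:
    """k, n, lod of the trait against every marker (H/missing excluded)."""
    trait = pd.Series(pheno.as_genotype_codes())
    samples = [s for s in matrix.columns if s in trait.index]
    sub = matrix[samples]
    tvec = trait[samples]
    rows = []
    for marker, gvec in sub.iterrows():
        ok = gvec.isin(["A", "B"])
        n = int(ok.sum())
        k = int((gvec[ok] != tvec[ok]).sum())
        rows.append((marker, n, k, _lod(k, n)))
    return pd.DataFrame(rows, columns=["marker_id", "n", "k", "lod"]
                        ).set_index("marker_id")


@dataclass
class TraitLinkageReport:
    trait: str
    group: str | None
    position_cm: float | None
    per_marker: pd.DataFrame        # distance_cm, k, n, lod per mapped marker

    @property
    def placed(self) -> bool:
        return self.group is not None

    def linked_markers(self, window: float = 5.0) -> list[str]:
        """Markers within ``window`` cM of the trait locus, sorted by
        distance then id."""
        if not self.placed:
            return []
        sub = self.per_marker[self.per_marker["distance_cm"] <= window]
        sub = sub.reset_index(names="marker_id")
        return list(sub.sort_values(["distance_cm", "marker_id"])["marker_id"])

    def cosegregating_markers(self) -> list[str]:
        """Markers with zero observed recombinants against the trait."""
        sub = self.per_marker[(self.per_marker["k"] == 0)
                              & (self.per_marker["n"] > 0)]
        return sorted(sub.index)


def map_trait(matrix: pd.DataFrame, pheno: TraitPhenotype,
              lmap: LinkageGroupMap, lod_floor: float = 3.0,
              min_informative: int = 10) -> TraitLinkageReport:
    """Place a binary trait on the map as an extra two-class marker.

    The trait joins the group of its highest-LOD marker; its position
    is the locus of the co-segregating marker set when one exists,
    otherwise the locus of the best-linked marker.  A trait whose best
    LOD is below the floor is reported unplaced.
    """
    tp = _trait_two_point(matrix, pheno)
    tp = tp[tp["n"] >= min_informative]
    if tp.empty or tp["lod"].max() < lod_floor:
        return TraitLinkageReport(pheno.name, None, None,
                                  tp.assign(distance_cm=float("nan")))
    best_marker = tp["lod"].idxmax()
    located = lmap.locus_of(best_marker)
    if located is None:
        return TraitLinkageReport(pheno.name, None, None,
                                  tp.assign(distance_cm=float("nan")))
    group_name, _ = located

    group = next(g for g in lmap.groups if g.name == group_name)
    positions = {m: locus.position_cm
                 for locus in group.loci for m in locus.markers}
    in_group = tp.loc[[m for m in tp.index if m in positions]].copy()

    coseg = in_group[(in_group["k"] == 0) & (in_group["n"] > 0)]
    if not coseg.empty:
        # place at the locus of the nearest co-segregating marker set:
        # the best-supported (highest n, then lod) zero-recombinant locus
        anchor_marker = coseg.sort_values(["n", "lod"],
                                          ascending=False).index[0]
    else:
        anchor_marker = in_group["lod"].idxmax()
    trait_pos = positions[anchor_marker]

    in_group["distance_cm"] = [abs(positions[m] - trait_pos)
                               for m in in_group.index]
    return TraitLinkageReport(pheno.name, group_name, trait_pos, in_group)


def cosegregating_markers(matrix: pd.DataFrame, pheno: TraitPhenotype,
                          min_informative: int = 10) -> list[str]:
    """Markers with zero observed recombinants against the phenotype,
    independent of any map."""
    tp = _trait_two_point(matrix, pheno)
    hits = tp[(tp["k"] == 0) & (tp["n"] >= min_informative)]
    return sorted(hits.index)


def candidate_scaffolds(cosegregating: list[str], anchors: pd.DataFrame,
                        scaffold_lengths=None) -> pd.DataFrame:
    """Distinct anchored scaffolds carrying co-segregating markers.

    One row per scaffold with its member markers and (when lengths are
    supplied) its size; an empty annotation slot is left for downstream
    gene analysis.
    """
    sub = anchors[anchors["marker_id"].isin(cosegregating)]
    rows = []
    for scaffold, grp in sub.groupby("scaffold"):
        rows.append({
            "scaffold": scaffold,
            "markers": ",".join(sorted(grp["marker_id"])),
            "scaffold_size_bp": (scaffold_lengths.get(scaffold)
                                 if scaffold_lengths else None),
            "annotation": "",
        })
    return pd.DataFrame(rows, columns=["scaffold", "markers",
                                       "scaffold_size_bp", "annotation"])


def validate_panel(marker_genotypes: dict[str, str],
                   panel_phenotypes: dict[str, str],
                   resistant_genotype: str = "B",
                   resistant_phenotype: str = "R",
                   ) -> tuple[float, pd.DataFrame, int]:
    """Genotype-phenotype concordance on an external validation panel.

    Samples with missing genotypes are excluded and counted.  Returns
    (consistent fraction, per-sample table, n_excluded).
    """
    rows = []
    excluded = 0
    for sample, pheno in panel_phenotypes.items():
        geno = marker_genotypes.get(sample)
        if geno is None or geno in MISSING_CODES:
            excluded += 1
            continue
        consistent = ((geno == resistant_genotype)
                      == (pheno == resistant_phenotype))
        rows.append((sample, geno, pheno, consistent))
    table = pd.DataFrame(rows, columns=["sample", "genotype", "phenotype",
                                        "consistent"])
    frac = float(table["consistent"].mean()) if len(table) else float("nan")
    return frac, table, excluded
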