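"""Genetic map construction for selfing RIL populations.

Two-point analysis counts recombinant RILs between marker pairs.  In a
population advanced by repeated selfing, recombination accumulates over
generations; the observed RIL recombinant fraction R relates to the
per-meiosis fraction r by the Haldane-Waddington limit for selfing
RILs,

    R = 2r / (1 + 2r)        r = R / (2 (1 - R)),

which is applied before any map-distance computation.  Heterozygous
calls are treated as missing: an F8 analysis is effectively two-class
and the recombinant status of a residual heterozygote is ambiguous.

Grouping is single-linkage on LOD > 6 followed by stepwise relaxation
of the threshold (0.5 LOD per step, small groups only) down to a floor,
mirroring the practice of grouping at high stringency and then
distributing small groups until the group count approaches the
chromosome number.  Ordering minimizes the COUNT criterion (total
observed recombination events between adjacent markers) by randomized
greedy insertion plus window ripple, the strategy of the RECORD
ordering heuristic.  Markers with zero observed recombinants collapse
into one locus; loci are positioned by cumulative Kosambi (default) or
Haldane distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

MISSING_CODES = ("H", "-")


# ---------------------------------------------------------------------------
# two-point estimation


def encode_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Genotype codes to int8: A=0, B=1, H/missing=-1."""
    arr = np.full(matrix.shape, -1, dtype=np.int8)
    arr[(matrix == "A").to_numpy()] = 0
    arr[(matrix == "B").to_numpy()] = 1
    return arr


@dataclass(frozen=True)
class TwoPointEstimate:
    marker_1: str
    marker_2: str
    n_informative: int
    n_recombinant: int
    r_hat: float       # observed RIL recombinant fraction R
    r: float           # Haldane-Waddington corrected meiotic fraction
    lod: float


def haldane_waddington_R(r: float) -> float:
    """Expected RIL recombinant fraction for meiotic fraction r."""
    return 2.0 * r / (1.0 + 2.0 * r)


def haldane_waddington_r(R: float) -> float:
    """Invert R = 2r/(1+2r); input clamped to [0, 0.5]."""
    R = min(max(R, 0.0), 0.5)
    return min(R / (2.0 * (1.0 - R)), 0.5)


def _lod(k: int, n: int) -> float:
    """LOD for linkage at R_hat = k/n against free recombination.

    k = 0 gives the closed form n*log10(2); R_hat >= 0.5 gives 0.
    """
    if n == 0:
        return 0.0
    if k == 0:
        return n * math.log10(2.0)
    R = k / n
    if R >= 0.5:
        return 0.0
    return k * math.log10(R / 0.5) + (n - k) * math.log10((1.0 - R) / 0.5)


def two_point(matrix: pd.DataFrame, pair: tuple[str, str],
              min_informative: int = 10) -> TwoPointEstimate:
    """Two-point estimate for one marker pair (H and '-' excluded)."""
    m1, m2 = pair
    g1 = matrix.loc[m1]
    g2 = matrix.loc[m2]
    ok = g1.isin(["A", "B"]) & g2.isin(["A", "B"])
    n = int(ok.sum())
    k = int((g1[ok] != g2[ok]).sum())
    if n < min_informative:
        return TwoPointEstimate(m1, m2, n, k, float("nan"), float("nan"), 0.0)
    R = min(k / n, 0.5)
    return TwoPointEstimate(m1, m2, n, k, k / n,
                            haldane_waddington_r(R), _lod(k, n))


@dataclass
class PairwiseTables:
    """Dense marker x marker two-point tables."""
    markers: list[str]
    k: np.ndarray          # recombinant counts
    n: np.ndarray          # informative counts
    r_hat: np.ndarray
    r: np.ndarray
    lod: np.ndarray
    min_informative: int

    def index(self, marker: str) -> int:
        return self.markers.index(marker)


def pairwise_two_point(matrix: pd.DataFrame,
                       min_informative: int = 10) -> PairwiseTables:
    """All-pairs two-point tables, vectorized over the marker matrix."""
    G = encode_matrix(matrix)
    a = (G == 0).astype(np.float64)
    b = (G == 1).astype(np.float64)
    valid = a + b
    n = valid @ valid.T
    k = a @ b.T + b @ a.T
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(n > 0, k / n, np.nan)
    Rc = np.clip(R, 0.0, 0.5)
    r = Rc / (2.0 * (1.0 - Rc))
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = np.where(
            k == 0,
            n * math.log10(2.0),
            k * np.log10(np.maximum(Rc, 1e-300) / 0.5)
            + (n - k) * np.log10((1.0 - Rc) / 0.5))
    lod = np.where((n > 0) & (R < 0.5), lod, 0.0)
    lod = np.where(n >= min_informative, lod, 0.0)
    np.fill_diagonal(lod, 0.0)
    return PairwiseTables(list(matrix.index), k.astype(np.int64),
                          n.astype(np.int64), R, np.minimum(r, 0.5),
                          lod, min_informative)


# ---------------------------------------------------------------------------
# grouping


def build_groups(tables: PairwiseTables, lod_start: float = 6.0,
                 target_groups: int = 20, lod_floor: float = 3.0,
                 step: float = 0.5, small_fraction: float = 0.05,
                 ) -> tuple[list[list[str]], list[tuple[float, int]]]:
    """Single-linkage LOD grouping with stepwise relaxation.

    Components are formed at lod > lod_start.  When that already yields
    fewer components than target_groups (a sampling-tail pair can
    merge two chromosomes even at high stringency), the threshold is
    raised stepwise until the partition reaches the target — the
    stopping rule is the group count approaching the chromosome
    number, from either side.  While there are more components than
    target_groups the threshold drops by ``step`` and only edges that
    join a small group (fewer than small_fraction of all markers) to
    any other group are added; this also repairs fragments split off
    by the upward search.  Stops at the target or the floor; returns
    the partition (largest first) and the (threshold, group count)
    trace.
    """
    m = len(tables.markers)
    graph = nx.Graph()
    graph.add_nodes_from(range(m))
    iu, ju = np.triu_indices(m, k=1)
    lods = tables.lod[iu, ju]
    order = np.argsort(-lods)
    edges = [(int(iu[t]), int(ju[t]), float(lods[t])) for t in order
             if lods[t] > min(lod_floor, lod_start)]
    max_lod = edges[0][2] if edges else lod_start

    thr = lod_start
    graph.add_edges_from((i, j) for i, j, l in edges if l > thr)
    comps = list(nx.connected_components(graph))
    trace = [(thr, len(comps))]
    while len(comps) < target_groups and thr <= max_lod:
        thr += step
        graph = nx.Graph()
        graph.add_nodes_from(range(m))
        graph.add_edges_from((i, j) for i, j, l in edges if l > thr)
        comps = list(nx.connected_components(graph))
        trace.append((thr, len(comps)))
    small_cut = max(1, int(small_fraction * m))
    while len(comps) > target_groups and thr - step >= lod_floor - 1e-9:
        thr -= step
        node_comp = {}
        sizes = {}
        for ci, comp in enumerate(comps):
            sizes[ci] = len(comp)
            for node in comp:
                node_comp[node] = ci
        for i, j, lod in edges:
            if lod <= thr:
                continue
            ci, cj = node_comp[i], node_comp[j]
            if ci == cj:
                continue
            if sizes[ci] < small_cut or sizes[cj] < small_cut:
                graph.add_edge(i, j)
        comps = list(nx.connected_components(graph))
        trace.append((thr, len(comps)))
    groups = [sorted(tables.markers[i] for i in comp) for comp in comps]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups, trace


# ---------------------------------------------------------------------------
# RECORD-style ordering (COUNT minimization)


def count_of_order(order: list[int], k: np.ndarray) -> int:
    """COUNT criterion: total adjacent-pair recombination events.

    Pairs without informative individuals contribute k = 0, i.e.
    missing cells are imputed as non-recombinant.
    """
    idx = np.asarray(order)
    return int(k[idx[:-1], idx[1:]].sum())


def _greedy_insertion(ids: np.ndarray, k: np.ndarray,
                      rng: np.random.Generator) -> list[int]:
    order = list(rng.permutation(len(ids)))
    built = [order[0]]
    for x in order[1:]:
        best_pos, best_cost = 0, None
        for pos in range(len(built) + 1):
            if pos == 0:
                delta = k[x, built[0]]
            elif pos == len(built):
                delta = k[built[-1], x]
            else:
                i, j = built[pos - 1], built[pos]
                delta = k[i, x] + k[x, j] - k[i, j]
            if best_cost is None or delta < best_cost:
                best_pos, best_cost = pos, delta
        built.insert(best_pos, x)
    return built


def _ripple(order: list[int], k: np.ndarray,
            window_sizes=(2, 3)) -> list[int]:
    m = len(order)
    improved = True
    while improved:
        improved = False
        for w in window_sizes:
            if w > m:
                continue
            for i in range(m - w + 1):
                window = order[i:i + w]
                left = order[i - 1] if i > 0 else None
                right = order[i + w] if i + w < m else None

                def local_cost(perm):
                    c = int(k[np.array(perm[:-1]), np.array(perm[1:])].sum()) \
                        if w > 1 else 0
                    if left is not None:
                        c += k[left, perm[0]]
                    if right is not None:
                        c += k[perm[-1], right]
                    return c

                base = local_cost(window)
                for perm in itertools.permutations(window):
                    perm = list(perm)
                    if perm == window:
                        continue
                    if local_cost(perm) < base:
                        order[i:i + w] = perm
                        improved = True
                        base = local_cost(perm)
                        window = perm
    return order


def order_group(tables: PairwiseTables, group: list[str],
                n_starts: int = 10, seed: int = 0,
                exhaustive_limit: int = 7) -> tuple[list[str], int]:
    """Order a linkage group by COUNT minimization.

    Groups of at most ``exhaustive_limit`` markers are solved exactly
    by enumerating every permutation.  Larger groups use randomized
    greedy insertion followed by window ripple (sizes 2 and 3), best
    of ``n_starts`` seeded restarts.  The returned order is
    orientation-normalized: the lexicographically smaller terminal
    marker comes first, which also resolves the two-marker tie.
    """
    idx = [tables.index(m) for m in sorted(group)]
    ids = np.array(idx)
    if len(idx) == 1:
        return [tables.markers[idx[0]]], 0
    sub_k = tables.k[np.ix_(idx, idx)]
    if len(idx) <= exhaustive_limit:
        best_order, best_count = None, None
        for perm in itertools.permutations(range(len(idx))):
            if perm[0] > perm[-1]:
                continue  # each order is COUNT-equal to its reverse
            count = count_of_order(list(perm), sub_k)
            if best_count is None or count < best_count:
                best_order, best_count = list(perm), count
    else:
        best_order, best_count = None, None
        rng = np.random.default_rng(seed)
        for _ in range(n_starts):
            order = _greedy_insertion(ids, sub_k, rng)
            order = _ripple(order, sub_k)
            count = count_of_order(order, sub_k)
            if best_count is None or count < best_count:
                best_order, best_count = order, count
    names = [tables.markers[idx[i]] for i in best_order]
    if names[0] > names[-1]:
        names.reverse()
    return names, int(best_count)


# ---------------------------------------------------------------------------
# loci, positions, map assembly


@dataclass
class Locus:
    id: str                 # first member marker
    position_cm: float
    markers: list[str]


@dataclass
class LinkageGroup:
    name: str
    loci: list[Locus]
    ordering_count: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def length_cm(self) -> float:
        return self.loci[-1].position_cm if self.loci else 0.0

    @property
    def n_markers(self) -> int:
        return sum(len(l.markers) for l in self.loci)


@dataclass
class LinkageGroupMap:
    groups: list[LinkageGroup]

    @property
    def total_length_cm(self) -> float:
        return sum(g.length_cm for g in self.groups)

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    @property
    def n_loci(self) -> int:
        return sum(len(g.loci) for g in self.groups)

    def locus_of(self, marker: str) -> tuple[str, Locus] | None:
        for g in self.groups:
            for locus in g.loci:
                if marker in locus.markers:
                    return g.name, locus
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for rank, locus in enumerate(g.loci, 1):
                for marker in locus.markers:
                    rows.append((g.name, rank, round(locus.position_cm, 1),
                                 marker))
        return pd.DataFrame(rows, columns=["group", "locus_rank", "cm",
                                           "marker_id"])


def collapse_loci(ordered: list[str], tables: PairwiseTables) -> list[list[str]]:
    """Merge consecutive markers with zero observed recombinants (on at
    least one informative individual) into a single locus."""
    loci: list[list[str]] = []
    for marker in ordered:
        if loci:
            prev = loci[-1][-1]
            i, j = tables.index(prev), tables.index(marker)
            if tables.n[i, j] > 0 and tables.k[i, j] == 0:
                loci[-1].append(marker)
                continue
        loci.append([marker])
    return loci


def haldane_cm(r: float) -> float:
    """Haldane map distance, no interference: d = -50 ln(1 - 2r)."""
    return -50.0 * math.log(1.0 - 2.0 * r)


def kosambi_cm(r: float) -> float:
    """Kosambi map distance, partial interference:
    d = 25 ln((1 + 2r) / (1 - 2r))."""
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


_MAP_FUNCTIONS = {"haldane": haldane_cm, "kosambi": kosambi_cm}


def position_loci(loci: list[list[str]], tables: PairwiseTables,
                  mapping_function: str = "kosambi",
                  d_max: float = 50.0) -> tuple[list[float], list[str]]:
    """Cumulative cM positions of loci along an ordered group.

    Adjacent-locus r is the corrected two-point estimate between the
    locus representative markers (first members).  Unlinked adjacencies
    (r = 0.5) are capped at d_max and flagged.
    """
    func = _MAP_FUNCTIONS[mapping_function]
    positions = [0.0]
    flags = []
    for a, b in zip(loci[:-1], loci[1:]):
        i, j = tables.index(a[0]), tables.index(b[0])
        r = tables.r[i, j]
        if not np.isfinite(r):
            r = 0.5
        if r >= 0.5 - 1e-12:
            d = d_max
            flags.append(f"unlinked adjacency {a[0]}..{b[0]} capped at "
                         f"{d_max} cM")
        else:
            d = min(func(r), d_max)
        positions.append(positions[-1] + d)
    return positions, flags


def build_map(matrix: pd.DataFrame, lod_start: float = 6.0,
              target_groups: int = 20, lod_floor: float = 3.0,
              mapping_function: str = "kosambi", n_starts: int = 10,
              min_informative: int = 10, seed: int = 0,
              ) -> LinkageGroupMap:
    """Full map construction from a genotype matrix of RIL columns."""
    tables = pairwise_two_point(matrix, min_informative)
    groups, _ = build_groups(tables, lod_start, target_groups, lod_floor)
    built = []
    for gi, group in enumerate(groups):
        ordered, count = order_group(tables, group, n_starts=n_starts,
                                     seed=seed + gi)
        loci_markers = collapse_loci(ordered, tables)
        positions, flags = position_loci(loci_markers, tables,
                                         mapping_function)
        loci = [Locus(mks[0], pos, mks)
                for mks, pos in zip(loci_markers, positions)]
        if len(group) == 1:
            flags = flags + ["singleton group"]
        built.append(LinkageGroup("", loci, count, flags))
    built.sort(key=lambda g: (-g.length_cm, -g.n_markers,
                              g.loci[0].id if g.loci else ""))
    for rank, g in enumerate(built, 1):
        g.name = f"SLG-{rank}"
    return LinkageGroupMap(built)


# ---------------------------------------------------------------------------
# gaps and summaries


def find_gaps(lmap: LinkageGroupMap, threshold: float = 20.0) -> pd.DataFrame:
    """Adjacent-locus intervals longer than ``threshold`` cM."""
    rows = []
    for g in lmap.groups:
        for a, b in zip(g.loci[:-1], g.loci[1:]):
            span = b.position_cm - a.position_cm
            if span > threshold:
                rows.append((g.name, a.id, b.id, round(span, 1)))
    return pd.DataFrame(rows, columns=["group", "locus_before", "locus_after",
                                       "gap_cm"])


def summarize_map(lmap: LinkageGroupMap,
                  integration: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-group summary with an exact-sum totals row.

    ``integration`` optionally supplies per-group scaffold counts and
    spans (columns: group, n_scaffolds, scaffold_span_bp).
    """
    rows = []
    for g in lmap.groups:
        rows.append({"group": g.name, "n_markers": g.n_markers,
                     "n_loci": len(g.loci),
                     "length_cm": round(g.length_cm, 1),
                     "n_scaffolds": 0, "scaffold_span_bp": 0})
    columns = ["group", "n_markers", "n_loci", "length_cm", "n_scaffolds",
               "scaffold_span_bp"]
    df = pd.DataFrame(rows, columns=columns)
    df["length_cm"] = df["length_cm"].astype(float)
    if integration is not None and len(integration):
        anchored = integration.set_index("group")
        for col in ("n_scaffolds", "scaffold_span_bp"):
            df[col] = df["group"].map(anchored[col]).fillna(0).astype(int)
    return add_totals_row(df)


def add_totals_row(per_group: pd.DataFrame) -> pd.DataFrame:
    """Append a 'Total' row of exact column sums to a per-group table."""
    total = {"group": "Total"}
    for col in per_group.columns:
        if col == "group":
            continue
        s = per_group[col].sum()
        total[col] = round(float(s), 1) if per_group[col].dtype.kind == "f" else s
    return pd.concat([per_group, pd.DataFrame([total])], ignore_index=True)


def map_statistics(summary: pd.DataFrame) -> dict[str, float]:
    """Headline statistics from a per-group summary table (with or
    without a totals row): totals, marker density per cM (1 decimal)
    and markers per locus (1 decimal)."""
    per_group = summary[summary["group"] != "Total"]
    markers = int(per_group["n_markers"].sum())
    loci = int(per_group["n_loci"].sum())
    length = float(round(per_group["length_cm"].sum(), 1))
    out = {"total_markers": markers, "total_loci": loci,
           "total_length_cm": length,
           "markers_per_cm": round(markers / length, 1) if length else 0.0,
           "markers_per_locus": round(markers / loci, 1) if loci else 0.0}
    if "n_scaffolds" in per_group:
        out["total_scaffolds"] = int(per_group["n_scaffolds"].sum())
        out["total_scaffold_span_bp"] = int(per_group["scaffold_span_bp"].sum())
    return out
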