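"""Temporal GO-GO "meta-flow" network over a 5-day two-condition time course.

Genes first responding to the perturbation on different days are generalized
to their GO biological-process categories.  For every pair of categories and
every *day pattern* — same-day (both genes first DE on day a) or consecutive
(one on day a, the other on day a+1; exactly 9 patterns over days 1-5) — we
count the backbone links connecting DE member genes (observed O), compare
against an independence expectation E built from the pattern's category
marginals, and score enrichment with a one-cell chi-square (O-E)^2/E.
Edges are retained when the score exceeds the 1-df 0.99 quantile (6.64,
p0 < 0.01) with O >= 3 and E > 0.5; consecutive edges are oriented from the
earlier day, giving the "flow" arrows.

Expected counts: for a consecutive pattern a->b the category-pair table is
rectangular and E_ij = N_i(a) * N_j(b) / T with marginals N and total T read
off the observed table, so that sum(E) = sum(O) exactly.  Same-day tables are
built ordered-and-symmetric (each link counted in both orientations) and then
halved, giving E_ij = N_i * N_j / (2T) off the diagonal and N_i^2 / (4T) on
it — the one convention that preserves sum(E) = sum(O).  A gene annotated to
several categories contributes to each.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .data import DAYS, BackboneNetwork, GoAnnotation
from .diffexpr import DeCall

__all__ = [
    "DayPattern",
    "GoGoEdge",
    "GoGoNode",
    "GoGoNetwork",
    "MetaflowParams",
    "all_patterns",
    "assign_pattern",
    "eligible_links",
    "tally",
    "expected_count",
    "chi_square_score",
    "build_metaflow",
]


@dataclass(frozen=True)
class DayPattern:
    """Same-day (a == b) or consecutive (b == a + 1) first-DE day pair."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if self.a not in DAYS or self.b not in DAYS:
            raise ValueError(f"days must be in {DAYS}")
        if self.b not in (self.a, self.a + 1):
            raise ValueError(f"not an admissible pattern: {self.a}->{self.b}")

    @property
    def kind(self) -> str:
        return "same_day" if self.a == self.b else "consecutive"

    def __str__(self) -> str:
        sep = "--" if self.kind == "same_day" else "->"
        return f"day{self.a}{sep}day{self.b}"


def all_patterns() -> list[DayPattern]:
    """The 9 admissible patterns: 5 same-day plus 4 consecutive."""
    out = [DayPattern(d, d) for d in DAYS]
    out += [DayPattern(d, d + 1) for d in DAYS[:-1]]
    return out


def assign_pattern(day_a: int, day_b: int) -> DayPattern | None:
    """Pattern for a link whose endpoints were first DE on day_a / day_b.

    Consecutive patterns are oriented earlier -> later; gaps of 2+ days are
    not among the enumerated patterns and return None.
    """
    if day_a not in DAYS or day_b not in DAYS:
        raise ValueError(f"days must be in {DAYS}, got ({day_a}, {day_b})")
    lo, hi = min(day_a, day_b), max(day_a, day_b)
    if hi - lo > 1:
        return None
    return DayPattern(lo, hi)


@dataclass
class EligibleLink:
    gene_a: str
    gene_b: str
    day_a: int  # first-DE day of gene_a
    day_b: int


def eligible_links(network: BackboneNetwork, de_calls: list[DeCall],
                   go_annotation: GoAnnotation,
                   fbs_min: float = 3.0) -> list[EligibleLink]:
    """Backbone links whose endpoints are both regulated, annotated, and fbs > fbs_min."""
    first_day = {c.gene: c.first_de_day for c in de_calls
                 if c.first_de_day is not None}
    annotated = go_annotation.genes
    out = []
    for a, b, fbs in network.edges():
        if fbs <= fbs_min:
            continue
        if a in first_day and b in first_day and a in annotated and b in annotated:
            out.append(EligibleLink(a, b, first_day[a], first_day[b]))
    return out


class Tally:
    """Observed category-pair counts and marginals for one day pattern.

    ``observed`` maps (go_i, go_j) to O_ij — ordered (source day a, target
    day b) for consecutive patterns, unordered (go_i <= go_j) for same-day
    ones.  ``n_a`` / ``n_b`` are the marginals N_i(a), N_j(b) and ``total``
    is T, all on the scale expected by :func:`expected_count`.
    """

    def __init__(self, pattern: DayPattern):
        self.pattern = pattern
        self.observed: dict[tuple[str, str], float] = {}
        self.n_a: dict[str, float] = {}
        self.n_b: dict[str, float] = {}
        self.total: float = 0.0

    def expected(self, go_i: str, go_j: str) -> float:
        return expected_count(
            self.n_a.get(go_i, 0.0), self.n_b.get(go_j, 0.0), self.total,
            same_day=self.pattern.kind == "same_day", diagonal=go_i == go_j,
        )


def tally(links: list[EligibleLink], go_annotation: GoAnnotation,
          pattern: DayPattern) -> Tally:
    """Count qualifying gene-gene links per GO category pair for one pattern.

    A gene in multiple categories contributes one count per category; the
    marginals and total are read off the observed table so that the
    independence expectation reproduces the observed total in aggregate.
    """
    t = Tally(pattern)
    if pattern.kind == "consecutive":
        O: Counter = Counter()
        for lk in links:
            if {lk.day_a, lk.day_b} != {pattern.a, pattern.b}:
                continue
            if lk.day_a == pattern.a:
                src, tgt = lk.gene_a, lk.gene_b
            else:
                src, tgt = lk.gene_b, lk.gene_a
            for ci in sorted(go_annotation.terms_for(src)):
                for cj in sorted(go_annotation.terms_for(tgt)):
                    O[(ci, cj)] += 1
        t.observed = {k: float(v) for k, v in O.items()}
        for (ci, cj), o in t.observed.items():
            t.n_a[ci] = t.n_a.get(ci, 0.0) + o
            t.n_b[cj] = t.n_b.get(cj, 0.0) + o
        t.total = float(sum(t.observed.values()))
    else:
        # ordered symmetric table, halved for reporting
        S: Counter = Counter()
        for lk in links:
            if not (lk.day_a == lk.day_b == pattern.a):
                continue
            ca = sorted(go_annotation.terms_for(lk.gene_a))
            cb = sorted(go_annotation.terms_for(lk.gene_b))
            for ci in ca:
                for cj in cb:
                    S[(ci, cj)] += 1
                    S[(cj, ci)] += 1
        rows: dict[str, float] = defaultdict(float)
        for (ci, cj), v in S.items():
            rows[ci] += v
        for (ci, cj), v in S.items():
            if ci < cj:
                t.observed[(ci, cj)] = float(v)  # = (S_ij + S_ji)/2 by symmetry
            elif ci == cj:
                t.observed[(ci, cj)] = v / 2.0
        t.n_a = dict(rows)
        t.n_b = dict(rows)
        t.total = sum(rows.values()) / 2.0  # single-count link-incidence total
    return t


def expected_count(n_i_a: float, n_j_b: float, total: float,
                   same_day: bool = False, diagonal: bool = False) -> float:
    """Independence expectation E_ij = N_i(a) * N_j(b) / T.

    Same-day patterns use the unordered convention E = N_i N_j / (2T), with
    one further halving on the diagonal (both endpoints in the same category)
    so that sum(E) = sum(O) holds exactly.
    """
    if total <= 0:
        raise ValueError("total pattern link count must be > 0")
    e = n_i_a * n_j_b / total
    if same_day:
        e /= 2.0
        if diagonal:
            e /= 2.0
    return e


def chi_square_score(observed: float, expected: float) -> float:
    """One-cell goodness-of-fit score (O - E)^2 / E, thresholded at the 1-df quantile."""
    if expected <= 0:
        raise ValueError("expected count must be > 0")
    return (observed - expected) ** 2 / expected


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaflowParams:
    chi_min: float = 6.64   # 1-df chi-square 0.99 quantile (p0 < 0.01)
    o_min: float = 3.0      # minimum observed gene-gene links
    e_min: float = 0.5      # minimum expected count
    fbs_min: float = 3.0    # backbone confidence floor


@dataclass
class GoGoNode:
    go_id: str
    member_genes: frozenset[str]
    regulated_fraction: float


@dataclass
class GoGoEdge:
    go_i: str
    go_j: str
    pattern: DayPattern
    observed: float
    expected: float
    chi2: float


@dataclass
class GoGoNetwork:
    nodes: dict[str, GoGoNode] = field(default_factory=dict)
    edges: list[GoGoEdge] = field(default_factory=list)

    def pattern_edges(self, pattern: DayPattern) -> list[GoGoEdge]:
        return [e for e in self.edges if e.pattern == pattern]


def build_metaflow(network: BackboneNetwork, de_calls: list[DeCall],
                   go_annotation: GoAnnotation,
                   params: MetaflowParams = MetaflowParams()) -> GoGoNetwork:
    """Assemble the GO-GO meta-flow network across all 9 day patterns."""
    links = eligible_links(network, de_calls, go_annotation, params.fbs_min)
    net = GoGoNetwork()
    for pattern in all_patterns():
        t = tally(links, go_annotation, pattern)
        if t.total <= 0:
            continue
        for (go_i, go_j), o in sorted(t.observed.items()):
            e = t.expected(go_i, go_j)
            if e <= 0:
                continue
            chi2 = chi_square_score(o, e)
            if chi2 > params.chi_min and o >= params.o_min and e > params.e_min:
                net.edges.append(GoGoEdge(go_i, go_j, pattern, o, e, chi2))
    # nodes: GO terms incident to retained edges, colored by regulated fraction
    regulated = {c.gene for c in de_calls if c.de_days}
    universe = {c.gene for c in de_calls}
    for term in sorted({g for e in net.edges for g in (e.go_i, e.go_j)}):
        members = go_annotation.genes_for(term) & universe
        frac = len(members & regulated) / len(members) if members else 0.0
        net.nodes[term] = GoGoNode(term, frozenset(members), frac)
    return net


def gogo_to_frames(net: GoGoNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(node attribute table, edge attribute table) for TSV export."""
    nodes = pd.DataFrame([{
        "go_id": n.go_id, "n_genes": len(n.member_genes),
        "regulated_fraction": n.regulated_fraction,
    } for n in net.nodes.values()])
    edges = pd.DataFrame([{
        "go_i": e.go_i, "go_j": e.go_j, "pattern": str(e.pattern),
        "observed": e.observed, "expected": e.expected, "chi2": e.chi2,
    } for e in net.edges])
    return nodes, edges


def write_gogo(net: GoGoNetwork, sif_path, node_attr_path=None,
               edge_attr_path=None) -> None:
    """Export as Cytoscape-loadable SIF plus node/edge attribute TSVs."""
    with open(sif_path, "w") as fh:
        for e in net.edges:
            fh.write(f"{e.go_i}\t{e.pattern}\t{e.go_j}\n")
    nodes, edges = gogo_to_frames(net)
    if node_attr_path is not None:
        nodes.to_csv(node_attr_path, sep="\t", index=False)
    if edge_attr_path is not None:
        edges.to_csv(edge_attr_path, sep="\t", index=False)
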