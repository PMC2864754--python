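"""Discovery of topologically cohesive network modules enriched in DELs.

A module is a connected node set whose induced backbone edges are unusually
rich in differentially expressed links of a given polarity: P (enabled-only
seeds), N (sensitive-only), or PN (mixed).  Enrichment is the hypergeometric
upper tail of drawing k DEL edges among the m induced edges from a universe
of M backbone edges containing K DELs.

The search is a deterministic greedy seed-and-extend: every DEL edge seeds a
candidate module which repeatedly absorbs the neighboring node that most
decreases the enrichment p-value (ties broken by lexicographically smallest
gene id), stopping when no addition improves the p-value or the size cap is
hit.  Overlapping candidates (node Jaccard > 0.5) are merged keeping the
better p; survivors are kept at BH-adjusted q < 0.05.

The underlying clustering idea follows an unpublished in-house tool whose
algorithm was never described; this is a documented reimplementation chosen
for determinism, not a reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data import BackboneNetwork, GoAnnotation
from .links import LinkRecord

__all__ = [
    "DelModule",
    "del_enrichment_p",
    "grow_module",
    "find_modules",
    "go_enrich_module",
]

Edge = frozenset  # unordered gene pair


@dataclass
class DelModule:
    id: str
    nodes: frozenset[str]
    core_nodes: frozenset[str]  # genes incident to >= 1 DEL
    polarity: str               # P, N, or PN
    enrichment_p: float
    enrichment_q: float | None = None
    n_edges: int = 0
    n_del_edges: int = 0
    seed: tuple[str, str] | None = field(default=None, repr=False)


def _induced_counts(nodes: frozenset, network: BackboneNetwork,
                    del_edges: set[Edge]) -> tuple[int, int]:
    m = k = 0
    sub = network.graph.subgraph(nodes)
    for u, v in sub.edges():
        m += 1
        if Edge((u, v)) in del_edges:
            k += 1
    return m, k


def del_enrichment_p(module_nodes, network: BackboneNetwork,
                     del_edges: set[Edge]) -> float:
    """Hypergeometric upper-tail p for the module's DEL edge count."""
    nodes = frozenset(module_nodes)
    M = network.n_edges
    K = sum(1 for e in del_edges if network.graph.has_edge(*tuple(e)))
    m, k = _induced_counts(nodes, network, del_edges)
    if m == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, M, K, m))


def grow_module(seed_edge: tuple[str, str], network: BackboneNetwork,
                del_edges: set[Edge], polarity: str,
                max_size: int = 130) -> DelModule:
    """Greedy seed-and-extend growth from one DEL edge.

    Connectivity is maintained by construction (only neighbors are added).
    Deterministic: ties on equal p go to the smallest gene id.
    """
    a, b = seed_edge
    nodes = frozenset((a, b))
    p = del_enrichment_p(nodes, network, del_edges)
    while len(nodes) < max_size:
        candidates = set()
        for n in nodes:
            candidates |= set(network.graph.neighbors(n))
        candidates -= nodes
        best_node, best_p = None, p
        for cand in sorted(candidates):
            cand_p = del_enrichment_p(nodes | {cand}, network, del_edges)
            if cand_p < best_p:
                best_node, best_p = cand, cand_p
        if best_node is None:
            break
        nodes = nodes | {best_node}
        p = best_p
    m, k = _induced_counts(nodes, network, del_edges)
    core = frozenset(g for e in del_edges for g in e if e <= nodes)
    return DelModule(
        id="", nodes=nodes, core_nodes=core, polarity=polarity,
        enrichment_p=p, n_edges=m, n_del_edges=k, seed=tuple(sorted(seed_edge)),
    )


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def find_modules(network: BackboneNetwork, del_records: list[LinkRecord],
                 max_size: int = 130, merge_jaccard: float = 0.5,
                 q_max: float = 0.05) -> list[DelModule]:
    """Run one growth pass per DEL seed per polarity; merge, BH-filter, name.

    P modules grow against the enabled DEL set, N against the sensitive set,
    PN against their union (and must retain at least one internal DEL of each
    sign).  Ids are assigned ``P-k`` / ``N-k`` / ``PN-k`` in discovery order.
    """
    enabled = {Edge((r.gene_a, r.gene_b)) for r in del_records
               if r.link_class == "enabled"}
    sensitive = {Edge((r.gene_a, r.gene_b)) for r in del_records
                 if r.link_class == "sensitive"}
    if not enabled and not sensitive:
        return []
    plans = [
        ("P", sorted(enabled, key=lambda e: tuple(sorted(e))), enabled),
        ("N", sorted(sensitive, key=lambda e: tuple(sorted(e))), sensitive),
        ("PN", sorted(enabled | sensitive, key=lambda e: tuple(sorted(e))),
         enabled | sensitive),
    ]
    candidates: list[DelModule] = []
    for polarity, seeds, del_set in plans:
        grown: list[DelModule] = []
        for seed in seeds:
            mod = grow_module(tuple(sorted(seed)), network, del_set, polarity, max_size)
            if polarity == "PN":
                has_e = any(e <= mod.nodes for e in enabled)
                has_s = any(e <= mod.nodes for e in sensitive)
                if not (has_e and has_s):
                    continue
            grown.append(mod)
        # merge overlapping candidates within polarity, keeping the better p
        merged: list[DelModule] = []
        for mod in sorted(grown, key=lambda m: (m.enrichment_p, tuple(sorted(m.nodes)))):
            if any(_jaccard(mod.nodes, kept.nodes) > merge_jaccard for kept in merged):
                continue
            merged.append(mod)
        candidates.extend(merged)
    if not candidates:
        return []
    reject, q, _, _ = multipletests([m.enrichment_p for m in candidates],
                                    alpha=q_max, method="fdr_bh")
    kept: list[DelModule] = []
    ordinal = {"P": 0, "N": 0, "PN": 0}
    for mod, keep, qv in zip(candidates, reject, q):
        mod.enrichment_q = float(qv)
        if keep:
            ordinal[mod.polarity] += 1
            mod.id = f"{mod.polarity}-{ordinal[mod.polarity]}"
            kept.append(mod)
    return kept


def go_enrich_module(module: DelModule, go_annotation: GoAnnotation,
                     universe: set[str], q_max: float = 0.05,
                     significant_only: bool = True) -> pd.DataFrame:
    """Hypergeometric GO over-representation for one module, BH-corrected.

    ``universe`` is the annotated measured gene background; only terms with
    at least one universe gene are tested.
    """
    universe = set(universe) & go_annotation.genes
    module_genes = set(module.nodes) & universe
    if not universe or not module_genes:
        return pd.DataFrame(columns=["term", "overlap", "term_size", "p", "q"])
    rows = []
    N, n = len(universe), len(module_genes)
    for term in sorted(go_annotation.terms):
        members = go_annotation.genes_for(term) & universe
        if not members:
            continue
        k = len(members & module_genes)
        p = float(hypergeom.sf(k - 1, N, len(members), n))
        rows.append({"term": term, "overlap": k, "term_size": len(members), "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q=[])
    _, q, _, _ = multipletests(df["p"], alpha=q_max, method="fdr_bh")
    df["q"] = q
    df = df.sort_values(["q", "p", "term"]).reset_index(drop=True)
    return df[df["q"] < q_max].reset_index(drop=True) if significant_only else df


def modules_to_frame(modules: list[DelModule]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": m.id, "polarity": m.polarity, "size": len(m.nodes),
        "n_edges": m.n_edges, "n_del_edges": m.n_del_edges,
        "p": m.enrichment_p, "q": m.enrichment_q,
        "nodes": ",".join(sorted(m.nodes)),
        "core_nodes": ",".join(sorted(m.core_nodes)),
    } for m in modules])
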