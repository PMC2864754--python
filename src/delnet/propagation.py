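"""Day-1 seed linkage statistics and degree comparison for altered genes.

Tests the propagation hypothesis at the gene level: do the genes perturbed on
day 1 (the "seeds") directly contact an unexpectedly large fraction of the
genes that first respond on later days?  The observed contacted fraction is
compared to a permutation null in which the seed set is replaced by random
measured genes of equal size — uniformly, or matched to the seeds' degree
distribution, since altered genes tend to sit on network hubs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import BackboneNetwork
from .diffexpr import DeCall

__all__ = ["LinkageStats", "linkage_stats", "degree_comparison", "contacted_fraction"]


@dataclass
class LinkageStats:
    n_seed: int
    n_later: int
    n_seed_edges: int
    contacted_fraction: float
    expected_fraction: float
    empirical_p: float


def contacted_fraction(network: BackboneNetwork, seeds: set[str],
                       later: set[str]) -> float:
    """Fraction of `later` genes adjacent to at least one seed."""
    if not later:
        return 0.0
    G = network.graph
    hit = 0
    for g in later:
        if g in G and any(nb in seeds for nb in G.neighbors(g)):
            hit += 1
    return hit / len(later)


def _degree_bins(degrees: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Assign nodes to approximately equal-occupancy degree bins."""
    qs = np.quantile(degrees, np.linspace(0, 1, n_bins + 1))
    qs = np.unique(qs)
    return np.clip(np.searchsorted(qs, degrees, side="right") - 1, 0, len(qs) - 2)


def linkage_stats(network: BackboneNetwork, de_calls: list[DeCall],
                  n_draws: int = 1000, seed: int = 0,
                  degree_matched: bool = False,
                  fbs_min: float | None = None) -> LinkageStats:
    """Observed vs null contacted fraction of later-day genes by day-1 seeds.

    ``de_calls`` supply first-DE days; seeds are genes first DE on day 1,
    "later" genes are those first DE on days 2-5.  The network should already
    be restricted to measured genes; an optional FBS floor drops weak edges
    first.  empirical_p = (1 + #null >= observed) / (1 + n_draws).
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if fbs_min is not None:
        import networkx as nx
        G = nx.Graph()
        G.add_nodes_from(network.graph.nodes)
        for a, b, f in network.edges(fbs_min=fbs_min):
            G.add_edge(a, b, fbs=f)
        network = BackboneNetwork(G)
    measured = sorted(network.nodes)
    seeds = {c.gene for c in de_calls if c.first_de_day == 1} & set(measured)
    later = {c.gene for c in de_calls
             if c.first_de_day is not None and c.first_de_day >= 2} & set(measured)
    n_seed_edges = sum(1 for a, b, _ in network.edges() if a in seeds or b in seeds)
    if not seeds or not later:
        return LinkageStats(len(seeds), len(later), n_seed_edges, 0.0, 0.0, 1.0)
    observed = contacted_fraction(network, seeds, later)
    rng = np.random.default_rng(seed)
    pool = np.array(measured)
    degrees = np.array([network.graph.degree(g) for g in measured])
    if degree_matched:
        bins = _degree_bins(degrees)
        bin_of = dict(zip(measured, bins))
        by_bin = {b: pool[bins == b] for b in np.unique(bins)}
        seed_bins = [bin_of[g] for g in seeds]
    null = np.empty(n_draws)
    for i in range(n_draws):
        if degree_matched:
            draw = {str(rng.choice(by_bin[b])) for b in seed_bins}
        else:
            draw = set(rng.choice(pool, size=len(seeds), replace=False).tolist())
        null[i] = contacted_fraction(network, draw, later)
    empirical_p = (1 + int((null >= observed).sum())) / (1 + n_draws)
    return LinkageStats(
        n_seed=len(seeds), n_later=len(later), n_seed_edges=n_seed_edges,
        contacted_fraction=observed, expected_fraction=float(null.mean()),
        empirical_p=float(empirical_p),
    )


def degree_comparison(network: BackboneNetwork,
                      altered_genes: set[str]) -> tuple[float, float, float]:
    """(mean degree of altered genes, mean of the rest, 1-way ANOVA p)."""
    altered = set(altered_genes) & network.nodes
    other = network.nodes - altered
    if not altered or not other:
        raise ValueError("both the altered and the non-altered group must be non-empty")
    deg_a = np.array([network.graph.degree(g) for g in sorted(altered)], dtype=float)
    deg_o = np.array([network.graph.degree(g) for g in sorted(other)], dtype=float)
    _, p = stats.f_oneway(deg_a, deg_o)
    return float(deg_a.mean()), float(deg_o.mean()), float(p)
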