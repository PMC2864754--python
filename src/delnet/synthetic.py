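"""Synthetic study generator with the structure the pipeline assumes.

Emulates the real design this kind of analysis targets: a scale-free
functional-coupling backbone with per-edge confidences, and a replicated
two-condition developmental time course (2 conditions x 5 days x 4
replicates, optionally with one treated day-2 replicate dropped to give 39
arrays).  Ground truth is planted at three levels:

* *differential expression* — a per-gene schedule (first responding day,
  log10 effect size) switches a constant treated-arm shift on from that day;
* *condition-specific co-expression* — planted gene sets share a per-sample
  latent factor active in only one condition (treated for enabled links,
  control for sensitive), so within-set backbone edges become true DELs with
  a controlled within-condition correlation;
* *temporal propagation* — first-DE days are assigned so that chosen GO
  category pairs are connected by enough day-a -> day-(a+1) links to form
  true meta-flow edges.

Generative model per gene g and sample s (log10 ratio scale):

    value = baseline(g, day(s))                      # random-walk trajectory
          + effect(g) * [treated(s) and day(s) >= first_de_day(g)]
          + lambda * Z_set(s) * [g planted, condition(s) active for its set]
          + Normal(0, noise_sd)

Developmental random-walk baselines make DAY the dominant variance component,
as in real embryogenesis data.  Planted co-expression genes carry damped
baselines (``planted_day_scale``) so the latent factor, not the trajectory,
sets their within-condition correlation; their effect sizes are drawn with
wide per-gene heterogeneity so the GENE x TREATMENT interaction is detectable.
Everything is driven by one mandatory seed; identical configs are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data import DAYS, BackboneNetwork, ExpressionDataset, SampleMeta, GoAnnotation

__all__ = [
    "TruthConfig",
    "TruthLabels",
    "generate_backbone",
    "simulate_dataset",
    "make_coexpression_truth",
    "plant_propagation",
    "random_go_scheme",
]


@dataclass
class TruthConfig:
    """Everything that defines one synthetic study."""

    seed: int
    n_replicates: int = 4
    drop_sample: tuple[int, str, int] | None = None  # (day, treatment, replicate)
    planted_enabled: list[list[str]] = field(default_factory=list)
    planted_sensitive: list[list[str]] = field(default_factory=list)
    de_schedule: dict[str, tuple[int, float]] = field(default_factory=dict)
    go_scheme: dict[str, set[str]] = field(default_factory=dict)
    noise_sd: float = 0.05
    day_sd: float = 0.15          # random-walk step of developmental baselines
    latent_strength: float = 0.15  # lambda: loading on the shared condition factor
    planted_day_scale: float = 0.0  # baseline damping for planted co-expression genes

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for day, eff in self.de_schedule.values():
            if day not in DAYS or not np.isfinite(eff):
                raise ValueError(f"bad de_schedule entry ({day}, {eff})")


@dataclass
class TruthLabels:
    """Ground truth returned alongside the simulated dataset, for scoring."""

    enabled_links: set[frozenset]
    sensitive_links: set[frozenset]
    de_schedule: dict[str, tuple[int, float]]


def generate_backbone(n_nodes: int, m: int, seed: int,
                      fbs_range: tuple[float, float] = (3.0, 12.0)) -> BackboneNetwork:
    """Preferential-attachment backbone with uniform FBS confidences.

    Node ids are zero-padded ``g0001``-style strings so lexicographic and
    numeric orders agree.
    """
    if not (n_nodes > m >= 1):
        raise ValueError(f"need n_nodes > m >= 1, got n={n_nodes}, m={m}")
    rng = np.random.default_rng(seed)
    G = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    width = len(str(n_nodes - 1))
    mapping = {i: f"g{i:0{width}d}" for i in G.nodes}
    G = nx.relabel_nodes(G, mapping)
    lo, hi = fbs_range
    for a, b in sorted(G.edges()):
        G.edges[a, b]["fbs"] = float(rng.uniform(lo, hi))
        G.edges[a, b]["relation"] = "pp"
    return BackboneNetwork(G)


def _sample_sheet(config: TruthConfig) -> list[SampleMeta]:
    samples = []
    for day in DAYS:
        for treatment in ("control", "treated"):
            for rep in range(1, config.n_replicates + 1):
                if config.drop_sample == (day, treatment, rep):
                    continue
                samples.append(SampleMeta(f"d{day}_{treatment}_r{rep}", day, treatment, rep))
    return samples


def simulate_dataset(backbone: BackboneNetwork,
                     config: TruthConfig) -> tuple[ExpressionDataset, TruthLabels]:
    """Simulate the expression matrix for every backbone gene plus truth labels.

    True enabled/sensitive links are the backbone edges internal to each
    planted set.
    """
    genes = sorted(backbone.nodes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    samples = _sample_sheet(config)
    n = len(samples)
    day = np.array([s.day for s in samples])
    treated = np.array([s.treatment == "treated" for s in samples])
    rng = np.random.default_rng(config.seed)

    planted = {g for s in config.planted_enabled + config.planted_sensitive for g in s}
    # developmental baselines: random walk over the 5 days
    steps = rng.normal(0.0, config.day_sd, size=(len(genes), len(DAYS)))
    baseline = np.cumsum(steps, axis=1)
    for g in planted:
        baseline[gene_idx[g]] *= config.planted_day_scale

    mean = baseline[:, day - 1].copy()
    for g, (first_day, eff) in config.de_schedule.items():
        if g in gene_idx:
            mask = treated & (day >= first_day)
            mean[gene_idx[g], mask] += eff

    values = mean.copy()
    for sets, active in ((config.planted_enabled, treated),
                         (config.planted_sensitive, ~treated)):
        for members in sets:
            z = rng.normal(size=n)
            for g in members:
                values[gene_idx[g], active] += config.latent_strength * z[active]
    values += rng.normal(0.0, config.noise_sd, size=values.shape)

    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                         columns=[s.sample_id for s in samples])
    dataset = ExpressionDataset(frame, samples)

    def internal_edges(sets: list[list[str]]) -> set[frozenset]:
        out: set[frozenset] = set()
        for members in sets:
            ms = set(members)
            for a in members:
                for b in backbone.graph.neighbors(a):
                    if b in ms and a != b:
                        out.add(frozenset((a, b)))
        return out

    labels = TruthLabels(
        enabled_links=internal_edges(config.planted_enabled),
        sensitive_links=internal_edges(config.planted_sensitive),
        de_schedule=dict(config.de_schedule),
    )
    return dataset, labels


def _connected_set(graph: nx.Graph, start: str, size: int,
                   taken: set[str]) -> list[str] | None:
    """BFS-grow a connected node set of the requested size avoiding `taken`."""
    if start in taken:
        return None
    members = [start]
    seen = {start}
    frontier = [start]
    while frontier and len(members) < size:
        node = frontier.pop(0)
        for nb in sorted(graph.neighbors(node)):
            if nb not in seen and nb not in taken:
                seen.add(nb)
                members.append(nb)
                frontier.append(nb)
                if len(members) == size:
                    break
    return members if len(members) == size else None


def make_coexpression_truth(backbone: BackboneNetwork, seed: int,
                            n_enabled: int = 3, n_sensitive: int = 2,
                            set_size: int = 5,
                            drop_sample: tuple[int, str, int] | None = (2, "treated", 4),
                            effect_range: tuple[float, float] = (0.2, 1.6),
                            **overrides) -> TruthConfig:
    """Build a TruthConfig with planted condition-specific co-expression sets.

    Each planted set is a backbone-connected group of ``set_size`` genes; its
    members get heterogeneous signed treatment effects from day 1 (drawn from
    ``effect_range`` on the log10 scale) so that planted links both correlate
    within the active condition and clear the ANOVA interaction gate.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(backbone.nodes)
    taken: set[str] = set()
    sets: list[list[str]] = []
    attempts = 0
    while len(sets) < n_enabled + n_sensitive and attempts < 100 * (n_enabled + n_sensitive):
        attempts += 1
        start = nodes[int(rng.integers(len(nodes)))]
        members = _connected_set(backbone.graph, start, set_size, taken)
        if members is not None:
            taken |= set(members)
            sets.append(members)
    if len(sets) < n_enabled + n_sensitive:
        raise ValueError("could not place all planted sets on the backbone")
    # Effect sizes are spread deterministically over the range with alternating
    # signs and shuffled over members: every planted pair then shows a
    # gene-specific treatment response (the defining property of an enabled/
    # sensitive link), not just shared correlation.
    lo, hi = effect_range
    de_schedule = {}
    for members in sets:
        mags = np.linspace(lo, hi, len(members))
        effs = [m * (1 if i % 2 == 0 else -1) for i, m in enumerate(mags)]
        for g, eff in zip(rng.permutation(members), effs):
            de_schedule[str(g)] = (1, float(eff))
    return TruthConfig(
        seed=int(rng.integers(2**31)),
        drop_sample=drop_sample,
        planted_enabled=sets[:n_enabled],
        planted_sensitive=sets[n_enabled:],
        de_schedule=de_schedule,
        **overrides,
    )


def random_go_scheme(genes: list[str], n_terms: int, seed: int,
                     multi_fraction: float = 0.0) -> dict[str, set[str]]:
    """Partition genes into ``n_terms`` GO-like categories, optionally with
    a fraction of genes annotated to two categories."""
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    scheme: dict[str, set[str]] = {}
    for g in sorted(genes):
        t = terms[int(rng.integers(n_terms))]
        scheme[g] = {t}
        if rng.random() < multi_fraction:
            scheme[g].add(terms[int(rng.integers(n_terms))])
    return scheme


def random_de_background(genes: list[str], n_genes: int, seed: int,
                         effect_range: tuple[float, float] = (0.4, 1.2)
                         ) -> dict[str, tuple[int, float]]:
    """Diffuse regulation background: n_genes random genes get uniform random
    first-DE days over 1-5 and signed effects.

    Meta-flow enrichment is relative to the overall linkage of categories on
    the days of interest, so planted flows are only detectable against such a
    background of regulated genes scattered over categories and days.
    """
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.array(sorted(genes)), size=n_genes, replace=False)
    lo, hi = effect_range
    schedule = {}
    for g in sorted(chosen.tolist()):
        day = int(rng.integers(1, 6))
        eff = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
        schedule[g] = (day, eff)
    return schedule


def make_propagation_truth(backbone: BackboneNetwork,
                           flows: list[tuple[int, int]], seed: int,
                           n_links: int = 8, n_terms: int = 12,
                           n_background: int = 300, max_degree: int = 3,
                           effect_range: tuple[float, float] = (0.4, 1.2)
                           ) -> tuple[dict[str, set[str]], dict[str, tuple[int, float]],
                                      list[tuple[str, int, str, int]]]:
    """Build a complete planted-propagation study: GO scheme + DE schedule.

    Each flow (day_a, day_b = day_a + 1) gets two dedicated GO categories —
    source members first DE on day_a, target members on day_b — connected by
    ``n_links`` backbone edges with disjoint endpoints, emulating coherent
    gene sets responding on consecutive days.  ``n_background`` other genes
    receive uniform random first-DE days and random categories from the
    remaining terms, providing the diffuse linkage background against which
    flow enrichment is measured.  Flow members are drawn from genes of degree
    <= ``max_degree``, so their incidental links do not swamp the category
    marginals the expectation is built from.

    Returns (go_scheme, de_schedule, flow specs as (GO_src, day_a, GO_tgt, day_b)).
    """
    rng = np.random.default_rng(seed)
    lo, hi = effect_range
    scheme: dict[str, set[str]] = {}
    schedule: dict[str, tuple[int, float]] = {}
    specs: list[tuple[str, int, str, int]] = []
    used: set[str] = set()
    deg = dict(backbone.graph.degree())
    edges = [tuple(sorted((a, b))) for a, b, _ in backbone.edges()
             if deg[a] <= max_degree and deg[b] <= max_degree]
    term_no = 0
    for day_a, day_b in flows:
        if day_b != day_a + 1:
            raise ValueError(f"flow days must be consecutive, got {day_a}->{day_b}")
        term_no += 2
        src_go = f"GO:{term_no - 1:07d}"
        tgt_go = f"GO:{term_no:07d}"
        order = rng.permutation(len(edges))
        placed = 0
        for i in order:
            a, b = edges[i]
            if a in used or b in used:
                continue
            src, tgt = (a, b) if rng.random() < 0.5 else (b, a)
            scheme[src] = {src_go}
            scheme[tgt] = {tgt_go}
            schedule[src] = (day_a, float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1))
            schedule[tgt] = (day_b, float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1))
            used |= {a, b}
            placed += 1
            if placed >= n_links:
                break
        if placed < n_links:
            raise ValueError(f"infeasible flow day{day_a}->day{day_b}: "
                             f"only {placed} of {n_links} disjoint links placeable")
        specs.append((src_go, day_a, tgt_go, day_b))
    other_terms = [f"GO:{term_no + 1 + i:07d}" for i in range(n_terms)]
    pool = np.array(sorted(set(map(str, backbone.nodes)) - used))
    background = rng.choice(pool, size=min(n_background, len(pool)), replace=False)
    for g in sorted(background.tolist()):
        scheme[g] = {other_terms[int(rng.integers(n_terms))]}
        day = int(rng.integers(1, 6))
        schedule[g] = (day, float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1))
    return scheme, schedule, specs


def plant_propagation(backbone: BackboneNetwork,
                      go_scheme: dict[str, set[str]],
                      flows: list[tuple[str, int, str, int]],
                      seed: int, n_links: int = 3,
                      effect_range: tuple[float, float] = (0.4, 1.2)
                      ) -> dict[str, tuple[int, float]]:
    """Assign first-DE days so each flow has >= n_links cross-category links.

    ``flows`` is a list of (GO_source, day_a, GO_target, day_b) with
    day_b = day_a + 1.  Genes already committed to one flow keep their day; a
    flow that cannot reach ``n_links`` consistent backbone edges raises an
    error naming it.
    """
    rng = np.random.default_rng(seed)
    members: dict[str, set[str]] = {}
    for g, terms in go_scheme.items():
        for t in terms:
            members.setdefault(t, set()).add(g)
    day_of: dict[str, int] = {}
    lo, hi = effect_range
    for src_go, day_a, tgt_go, day_b in flows:
        if day_b != day_a + 1:
            raise ValueError(f"flow {src_go}->{tgt_go}: day_b must be day_a + 1")
        placed = 0
        candidates = []
        for a in sorted(members.get(src_go, ())):
            if a not in backbone.graph:
                continue
            for b in sorted(backbone.graph.neighbors(a)):
                if b in members.get(tgt_go, set()):
                    candidates.append((a, b))
        rng.shuffle(candidates)
        for a, b in candidates:
            if day_of.get(a, day_a) != day_a or day_of.get(b, day_b) != day_b:
                continue
            day_of[a] = day_a
            day_of[b] = day_b
            placed += 1
            if placed >= n_links:
                break
        if placed < n_links:
            raise ValueError(
                f"infeasible flow {src_go} (day {day_a}) -> {tgt_go} (day {day_b}): "
                f"only {placed} of {n_links} links placeable"
            )
    schedule = {}
    for g, d in day_of.items():
        eff = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
        schedule[g] = (d, eff)
    return schedule
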