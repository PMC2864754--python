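"""Core data types and I/O for expression tables, SIF networks, and GO maps.

The in-memory containers are thin wrappers over pandas / networkx:

* :class:`ExpressionDataset` — genes x samples matrix of log10 sample/reference
  ratios with a sample sheet (day 1-5, control/treated, replicate).
* :class:`BackboneNetwork` — undirected functional-coupling graph with a
  per-edge confidence score (FBS, Final Bayesian Score).
* :class:`GoAnnotation` — gene -> set of GO biological-process term ids.

File formats are the plain-text Cytoscape conventions: 3-column SIF, edge
attribute tables keyed ``A (relation) B``, tab-separated expression tables and
sample sheets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

NA_TOKEN = "NA"
TREATMENTS = ("control", "treated")
DAYS = (1, 2, 3, 4, 5)

__all__ = [
    "SampleMeta",
    "ExpressionDataset",
    "BackboneNetwork",
    "GoAnnotation",
    "read_expression",
    "read_sif",
    "write_sif",
    "restrict_to_measured",
    "read_gene2go",
    "read_gaf",
    "collapse_probes",
    "merge_curated",
]


@dataclass(frozen=True)
class SampleMeta:
    """One microarray sample: day, treatment arm, and biological replicate."""

    sample_id: str
    day: int
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.day not in DAYS:
            raise ValueError(f"day must be in {DAYS}, got {self.day!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate!r}")

    @property
    def cell(self) -> tuple[int, str]:
        return (self.day, self.treatment)


class ExpressionDataset:
    """Genes x samples matrix of log10 expression ratios plus sample metadata.

    ``values`` is a DataFrame indexed by gene id with one column per sample id,
    in the order of ``samples``.  Missing values (degraded arrays, absent
    probes) are NaN and are dropped pairwise downstream.
    """

    def __init__(self, values: pd.DataFrame, samples: list[SampleMeta]):
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample_id in sample sheet")
        keys = [(s.day, s.treatment, s.replicate) for s in samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (day, treatment, replicate) in sample sheet")
        if list(values.columns) != sample_ids:
            missing = set(sample_ids) - set(values.columns)
            extra = set(values.columns) - set(sample_ids)
            if missing:
                raise ValueError(f"samples in sheet missing from table: {sorted(missing)}")
            if extra:
                raise ValueError(f"unknown samples in table: {sorted(extra)}")
            values = values[sample_ids]
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        self.values = values.astype(float)
        self.samples = list(samples)

    # -- convenience views -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def day(self) -> np.ndarray:
        return np.array([s.day for s in self.samples])

    @property
    def treatment(self) -> np.ndarray:
        return np.array([s.treatment for s in self.samples])

    @property
    def replicate(self) -> np.ndarray:
        return np.array([s.replicate for s in self.samples])

    def treated_mask(self) -> np.ndarray:
        return self.treatment == "treated"

    def control_mask(self) -> np.ndarray:
        return self.treatment == "control"

    def profile(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)

    def measured_genes(self) -> set[str]:
        """Genes with at least one non-missing value."""
        ok = self.values.notna().any(axis=1)
        return set(self.values.index[ok])

    def relabel_treatment(self, treatment: Mapping[str, str]) -> "ExpressionDataset":
        """Return a copy with treatment labels replaced per sample id.

        Used by the permutation FDR; values are shared, metadata is rebuilt.
        """
        samples = [
            SampleMeta(s.sample_id, s.day, treatment.get(s.sample_id, s.treatment), s.replicate)
            for s in self.samples
        ]
        return ExpressionDataset(self.values, samples)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionDataset({self.n_genes} genes x {self.n_samples} samples)"


class BackboneNetwork:
    """Undirected functional-coupling network with per-edge FBS confidence."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        for u, v, d in self.graph.edges(data=True):
            d.setdefault("fbs", 1.0)
            if d["fbs"] <= 0:
                raise ValueError(f"FBS must be > 0 on edge {u}-{v}, got {d['fbs']}")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            warnings.warn(f"dropping {len(loops)} self-loop(s)")
            self.graph.remove_edges_from(loops)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self, fbs_min: float | None = None) -> list[tuple[str, str, float]]:
        """Edges as (a, b, fbs) with a < b; optionally keep only fbs >= fbs_min."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            fbs = float(d.get("fbs", 1.0))
            if fbs_min is None or fbs >= fbs_min:
                out.append((a, b, fbs))
        return sorted(out)

    def fbs(self, a: str, b: str) -> float:
        return float(self.graph.edges[a, b].get("fbs", 1.0))

    def add_edge(self, a: str, b: str, fbs: float = 1.0, relation: str = "pp") -> None:
        if a == b:
            warnings.warn(f"dropping self-loop {a}-{b}")
            return
        if fbs <= 0:
            raise ValueError(f"FBS must be > 0, got {fbs}")
        if self.graph.has_edge(a, b):
            old = self.graph.edges[a, b].get("fbs", 1.0)
            self.graph.edges[a, b]["fbs"] = max(old, fbs)
        else:
            self.graph.add_edge(a, b, fbs=fbs, relation=relation)

    def subgraph(self, nodes: Iterable[str]) -> "BackboneNetwork":
        return BackboneNetwork(nx.Graph(self.graph.subgraph(nodes)))

    def __repr__(self) -> str:  # pragma: no cover
        return f"BackboneNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class GoAnnotation:
    """Gene -> set of GO biological-process term ids, with optional term names."""

    gene2terms: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, terms in self.gene2terms.items():
            if not gene:
                raise ValueError("empty gene id in GO annotation")
            if not terms:
                raise ValueError(f"empty term set for gene {gene!r}")

    def terms_for(self, gene: str) -> set[str]:
        return self.gene2terms.get(gene, set())

    def genes_for(self, term: str) -> set[str]:
        return {g for g, ts in self.gene2terms.items() if term in ts}

    @property
    def genes(self) -> set[str]:
        return set(self.gene2terms)

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene2terms.values():
            out |= ts
        return out

    def propagate(self, ontology) -> "GoAnnotation":
        """True-path propagation: add all ancestors of each direct annotation.

        ``ontology`` is a networkx DiGraph with child -> parent edges, e.g. as
        read by :func:`obonet.read_obo`.
        """
        gene2terms: dict[str, set[str]] = {}
        cache: dict[str, set[str]] = {}
        for gene, terms in self.gene2terms.items():
            full = set(terms)
            for t in terms:
                if t not in cache:
                    cache[t] = set(nx.descendants(ontology, t)) if t in ontology else set()
                full |= cache[t]
            gene2terms[gene] = full
        return GoAnnotation(gene2terms, dict(self.term_names))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(table_path, sample_sheet_path) -> ExpressionDataset:
    """Read a genes x samples log-ratio TSV plus its sample sheet.

    The table's first column holds gene ids; every other column must appear in
    the sheet and vice versa.  The sheet is a TSV with columns
    ``sample_id, day, treatment, replicate``.
    """
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "day", "treatment", "replicate"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    samples = [
        SampleMeta(r.sample_id, int(r.day), r.treatment, int(r.replicate))
        for r in sheet.itertuples()
    ]
    values = pd.read_csv(table_path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    if values.index.name is None or values.columns.duplicated().any():
        raise ValueError("malformed expression table header")
    non_numeric = values.select_dtypes(exclude="number").columns.tolist()
    if non_numeric:
        raise ValueError(f"non-numeric cells in columns {non_numeric}")
    return ExpressionDataset(values, samples)


def _edge_key(a: str, b: str, relation: str = "pp") -> str:
    return f"{a} ({relation}) {b}"


def read_sif(path, edge_attr_path=None, attr_name: str = "fbs") -> BackboneNetwork:
    """Read a 3-column SIF network, optionally with a per-edge FBS table.

    Duplicate A-B / B-A lines collapse to one undirected edge keeping the
    maximum FBS; self-loops are dropped with a warning.  Absent attributes
    default to FBS 1.0.
    """
    fbs_map: dict[frozenset, float] = {}
    if edge_attr_path is not None:
        with open(edge_attr_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or "=" not in line and "\t" not in line:
                    continue
                if "=" in line:
                    key, _, val = line.rpartition("=")
                else:
                    key, val = line.rsplit("\t", 1)
                key = key.strip()
                if "(" not in key:  # header line like "FBS"
                    continue
                a = key.split(" (")[0].strip()
                b = key.split(") ")[-1].strip()
                fbs = float(val)
                if fbs < 0:
                    raise ValueError(f"negative FBS for edge {a}-{b}")
                fbs_map[frozenset((a, b))] = fbs

    net = BackboneNetwork()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: SIF line must have 3 fields, got {len(fields)}")
            a, relation, b = (f.strip() for f in fields)
            if a == b:
                warnings.warn(f"{path}:{lineno}: dropping self-loop {a}")
                continue
            fbs = fbs_map.get(frozenset((a, b)), 1.0)
            if fbs <= 0:
                raise ValueError(f"FBS must be > 0 for edge {a}-{b}")
            net.add_edge(a, b, fbs=fbs, relation=relation)
    return net


def write_sif(network: BackboneNetwork, path, edge_attr_path=None) -> None:
    """Write SIF plus an optional FBS edge-attribute table; round-trip safe."""
    edges = network.edges()
    with open(path, "w") as fh:
        for a, b, _ in edges:
            relation = network.graph.edges[a, b].get("relation", "pp")
            fh.write(f"{a}\t{relation}\t{b}\n")
    if edge_attr_path is not None:
        with open(edge_attr_path, "w") as fh:
            fh.write("fbs\n")
            for a, b, fbs in edges:
                relation = network.graph.edges[a, b].get("relation", "pp")
                fh.write(f"{_edge_key(a, b, relation)} = {fbs!r}\n")


def restrict_to_measured(network: BackboneNetwork, dataset: ExpressionDataset) -> BackboneNetwork:
    """Induced subgraph on genes measured (>= 1 non-missing value) in the dataset."""
    keep = network.nodes & dataset.measured_genes()
    return network.subgraph(keep)


def merge_curated(network: BackboneNetwork, curated_sif_path, fbs: float = 10.0) -> BackboneNetwork:
    """Merge a curated extra-edge SIF into the backbone at a fixed confidence.

    Literature-derived manual edges have no Bayesian score, so they enter at a
    user-set constant (default 10, i.e. high confidence).
    """
    merged = BackboneNetwork(nx.Graph(network.graph))
    extra = read_sif(curated_sif_path)
    for a, b, _ in extra.edges():
        merged.add_edge(a, b, fbs=fbs, relation=extra.graph.edges[a, b].get("relation", "pp"))
    return merged


def read_gene2go(path) -> GoAnnotation:
    """Read a two-column (gene, GO id) TSV into a GoAnnotation."""
    gene2terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"GO map line needs 2 columns: {line!r}")
            gene2terms.setdefault(fields[0], set()).add(fields[1])
    return GoAnnotation(gene2terms)


def read_gaf(path, aspect: str | None = "P") -> GoAnnotation:
    """Read gene -> GO from a GAF 2.x file (columns 2 and 5, 1-based).

    By default only biological-process annotations (aspect ``P``, column 9)
    are kept; pass ``aspect=None`` to keep all.
    """
    gene2terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            if aspect is not None and len(fields) >= 9 and fields[8] != aspect:
                continue
            gene2terms.setdefault(fields[1], set()).add(fields[4])
    return GoAnnotation(gene2terms)


def collapse_probes(values: pd.DataFrame, probe2gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe rows to genes: keep the probe with highest median |log-ratio|.

    Probes without a gene mapping are dropped.
    """
    mapped = values.loc[[p for p in values.index if p in probe2gene]].copy()
    score = mapped.abs().median(axis=1)
    gene = pd.Series({p: probe2gene[p] for p in mapped.index})
    order = score.sort_values(ascending=False).index
    seen: set[str] = set()
    keep: list[str] = []
    for probe in order:
        g = gene[probe]
        if g not in seen:
            seen.add(g)
            keep.append(probe)
    out = mapped.loc[keep]
    out.index = [gene[p] for p in keep]
    out.index.name = "gene"
    return out.sort_index()
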