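"""Pipeline orchestration: run every analysis stage and write its outputs.

Stages run in method order — gene ANOVA / DE calls, DEL detection, module
discovery, seed linkage statistics, GO-GO meta-flow — and each writes plain
TSV/SIF files under the output directory.  A JSON run manifest records the
parameters, the seed, package/library versions, and SHA-256 checksums of the
inputs, so a run is reproducible bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .data import (BackboneNetwork, ExpressionDataset, GoAnnotation,
                   read_expression, read_gene2go, read_sif, restrict_to_measured,
                   write_sif)
from .diffexpr import anova_to_frame, call_de, fit_anova_table
from .links import DelParams, detect_dels, estimate_del_fdr, links_to_frame
from .metaflow import MetaflowParams, build_metaflow, write_gogo
from .modules import find_modules, go_enrich_module, modules_to_frame
from .propagation import linkage_stats

log = logging.getLogger("delnet")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


@dataclass
class PipelineConfig:
    expression: str
    sample_sheet: str
    sif: str
    out_dir: str
    edge_attrs: str | None = None
    go_map: str | None = None
    alpha: float = 0.01
    plc_high: float = 0.75
    plc_low: float = 0.5
    fbs_min: float = 3.0
    chi_min: float = 6.64
    o_min: float = 3.0
    e_min: float = 0.5
    n_perm: int = 0       # 0 disables the permutation FDR stage
    n_draws: int = 1000
    max_module_size: int = 130
    seed: int = 0

    def del_params(self) -> DelParams:
        return DelParams(plc_high=self.plc_high, plc_low=self.plc_low,
                         alpha=self.alpha, fbs_min=self.fbs_min)

    def metaflow_params(self) -> MetaflowParams:
        return MetaflowParams(chi_min=self.chi_min, o_min=self.o_min,
                              e_min=self.e_min, fbs_min=self.fbs_min)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a summary dict (also written as manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("load")
        dataset = read_expression(config.expression, config.sample_sheet)
        network = read_sif(config.sif, config.edge_attrs)
        network = restrict_to_measured(network, dataset)
        annotation: GoAnnotation | None = None
        if config.go_map is not None:
            annotation = read_gene2go(config.go_map)
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    try:
        stage("diffexpr")
        results = fit_anova_table(dataset)
        calls = call_de(dataset, config.alpha, results=results)
        anova_to_frame(results, calls).to_csv(out / "gene_anova.tsv", sep="\t")
        summary["n_genes"] = dataset.n_genes
        summary["n_samples"] = dataset.n_samples
        summary["n_regulated"] = sum(1 for c in calls if c.de_days)
        summary["n_developmental"] = sum(1 for c in calls if c.developmental)
    except Exception as exc:
        raise PipelineError("diffexpr", exc) from exc

    try:
        stage("dels")
        params = config.del_params()
        records = detect_dels(dataset, network, params)
        links_to_frame(records).to_csv(out / "links.tsv", sep="\t", index=False)
        for cls in ("enabled", "sensitive", "resistant", "developmental"):
            sub = BackboneNetwork()
            for r in records:
                if r.link_class == cls:
                    sub.add_edge(r.gene_a, r.gene_b, fbs=r.fbs)
            write_sif(sub, out / f"links_{cls}.sif")
        summary["n_links_tested"] = len(records)
        for cls in ("enabled", "sensitive", "resistant", "developmental", "ambiguous"):
            summary[f"n_{cls}"] = sum(r.link_class == cls for r in records)
        if config.n_perm:
            fdr = estimate_del_fdr(dataset, network, params,
                                   n_perm=config.n_perm, seed=config.seed)
            summary["del_fdr"] = fdr
    except Exception as exc:
        raise PipelineError("dels", exc) from exc

    try:
        stage("modules")
        modules = find_modules(network, records, max_size=config.max_module_size)
        modules_to_frame(modules).to_csv(out / "modules.tsv", sep="\t", index=False)
        summary["n_modules"] = len(modules)
        if annotation is not None and modules:
            universe = set(dataset.genes) & annotation.genes
            frames = []
            for m in modules:
                df = go_enrich_module(m, annotation, universe)
                if not df.empty:
                    df.insert(0, "module", m.id)
                    frames.append(df)
            if frames:
                import pandas as pd
                pd.concat(frames).to_csv(out / "module_go.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("modules", exc) from exc

    try:
        stage("propagation")
        ls = linkage_stats(network, calls, n_draws=config.n_draws, seed=config.seed)
        import pandas as pd
        pd.DataFrame([asdict(ls)]).to_csv(out / "linkage_stats.tsv", sep="\t", index=False)
        summary["contacted_fraction"] = ls.contacted_fraction
        summary["expected_fraction"] = ls.expected_fraction
    except Exception as exc:
        raise PipelineError("propagation", exc) from exc

    if annotation is None:
        log.warning("no GO map supplied; skipping the GO-GO meta-flow stage")
        summary["gogo_skipped"] = True
    else:
        try:
            stage("gogo")
            gogo = build_metaflow(network, calls, annotation, config.metaflow_params())
            write_gogo(gogo, out / "gogo.sif", out / "gogo_nodes.tsv",
                       out / "gogo_edges.tsv")
            summary["n_gogo_edges"] = len(gogo.edges)
            summary["n_gogo_nodes"] = len(gogo.nodes)
        except Exception as exc:
            raise PipelineError("gogo", exc) from exc

    manifest = {
        "delnet_version": __version__,
        "config": asdict(config),
        "inputs": {
            name: _sha256(path)
            for name, path in (("expression", config.expression),
                               ("sample_sheet", config.sample_sheet),
                               ("sif", config.sif),
                               ("edge_attrs", config.edge_attrs),
                               ("go_map", config.go_map))
            if path is not None
        },
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
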