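"""Differentially expressed link (DEL) detection on a backbone network.

A DEL is a backbone (functional-coupling) edge whose co-expression support
changes between conditions.  For each retained backbone edge we compute

* split-condition Pearson correlations (PLC over all samples, treated-only,
  control-only), and
* a 3-way fixed-effects ANOVA on the two genes' stacked profiles with factors
  GENE (2 levels), DAY (5), TREATMENT (2) and all interactions — the
  GENE-involving interaction terms are what separates a genuine change in
  coupling from parallel shifts of both genes.

The decision cascade (thresholds in :class:`DelParams`):

* *enabled*   — treated PLC >= plc_high, control PLC < plc_low, and
  min(p[GENExTREAT], p[GENExDAYxTREAT]) < alpha;
* *sensitive* — the mirror image (coupling present only in control);
* *developmental* — coupling at resistant level in both conditions that is
  explained by shared day dependence: the 5-point per-day-mean profiles
  correlate >= plc_high in both conditions and both genes have a significant
  DAY main effect;
* *resistant* — PLC >= plc_high in both conditions, not developmental;
* *ambiguous* — overall PLC >= plc_high with no condition or day structure;
* *none* — everything else, including edges with too few complete pairs.

Only backbone edges can become DELs; the false discovery rate is estimated by
permuting treatment labels within (day, replicate) strata and re-running the
full detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import BackboneNetwork, ExpressionDataset
from .diffexpr import dummy_matrix, fit_anova_table, residual_maker

__all__ = [
    "DelParams",
    "LinkRecord",
    "pearson_plc",
    "split_condition_plc",
    "fit_link_anova",
    "classify_link",
    "detect_dels",
    "estimate_del_fdr",
    "links_to_frame",
]

DEL_CLASSES = ("enabled", "sensitive", "resistant", "developmental", "ambiguous", "none")


@dataclass(frozen=True)
class DelParams:
    """Thresholds for the DEL decision cascade."""

    plc_high: float = 0.75   # co-expression present
    plc_low: float = 0.5     # co-expression absent (ceiling)
    alpha: float = 0.01      # ANOVA significance for the GENE interactions
    fbs_min: float = 3.0     # backbone confidence floor
    min_pairs: int = 10      # complete pairs per condition needed to classify

    def __post_init__(self) -> None:
        if not (-1.0 <= self.plc_low < self.plc_high <= 1.0):
            raise ValueError("need -1 <= plc_low < plc_high <= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0,1)")


@dataclass
class LinkRecord:
    """Everything measured about one backbone edge."""

    gene_a: str
    gene_b: str
    fbs: float
    plc_all: float | None = None
    plc_trt: float | None = None
    plc_ctl: float | None = None
    p_gene_x_treat: float | None = None
    p_gene_x_day: float | None = None
    p_gene_x_day_x_treat: float | None = None
    plc_daymean_trt: float | None = None
    plc_daymean_ctl: float | None = None
    p_day_a: float | None = None
    p_day_b: float | None = None
    link_class: str = "none"


def pearson_plc(x, y, min_pairs: int = 3) -> float | None:
    """Pearson correlation with pairwise deletion of missing values.

    Returns None (with a warning) when fewer than ``min_pairs`` complete pairs
    remain, or when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < min_pairs:
        warnings.warn(f"pearson_plc: only {int(keep.sum())} complete pairs (< {min_pairs})")
        return None
    xs, ys = x[keep], y[keep]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def split_condition_plc(dataset: ExpressionDataset, gene_a: str, gene_b: str,
                        min_pairs: int = 3) -> tuple[float | None, float | None, float | None]:
    """(PLC over all samples, treated-only PLC, control-only PLC)."""
    x = dataset.profile(gene_a)
    y = dataset.profile(gene_b)
    trt = dataset.treated_mask()
    ctl = dataset.control_mask()
    return (
        pearson_plc(x, y, min_pairs),
        pearson_plc(x[trt], y[trt], min_pairs),
        pearson_plc(x[ctl], y[ctl], min_pairs),
    )


# ---------------------------------------------------------------------------
# 3-way link ANOVA
# ---------------------------------------------------------------------------

class LinkAnovaDesign:
    """Cached Type-II projections for the stacked GENE x DAY x TREATMENT model.

    The stacked response holds gene A's values followed by gene B's, so the
    design depends only on which samples are present — projections are
    computed once per missingness pattern and reused across edges.
    """

    def __init__(self, day: np.ndarray, treatment: np.ndarray):
        n = len(day)
        gene = np.repeat([0, 1], n)
        day2 = np.tile(day, 2)
        tr2 = np.tile(treatment, 2)
        from collections import Counter
        counts = Counter(zip(gene.tolist(), day2.tolist(), tr2.tolist()))
        n_cells = 2 * len(set(day2.tolist())) * len(set(tr2.tolist()))
        if len(counts) < n_cells or min(counts.values()) < 2:
            raise ValueError("3-way link ANOVA needs >= 2 replicates per cell")
        ones = np.ones((2 * n, 1))
        G = dummy_matrix(gene)
        D = dummy_matrix(day2)
        T = dummy_matrix(tr2)
        GD = dummy_matrix(gene, day2)
        GT = dummy_matrix(gene, tr2)
        DT = dummy_matrix(day2, tr2)
        GDT = dummy_matrix(gene, day2, tr2)
        main = [ones, G, D, T]
        self.M_full, r_full = residual_maker(np.hstack(main + [GD, GT, DT, GDT]))
        self.M_no3, r_no3 = residual_maker(np.hstack(main + [GD, GT, DT]))
        self.M_base_gt, r_bgt = residual_maker(np.hstack(main + [GD, DT]))
        self.M_base_gd, r_bgd = residual_maker(np.hstack(main + [GT, DT]))
        self.df_gt = r_no3 - r_bgt
        self.df_gd = r_no3 - r_bgd
        self.df_gdt = r_full - r_no3
        self.df_resid = 2 * n - r_full
        if self.df_resid <= 0:
            raise ValueError("insufficient replication: zero residual df")

    def pvalues(self, stacked: np.ndarray) -> dict[str, float]:
        rss_full = float(stacked @ (self.M_full @ stacked))
        rss_no3 = float(stacked @ (self.M_no3 @ stacked))
        rss_bgt = float(stacked @ (self.M_base_gt @ stacked))
        rss_bgd = float(stacked @ (self.M_base_gd @ stacked))
        ms_resid = rss_full / self.df_resid
        out: dict[str, float] = {}
        for name, ss, df in (
            ("gene_x_treat", max(rss_bgt - rss_no3, 0.0), self.df_gt),
            ("gene_x_day", max(rss_bgd - rss_no3, 0.0), self.df_gd),
            ("gene_x_day_x_treat", max(rss_no3 - rss_full, 0.0), self.df_gdt),
        ):
            if ms_resid > 0:
                F = (ss / df) / ms_resid
                out[name] = float(stats.f.sf(F, df, self.df_resid))
            else:
                out[name] = 0.0 if ss > 0 else 1.0
        return out


def fit_link_anova(dataset: ExpressionDataset, gene_a: str, gene_b: str,
                   design: LinkAnovaDesign | None = None) -> dict[str, float]:
    """GENE-interaction p-values for one backbone edge.

    Returns ``{"gene_x_treat", "gene_x_day", "gene_x_day_x_treat"}``.  Samples
    missing in either gene are dropped from both (pairwise deletion on the
    stacked response).
    """
    x = dataset.profile(gene_a)
    y = dataset.profile(gene_b)
    keep = np.isfinite(x) & np.isfinite(y)
    if design is None or not keep.all():
        design = LinkAnovaDesign(dataset.day[keep], dataset.treatment[keep])
        stacked = np.concatenate([x[keep], y[keep]])
    else:
        stacked = np.concatenate([x, y])
    return design.pvalues(stacked)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _ge(v: float | None, thr: float) -> bool:
    return v is not None and v >= thr


def _lt(v: float | None, thr: float) -> bool:
    return v is not None and v < thr


def classify_link(record: LinkRecord, params: DelParams = DelParams()) -> str:
    """Apply the DEL decision cascade to a populated LinkRecord."""
    r, p = record, params
    if r.plc_trt is None or r.plc_ctl is None:
        return "none"
    anova_gate = min(
        x for x in (r.p_gene_x_treat, r.p_gene_x_day_x_treat) if x is not None
    ) < p.alpha if (r.p_gene_x_treat is not None or r.p_gene_x_day_x_treat is not None) else False
    if _ge(r.plc_trt, p.plc_high) and _lt(r.plc_ctl, p.plc_low) and anova_gate:
        return "enabled"
    if _ge(r.plc_ctl, p.plc_high) and _lt(r.plc_trt, p.plc_low) and anova_gate:
        return "sensitive"
    if _ge(r.plc_trt, p.plc_high) and _ge(r.plc_ctl, p.plc_high):
        day_sync = (
            _ge(r.plc_daymean_trt, p.plc_high)
            and _ge(r.plc_daymean_ctl, p.plc_high)
            and r.p_day_a is not None and r.p_day_a < p.alpha
            and r.p_day_b is not None and r.p_day_b < p.alpha
        )
        return "developmental" if day_sync else "resistant"
    if _ge(r.plc_all, p.plc_high):
        return "ambiguous"
    return "none"


def _day_mean_profiles(dataset: ExpressionDataset, gene: str) -> dict[str, np.ndarray]:
    """5-point per-day mean profile of a gene in each condition."""
    y = dataset.profile(gene)
    out = {}
    for cond in ("treated", "control"):
        mask_c = dataset.treatment == cond
        means = []
        for d in sorted(set(dataset.day.tolist())):
            m = mask_c & (dataset.day == d)
            vals = y[m]
            vals = vals[np.isfinite(vals)]
            means.append(vals.mean() if len(vals) else np.nan)
        out[cond] = np.array(means)
    return out


def detect_dels(dataset: ExpressionDataset, network: BackboneNetwork,
                params: DelParams = DelParams()) -> list[LinkRecord]:
    """Classify every retained backbone edge; only backbone edges can be DELs.

    The network should already be restricted to measured genes; edges below
    the FBS floor are skipped.
    """
    edges = network.edges(fbs_min=params.fbs_min)
    edges = [(a, b, f) for a, b, f in edges
             if a in dataset.values.index and b in dataset.values.index]
    if not edges:
        warnings.warn("no backbone edges overlap the measured genes")
        return []
    genes = sorted({g for a, b, _ in edges for g in (a, b)})
    anova = {r.gene: r for r in fit_anova_table(dataset, genes)}
    try:
        shared_design = LinkAnovaDesign(dataset.day, dataset.treatment)
    except ValueError:
        shared_design = None

    trt = dataset.treated_mask()
    ctl = dataset.control_mask()
    day_means = {g: _day_mean_profiles(dataset, g) for g in genes}
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short-pair warnings handled via min_pairs
        for a, b, fbs in edges:
            x, y = dataset.profile(a), dataset.profile(b)
            rec = LinkRecord(gene_a=a, gene_b=b, fbs=fbs)
            rec.plc_all = pearson_plc(x, y, 3)
            rec.plc_trt = pearson_plc(x[trt], y[trt], params.min_pairs)
            rec.plc_ctl = pearson_plc(x[ctl], y[ctl], params.min_pairs)
            pv = fit_link_anova(dataset, a, b, design=shared_design)
            rec.p_gene_x_treat = pv["gene_x_treat"]
            rec.p_gene_x_day = pv["gene_x_day"]
            rec.p_gene_x_day_x_treat = pv["gene_x_day_x_treat"]
            rec.plc_daymean_trt = pearson_plc(
                day_means[a]["treated"], day_means[b]["treated"], 3)
            rec.plc_daymean_ctl = pearson_plc(
                day_means[a]["control"], day_means[b]["control"], 3)
            rec.p_day_a = anova[a].p_day
            rec.p_day_b = anova[b].p_day
            rec.link_class = classify_link(rec, params)
            records.append(rec)
    return records


def estimate_del_fdr(dataset: ExpressionDataset, network: BackboneNetwork,
                     params: DelParams = DelParams(), n_perm: int = 20,
                     seed: int = 0) -> float | None:
    """Permutation estimate of the enabled+sensitive false discovery rate.

    Treatment labels are permuted within each (day, replicate) stratum —
    i.e. the control/treated pair of arrays from the same week and day is
    swapped with probability 1/2 — preserving the day structure of the data.
    FDR = mean permuted DEL count / observed DEL count, truncated to [0, 1].
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    observed = sum(r.link_class in ("enabled", "sensitive")
                   for r in detect_dels(dataset, network, params))
    if observed == 0:
        warnings.warn("no observed enabled/sensitive DELs; FDR undefined")
        return None
    rng = np.random.default_rng(seed)
    strata: dict[tuple[int, int], list] = {}
    for s in dataset.samples:
        strata.setdefault((s.day, s.replicate), []).append(s)
    counts = []
    for _ in range(n_perm):
        relabel = {}
        for members in strata.values():
            if len(members) == 2 and rng.random() < 0.5:
                relabel[members[0].sample_id] = members[1].treatment
                relabel[members[1].sample_id] = members[0].treatment
        perm = dataset.relabel_treatment(relabel)
        counts.append(sum(r.link_class in ("enabled", "sensitive")
                          for r in detect_dels(perm, network, params)))
    return float(np.clip(np.mean(counts) / observed, 0.0, 1.0))


def links_to_frame(records: list[LinkRecord]) -> pd.DataFrame:
    """One row per backbone edge, ready for TSV export."""
    return pd.DataFrame([{
        "gene_a": r.gene_a, "gene_b": r.gene_b, "fbs": r.fbs,
        "plc_all": r.plc_all, "plc_trt": r.plc_trt, "plc_ctl": r.plc_ctl,
        "p_gene_x_treat": r.p_gene_x_treat,
        "p_gene_x_day": r.p_gene_x_day,
        "p_gene_x_day_x_treat": r.p_gene_x_day_x_treat,
        "link_class": r.link_class,
    } for r in records])
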