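"""Per-gene two-way ANOVA (DAY x TREATMENT) and differential-expression calls.

The experimental design is a replicated two-factor layout: 5 developmental
days x 2 treatment arms x ~4 independent replicates, measured as log10
sample/reference ratios.  For each gene we fit a classical fixed-effects
two-way ANOVA with interaction and report

* main-effect and interaction p-values (Type II sums of squares, robust to
  the mild imbalance left by a degraded replicate),
* per-day treatment contrasts (treated-vs-control difference within day d,
  tested against the pooled residual variance of the full model), and
* eta-squared variance fractions per factor with bootstrap CIs.

A gene is called differentially expressed on day d when the day-d contrast
p-value falls below alpha (default 0.01, uncorrected — the network analyses
downstream provide their own error control), and "developmental" when the
DAY main effect is significant.

The fits are computed for all genes at once via residual-maker projections
(RSS of a nested model sequence), which reproduces per-gene OLS exactly while
being fast enough for genome-scale tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import DAYS, ExpressionDataset

__all__ = [
    "GeneAnovaResult",
    "DeCall",
    "fit_gene_anova",
    "fit_anova_table",
    "call_de",
    "variance_fractions",
    "threshold_filter",
]


@dataclass
class GeneAnovaResult:
    """Two-way ANOVA summary for one gene."""

    gene: str
    p_day: float
    p_treat: float
    p_interaction: float
    p_day_contrast: dict[int, float]
    fc: dict[int, float]  # treated/control ratio per day (10**contrast)
    eta2: dict[str, float] = field(default_factory=dict)
    ss: dict[str, float] = field(default_factory=dict)


@dataclass
class DeCall:
    """Per-gene differential-expression call derived from the day contrasts."""

    gene: str
    de_days: frozenset[int]
    first_de_day: int | None
    developmental: bool


# ---------------------------------------------------------------------------
# Projection machinery (shared with the 3-way link ANOVA in links.py)
# ---------------------------------------------------------------------------

def dummy_matrix(*factors: np.ndarray) -> np.ndarray:
    """Full-rank-agnostic indicator matrix for the interaction of factors."""
    labels = list(zip(*(np.asarray(f) for f in factors)))
    levels = sorted(set(labels))
    index = {lv: j for j, lv in enumerate(levels)}
    X = np.zeros((len(labels), len(levels)))
    for i, lv in enumerate(labels):
        X[i, index[lv]] = 1.0
    return X


def residual_maker(X: np.ndarray) -> tuple[np.ndarray, int]:
    """(I - P_X, rank(X)): projects onto the orthocomplement of col(X)."""
    n = X.shape[0]
    # QR with column pivoting is overkill; SVD-based pinv handles redundancy.
    P = X @ np.linalg.pinv(X)
    rank = int(round(np.trace(P)))
    return np.eye(n) - P, rank


class TwoWayDesign:
    """Precomputed projections for a DAY x TREATMENT layout (shared by genes)."""

    def __init__(self, day: np.ndarray, treatment: np.ndarray):
        day = np.asarray(day)
        treatment = np.asarray(treatment)
        self.day = day
        self.treatment = treatment
        self.n = len(day)
        self.days = sorted(set(day.tolist()))
        cells = pd.crosstab(pd.Series(day), pd.Series(treatment))
        if (cells.to_numpy() < 2).any() or cells.shape[1] < 2 or cells.shape[0] < 2:
            raise ValueError(
                "two-way ANOVA needs >= 2 replicates in every (day, treatment) cell "
                "and >= 2 levels per factor"
            )
        ones = np.ones((self.n, 1))
        D = dummy_matrix(day)
        T = dummy_matrix(treatment)
        DT = dummy_matrix(day, treatment)
        self.M0, r0 = residual_maker(ones)                       # intercept
        self.M_t, r_t = residual_maker(np.hstack([ones, T]))     # treat only
        self.M_d, r_d = residual_maker(np.hstack([ones, D]))     # day only
        self.M_dt, r_dt = residual_maker(np.hstack([ones, D, T]))
        self.M_full, r_full = residual_maker(np.hstack([ones, D, T, DT]))
        self.df_day = r_dt - r_t
        self.df_treat = r_dt - r_d
        self.df_int = r_full - r_dt
        self.df_resid = self.n - r_full
        if self.df_resid <= 0:
            raise ValueError("insufficient replication: zero residual df")
        # per-day cell selectors for contrasts
        self.cell_masks = {
            d: {
                "treated": (day == d) & (treatment == "treated"),
                "control": (day == d) & (treatment == "control"),
            }
            for d in self.days
        }


def _rss(M: np.ndarray, Y: np.ndarray) -> np.ndarray:
    R = M @ Y
    return np.einsum("ij,ij->j", R, R)


def _batch_anova(Y: np.ndarray, design: TwoWayDesign) -> dict[str, np.ndarray]:
    """Type II two-way ANOVA for a (n_samples x n_genes) response block."""
    rss_tot = _rss(design.M0, Y)
    rss_t = _rss(design.M_t, Y)
    rss_d = _rss(design.M_d, Y)
    rss_dt = _rss(design.M_dt, Y)
    rss_full = _rss(design.M_full, Y)
    ss_day = np.maximum(rss_t - rss_dt, 0.0)
    ss_treat = np.maximum(rss_d - rss_dt, 0.0)
    ss_int = np.maximum(rss_dt - rss_full, 0.0)
    ms_resid = rss_full / design.df_resid
    out: dict[str, np.ndarray] = {
        "ss_day": ss_day, "ss_treat": ss_treat, "ss_int": ss_int,
        "ss_resid": rss_full, "ss_total": rss_tot, "ms_resid": ms_resid,
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, ss, df in (
            ("day", ss_day, design.df_day),
            ("treat", ss_treat, design.df_treat),
            ("interaction", ss_int, design.df_int),
        ):
            F = np.where(ms_resid > 0, (ss / df) / ms_resid, 0.0)
            p = stats.f.sf(F, df, design.df_resid)
            # all-constant profile convention: F = 0, p = 1
            p = np.where(rss_tot <= 1e-12 * np.maximum(1.0, np.abs(Y).max(axis=0)) ** 2, 1.0, p)
            p = np.where(ms_resid <= 0, np.where(ss > 0, 0.0, 1.0), p)
            out[f"p_{name}"] = p
    # per-day treated-vs-control contrasts against pooled residual variance
    for d in design.days:
        mt = design.cell_masks[d]["treated"]
        mc = design.cell_masks[d]["control"]
        nt, nc = mt.sum(), mc.sum()
        diff = Y[mt].mean(axis=0) - Y[mc].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(ms_resid * (1.0 / nt + 1.0 / nc))
            t = np.where(se > 0, diff / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), design.df_resid)
        p = np.where((se <= 0) & (np.abs(diff) > 0), 0.0, p)
        p = np.where((se <= 0) & (np.abs(diff) <= 0), 1.0, p)
        out[f"contrast_diff_{d}"] = diff
        out[f"p_contrast_{d}"] = p
    return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _results_from_batch(genes: list[str], batch: dict[str, np.ndarray],
                        design: TwoWayDesign) -> list[GeneAnovaResult]:
    results = []
    scale = np.maximum(1.0, np.abs(batch["ss_total"]).max()) if len(genes) else 1.0
    for j, gene in enumerate(genes):
        ss_total = batch["ss_total"][j]
        if ss_total > 1e-12 * scale:
            eta2 = {
                "day": batch["ss_day"][j] / ss_total,
                "treatment": batch["ss_treat"][j] / ss_total,
                "interaction": batch["ss_int"][j] / ss_total,
                "residual": batch["ss_resid"][j] / ss_total,
            }
        else:
            eta2 = {"day": 0.0, "treatment": 0.0, "interaction": 0.0, "residual": 0.0}
        results.append(GeneAnovaResult(
            gene=gene,
            p_day=float(batch["p_day"][j]),
            p_treat=float(batch["p_treat"][j]),
            p_interaction=float(batch["p_interaction"][j]),
            p_day_contrast={d: float(batch[f"p_contrast_{d}"][j]) for d in design.days},
            fc={d: float(10.0 ** batch[f"contrast_diff_{d}"][j]) for d in design.days},
            eta2=eta2,
            ss={
                "day": float(batch["ss_day"][j]),
                "treatment": float(batch["ss_treat"][j]),
                "interaction": float(batch["ss_int"][j]),
                "residual": float(batch["ss_resid"][j]),
                "total": float(batch["ss_total"][j]),
            },
        ))
    return results


def fit_anova_table(dataset: ExpressionDataset,
                    genes: list[str] | None = None) -> list[GeneAnovaResult]:
    """Fit the two-way ANOVA for every (or the given) genes, vectorized.

    Genes with missing values fall back to a per-gene fit on their complete
    samples.
    """
    genes = list(genes) if genes is not None else dataset.genes
    V = dataset.values.loc[genes]
    mask_ok = V.notna().all(axis=1)
    results: dict[str, GeneAnovaResult] = {}
    complete = V.index[mask_ok].tolist()
    if complete:
        design = TwoWayDesign(dataset.day, dataset.treatment)
        Y = V.loc[complete].to_numpy(dtype=float).T  # samples x genes
        batch = _batch_anova(Y, design)
        for r in _results_from_batch(complete, batch, design):
            results[r.gene] = r
    for gene in V.index[~mask_ok]:
        y = V.loc[gene].to_numpy(dtype=float)
        keep = np.isfinite(y)
        design = TwoWayDesign(dataset.day[keep], dataset.treatment[keep])
        batch = _batch_anova(y[keep][:, None], design)
        results[gene] = _results_from_batch([gene], batch, design)[0]
    return [results[g] for g in genes]


def fit_gene_anova(dataset: ExpressionDataset, gene: str) -> GeneAnovaResult:
    """Two-way DAY x TREATMENT ANOVA for a single gene profile."""
    return fit_anova_table(dataset, [gene])[0]


def call_de(dataset: ExpressionDataset, alpha: float = 0.01,
            results: list[GeneAnovaResult] | None = None) -> list[DeCall]:
    """Differential-expression calls: de_days, first_de_day, developmental flag."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if results is None:
        results = fit_anova_table(dataset)
    calls = []
    for r in results:
        de_days = frozenset(d for d, p in r.p_day_contrast.items() if p < alpha)
        calls.append(DeCall(
            gene=r.gene,
            de_days=de_days,
            first_de_day=min(de_days) if de_days else None,
            developmental=r.p_day < alpha,
        ))
    return calls


def variance_fractions(dataset: ExpressionDataset, gene: str,
                       n_boot: int = 1000, seed: int = 0,
                       ci: float = 0.95) -> dict[str, tuple[float, tuple[float, float]]]:
    """Eta-squared per factor with bootstrap confidence intervals.

    The bootstrap resamples replicates within each (day, treatment) cell,
    keeping the design fixed; CIs are percentile intervals.
    """
    r = fit_gene_anova(dataset, gene)
    y = dataset.profile(gene)
    keep = np.isfinite(y)
    y = y[keep]
    day = dataset.day[keep]
    treatment = dataset.treatment[keep]
    design = TwoWayDesign(day, treatment)
    rng = np.random.default_rng(seed)
    factors = ("day", "treatment", "interaction", "residual")
    boots = {f: np.empty(n_boot) for f in factors}
    cell_idx = [
        np.flatnonzero((day == d) & (treatment == t))
        for d in design.days for t in ("control", "treated")
    ]
    for b in range(n_boot):
        yb = np.empty_like(y)
        for idx in cell_idx:
            yb[idx] = y[rng.choice(idx, size=len(idx), replace=True)]
        batch = _batch_anova(yb[:, None], design)
        tot = batch["ss_total"][0]
        if tot > 0:
            boots["day"][b] = batch["ss_day"][0] / tot
            boots["treatment"][b] = batch["ss_treat"][0] / tot
            boots["interaction"][b] = batch["ss_int"][0] / tot
            boots["residual"][b] = batch["ss_resid"][0] / tot
        else:
            for f in factors:
                boots[f][b] = 0.0
    lo, hi = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    out = {}
    for f in factors:
        point = r.eta2[f]
        out[f] = (point, (float(np.percentile(boots[f], lo)),
                          float(np.percentile(boots[f], hi))))
    return out


def threshold_filter(fold_change: pd.DataFrame, p_value: pd.DataFrame,
                     intensity: pd.DataFrame, p_max: float = 0.1,
                     fc_min: float = 1.3, intensity_min: float = 2.5,
                     min_reps: int = 3, per_day: bool = False):
    """Replicate-consistency DE filter on per-replicate array statistics.

    Inputs are gene x (day, replicate) tables (MultiIndex columns) of the
    per-replicate ratio p-value, treated/control fold change (ratio scale),
    and log10 intensity.  A gene passes on day d when, in at least
    ``min_reps`` replicates of that day, simultaneously p < p_max,
    |fold change| > fc_min (on the ratio scale: fc > fc_min or fc < 1/fc_min),
    and intensity > intensity_min.

    Returns the sorted list of genes passing on >= 1 day, or the boolean
    gene x day table when ``per_day`` is True.
    """
    days = sorted({d for d, _ in fold_change.columns})
    n_reps = {d: sum(1 for dd, _ in fold_change.columns if dd == d) for d in days}
    if any(min_reps > n for n in n_reps.values()):
        raise ValueError(f"min_reps={min_reps} exceeds replicate count {n_reps}")
    abs_fc = np.maximum(fold_change.abs(), 1.0 / fold_change.abs().replace(0, np.nan))
    ok = (p_value < p_max) & (abs_fc > fc_min) & (intensity > intensity_min)
    per_day_pass = pd.DataFrame(
        {d: ok.loc[:, d].sum(axis=1) >= min_reps for d in days},
        index=fold_change.index,
    )
    if per_day:
        return per_day_pass
    return sorted(per_day_pass.index[per_day_pass.any(axis=1)])


def anova_to_frame(results: list[GeneAnovaResult],
                   calls: list[DeCall] | None = None) -> pd.DataFrame:
    """Flatten ANOVA results (and optional DE calls) to one row per gene."""
    rows = []
    call_map = {c.gene: c for c in calls} if calls else {}
    for r in results:
        row = {"gene": r.gene, "p_day": r.p_day, "p_treat": r.p_treat,
               "p_interaction": r.p_interaction}
        for d in sorted(r.p_day_contrast):
            row[f"p_contrast_day{d}"] = r.p_day_contrast[d]
            row[f"fc_day{d}"] = r.fc[d]
        c = call_map.get(r.gene)
        if c is not None:
            row["de_days"] = ",".join(str(d) for d in sorted(c.de_days))
            row["first_de_day"] = c.first_de_day if c.first_de_day is not None else ""
            row["developmental"] = c.developmental
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
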