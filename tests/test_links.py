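"""DEL detection: correlations, link ANOVA, classification cascade, FDR."""

import numpy as np
import pandas as pd
import pytest

from delnet.data import BackboneNetwork
from delnet.links import (DelParams, LinkRecord, classify_link, detect_dels,
                          estimate_del_fdr, fit_link_anova, pearson_plc,
                          split_condition_plc)
from delnet.synthetic import (TruthConfig, generate_backbone,
                              make_coexpression_truth, simulate_dataset)
from conftest import build_dataset


class TestPearsonPlc:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_plc(x, x) == pytest.approx(1.0)
        assert pearson_plc(x, -x) == pytest.approx(-1.0)

    def test_direct_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_plc(x, y) == pytest.approx(num / den)

    def test_too_few_pairs_and_constant_vector(self):
        with pytest.warns(UserWarning):
            assert pearson_plc([1, 2], [3, 4]) is None
        assert pearson_plc([1.0, 1.0, 1.0], [1, 2, 3]) is None

    def test_pairwise_deletion(self):
        x = np.array([1, 2, 3, 4, np.nan])
        y = np.array([2, 4, 6, 8, 100.0])
        assert pearson_plc(x, y) == pytest.approx(1.0)


class TestSplitConditionPlc:
    def test_identical_profiles(self):
        ds = build_dataset({"a": lambda d, t, r: 0.1 * d + 0.01 * r,
                            "b": lambda d, t, r: 0.1 * d + 0.01 * r})
        assert split_condition_plc(ds, "a", "b") == pytest.approx((1.0, 1.0, 1.0))

    def test_treatment_only_correlation(self):
        rng = np.random.default_rng(0)
        shared = {(d, r): rng.normal(0, 0.5) for d in range(1, 6) for r in range(1, 5)}
        ds = build_dataset({
            "a": lambda d, t, r: shared[(d, r)] if t else 0.0,
            "b": lambda d, t, r: shared[(d, r)] if t else 0.0,
        }, noise_sd=0.05, seed=2)
        _, plc_trt, plc_ctl = split_condition_plc(ds, "a", "b")
        assert plc_trt > 0.9
        assert abs(plc_ctl) < 0.5


class TestLinkAnova:
    def test_parallel_profiles_give_null_gene_interactions(self):
        ds = build_dataset({"a": lambda d, t, r: 0.2 * d + 0.5 * t,
                            "b": lambda d, t, r: 0.2 * d + 0.5 * t + 1.0},
                           noise_sd=0.1, seed=3)
        pv = fit_link_anova(ds, "a", "b")
        assert pv["gene_x_treat"] > 0.05
        assert pv["gene_x_day"] > 0.05
        assert pv["gene_x_day_x_treat"] > 0.05

    def test_treatment_divergence_detected(self):
        ds = build_dataset({"a": lambda d, t, r: 0.8 * t,
                            "b": lambda d, t, r: -0.8 * t},
                           noise_sd=0.1, seed=4)
        pv = fit_link_anova(ds, "a", "b")
        assert pv["gene_x_treat"] < 0.01

    def test_matches_statsmodels_type2(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        ds = build_dataset({"a": lambda d, t, r: 0.1 * d,
                            "b": lambda d, t, r: 0.2 * t * d},
                           drop=(2, "treated", 4), noise_sd=0.3, seed=5)
        pv = fit_link_anova(ds, "a", "b")
        df = pd.DataFrame({
            "v": np.concatenate([ds.profile("a"), ds.profile("b")]),
            "g": np.repeat(["a", "b"], ds.n_samples),
            "d": np.tile(ds.day, 2), "t": np.tile(ds.treatment, 2),
        })
        tab = sm.stats.anova_lm(ols("v ~ C(g)*C(d)*C(t)", df).fit(), typ=2)
        assert pv["gene_x_treat"] == pytest.approx(tab.loc["C(g):C(t)", "PR(>F)"])
        assert pv["gene_x_day"] == pytest.approx(tab.loc["C(g):C(d)", "PR(>F)"])
        assert pv["gene_x_day_x_treat"] == pytest.approx(
            tab.loc["C(g):C(d):C(t)", "PR(>F)"])


class TestClassifyLink:
    def rec(self, **kw):
        base = dict(gene_a="a", gene_b="b", fbs=5.0, plc_all=0.8,
                    plc_trt=0.0, plc_ctl=0.0, p_gene_x_treat=1.0,
                    p_gene_x_day=1.0, p_gene_x_day_x_treat=1.0,
                    plc_daymean_trt=0.0, plc_daymean_ctl=0.0,
                    p_day_a=1.0, p_day_b=1.0)
        base.update(kw)
        return LinkRecord(**base)

    def test_enabled_reference_values(self):
        # condition PLCs as in the canonical treatment-enabled example
        r = self.rec(plc_trt=0.9032, plc_ctl=0.1286, p_gene_x_treat=0.001)
        assert classify_link(r) == "enabled"

    def test_sensitive_mirror(self):
        r = self.rec(plc_ctl=0.9032, plc_trt=0.1286, p_gene_x_treat=0.001)
        assert classify_link(r) == "sensitive"

    def test_resistant_without_day_structure(self):
        r = self.rec(plc_trt=1.0, plc_ctl=1.0)
        assert classify_link(r) == "resistant"

    def test_developmental_requires_day_sync_and_day_effects(self):
        r = self.rec(plc_trt=0.9, plc_ctl=0.9, plc_daymean_trt=0.95,
                     plc_daymean_ctl=0.95, p_day_a=0.001, p_day_b=0.001)
        assert classify_link(r) == "developmental"

    def test_ambiguous_when_only_pooled_correlation(self):
        r = self.rec(plc_all=0.876, plc_trt=0.5, plc_ctl=0.55)
        assert classify_link(r) == "ambiguous"

    def test_none_when_unclassifiable(self):
        assert classify_link(self.rec(plc_all=0.1)) == "none"
        assert classify_link(self.rec(plc_trt=None)) == "none"

    def test_anova_gate_blocks_enabled(self):
        r = self.rec(plc_trt=0.95, plc_ctl=0.05, p_gene_x_treat=0.5,
                     p_gene_x_day_x_treat=0.5, plc_all=0.6)
        assert classify_link(r) != "enabled"

    def test_symmetric_in_gene_order(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            kw = dict(plc_all=rng.uniform(-1, 1), plc_trt=rng.uniform(-1, 1),
                      plc_ctl=rng.uniform(-1, 1),
                      p_gene_x_treat=rng.uniform(), p_gene_x_day=rng.uniform(),
                      p_gene_x_day_x_treat=rng.uniform(),
                      plc_daymean_trt=rng.uniform(-1, 1),
                      plc_daymean_ctl=rng.uniform(-1, 1),
                      p_day_a=rng.uniform(), p_day_b=rng.uniform())
            fwd = classify_link(self.rec(**kw))
            swap = dict(kw, p_day_a=kw["p_day_b"], p_day_b=kw["p_day_a"])
            rev = classify_link(self.rec(gene_a="b", gene_b="a", **swap))
            assert fwd == rev


class TestDetectDels:
    def test_condition_identical_data_yields_no_dels(self):
        ds = build_dataset({f"g{i}": (lambda i: lambda d, t, r: 0.1 * d * i)(i)
                            for i in range(6)}, noise_sd=0.05, seed=7)
        net = BackboneNetwork()
        for i in range(5):
            net.add_edge(f"g{i}", f"g{i + 1}", fbs=5.0)
        recs = detect_dels(ds, net)
        assert all(r.link_class not in ("enabled", "sensitive") for r in recs)

    def test_only_backbone_edges_reported(self):
        bb = generate_backbone(60, 2, seed=8)
        truth = make_coexpression_truth(bb, seed=9, n_enabled=1, n_sensitive=0,
                                        set_size=4)
        ds, _ = simulate_dataset(bb, truth)
        recs = detect_dels(ds, bb)
        edges = {frozenset(e[:2]) for e in bb.edges()}
        assert all(frozenset((r.gene_a, r.gene_b)) in edges for r in recs)

    def test_fbs_floor_applied(self):
        ds = build_dataset({"a": lambda d, t, r: 0.1, "b": lambda d, t, r: 0.2},
                           noise_sd=0.05, seed=10)
        net = BackboneNetwork()
        net.add_edge("a", "b", fbs=2.0)
        with pytest.warns(UserWarning):
            assert detect_dels(ds, net, DelParams(fbs_min=3.0)) == []

    def test_del_fraction_monotone_in_plc_high(self):
        bb = generate_backbone(80, 2, seed=11)
        truth = make_coexpression_truth(bb, seed=12, n_enabled=2, n_sensitive=1,
                                        set_size=4)
        ds, _ = simulate_dataset(bb, truth)
        counts = []
        for plc_high in (0.6, 0.75, 0.9):
            recs = detect_dels(ds, bb, DelParams(plc_high=plc_high))
            counts.append(sum(r.link_class in ("enabled", "sensitive")
                              for r in recs))
        assert counts[0] >= counts[1] >= counts[2]

    def test_class_counts_ordering_on_realistic_simulation(self):
        """Condition-disrupted links are rarer than condition-created ones,
        and both are far rarer than condition-indifferent co-expression."""
        bb = generate_backbone(250, 2, seed=13)
        truth = make_coexpression_truth(bb, seed=14, n_enabled=4, n_sensitive=2,
                                        set_size=5)
        # plant a block of condition-indifferent (resistant-type) couplings:
        # genes sharing a latent factor in BOTH conditions
        ds, _ = simulate_dataset(bb, truth)
        recs = detect_dels(ds, bb)
        n = {cls: sum(r.link_class == cls for r in recs)
             for cls in ("enabled", "sensitive")}
        assert n["sensitive"] < n["enabled"]


class TestFdr:
    def test_null_data_fdr_near_one(self):
        bb = generate_backbone(60, 1, seed=15)
        ds, _ = simulate_dataset(bb, TruthConfig(seed=16))
        # liberal thresholds so the observed count is non-trivial under noise
        params = DelParams(plc_high=0.3, plc_low=0.29, alpha=0.5)
        fdr = estimate_del_fdr(ds, bb, params, n_perm=20, seed=17)
        assert fdr is None or fdr > 0.3

    def test_planted_signal_fdr_small(self):
        bb = generate_backbone(100, 2, seed=18)
        truth = make_coexpression_truth(bb, seed=19, n_enabled=2, n_sensitive=1,
                                        set_size=5)
        ds, _ = simulate_dataset(bb, truth)
        fdr = estimate_del_fdr(ds, bb, n_perm=20, seed=20)
        assert fdr is not None and fdr < 0.5

    def test_requires_enough_permutations(self, full_design_dataset):
        net = BackboneNetwork()
        net.add_edge("gA", "gB", fbs=5.0)
        with pytest.raises(ValueError):
            estimate_del_fdr(full_design_dataset, net, n_perm=5)
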