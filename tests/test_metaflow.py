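"""Temporal GO-GO meta-flow: day patterns, tallies, expectations, chi-square."""

import copy

import numpy as np
import pytest

from delnet.data import BackboneNetwork, GoAnnotation
from delnet.diffexpr import call_de
from delnet.metaflow import (DayPattern, MetaflowParams, all_patterns,
                             assign_pattern, build_metaflow, chi_square_score,
                             eligible_links, expected_count, tally)
from delnet.metaflow import EligibleLink
from delnet.synthetic import (TruthConfig, generate_backbone,
                              make_propagation_truth, simulate_dataset)
from conftest import build_dataset


class TestDayPatterns:
    def test_exactly_nine_patterns(self):
        pats = all_patterns()
        assert len(pats) == 9
        assert sum(p.kind == "same_day" for p in pats) == 5
        assert sum(p.kind == "consecutive" for p in pats) == 4

    @pytest.mark.parametrize("da,db,expect", [
        (1, 1, DayPattern(1, 1)),
        (2, 3, DayPattern(2, 3)),
        (3, 2, DayPattern(2, 3)),  # oriented earlier -> later
        (1, 3, None),              # skip-day pairs are not patterns
        (5, 5, DayPattern(5, 5)),
    ])
    def test_assign_pattern(self, da, db, expect):
        assert assign_pattern(da, db) == expect

    def test_invalid_day_raises(self):
        with pytest.raises(ValueError):
            assign_pattern(0, 1)


class TestEligibleLinks:
    def make_inputs(self):
        net = BackboneNetwork()
        edges = [("a", "b", 5), ("b", "c", 5), ("c", "d", 2), ("d", "e", 5),
                 ("e", "f", 5), ("f", "g", 5), ("g", "h", 5), ("a", "h", 5)]
        for a, b, f in edges:
            net.add_edge(a, b, fbs=float(f))
        from delnet.diffexpr import DeCall
        first = {"a": 1, "b": 2, "c": 2, "d": 3, "e": None, "f": 1, "g": 2, "h": None}
        calls = [DeCall(g, frozenset([d]) if d else frozenset(), d, False)
                 for g, d in first.items()]
        ann = GoAnnotation({g: {"GO:1"} for g in "abcdf"} | {"g": {"GO:2"}})
        return net, calls, ann

    def test_hand_enumerated(self):
        net, calls, ann = self.make_inputs()
        links = eligible_links(net, calls, ann, fbs_min=3.0)
        got = {frozenset((l.gene_a, l.gene_b)) for l in links}
        # a-b: both DE+annotated+fbs ok; b-c ok; c-d fbs 2 excluded;
        # d-e: e not DE; e-f: e not DE; f-g ok; g-h: h not DE; a-h: h not DE
        assert got == {frozenset("ab"), frozenset("bc"), frozenset("fg")}

    def test_no_de_genes_empty(self):
        net, calls, ann = self.make_inputs()
        from delnet.diffexpr import DeCall
        null_calls = [DeCall(c.gene, frozenset(), None, False) for c in calls]
        assert eligible_links(net, null_calls, ann) == []


class TestTally:
    def test_single_link_single_category(self):
        ann = GoAnnotation({"a": {"GO:1"}, "b": {"GO:2"}})
        links = [EligibleLink("a", "b", 1, 2)]
        t = tally(links, ann, DayPattern(1, 2))
        assert t.observed == {("GO:1", "GO:2"): 1.0}
        assert t.total == 1.0

    def test_multi_membership_contributes_per_category(self):
        ann = GoAnnotation({"a": {"GO:1", "GO:2"}, "b": {"GO:3"}})
        links = [EligibleLink("a", "b", 1, 2)]
        t = tally(links, ann, DayPattern(1, 2))
        assert t.observed == {("GO:1", "GO:3"): 1.0, ("GO:2", "GO:3"): 1.0}

    def test_same_day_diagonal_and_offdiagonal(self):
        ann = GoAnnotation({"a": {"GO:1"}, "b": {"GO:1"}, "c": {"GO:2"}})
        links = [EligibleLink("a", "b", 2, 2), EligibleLink("a", "c", 2, 2)]
        t = tally(links, ann, DayPattern(2, 2))
        assert t.observed[("GO:1", "GO:1")] == 1.0
        assert t.observed[("GO:1", "GO:2")] == 1.0

    def test_conservation_of_counts(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        ann = GoAnnotation({g: {f"GO:{rng.integers(1, 6)}"} |
                            ({f"GO:{rng.integers(1, 6)}"} if rng.random() < 0.3 else set())
                            for g in genes})
        links = [EligibleLink(*rng.choice(genes, 2, replace=False), 3, 4)
                 for _ in range(25)]
        t = tally(links, ann, DayPattern(3, 4))
        expected_total = sum(len(ann.terms_for(l.gene_a)) * len(ann.terms_for(l.gene_b))
                             for l in links)
        assert sum(t.observed.values()) == expected_total


class TestExpectedAndChi2:
    def test_direct_evaluation(self):
        assert expected_count(4, 5, 10) == pytest.approx(2.0)

    def test_degenerate_universe_normalization(self):
        # all pattern links between categories i and j only -> E = O
        ann = GoAnnotation({f"a{i}": {"GO:1"} for i in range(4)} |
                           {f"b{i}": {"GO:2"} for i in range(4)})
        links = [EligibleLink(f"a{i}", f"b{i}", 1, 2) for i in range(4)]
        t = tally(links, ann, DayPattern(1, 2))
        assert t.expected("GO:1", "GO:2") == pytest.approx(
            t.observed[("GO:1", "GO:2")])

    def test_sum_e_equals_sum_o_consecutive_and_same_day(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(40)]
        ann = GoAnnotation({g: {f"GO:{rng.integers(1, 7)}"} |
                            ({f"GO:{rng.integers(1, 7)}"} if rng.random() < 0.25 else set())
                            for g in genes})
        cons = [EligibleLink(*rng.choice(genes, 2, replace=False), 2, 3)
                for _ in range(30)]
        same = [EligibleLink(*rng.choice(genes, 2, replace=False), 4, 4)
                for _ in range(30)]
        for links, pat in ((cons, DayPattern(2, 3)), (same, DayPattern(4, 4))):
            t = tally(links, ann, pat)
            sum_o = sum(t.observed.values())
            sum_e = sum(t.expected(i, j) for i, j in t.observed)
            # expand E over all marginal pairs, not just observed cells
            keys_i = list(t.n_a)
            keys_j = list(t.n_b)
            if pat.kind == "consecutive":
                sum_e_full = sum(t.expected(i, j) for i in keys_i for j in keys_j)
            else:
                sum_e_full = sum(t.expected(i, j) for i in keys_i for j in keys_j
                                 if i <= j)
            assert sum_e_full == pytest.approx(sum_o)

    def test_chi_square_values(self):
        assert chi_square_score(2.0, 2.0) == 0.0
        assert chi_square_score(10.0, 2.0) == pytest.approx(32.0)
        with pytest.raises(ValueError):
            chi_square_score(1.0, 0.0)

    def test_chi_square_scale_consistency(self):
        assert chi_square_score(8.0, 2.0) * 2 == pytest.approx(
            chi_square_score(16.0, 4.0))

    def test_threshold_is_the_1df_99_percent_quantile(self):
        from scipy.stats import chi2
        assert MetaflowParams().chi_min == pytest.approx(chi2.ppf(0.99, 1), abs=0.01)


class TestBuildMetaflow:
    def run_planted(self, seed):
        bb = generate_backbone(600, 2, seed=seed)
        scheme, sched, specs = make_propagation_truth(bb, [(1, 2), (2, 3)],
                                                      seed=seed + 1)
        cfg = TruthConfig(seed=seed + 2, de_schedule=sched,
                          drop_sample=(2, "treated", 4))
        ds, _ = simulate_dataset(bb, cfg)
        calls = call_de(ds)
        return bb, GoAnnotation(scheme), calls, specs

    def test_planted_flows_retained_at_defaults(self):
        bb, ann, calls, specs = self.run_planted(100)
        net = build_metaflow(bb, calls, ann)
        got = {(e.go_i, e.go_j, e.pattern.a, e.pattern.b) for e in net.edges}
        for src_go, a, tgt_go, b in specs:
            assert (src_go, tgt_go, a, b) in got
        # node colors: flow categories are fully regulated
        for src_go, _, tgt_go, _ in specs:
            assert net.nodes[src_go].regulated_fraction == pytest.approx(1.0)

    def test_permuted_day_labels_destroy_flows(self):
        bb, ann, calls, specs = self.run_planted(200)
        n_planted_links = 2 * 8  # two flows x 8 planted gene-gene links
        rng = np.random.default_rng(0)
        retained = []
        for _ in range(10):
            perm = copy.deepcopy(calls)
            days = [c.first_de_day for c in perm if c.first_de_day]
            rng.shuffle(days)
            it = iter(days)
            for c in perm:
                if c.first_de_day:
                    c.first_de_day = next(it)
            retained.append(len(build_metaflow(bb, perm, ann).edges))
        assert np.mean(retained) <= 0.05 * n_planted_links
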