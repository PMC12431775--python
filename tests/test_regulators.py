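"""Bound sites, three-condition regulator calls and the overlap permutation null."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crelink.conservation import MotifSite
from crelink.genome_core import CellGroupMap, GenomicInterval
from crelink.linkage import LinkRecord, call_ccres
from crelink.regulators import (bound_site_set, identify_regulators,
                                permutation_overlap_test,
                                summarize_common_regulators)


class TestBoundSiteSet:
    fp = pd.DataFrame({
        "site_id": ["s1", "s2", "s3", "s1"],
        "cell_group": ["GA1_2", "GA1_2", "GA1_2", "GL1_2"],
        "footprint_score": [0.3, 0.0, -0.2, -1.0],
    })

    def test_strictly_positive_scores_only(self):
        assert bound_site_set(self.fp, "GA1_2") == {"s1"}
        assert bound_site_set(self.fp, "GL1_2") == set()

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            bound_site_set(self.fp, "NOPE")


def _toy_evidence(conservation=0.8, score=0.5, expr=1.5):
    """One selector gene, one cCRE, one TF site: all thresholds adjustable."""
    groups = CellGroupMap(pd.Series(
        ["GA1_2"] * 4 + ["GL1_2"] * 4,
        index=[f"c{i}" for i in range(8)]))
    ccres = [LinkRecord("feat1", "sel", 0.9, 3.0, 0.001)]
    sites = [MotifSite("s1", "TFX.M1", "TFX",
                       GenomicInterval("chr1", 100, 110), "+", "feat1",
                       conservation)]
    fp = pd.DataFrame({"site_id": ["s1"], "cell_group": ["GA1_2"],
                       "footprint_score": [score]})
    expr_df = pd.DataFrame({"TFX": [expr] * 4 + [0.1] * 4},
                           index=[f"c{i}" for i in range(8)])
    return ccres, sites, fp, expr_df, groups


class TestIdentifyRegulators:
    def test_all_three_conditions_met(self):
        ccres, sites, fp, expr, groups = _toy_evidence()
        calls = identify_regulators("sel", "GA1_2", ccres, sites, fp, expr,
                                    groups)
        assert set(calls) == {"TFX"}
        call = calls["TFX"]
        assert call.ccre_ids == ("feat1",)
        assert call.min_link_p == pytest.approx(0.001)
        assert call.tf_mean_expression == pytest.approx(1.5)

    @pytest.mark.parametrize("kw,value", [
        ("conservation", 0.5),   # boundary: strict > 0.5
        ("score", 0.0),          # boundary: strict > 0
        ("expr", 1.2),           # boundary: strict > 1.2
    ])
    def test_boundary_values_excluded(self, kw, value):
        ccres, sites, fp, expr, groups = _toy_evidence(**{kw: value})
        assert identify_regulators("sel", "GA1_2", ccres, sites, fp, expr,
                                   groups) == {}

    def test_relaxing_any_threshold_is_monotone(self):
        ccres, sites, fp, expr, groups = _toy_evidence(conservation=0.4)
        strict = identify_regulators("sel", "GA1_2", ccres, sites, fp, expr,
                                     groups)
        relaxed = identify_regulators("sel", "GA1_2", ccres, sites, fp, expr,
                                      groups, conservation_min=None)
        assert set(strict) <= set(relaxed)
        assert set(relaxed) == {"TFX"}

    def test_tf_absent_from_expression_skipped(self):
        ccres, sites, fp, expr, groups = _toy_evidence()
        expr = expr.rename(columns={"TFX": "OTHER"})
        assert identify_regulators("sel", "GA1_2", ccres, sites, fp, expr,
                                   groups) == {}

    def test_zero_noise_bundle_recovers_planted_sets(self, bundle_noiseless,
                                                     linked_noiseless):
        b = bundle_noiseless
        all_links, tad_of = linked_noiseless
        for (gid, grp), truth in b.truth.regulator_sets.items():
            ccres = call_ccres(b.gene(gid), tad_of[gid], b.features,
                               all_links[gid])
            got = set(identify_regulators(gid, grp, ccres, b.sites,
                                          b.footprints, b.expression,
                                          b.groups))
            assert got == truth, (gid, grp)

    def test_dropping_expression_condition_gives_superset(self,
                                                          bundle_noiseless,
                                                          linked_noiseless):
        b = bundle_noiseless
        all_links, tad_of = linked_noiseless
        for (gid, grp) in b.truth.regulator_sets:
            ccres = call_ccres(b.gene(gid), tad_of[gid], b.features,
                               all_links[gid])
            base = set(identify_regulators(gid, grp, ccres, b.sites,
                                           b.footprints, b.expression,
                                           b.groups))
            no_expr = set(identify_regulators(gid, grp, ccres, b.sites,
                                              b.footprints, b.expression,
                                              b.groups, expression_min=None))
            assert base <= no_expr


class TestSummarizeCommonRegulators:
    def _calls(self, gene, tf_to_p):
        from crelink.regulators import RegulatorCall
        return {tf: RegulatorCall(gene, "GA1_2", tf, ("f",), ("s",), (0.8,),
                                  2.0, p)
                for tf, p in tf_to_p.items()}

    def test_identical_sets(self):
        per_gene = {g: self._calls(g, {"A": 0.01, "B": 0.02})
                    for g in ["g1", "g2", "g3"]}
        partition, summary = summarize_common_regulators(per_gene)
        assert partition[frozenset(["g1", "g2", "g3"])] == {"A", "B"}
        assert partition[frozenset(["g1"])] == set()
        assert set(summary["tf_name"]) == {"A", "B"}

    def test_disjoint_sets(self):
        per_gene = {"g1": self._calls("g1", {"A": 0.01}),
                    "g2": self._calls("g2", {"B": 0.01}),
                    "g3": self._calls("g3", {"C": 0.01})}
        partition, summary = summarize_common_regulators(per_gene)
        assert partition[frozenset(["g1", "g2", "g3"])] == set()
        assert partition[frozenset(["g1"])] == {"A"}
        assert summary.empty

    def test_significance_is_max_over_genes_of_min_link_p(self):
        per_gene = {
            "g1": self._calls("g1", {"A": 0.001, "B": 0.04}),
            "g2": self._calls("g2", {"A": 0.020, "B": 0.01}),
            "g3": self._calls("g3", {"A": 0.005, "B": 0.03}),
        }
        _, summary = summarize_common_regulators(per_gene)
        row_a = summary[summary["tf_name"] == "A"].iloc[0]
        # enumeration oracle: max over genes of (min over that gene's links)
        assert row_a["max_min_p"] == pytest.approx(
            max(0.001, 0.020, 0.005))
        row_b = summary[summary["tf_name"] == "B"].iloc[0]
        assert row_b["max_min_p"] == pytest.approx(max(0.04, 0.01, 0.03))


class TestPermutationOverlapTest:
    def test_saturated_sets_give_p_one(self):
        res = permutation_overlap_test(10, [10, 10, 10], 5, n_iterations=500,
                                       seed=0)
        assert res.p_value == 1.0
        assert not res.upper_bound

    def test_impossible_observation_rejected(self):
        with pytest.raises(ValueError):
            permutation_overlap_test(10, [3, 5, 7], 4, 100, seed=0)

    def test_small_universe_matches_exhaustive_enumeration(self):
        # universe of 6, three 2-subsets, P(intersection >= 1) by enumeration
        universe = range(6)
        triples = list(itertools.combinations(universe, 2))
        hits = total = 0
        for a in triples:
            for b in triples:
                for c in triples:
                    total += 1
                    hits += len(set(a) & set(b) & set(c)) >= 1
        exact = hits / total
        res = permutation_overlap_test(6, [2, 2, 2], 1, n_iterations=100_000,
                                       seed=3)
        se = np.sqrt(exact * (1 - exact) / res.n_iterations)
        assert abs(res.p_value - exact) <= 3 * se

    def test_p_monotone_in_observed(self):
        ps = [permutation_overlap_test(30, [10, 12, 14], k, 20_000, seed=5).p_value
              for k in range(0, 6)]
        assert ps == sorted(ps, reverse=True)

    def test_zero_exceedances_reports_upper_bound(self):
        res = permutation_overlap_test(1000, [5, 5, 5], 5, 2_000, seed=1)
        assert res.upper_bound
        assert res.p_value == pytest.approx(1 / 2_001)
        assert 0 < res.p_value <= 1
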