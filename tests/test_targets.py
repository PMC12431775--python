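"""Four-condition target calling, DE, classification, GSEA and marker matching."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from crelink.conservation import MotifSite
from crelink.genome_core import GeneModel, GenomicInterval, TadSet
from crelink.linkage import LinkRecord
from crelink.targets import (characterize_targets, classify_targets,
                             de_wilcoxon, distance_bin, gsea_two_edge,
                             identify_targets, marker_similarity,
                             rank_genes_for_gsea, target_expression_subset)


def _toy_world(*, peak=True, cons=0.7, z=2.5, p=0.005, bound_group="GA1_2"):
    genes = [GeneModel("g1", "chr1", 5_000)]
    tads = TadSet([GenomicInterval("chr1", 0, 50_000, "tad")])
    features = {"f1": GenomicInterval("chr1", 8_000, 8_500, "f1")}
    links = {"g1": [LinkRecord("f1", "g1", 0.8, z, p)]}
    sites = [MotifSite("s1", "T.M1", "T", GenomicInterval("chr1", 8_100, 8_110),
                       "+", "f1", cons)]
    fp = pd.DataFrame({"site_id": ["s1"], "cell_group": [bound_group],
                       "footprint_score": [0.4]})
    peaks = {"T": [GenomicInterval("chr1", 8_200, 8_400, "pk")] if peak else []}
    return genes, tads, links, features, sites, fp, peaks


class TestIdentifyTargets:
    def test_all_four_conditions_met(self):
        genes, tads, links, features, sites, fp, peaks = _toy_world()
        calls = identify_targets("T", genes, tads, links, features, sites,
                                 fp, peaks)
        assert [c.gene_id for c in calls] == ["g1"]
        feat = calls[0].features[0]
        assert feat.sign == "+"
        assert feat.peak_id == "pk"
        assert calls[0].nearest_distance == 3_000
        assert calls[0].distance_bin == "0-5"

    @pytest.mark.parametrize("kw", [
        {"peak": False},
        {"cons": 0.5},
        {"p": 0.02},
        {"z": 2.0},
        {"bound_group": "GA3_4"},  # not an early-precursor group
    ])
    def test_failing_any_condition_drops_the_call(self, kw):
        genes, tads, links, features, sites, fp, peaks = _toy_world(**kw)
        if not peaks["T"]:
            peaks = {}
            with pytest.raises(KeyError):
                identify_targets("T", genes, tads, links, features, sites,
                                 fp, peaks)
            return
        assert identify_targets("T", genes, tads, links, features, sites,
                                fp, peaks) == []

    def test_zero_noise_bundle_recovers_planted_targets(self, bundle_noiseless,
                                                        linked_noiseless):
        b = bundle_noiseless
        all_links, _ = linked_noiseless
        for tf, truth in b.truth.target_sets.items():
            got = {c.gene_id for c in identify_targets(
                tf, b.genes, b.tads, all_links, b.features, b.sites,
                b.footprints, b.peaks)}
            assert got == truth, tf

    def test_disabling_any_condition_yields_superset(self, bundle_default,
                                                     linked_default):
        b = bundle_default
        all_links, _ = linked_default
        for tf in b.truth.target_sets:
            base = {c.gene_id for c in identify_targets(
                tf, b.genes, b.tads, all_links, b.features, b.sites,
                b.footprints, b.peaks)}
            for relax in ({"require_peak": False}, {"require_footprint": False},
                          {"conservation_min": None},
                          {"z_min": None, "p_max": None}):
                relaxed = {c.gene_id for c in identify_targets(
                    tf, b.genes, b.tads, all_links, b.features, b.sites,
                    b.footprints, b.peaks, **relax)}
                assert base <= relaxed, (tf, relax)


def rank_sum_enumeration_oracle(a, b):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pool = list(a) + list(b)
    n1, n2 = len(a), len(b)

    def ustat(group_a):
        rest = list(pool)
        for x in group_a:
            rest.remove(x)
        return sum((x > y) + 0.5 * (x == y) for x in group_a for y in rest)

    u_obs = ustat(list(a))
    m_obs = min(u_obs, n1 * n2 - u_obs)
    cnt = tot = 0
    for combo in itertools.combinations(range(len(pool)), n1):
        u = ustat([pool[i] for i in combo])
        tot += 1
        cnt += min(u, n1 * n2 - u) <= m_obs + 1e-9
    return cnt / tot


class TestDeWilcoxon:
    def _expr(self, a_vals, b_vals):
        cells = [f"a{i}" for i in range(len(a_vals))] + \
                [f"b{i}" for i in range(len(b_vals))]
        return (pd.DataFrame({"g": list(a_vals) + list(b_vals)}, index=cells),
                [f"a{i}" for i in range(len(a_vals))],
                [f"b{i}" for i in range(len(b_vals))])

    def test_identical_groups(self):
        expr, ca, cb = self._expr([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        (rec,) = de_wilcoxon(expr, ca, cb)
        assert rec.log2fc == pytest.approx(0.0)
        assert rec.p == pytest.approx(1.0)

    def test_one_sided_expression(self):
        expr, ca, cb = self._expr([1.0, 1.5, 2.0], [0.0, 0.0, 0.0])
        (rec,) = de_wilcoxon(expr, ca, cb)
        assert rec.frac_b == 0.0
        assert rec.log2fc > 0

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, 11.0))
        a, b = vals[:5], vals[5:]
        expr, ca, cb = self._expr(a, b)
        (rec,) = de_wilcoxon(expr, ca, cb)
        assert rec.p == pytest.approx(rank_sum_enumeration_oracle(a, b),
                                      abs=1e-9)

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(1)
        cells = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        expr = pd.DataFrame(rng.random((10, 6)), index=cells,
                            columns=[f"g{i}" for i in range(6)])
        for rec in de_wilcoxon(expr, cells[:5], cells[5:]):
            assert rec.p_adj >= rec.p

    def test_empty_group_rejected(self):
        expr, ca, cb = self._expr([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            de_wilcoxon(expr, ca, [])


class TestClassifyTargets:
    def _target(self, gene):
        from crelink.targets import TargetCall
        return TargetCall("T", gene, (), 1000, "0-5")

    def _de(self, gene, log2fc):
        from crelink.targets import DeRecord
        return {gene: DeRecord(gene, log2fc, 0.001, 0.001, 0.9, 0.1)}

    def test_gaba_specific(self):
        (out,) = classify_targets([self._target("g")], self._de("g", 0.8),
                                  {"g": 0.9}, {"g": 0.2})
        assert out.label == "GABA-specific"

    def test_glut_specific(self):
        (out,) = classify_targets([self._target("g")], self._de("g", -0.8),
                                  {"g": 0.2}, {"g": 0.9})
        assert out.label == "glut-specific"

    def test_ambiguous_unclassified(self):
        (out,) = classify_targets([self._target("g")], self._de("g", 0.0),
                                  {"g": 0.6}, {"g": 0.6})
        assert out.label == "unclassified"


class TestCharacterizeTargets:
    def test_distance_bins_half_open(self):
        assert distance_bin(3_000) == "0-5"
        assert distance_bin(5_000) == "5-50"
        assert distance_bin(50_000) == ">50"
        assert distance_bin(49_999) == "5-50"

    def test_bin_counts_sum_to_total(self, bundle_noiseless, linked_noiseless):
        b = bundle_noiseless
        all_links, _ = linked_noiseless
        tf = next(iter(b.truth.target_sets))
        calls = identify_targets(tf, b.genes, b.tads, all_links, b.features,
                                 b.sites, b.footprints, b.peaks)
        if not calls:
            pytest.skip("no targets for this TF")
        tables = characterize_targets(calls)
        assert tables["distance_bins"]["n_genes"].sum() == len(calls)

    def test_variability_is_sd_of_group_means(self):
        from crelink.targets import TargetCall
        calls = [TargetCall("T", "g", (), 1_000, "0-5")]
        group_means = pd.DataFrame({"g": [1.0, 2.0, 3.0]},
                                   index=["A", "B", "C"])
        tables = characterize_targets(calls, group_means)
        # hand oracle: sd of (1, 2, 3) with ddof=1 is 1.0
        assert tables["variability"]["variability"].iloc[0] == pytest.approx(1.0)


class TestTargetExpressionSubset:
    def _t(self, gene):
        from crelink.targets import TargetCall
        return TargetCall("T", gene, (), 0, "0-5")

    def test_or_rule_and_strict_threshold(self):
        targets = [self._t("kept"), self._t("boundary"), self._t("low")]
        ga = {"kept": 0.6, "boundary": 0.5, "low": 0.1}
        gl = {"kept": 0.1, "boundary": 0.5, "low": 0.2}
        assert target_expression_subset(targets, ga, gl) == ["kept"]

    def test_all_below_threshold(self):
        assert target_expression_subset([self._t("g")], {"g": 0.1},
                                        {"g": 0.1}) == []


class TestGseaTwoEdge:
    def test_hand_computed_running_sum(self):
        ranked = [f"g{i}" for i in range(1, 11)]
        res = gsea_two_edge(ranked, {"g2", "g5", "g9"})
        # hand oracle: hits +1/3, misses -1/7
        expect = np.array([-1 / 7, -1 / 7 + 1 / 3, 4 / 21 - 1 / 7, -2 / 21,
                           -2 / 21 + 1 / 3, 2 / 21, -1 / 21, -4 / 21,
                           -4 / 21 + 1 / 3, 0.0])
        np.testing.assert_allclose(res.running, expect, atol=1e-12)
        assert res.argmax == 4 and res.argmin == 7
        assert res.leading_edge_a == ("g2", "g5")
        assert res.leading_edge_b == ("g9",)
        assert abs(res.running[-1]) < 1e-9

    def test_top_k_set_gives_edge_a_equal_to_set(self):
        ranked = [f"g{i}" for i in range(20)]
        gene_set = set(ranked[:4])
        res = gsea_two_edge(ranked, gene_set)
        assert res.argmax == 3
        assert set(res.leading_edge_a) == gene_set

    def test_bottom_k_set_gives_edge_b_equal_to_set(self):
        ranked = [f"g{i}" for i in range(20)]
        gene_set = set(ranked[-4:])
        res = gsea_two_edge(ranked, gene_set)
        assert set(res.leading_edge_b) == gene_set

    def test_reversing_ranking_swaps_edges(self):
        # top-3 + bottom-3 set: the running-sum extremes are unique, so
        # reversal swaps the two edges exactly
        ranked = [f"g{i}" for i in range(30)]
        gene_set = set(ranked[:3]) | set(ranked[-3:])
        res = gsea_two_edge(ranked, gene_set)
        rev = gsea_two_edge(ranked[::-1], gene_set)
        assert set(res.leading_edge_a) == set(rev.leading_edge_b)
        assert set(res.leading_edge_b) == set(rev.leading_edge_a)
        # exact reversal identity of the running sum (holds with ties too)
        np.testing.assert_allclose(rev.running[:-1], -res.running[:-1][::-1],
                                   atol=1e-12)

    def test_degenerate_sets_rejected(self):
        ranked = ["a", "b", "c"]
        with pytest.raises(ValueError):
            gsea_two_edge(ranked, {"x"})
        with pytest.raises(ValueError):
            gsea_two_edge(ranked, {"a", "b", "c"})

    def test_planted_ga_targets_recovered_in_edge_a(self):
        """GA-elevated planted targets fall in the GA-side leading edge."""
        from crelink.pipeline import link_all
        from crelink.synthetic_data import SynthConfig, simulate_bundle

        b = simulate_bundle(SynthConfig(seed=21, link_patterns="ga_only"))
        all_links, _ = link_all(b, seed=22)
        cells_a = list(b.groups.cells_in("GA1_2"))
        cells_b = list(b.groups.cells_in("GL1_2"))
        de = de_wilcoxon(b.expression, cells_a, cells_b)
        ranking = rank_genes_for_gsea(de)
        recovered = total = 0
        for tf, truth in b.truth.target_sets.items():
            gene_set = set(truth) & set(ranking)
            if not gene_set or len(gene_set) == len(ranking):
                continue
            res = gsea_two_edge(ranking, gene_set)
            total += len(gene_set)
            recovered += len(set(res.leading_edge_a) & gene_set)
        assert total > 0
        assert recovered / total >= 0.9


def hypergeom_tail_oracle(k, n_universe, n_b, n_a):
    """P[X >= k] by exact rational enumeration."""
    total = Fraction(0)
    denom = comb(n_universe, n_a)
    for x in range(k, min(n_a, n_b) + 1):
        total += Fraction(comb(n_b, x) * comb(n_universe - n_b, n_a - x), denom)
    return float(total)


class TestMarkerSimilarity:
    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        mat = marker_similarity({"a": universe[:5]}, {"b": universe[10:15]},
                                universe)
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_saturated_universe(self):
        universe = [f"g{i}" for i in range(25)]
        mat = marker_similarity({"a": universe}, {"b": universe}, universe)
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(100)]
        a = list(rng.choice(universe, 25, replace=False))
        b = list(a[:10]) + [g for g in universe if g not in a][:15]
        mat = marker_similarity({"ca": a}, {"cb": b}, universe)
        k = len(set(a) & set(b))
        assert k == 10
        assert mat.loc["ca", "cb"] == pytest.approx(
            hypergeom_tail_oracle(k, 100, len(b), len(a)), abs=1e-12)

    def test_markers_outside_universe_dropped(self):
        universe = [f"g{i}" for i in range(20)]
        mat = marker_similarity({"a": universe[:5] + ["missing"]},
                                {"b": universe[:5]}, universe)
        assert mat.loc["a", "b"] == pytest.approx(
            hypergeom_tail_oracle(5, 20, 5, 5), abs=1e-12)
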