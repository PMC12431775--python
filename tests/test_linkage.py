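"""Spearman linking, background z-scores and cCRE calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crelink.genome_core import GeneModel, GenomicInterval
from crelink.linkage import (DegenerateVectorError, LinkRecord, call_ccres,
                             link_feature_gene, spearman_rho)


def rank_formula_oracle(x, y):
    """Spearman rho from the average-rank definition, independently."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


class TestSpearmanRho:
    def test_perfect_monotone(self):
        x = [1.0, 2.5, 7.0, 9.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_tied_values_match_rank_formula(self):
        x, y = (1, 2, 2, 4), (1, 3, 2, 4)
        expect = rank_formula_oracle(x, y)  # = 4.5 / sqrt(22.5)
        assert expect == pytest.approx(0.9486832980505138)
        assert spearman_rho(x, y) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_vectors_match_rank_formula(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 20).astype(float)  # plenty of ties
        y = rng.normal(size=20)
        assert spearman_rho(x, y) == pytest.approx(rank_formula_oracle(x, y),
                                                   abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x, y = rng.random(30), rng.random(30)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(3 * x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, y ** 3 + 5) == pytest.approx(base, abs=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateVectorError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


def _toy_matrices(n_cells=40, n_features=60, seed=0):
    rng = np.random.default_rng(seed)
    cells = [f"c{i}" for i in range(n_cells)]
    feats = [f"f{i}" for i in range(n_features)]
    acc = pd.DataFrame(rng.random((n_cells, n_features)), index=cells,
                       columns=feats)
    expr = pd.DataFrame({"g": acc["f0"] + 0.1 * rng.normal(size=n_cells)},
                        index=cells)
    return acc, expr


class TestLinkFeatureGene:
    def test_standardization_identity(self):
        acc, expr = _toy_matrices()
        bg = [f"f{i}" for i in range(1, 56)]
        rec = link_feature_gene("f0", "g", acc, expr, bg)
        # recompute z from the definition
        rhos = np.array([spearman_rho(acc[b], expr["g"]) for b in bg])
        obs = spearman_rho(acc["f0"], expr["g"])
        expect_z = (obs - rhos.mean()) / rhos.std(ddof=1)
        assert rec.rho == pytest.approx(obs, abs=1e-12)
        assert rec.z == pytest.approx(expect_z, abs=1e-9)
        assert rec.p == pytest.approx(2 * stats.norm.sf(abs(expect_z)), abs=1e-12)
        assert rec.sign == ("+" if rec.z >= 0 else "-")

    def test_constant_feature_raises(self):
        acc, expr = _toy_matrices()
        acc["f0"] = 1.0
        with pytest.raises(DegenerateVectorError):
            link_feature_gene("f0", "g", acc, expr,
                              [f"f{i}" for i in range(1, 56)])

    def test_too_few_background_rejected(self):
        acc, expr = _toy_matrices()
        with pytest.raises(ValueError):
            link_feature_gene("f0", "g", acc, expr, ["f1"] * 10)

    def test_negating_expression_flips_z(self):
        acc, expr = _toy_matrices(seed=3)
        bg = [f"f{i}" for i in range(1, 56)]
        rec = link_feature_gene("f0", "g", acc, expr, bg)
        rec_neg = link_feature_gene("f0", "g", acc, -expr + 2.0, bg)
        assert np.sign(rec_neg.z) == -np.sign(rec.z)
        assert abs(rec_neg.z) == pytest.approx(abs(rec.z), rel=0.15)


class TestCallCcres:
    gene = GeneModel("g", "chr1", 5_000)
    tad = GenomicInterval("chr1", 0, 10_000, "tad")
    features = {
        "in": GenomicInterval("chr1", 1_000, 1_500, "in"),
        "out": GenomicInterval("chr1", 20_000, 20_500, "out"),
    }

    def _link(self, fid, z, p):
        return LinkRecord(fid, "g", 0.5, z, p)

    def test_passing_link_retained(self):
        kept = call_ccres(self.gene, self.tad, self.features,
                          [self._link("in", 2.1, 0.03)])
        assert [ln.feature_id for ln in kept] == ["in"]

    def test_thresholds_are_strict(self):
        assert call_ccres(self.gene, self.tad, self.features,
                          [self._link("in", 2.0, 0.001)]) == []
        assert call_ccres(self.gene, self.tad, self.features,
                          [self._link("in", 1.9, 0.001)]) == []
        assert call_ccres(self.gene, self.tad, self.features,
                          [self._link("in", 3.0, 0.05)]) == []

    def test_feature_outside_tad_excluded(self):
        assert call_ccres(self.gene, self.tad, self.features,
                          [self._link("out", 3.0, 0.01)]) == []

    def test_gene_without_tad_yields_empty(self, caplog):
        assert call_ccres(self.gene, None, self.features,
                          [self._link("in", 3.0, 0.01)]) == []


class TestRecoveryOnBundles:
    def test_zero_noise_planted_link_is_called(self, bundle_noiseless,
                                               linked_noiseless):
        all_links, _ = linked_noiseless
        planted = {(ln.feature_id, ln.gene_id) for ln in
                   bundle_noiseless.truth.links}
        by_pair = {(ln.feature_id, ln.gene_id): ln
                   for lns in all_links.values() for ln in lns}
        for pair in planted:
            rec = by_pair[pair]
            assert abs(rec.z) > 2 and rec.p < 0.05

    def test_zero_noise_single_positive_link_rho_is_one(self, bundle_noiseless):
        ln = next(ln for ln in bundle_noiseless.truth.links if ln.sign == "+")
        acc = bundle_noiseless.accessibility[ln.feature_id]
        # pick a gene with exactly one planted link for the exact-rho check
        from collections import Counter
        counts = Counter(l.gene_id for l in bundle_noiseless.truth.links)
        singles = [l for l in bundle_noiseless.truth.links
                   if counts[l.gene_id] == 1 and l.sign == "+"]
        if not singles:
            pytest.skip("no single-link gene in this bundle")
        ln = singles[0]
        rho = spearman_rho(bundle_noiseless.accessibility[ln.feature_id],
                           bundle_noiseless.expression[ln.gene_id])
        assert rho == pytest.approx(1.0)

    def test_default_noise_recovery_and_fpr(self, bundle_default,
                                            linked_default):
        all_links, _ = linked_default
        planted = {(ln.feature_id, ln.gene_id) for ln in
                   bundle_default.truth.links}
        rec = tot = fp = fptot = 0
        for lns in all_links.values():
            for ln in lns:
                called = abs(ln.z) > 2 and ln.p < 0.05
                if (ln.feature_id, ln.gene_id) in planted:
                    tot += 1
                    rec += called
                else:
                    fptot += 1
                    fp += called
        assert rec / tot >= 0.9
        assert fp / fptot <= 0.10
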