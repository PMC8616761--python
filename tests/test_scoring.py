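"""ssGSEA running-sum scores, responder score, and score statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import prosubtype as ps
from prosubtype.containers import ValidationError
from prosubtype.scoring import groupwise_score_test


def brute_ssgsea(values: pd.Series, genes: set, weight: float) -> float:
    """Independent position-by-position enumeration of the running sum."""
    ordered = sorted(values.sort_index().items(), key=lambda kv: -kv[1])
    N = len(ordered)
    m = sum(1 for g, _ in ordered if g in genes)
    norm = sum((N - j) ** weight for j, (g, _) in enumerate(ordered) if g in genes)
    rs, total = 0.0, 0.0
    for j, (g, _) in enumerate(ordered):
        if g in genes:
            rs += (N - j) ** weight / norm
        else:
            rs -= 1.0 / (N - m)
        total += rs
    return total / N


class TestSsgsea:
    def test_top_gene_set_hand_value(self):
        vals = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("WXYZ"))
        score = ps.ssgsea(vals, ps.GeneSet("top", frozenset("W")), weight=0)
        # running sum 1, 2/3, 1/3, 0 -> integrated 2, scaled by 1/4
        assert score == pytest.approx(0.5, abs=1e-12)

    def test_bottom_gene_set_negated(self):
        vals = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("WXYZ"))
        up = ps.ssgsea(vals, ps.GeneSet("top", frozenset("W")), weight=0)
        dn = ps.ssgsea(vals, ps.GeneSet("bot", frozenset("Z")), weight=0)
        assert dn == pytest.approx(-up, abs=1e-12)

    @pytest.mark.parametrize("n", range(2, 9))
    @pytest.mark.parametrize("weight", [0.0, 0.75])
    def test_matches_brute_force_enumeration(self, n, weight):
        rng = np.random.default_rng(n)
        vals = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        genes = list(vals.index)
        for m in range(1, n):
            for combo in combinations(genes, m):
                gs = ps.GeneSet("s", frozenset(combo))
                assert ps.ssgsea(vals, gs, weight) == pytest.approx(
                    brute_ssgsea(vals, set(combo), weight), abs=1e-12
                )

    def test_monotone_transform_invariance_at_weight_zero(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        gs = ps.GeneSet("s", frozenset(vals.index[:7]))
        transformed = np.exp(vals) + 3.0  # strictly increasing
        assert ps.ssgsea(vals, gs, weight=0) == pytest.approx(
            ps.ssgsea(transformed, gs, weight=0), abs=1e-12
        )
        # at weight 0.75 only the sign is guaranteed
        assert np.sign(ps.ssgsea(vals, gs, 0.75)) == np.sign(ps.ssgsea(transformed, gs, 0.75))

    def test_set_and_complement_cancel_at_weight_zero(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.normal(size=12), index=[f"g{i}" for i in range(12)])
        sub = frozenset(list(vals.index)[2:7])
        comp = frozenset(vals.index) - sub
        s1 = ps.ssgsea(vals, ps.GeneSet("a", sub), weight=0)
        s2 = ps.ssgsea(vals, ps.GeneSet("b", comp), weight=0)
        assert s1 + s2 == pytest.approx(0.0, abs=1e-12)

    def test_empty_or_full_set_errors(self):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValidationError):
            ps.ssgsea(vals, ps.GeneSet("none", frozenset(["zz"])))
        with pytest.raises(ValidationError):
            ps.ssgsea(vals, ps.GeneSet("all", frozenset(["a", "b"])))


class TestDocetaxelScore:
    def _expr(self, n_genes=40, n_samples=12, seed=0):
        rng = np.random.default_rng(seed)
        return ps.ExpressionMatrix(
            pd.DataFrame(
                rng.lognormal(1, 1, size=(n_genes, n_samples)),
                index=[f"g{i:02d}" for i in range(n_genes)],
                columns=[f"s{i}" for i in range(n_samples)],
            )
        )

    def test_overlapping_sets_error(self):
        expr = self._expr()
        gs = ps.GeneSet("x", frozenset(["g00", "g01"]))
        with pytest.raises(ValidationError, match="disjoint"):
            ps.docetaxel_score(expr, gs, gs)

    def test_swapping_sets_negates_raw_scores(self):
        expr = self._expr()
        up = ps.GeneSet("up", frozenset([f"g{i:02d}" for i in range(5)]), "up")
        dn = ps.GeneSet("dn", frozenset([f"g{i:02d}" for i in range(5, 15)]), "down")
        a = ps.docetaxel_score(expr, up, dn).raw_scores.iloc[:, 0]
        b = ps.docetaxel_score(expr, dn, up).raw_scores.iloc[:, 0]
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_extremal_ranks_maximize_raw_score(self):
        # one sample puts up-genes at the very top and down-genes at the very
        # bottom; its raw score must beat 100 random samples
        rng = np.random.default_rng(3)
        genes = [f"g{i:02d}" for i in range(30)]
        up = ps.GeneSet("up", frozenset(genes[:4]), "up")
        dn = ps.GeneSet("dn", frozenset(genes[-6:]), "down")
        extremal = pd.Series(np.arange(30, 0, -1, dtype=float), index=genes)
        cols = {"extremal": extremal}
        for i in range(100):
            cols[f"r{i}"] = pd.Series(rng.permutation(extremal.to_numpy()), index=genes)
        expr = ps.ExpressionMatrix(pd.DataFrame(cols))
        raw = ps.docetaxel_score(expr, up, dn).raw_scores["docetaxel_responder"]
        assert raw.idxmax() == "extremal"

    def test_z_normalization_moments(self):
        expr = self._expr(seed=5)
        up = ps.GeneSet("up", frozenset([f"g{i:02d}" for i in range(6)]), "up")
        dn = ps.GeneSet("dn", frozenset([f"g{i:02d}" for i in range(6, 12)]), "down")
        z = ps.docetaxel_score(expr, up, dn).scores.iloc[:, 0]
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9


class TestCorrelationSet:
    def _expr_and_sens(self):
        rng = np.random.default_rng(7)
        sens = pd.Series(rng.random(10), index=[f"s{i}" for i in range(10)])
        data = pd.DataFrame(
            rng.lognormal(0, 1, size=(5, 10)), index=[f"g{i}" for i in range(5)],
            columns=sens.index,
        )
        data.loc["g0"] = sens.to_numpy()  # r = 1
        data.loc["g1"] = (1.0 - sens).to_numpy()  # r = -1
        data.loc["g2"] = 5.0  # zero variance
        return ps.ExpressionMatrix(data), sens

    def test_perfect_correlation_included_negative_excluded(self):
        expr, sens = self._expr_and_sens()
        gs = ps.build_correlation_set(expr, sens)
        assert "g0" in gs.genes
        assert "g1" not in gs.genes
        assert "g2" not in gs.genes  # skipped, undefined r

    def test_threshold_is_strict(self):
        expr, sens = self._expr_and_sens()
        from scipy.stats import pearsonr

        r_g3 = pearsonr(expr.data.loc["g3"], sens).statistic
        gs = ps.build_correlation_set(expr, sens, r_threshold=r_g3)
        assert "g3" not in gs.genes  # r > r is false at equality


class TestScorePECorrelation:
    def _calls(self, pe_frame):
        return [
            ps.SubtypeCall(s, row / row.sum(), 0.01, "A")
            for s, row in pe_frame.iterrows()
        ]

    def test_score_identical_to_pe_gives_r_one(self):
        rng = np.random.default_rng(0)
        pe = pd.DataFrame(
            rng.dirichlet([1] * 4, size=10), index=[f"s{i}" for i in range(10)],
            columns=list("ABCD"),
        )
        raw = pe[["A"]].rename(columns={"A": "score1"})
        panel = ps.ScorePanel(raw_scores=raw, scores=ps.z_normalize(raw))
        tab = ps.score_pe_correlation(panel, self._calls(pe))
        rA = tab.query("score == 'score1' and cluster == 'A'")["spearman_r"].iloc[0]
        assert rA == pytest.approx(1.0)

    def test_constant_score_reported_missing(self):
        pe = pd.DataFrame(
            np.full((6, 2), 0.5), index=[f"s{i}" for i in range(6)], columns=list("AB")
        )
        raw = pd.DataFrame({"flat": np.ones(6)}, index=pe.index)
        panel = ps.ScorePanel(raw_scores=raw, scores=raw * np.nan)
        tab = ps.score_pe_correlation(panel, self._calls(pe))
        assert tab["spearman_r"].isna().all()

    def test_too_few_shared_samples_is_error(self):
        pe = pd.DataFrame(np.full((3, 2), 0.5), index=["a", "b", "c"], columns=list("AB"))
        raw = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=pe.index)
        panel = ps.ScorePanel(raw_scores=raw, scores=ps.z_normalize(raw))
        with pytest.raises(ValidationError, match="shared samples"):
            ps.score_pe_correlation(panel, self._calls(pe))


class TestGroupwiseTest:
    def test_null_omnibus_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(300):
            scores = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
            labels = pd.Series(["a"] * 20 + ["b"] * 20, index=scores.index)
            pvals.append(groupwise_score_test(scores, labels)["kruskal_p"])
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(
            np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)]),
            index=[f"s{i}" for i in range(60)],
        )
        labels = pd.Series(["a"] * 30 + ["b"] * 30, index=scores.index)
        out = groupwise_score_test(scores, labels)
        assert out["kruskal_p"] < 0.001
        assert (out["pairwise"]["p_adj"] < 0.001).all()

    def test_identical_constants_give_p_one(self):
        scores = pd.Series(np.ones(10), index=[f"s{i}" for i in range(10)])
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=scores.index)
        out = groupwise_score_test(scores, labels)
        assert out["kruskal_p"] == 1.0
        assert (out["pairwise"]["p_adj"] == 1.0).all()

    def test_single_group_is_error(self):
        scores = pd.Series(np.arange(4.0), index=list("abcd"))
        labels = pd.Series(["x"] * 4, index=scores.index)
        with pytest.raises(ValidationError):
            groupwise_score_test(scores, labels)
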