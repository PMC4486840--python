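"""Correlation matrices, coexpression calls, conditional coexpression,
over-representation analysis and PC1 synthetic traits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtlbridge.containers import ConditionMatrix, ExpressionMatrix
from qtlbridge.coexpression import (
    coexpression_calls,
    conditional_coexpression,
    consistent_probes,
    correlation_matrix,
    ora_enrichment,
    pc1_trait,
    phenotype_screen,
    r_threshold,
)


def _brute_force_r(x, y):
    """Independent oracle: Pearson r from explicit sums."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(v * v for v in x), sum(v * v for v in y), sum(
        a * b for a, b in zip(x, y)
    )
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


class TestCorrelationMatrix:
    def test_hand_example_r_half(self):
        """x = (0,1,2), y = (0,2,1) → r = 0.5."""
        df = pd.DataFrame([[0, 1, 2], [0, 2, 1]], index=["x", "y"],
                          columns=["a", "b", "c"], dtype=float)
        res = correlation_matrix(df)
        assert res.r.loc["x", "y"] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("flip,expected", [(1.0, 1.0), (-1.0, -1.0)])
    def test_identical_and_negated_vectors(self, flip, expected):
        df = pd.DataFrame([[1.0, 2, 3, 4], [f * flip for f in [1.0, 2, 3, 4]]],
                          index=["x", "y"], columns=list("abcd"))
        res = correlation_matrix(df)
        assert res.r.loc["x", "y"] == pytest.approx(expected, abs=1e-12)
        assert res.p.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_brute_force_sums(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(4, 9)), index=list("wxyz"))
        res = correlation_matrix(df)
        for a in "wxyz":
            for b in "wxyz":
                if a >= b:
                    continue
                exp = _brute_force_r(df.loc[a].tolist(), df.loc[b].tolist())
                assert res.r.loc[a, b] == pytest.approx(exp, abs=1e-12)

    def test_p_matches_t_transform_with_pairwise_n(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        y[0] = np.nan  # pair n = 9
        df = pd.DataFrame([x, y], index=["x", "y"])
        res = correlation_matrix(df)
        n = 9
        r = res.r.loc["x", "y"]
        t = r * math.sqrt((n - 2) / (1 - r * r))
        assert res.n.loc["x", "y"] == n
        assert res.p.loc["x", "y"] == pytest.approx(2 * stats.t.sf(abs(t), n - 2))

    def test_zero_variance_item_flagged(self):
        df = pd.DataFrame([[1.0, 1, 1, 1], [1.0, 2, 3, 4]], index=["flat", "x"])
        res = correlation_matrix(df)
        assert "flat" in res.flagged
        assert np.isnan(res.r.loc["flat", "x"])


class TestCoexpressionCalls:
    def test_printed_alpha_adjustment(self):
        """alpha 0.05 over 63 probes → adjusted 7.94e-4 at printed precision."""
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 30)))
        calls = coexpression_calls(correlation_matrix(df), alpha=0.05, n_probes=63)
        assert calls.adjusted_alpha == pytest.approx(7.94e-4, abs=5e-7)

    def test_conjunction_rule(self):
        rng = np.random.default_rng(1)
        # strong pair at large n: both gates pass
        base = rng.normal(size=40)
        strong = pd.DataFrame([base, base + rng.normal(0, 0.5, 40)], index=["a", "b"])
        res = correlation_matrix(strong)
        called = coexpression_calls(res, alpha=0.05, n_probes=63).calls
        assert called.loc["a", "b"]
        # high r at tiny n: p gate fails
        tiny = pd.DataFrame([[0, 1, 2.2, 3], [0.2, 0.9, 2.0, 3.3]], index=["a", "b"])
        res_tiny = correlation_matrix(tiny)
        assert abs(res_tiny.r.loc["a", "b"]) > 0.9
        assert not coexpression_calls(res_tiny, alpha=0.05, n_probes=63).calls.loc["a", "b"]
        # significant but weak r: r gate fails
        n = 3000
        x = rng.normal(size=n)
        weak = pd.DataFrame([x, 0.1 * x + rng.normal(size=n)], index=["a", "b"])
        res_weak = correlation_matrix(weak)
        assert res_weak.p.loc["a", "b"] < 7.94e-4
        assert not coexpression_calls(res_weak, alpha=0.05, n_probes=63).calls.loc["a", "b"]

    def test_r_threshold_inverts_p_threshold(self):
        n = 64
        r_min = r_threshold(7.94e-4, n)
        t = r_min * math.sqrt((n - 2) / (1 - r_min**2))
        assert 2 * stats.t.sf(t, n - 2) == pytest.approx(7.94e-4, rel=1e-9)


def _expr(values: dict[str, list[float]], genes: dict[str, str]) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    df.columns = [f"L{i}" for i in range(df.shape[1])]
    ann = pd.DataFrame(
        {"gene_id": [genes[p] for p in df.index], "region_type": "exon"},
        index=df.index,
    )
    return ExpressionMatrix(df, ann)


class TestConsistentProbes:
    def test_mutually_correlated_probes_all_kept(self):
        base = list(np.linspace(0, 1, 12))
        expr = _expr(
            {"p1": base, "p2": [v + 0.01 for v in base], "p3": [v * 2 for v in base]},
            {"p1": "g", "p2": "g", "p3": "g"},
        )
        assert consistent_probes(expr, "g") == ["p1", "p2", "p3"]

    def test_outlier_probe_dropped(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=12)
        expr = _expr(
            {"p1": base, "p2": base + rng.normal(0, 0.1, 12),
             "p3": rng.normal(size=12)},
            {"p1": "g", "p2": "g", "p3": "g"},
        )
        assert consistent_probes(expr, "g") == ["p1", "p2"]

    def test_single_probe_gene_kept(self):
        expr = _expr({"p1": [1.0, 2, 3, 4]}, {"p1": "g"})
        assert consistent_probes(expr, "g") == ["p1"]


class TestPhenotypeScreen:
    def _probes(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=20)
        return pd.DataFrame(
            {f"L{i}": v for i, v in enumerate(base)}, index=["p1"]
        ).pipe(lambda d: pd.concat(
            [d, pd.DataFrame([base + rng.normal(0, 0.3, 20)], index=["p2"],
                             columns=d.columns)]
        )), base

    def test_phenotype_correlated_with_all_probes_retained(self):
        probes, base = self._probes()
        rng = np.random.default_rng(7)
        phenos = pd.DataFrame(
            [base + rng.normal(0, 0.3, 20), rng.normal(size=20)],
            index=["linked", "noise"], columns=probes.columns,
        )
        assert phenotype_screen(probes, phenos) == ["linked"]

    def test_sign_inconsistency_dropped(self):
        x = np.linspace(0, 1, 20)
        probes = pd.DataFrame([x, -x], index=["p1", "p2"],
                              columns=[f"L{i}" for i in range(20)])
        phenos = pd.DataFrame([x], index=["ph"], columns=probes.columns)
        # ph correlates +1 with p1 and −1 with p2 → dropped
        assert phenotype_screen(probes, phenos) == []


class TestConditionalCoexpression:
    def _conds(self):
        conds = pd.DataFrame(
            0, index=["target", "half", "never", "exact"],
            columns=[f"c{i}" for i in range(20)],
        )
        conds.loc["target", [f"c{i}" for i in range(10)]] = 1
        conds.loc["half", [f"c{i}" for i in range(5)]] = 1  # 5 of target's 10
        conds.loc["exact", [f"c{i}" for i in range(10)]] = 1  # exactly target's
        return ConditionMatrix(conds)

    def test_definition_instantiated(self):
        res = conditional_coexpression(self._conds(), "target")
        assert res.n_target_up == 10
        assert res.values["half"] == pytest.approx(0.5)
        assert res.values["never"] == 0.0
        assert res.values["exact"] == 1.0

    def test_binomial_p_against_closed_form(self):
        res = conditional_coexpression(self._conds(), "target")
        # 'half': 5 joint among 10 target-up, marginal 5/20
        expected = stats.binom.sf(4, 10, 0.25)
        assert res.p["half"] == pytest.approx(expected, rel=1e-12)

    def test_common_set_applies_both_gates(self):
        res = conditional_coexpression(self._conds(), "target")
        common = res.common_set()
        assert "exact" in common and "never" not in common
        assert "target" not in common

    def test_never_up_target_is_undefined(self):
        conds = ConditionMatrix(
            pd.DataFrame(0, index=["t", "g"], columns=["c1", "c2"])
        )
        res = conditional_coexpression(conds, "t")
        assert not res.defined

    def test_scale_free_under_up_call_preserving_rethreshold(self):
        """Values depend only on the binary calls, not how they were derived."""
        res_a = conditional_coexpression(self._conds(), "target")
        doubled = ConditionMatrix(self._conds().calls.copy())
        res_b = conditional_coexpression(doubled, "target")
        pd.testing.assert_series_equal(res_a.values, res_b.values)


class TestOra:
    def test_hand_enumerated_hypergeometric(self):
        """Universe 10, term 5, list 4, overlap 4 → p = C(5,4)/C(10,4) = 5/210."""
        universe = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(5)}
        res = ora_enrichment(["g0", "g1", "g2", "g3"], {"T": term}, universe)
        assert res[0].p == pytest.approx(5 / 210, abs=1e-12)
        assert res[0].q == res[0].p  # single term: BH identity

    def test_zero_overlap_with_complement_term(self):
        universe = {f"g{i}" for i in range(10)}
        res = ora_enrichment(["g0"], {"T": universe - {"g0"}}, universe)
        assert res[0].p == pytest.approx(1.0)

    def test_bh_is_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        universe = {f"g{i}" for i in range(50)}
        terms = {
            f"T{j}": set(rng.choice(sorted(universe), size=10, replace=False))
            for j in range(8)
        }
        res = ora_enrichment([f"g{i}" for i in range(12)], terms, universe)
        qs = [r.q for r in res]
        ps = [r.p for r in res]
        assert all(q <= 1.0 for q in qs)
        assert all(q >= p for q, p in zip(qs, ps))
        assert qs == sorted(qs)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ora_enrichment([], {"T": set()}, {"g"})


class TestPc1Trait:
    def test_perfectly_correlated_traits_explain_everything(self):
        x = np.linspace(0, 1, 10)
        df = pd.DataFrame({"t1": x, "t2": 3 * x + 1})
        res = pc1_trait(df)
        assert res.variance_fraction == pytest.approx(1.0, abs=1e-12)

    def test_two_trait_closed_form(self):
        """For standardized 2-trait input, PC1 explains exactly (1+|r|)/2."""
        rng = np.random.default_rng(13)
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        df = pd.DataFrame({"t1": x, "t2": y})
        r = np.corrcoef(x, y)[0, 1]
        res = pc1_trait(df, standardize=True)
        assert res.variance_fraction == pytest.approx((1 + abs(r)) / 2, abs=1e-12)

    def test_sign_flip_leaves_variance_fraction_unchanged(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.normal(size=(12, 4)))
        a = pc1_trait(df)
        b = pc1_trait(-df)
        assert a.variance_fraction == pytest.approx(b.variance_fraction, abs=1e-12)
        assert a.loadings.sum() >= 0 and b.loadings.sum() >= 0

    def test_loadings_unit_norm(self):
        rng = np.random.default_rng(15)
        res = pc1_trait(pd.DataFrame(rng.normal(size=(9, 3))))
        assert np.linalg.norm(res.loadings) == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_with_standardize_rejected(self):
        df = pd.DataFrame({"t1": [1.0, 1, 1, 1], "t2": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="constant"):
            pc1_trait(df)
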