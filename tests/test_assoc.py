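"""Median split, Cox survival, rank tests, meta-correlation, GES."""

import numpy as np
import pandas as pd
import pytest

from methsig.assoc import (
    cox_survival,
    derive_ges,
    ges_fraction,
    group_compare,
    ici_multivariate,
    median_split,
    time_correlation,
    variance_attribution,
)


class TestMedianSplit:
    def test_even_split(self):
        out = median_split(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(out) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        out = median_split(pd.Series([1.0, 2.0, 2.0, 4.0]))
        assert list(out) == ["low", "low", "low", "high"]

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            median_split(pd.Series([5.0]))

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split(pd.Series([2.0, 2.0, 2.0]))


class TestCoxSurvival:
    def test_matches_partial_likelihood_grid_oracle(self):
        # 4 subjects, distinct event times, no censoring, binary group
        times = np.array([2.0, 5.0, 9.0, 14.0])
        events = np.array([1, 1, 1, 1])
        groups = pd.Series(["high", "low", "high", "low"])
        res = cox_survival(groups, times, events)

        x = (groups == "high").astype(float).to_numpy()
        order = np.argsort(times)

        def neg_log_pl(b):
            ll = 0.0
            risk = list(order)
            for i in order:
                ll += b * x[i] - np.log(
                    np.sum(np.exp(b * x[risk]))
                )
                risk.remove(i)
            return -ll

        grid = np.arange(-5, 5, 1e-4)
        best = grid[np.argmin([neg_log_pl(b) for b in grid])]
        assert res["coef"] == pytest.approx(best, abs=1e-3)

    def test_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(3)
        n = 500
        group = rng.random(n) < 0.5
        lam = 0.01 * np.where(group, 2.0, 1.0)
        t_event = rng.exponential(1 / lam)
        t_cens = rng.exponential(1 / (lam * 0.25))
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
        labels = pd.Series(np.where(group, "high", "low"))
        res = cox_survival(labels, times, events)
        assert 1.6 <= res["hr"] <= 2.5

    def test_null_labels_give_hr_near_one(self):
        covered = 0
        for rep in range(40):
            rng = np.random.default_rng(100 + rep)
            times = rng.exponential(100, size=120)
            events = np.ones(120, int)
            labels = pd.Series(
                np.where(rng.random(120) < 0.5, "high", "low")
            )
            res = cox_survival(labels, times, events)
            covered += res["ci_low"] <= 1.0 <= res["ci_high"]
        assert covered >= 36  # planted log-HR 0 inside the 95% CI

    def test_eventless_group_errors(self):
        with pytest.raises(ValueError, match="event"):
            cox_survival(
                pd.Series(["high", "low"]),
                np.array([5.0, 8.0]),
                np.array([1, 0]),
            )


class TestGroupCompare:
    def test_exact_small_sample(self):
        stat, p = group_compare(
            pd.Series([1, 2, 3, 4, 5, 6.0]),
            pd.Series(["a", "a", "a", "b", "b", "b"]),
        )
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        stat, p = group_compare(
            pd.Series([1.0, 1.0, 1.0, 1.0]),
            pd.Series(["a", "a", "b", "b"]),
        )
        assert p == pytest.approx(1.0)

    def test_exact_and_approximate_paths_agree(self):
        rng = np.random.default_rng(4)
        from scipy.stats import mannwhitneyu

        a = rng.normal(0, 1, 10)
        b = rng.normal(0.8, 1, 10)
        _, p_exact = mannwhitneyu(a, b, method="exact",
                                  alternative="two-sided")
        _, p_approx = mannwhitneyu(a, b, method="asymptotic",
                                   alternative="two-sided")
        assert abs(p_exact - p_approx) < 0.01

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_compare(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))


class TestTimeCorrelation:
    def _data(self, rs_by_type, ns_by_type, seed=0):
        rng = np.random.default_rng(seed)
        act, feat, ct = [], [], []
        for (c, r), n in zip(rs_by_type.items(), ns_by_type):
            z = rng.normal(size=n)
            act.append(z)
            feat.append(r * z + np.sqrt(1 - r**2) * rng.normal(size=n))
            ct += [c] * n
        idx = [f"S{i}" for i in range(sum(ns_by_type))]
        return (
            pd.Series(np.concatenate(act), index=idx),
            pd.DataFrame({"feat": np.concatenate(feat)}, index=idx),
            pd.Series(ct, index=idx),
        )

    def test_identical_strata_collapse(self):
        out = time_correlation(
            *self._data({"A": 0.5, "B": 0.5}, [200, 200], seed=1)
        )
        assert out["meta_r"].iloc[0] == pytest.approx(0.5, abs=0.1)

    def test_matches_fisher_z_oracle(self):
        act, feats, ct = self._data({"A": 0.5, "B": 0.3}, [103, 53], seed=2)
        out = time_correlation(act, feats, ct)
        from scipy.stats import spearmanr

        r_a = spearmanr(act[ct == "A"], feats["feat"][ct == "A"]).statistic
        r_b = spearmanr(act[ct == "B"], feats["feat"][ct == "B"]).statistic
        z = np.arctanh([r_a, r_b])
        w = np.array([100.0, 50.0])
        expected = np.tanh((w * z).sum() / w.sum())
        assert out["meta_r"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_constant_stratum_excluded_with_warning(self):
        act, feats, ct = self._data({"A": 0.5, "B": 0.3}, [50, 50], seed=3)
        feats.loc[ct == "B", "feat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            out = time_correlation(act, feats, ct)
        assert out["n_strata"].iloc[0] == 1
        assert out["single_stratum"].iloc[0]


class TestVarianceAttribution:
    def test_pure_between_group_structure(self):
        H = pd.DataFrame(
            [[1.0, 1.0, 5.0, 5.0]], index=["MS1"],
            columns=["a", "b", "c", "d"],
        )
        ct = pd.Series(["X", "X", "Y", "Y"], index=H.columns)
        assert variance_attribution(H, ct)["MS1"] == pytest.approx(1.0)

    def test_single_group_zero(self):
        H = pd.DataFrame([[1.0, 2.0, 3.0]], index=["MS1"],
                         columns=["a", "b", "c"])
        ct = pd.Series(["X", "X", "X"], index=H.columns)
        assert variance_attribution(H, ct)["MS1"] == 0.0

    def test_permuted_labels_match_null_expectation(self):
        # under random grouping E[R^2] = (g - 1) / (n - 1)
        rng = np.random.default_rng(5)
        n, g = 60, 3
        fracs = []
        for rep in range(200):
            H = pd.DataFrame(
                rng.normal(size=(1, n)), index=["MS1"],
                columns=[f"s{i}" for i in range(n)],
            )
            ct = pd.Series(
                rng.permutation(np.repeat(np.arange(g), n // g)),
                index=H.columns,
            )
            fracs.append(variance_attribution(H, ct)["MS1"])
        assert np.mean(fracs) == pytest.approx((g - 1) / (n - 1), abs=0.01)


class TestIciModel:
    def test_balanced_two_by_two_odds_ratio(self):
        # counts {{30,10},{10,30}}: cross-product OR = 9; constant TP53 and
        # FOXA1 columns are dropped so the model is single-predictor
        resp = ["responder"] * 30 + ["nonresponder"] * 10 \
            + ["responder"] * 10 + ["nonresponder"] * 30
        activity = [0.0] * 40 + [1.0] * 40
        with pytest.warns(UserWarning, match="constant"):
            out = ici_multivariate(
                pd.Series(resp), activity, np.zeros(80), np.zeros(80)
            )
        assert out.loc["activity", "odds_ratio"] == pytest.approx(
            1.0 / 9.0, rel=1e-4
        )

    def test_null_coefficients_give_or_near_one(self):
        rng = np.random.default_rng(6)
        n = 4000
        resp = pd.Series(
            np.where(rng.random(n) < 0.5, "responder", "nonresponder")
        )
        out = ici_multivariate(
            resp, rng.normal(size=n), (rng.random(n) < 0.4).astype(int),
            rng.normal(size=n),
        )
        ors = out.loc[["activity", "tp53_status", "foxa1_expr"], "odds_ratio"]
        assert np.allclose(ors, 1.0, atol=0.15)

    def test_planted_negative_activity_effect_recovered(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            n = 300
            z = rng.normal(size=n)
            tp53 = (rng.random(n) < 0.4).astype(int)
            foxa1 = rng.normal(size=n)
            lin = -0.3 * z + 0.0 * tp53 + 0.0 * foxa1
            resp = pd.Series(
                np.where(
                    rng.random(n) < 1 / (1 + np.exp(-lin)),
                    "responder",
                    "nonresponder",
                )
            )
            out = ici_multivariate(resp, z, tp53, foxa1)
            hits += out.loc["activity", "odds_ratio"] < 1.0
        assert hits >= 18

    def test_linear_probability_option(self):
        rng = np.random.default_rng(7)
        n = 500
        resp = pd.Series((rng.random(n) < 0.5).astype(int))
        out = ici_multivariate(
            resp, rng.normal(size=n), rng.integers(0, 2, n),
            rng.normal(size=n), model="linear",
        )
        assert "coef" in out.columns


class TestGES:
    def _expr(self, n_cells, n_genes, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n_cells, n_genes)),
            index=[f"c{i}" for i in range(n_cells)],
            columns=[f"g{j}" for j in range(n_genes)],
        )

    def test_perfect_predictor_ranked_first(self):
        expr = self._expr(100, 50, seed=1)
        act = expr["g7"].copy()
        model = derive_ges(expr, act, n_genes=1, seed=2)
        assert model["genes"][0] == "g7"
        assert model["auc"] == pytest.approx(1.0)

    def test_null_genes_give_chance_auc(self):
        aucs = []
        for rep in range(20):
            expr = self._expr(150, 60, seed=300 + rep)
            act = pd.Series(
                np.random.default_rng(900 + rep).normal(size=150),
                index=expr.index,
            )
            aucs.append(derive_ges(expr, act, n_genes=10, seed=rep)["auc"])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.08)

    def test_planted_signal_genes_recovered(self):
        rng = np.random.default_rng(11)
        n_cells, n_genes, n_signal = 300, 500, 50
        act = pd.Series(rng.normal(size=n_cells),
                        index=[f"c{i}" for i in range(n_cells)])
        expr = self._expr(n_cells, n_genes, seed=12)
        high = (act > act.median()).to_numpy()
        signal = [f"g{j}" for j in range(n_signal)]
        expr.loc[high, signal] += 1.0
        model = derive_ges(expr, act, n_genes=n_signal, seed=13)
        frac = len(set(model["genes"]) & set(signal)) / n_signal
        assert frac >= 0.8

    def test_score_invariant_to_affine_gene_rescaling(self):
        expr = self._expr(80, 30, seed=21)
        act = pd.Series(np.random.default_rng(22).normal(size=80),
                        index=expr.index)
        m1 = derive_ges(expr, act, n_genes=8, seed=3)
        scaled = expr * 7.0 + 3.0
        m2 = derive_ges(scaled, act, n_genes=8, seed=3)
        np.testing.assert_allclose(
            m1["score"](expr).to_numpy(), m2["score"](scaled).to_numpy(),
            atol=1e-10,
        )

    def test_too_many_genes_requested_errors(self):
        expr = self._expr(20, 5)
        with pytest.raises(ValueError):
            derive_ges(expr, expr["g0"], n_genes=10)


class TestGesFraction:
    def test_all_above_threshold(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0])
        out = ges_fraction(s, pd.Series(["a", "a", "b", "b"]), threshold=0.0)
        assert (out == 1.0).all()

    def test_median_threshold_splits_half(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0])
        out = ges_fraction(s, pd.Series(["g"] * 4))
        assert out["g"] == pytest.approx(0.5)

    def test_recovers_planted_group_fractions(self):
        rng = np.random.default_rng(31)
        scores = np.concatenate(
            [
                (rng.random(500) < 0.3).astype(float),
                (rng.random(500) < 0.7).astype(float),
            ]
        )
        # jitter so the 0.5 threshold separates cleanly
        scores += rng.normal(0, 0.01, 1000)
        groups = pd.Series(["lo"] * 500 + ["hi"] * 500)
        out = ges_fraction(pd.Series(scores), groups, threshold=0.5)
        assert out["lo"] == pytest.approx(0.3, abs=0.05)
        assert out["hi"] == pytest.approx(0.7, abs=0.05)


def test_order_invariance_of_tests():
    rng = np.random.default_rng(41)
    act = pd.Series(rng.normal(size=60), index=[f"s{i}" for i in range(60)])
    labels = pd.Series(
        np.where(rng.random(60) < 0.5, "a", "b"), index=act.index
    )
    stat1, p1 = group_compare(act, labels)
    perm = rng.permutation(60)
    stat2, p2 = group_compare(act.iloc[perm], labels.iloc[perm])
    assert p1 == pytest.approx(p2)
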