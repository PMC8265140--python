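"""Wagstaff decomposition: identity, contributions, groups."""

import numpy as np
import pandas as pd
import pytest

from healthineq import (
    concentration_index,
    fractional_rank,
    group_contributions,
    percentage_contributions,
    wagstaff_decompose,
)


def random_instance(rng, n=None):
    n = n or int(rng.integers(10, 60))
    y = (rng.random(n) < 0.4).astype(float)
    if y.sum() == 0:
        y[0] = 1.0
    k = int(rng.integers(1, 4))
    X = pd.DataFrame(
        {f"d{j}": (rng.random(n) < rng.uniform(0.2, 0.8)).astype(float)
         for j in range(k)}
    )
    # guard against degenerate or collinear dummies
    for c in X.columns:
        if X[c].nunique() < 2:
            X.loc[: n // 2, c] = 1.0
            X.loc[n // 2:, c] = 0.0
    scores = rng.normal(size=n)
    w = rng.random(n) + 0.1
    return y, X, scores, w


class TestIdentity:
    def test_explained_plus_residual_equals_actual(self, rng):
        for _ in range(100):
            y, X, s, w = random_instance(rng)
            res = wagstaff_decompose(y, X, s, weights=w)
            assert res.explained_ci + res.residual == pytest.approx(
                res.actual_ci, abs=1e-10
            )
            # residual equals the generalized index of the OLS error term
            assert res.residual == pytest.approx(res.residual_check, abs=1e-8)

    def test_actual_matches_inequality_module(self, rng):
        y, X, s, w = random_instance(rng, n=40)
        res = wagstaff_decompose(y, X, s, weights=w)
        direct = concentration_index(y, fractional_rank(s, w), w)
        assert res.actual_ci == pytest.approx(direct.C, abs=1e-12)
        assert res.mu == pytest.approx(direct.mu, abs=1e-12)


class TestContributions:
    def test_saturated_self_decomposition(self):
        y = np.array([1.0, 0, 0, 1, 0, 1, 0, 0])
        s = np.arange(8.0)
        X = pd.DataFrame({"self": y})
        res = wagstaff_decompose(y, X, s)
        row = res.table.loc["self"]
        assert row["coefficient"] == pytest.approx(1.0, abs=1e-10)
        assert row["mean"] == pytest.approx(res.mu, abs=1e-12)
        assert row["elasticity"] == pytest.approx(1.0, abs=1e-10)
        assert row["ci"] == pytest.approx(res.actual_ci, abs=1e-10)
        assert res.explained_ci == pytest.approx(res.actual_ci, abs=1e-10)
        assert res.residual == pytest.approx(0.0, abs=1e-10)
        assert row["percentage_contribution"] == pytest.approx(100.0, abs=1e-8)

    def test_independent_noise_regressor_contributes_nothing(self):
        rng = np.random.default_rng(99)
        n = 10_000
        s = rng.normal(size=n)
        r = fractional_rank(s, np.ones(n))
        y = (rng.random(n) < 0.5 - 0.4 * (r - 0.5)).astype(float)
        X = pd.DataFrame(
            {
                "wealthy_half": (r > 0.5).astype(float),
                "noise": (rng.random(n) < 0.5).astype(float),
            }
        )
        res = wagstaff_decompose(y, X, s)
        assert abs(res.table.loc["noise", "absolute_contribution"]) < 0.005

    def test_absolute_contribution_is_elasticity_times_ci(self, rng):
        y, X, s, w = random_instance(rng, n=50)
        res = wagstaff_decompose(y, X, s, weights=w)
        prod = res.table["elasticity"] * res.table["ci"]
        np.testing.assert_allclose(
            res.table["absolute_contribution"], prod, atol=1e-12
        )

    def test_orthogonal_regressor_leaves_others_unchanged(self):
        rng = np.random.default_rng(7)
        n = 5000
        s = rng.normal(size=n)
        x1 = (s + rng.normal(size=n) > 0).astype(float)
        y = (rng.random(n) < 0.3 + 0.3 * x1).astype(float)
        base = wagstaff_decompose(y, pd.DataFrame({"x1": x1}), s)
        # regressor independent of y, s and x1
        x2 = (rng.random(n) < 0.5).astype(float)
        ext = wagstaff_decompose(y, pd.DataFrame({"x1": x1, "x2": x2}), s)
        assert ext.table.loc["x1", "absolute_contribution"] == pytest.approx(
            base.table.loc["x1", "absolute_contribution"], abs=0.005
        )

    def test_percentage_denominators(self, rng):
        y, X, s, w = random_instance(rng, n=60)
        res = wagstaff_decompose(y, X, s, weights=w)
        pct_exp = percentage_contributions(res, "explained")
        assert pct_exp.sum() == pytest.approx(100.0, abs=0.5)
        pct_act = percentage_contributions(res, "actual")
        assert pct_act.sum() == pytest.approx(
            100.0 * res.explained_ci / res.actual_ci, abs=1e-8
        )

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(1)
        n = 30
        x = (rng.random(n) < 0.5).astype(float)
        X = pd.DataFrame({"a": x, "b": 1.0 - x})  # a + b = const
        y = (rng.random(n) < 0.5).astype(float)
        y[0] = 1.0
        with pytest.raises(ValueError, match="rank deficient"):
            wagstaff_decompose(y, X, rng.normal(size=n))


class TestGroups:
    def _result(self):
        rng = np.random.default_rng(21)
        y, X, s, w = random_instance(rng, n=80)
        while X.shape[1] < 3:
            y, X, s, w = random_instance(rng, n=80)
        return wagstaff_decompose(y, X, s, weights=w)

    def test_group_totals_are_member_sums(self):
        res = self._result()
        cols = list(res.table.index)
        grouping = {"g1": cols[:2], "g2": cols[2:]}
        gt = group_contributions(res, grouping).set_index("group")
        for g, members in grouping.items():
            assert gt.loc[g, "absolute_contribution"] == pytest.approx(
                res.table.loc[members, "absolute_contribution"].sum(), abs=1e-12
            )
            assert gt.loc[g, "percentage_contribution"] == pytest.approx(
                res.table.loc[members, "percentage_contribution"].sum(), abs=1e-10
            )

    def test_empty_group_is_zero(self):
        res = self._result()
        gt = group_contributions(res, {"empty": []}).set_index("group")
        assert gt.loc["empty", "absolute_contribution"] == 0.0

    def test_column_in_two_groups_rejected(self):
        res = self._result()
        c = res.table.index[0]
        with pytest.raises(ValueError, match="assigned to both"):
            group_contributions(res, {"g1": [c], "g2": [c]})

    def test_wealth_dominates_when_only_wealth_planted(self):
        """Inequality planted purely through wealth: the wealth group's
        share of the explained index dwarfs every other group's."""
        from healthineq import SimulationConfig, generate_dataset
        from healthineq.models import build_dummies

        cfg = SimulationConfig.null(seed=31, wealth_effect=-0.6,
                                    n_clusters=1430)
        df = generate_dataset(cfg)
        df["wq"] = pd.Categorical([f"Q{q}" for q in df["wealth_quintile"]])
        covs = {"wq": "Q1", "education": "no_education", "region": "north",
                "bmi_class": "normal"}
        X, groups = build_dummies(df, covs)
        res = wagstaff_decompose(
            df["anaemic"].to_numpy(dtype=float), X,
            df["wealth_score"].to_numpy(), weights=df["weight"].to_numpy(),
        )
        gt = group_contributions(res, groups).set_index("group")
        shares = gt["percentage_contribution"].abs()
        assert shares["wq"] > shares.drop("wq").max()
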