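"""Concentration index and concentration curve."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthineq import (
    ConcentrationIndex,
    concentration_curve,
    concentration_index,
    fractional_rank,
    stratified_ci,
)


def brute_force_ci(y, r, w):
    """Independent weighted-covariance evaluation, loop arithmetic only."""
    wn = [wi / sum(w) for wi in w]
    mu = sum(wi * yi for wi, yi in zip(wn, y))
    rbar = sum(wi * ri for wi, ri in zip(wn, r))
    cov = sum(wi * (yi - mu) * (ri - rbar) for wi, yi, ri in zip(wn, y, r))
    return 2.0 * cov / mu


class TestConcentrationIndex:
    def test_four_point_hand_example(self):
        r = fractional_rank([1.0, 2.0, 3.0, 4.0], np.ones(4))
        res = concentration_index(np.array([1.0, 0, 0, 0]), r, np.ones(4))
        assert res.C == pytest.approx(-0.75, abs=1e-12)
        assert res.mu == pytest.approx(0.25)

    def test_mirror_case_positive(self):
        r = fractional_rank([1.0, 2.0, 3.0, 4.0], np.ones(4))
        res = concentration_index(np.array([0.0, 0, 0, 1]), r, np.ones(4))
        assert res.C == pytest.approx(0.75, abs=1e-12)

    def test_constant_outcome_zero_index(self):
        r = fractional_rank([1.0, 2.0, 3.0], np.ones(3))
        assert concentration_index(np.full(3, 0.4), r, np.ones(3)).C == pytest.approx(
            0.0, abs=1e-12
        )

    def test_zero_mean_outcome_rejected(self):
        r = fractional_rank([1.0, 2.0], np.ones(2))
        with pytest.raises(ValueError, match="zero mean"):
            concentration_index(np.zeros(2), r, np.ones(2))

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = rng.integers(2, 21)
            y = rng.random(n) + 0.05
            s = rng.normal(size=n)
            w = rng.random(n) + 0.1
            r = fractional_rank(s, w)
            got = concentration_index(y, r, w).C
            assert got == pytest.approx(brute_force_ci(y, r, w), abs=1e-10)

    def test_equals_convenient_regression_form(self, rng):
        # slope of the WLS fit of 2 var_w(R) y/mu on R equals C
        for _ in range(25):
            n = int(rng.integers(5, 30))
            y = rng.random(n) + 0.1
            s = rng.normal(size=n)
            w = rng.random(n) + 0.1
            r = fractional_rank(s, w)
            wn = w / w.sum()
            mu = wn @ y
            rbar = wn @ r
            var_r = wn @ (r - rbar) ** 2
            lhs = 2 * var_r * y / mu
            slope = (wn * (lhs - wn @ lhs)) @ (r - rbar) / var_r
            assert concentration_index(y, r, w).C == pytest.approx(slope, abs=1e-10)

    @settings(deadline=None, max_examples=60)
    @given(
        st.integers(3, 25),
        st.integers(0, 2**31 - 1),
        st.floats(0.5, 10.0),
    )
    def test_scale_invariance_and_rank_reversal(self, n, seed, scale):
        rng = np.random.default_rng(seed)
        y = rng.random(n) + 0.05
        s = rng.normal(size=n)
        w = rng.random(n) + 0.1
        r = fractional_rank(s, w)
        c = concentration_index(y, r, w).C
        assert concentration_index(scale * y, r, w).C == pytest.approx(c, abs=1e-10)
        r_rev = fractional_rank(-s, w)
        assert concentration_index(y, r_rev, w).C == pytest.approx(-c, abs=1e-10)

    def test_binary_bounds(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y = (rng.random(n) < 0.4).astype(float)
            if y.sum() == 0:
                y[0] = 1.0
            s = rng.normal(size=n)
            w = rng.random(n) + 0.1
            r = fractional_rank(s, w)
            res = concentration_index(y, r, w)
            assert -1.0 - 1e-12 <= res.C <= 1.0 + 1e-12
            assert res.mu - 1 - 1e-10 <= res.C <= 1 - res.mu + 1e-10


class TestConcentrationCurve:
    def test_outcome_mass_in_poorest_quartile(self):
        curve = concentration_curve(
            np.array([1.0, 0, 0, 0]), np.array([1.0, 2, 3, 4]), np.ones(4)
        )
        expected = np.array([[0, 0], [0.25, 1], [0.5, 1], [0.75, 1], [1, 1]])
        np.testing.assert_allclose(curve, expected, atol=1e-12)
        # everywhere on or above the diagonal
        assert np.all(curve[:, 1] >= curve[:, 0] - 1e-12)

    def test_uniform_outcome_gives_diagonal(self):
        curve = concentration_curve(
            np.full(6, 2.0), np.arange(6.0), np.ones(6)
        )
        np.testing.assert_allclose(curve[:, 0], curve[:, 1], atol=1e-12)

    def test_endpoints_and_monotonicity(self, small_survey):
        curve = concentration_curve(
            small_survey["anaemic"].to_numpy(dtype=float),
            small_survey["wealth_score"].to_numpy(),
            small_survey["weight"].to_numpy(),
        )
        np.testing.assert_allclose(curve[0], [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(curve[-1], [1.0, 1.0], atol=1e-10)
        assert np.all(np.diff(curve[:, 0]) >= -1e-12)
        assert np.all(np.diff(curve[:, 1]) >= -1e-12)

    def test_planted_propoor_curve_above_diagonal(self, small_survey):
        curve = concentration_curve(
            small_survey["anaemic"].to_numpy(dtype=float),
            small_survey["wealth_score"].to_numpy(),
            small_survey["weight"].to_numpy(),
        )
        interior = curve[(curve[:, 0] > 0.1) & (curve[:, 0] < 0.9)]
        assert np.mean(interior[:, 1] > interior[:, 0]) > 0.95


class TestStratifiedCI:
    @staticmethod
    def _frame(y, s, w, stratum):
        return pd.DataFrame(
            {"anaemic": y, "wealth_score": s, "weight": w, "region": stratum}
        )

    def test_identical_strata_identical_index(self):
        y = [1.0, 0, 0, 0] * 2
        s = [1.0, 2, 3, 4] * 2
        df = self._frame(y, s, np.ones(8), ["a"] * 4 + ["b"] * 4)
        results, skipped = stratified_ci(df, "region")
        assert not skipped
        assert results["a"].C == pytest.approx(results["b"].C, abs=1e-12)
        assert results["a"].C == pytest.approx(-0.75, abs=1e-12)

    def test_pooled_differs_from_stratum_mean(self):
        # pooled ranks mix the strata, so pooled C need not average stratum C
        y = np.array([1.0, 0, 0, 0, 1, 1, 0, 1])
        s = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        w = np.ones(8)
        df = self._frame(y, s, w, ["a"] * 4 + ["b"] * 4)
        results, _ = stratified_ci(df, "region")
        pooled = concentration_index(y, fractional_rank(s, w), w).C
        stratum_mean = (results["a"].C + results["b"].C) / 2
        assert pooled != pytest.approx(stratum_mean, abs=1e-3)

    def test_constant_outcome_stratum_skipped_with_reason(self):
        df = self._frame(
            [1.0, 0, 1, 1, 1, 1],
            [1.0, 2, 3, 1, 2, 3],
            np.ones(6),
            ["a"] * 3 + ["b"] * 3,
        )
        results, skipped = stratified_ci(df, "region")
        assert "a" in results
        assert skipped == {"b": "zero-variance outcome"}

    def test_constant_score_stratum_skipped(self):
        df = self._frame(
            [1.0, 0, 1, 0], [1.0, 1.0, 2.0, 3.0], np.ones(4), ["a", "a", "b", "b"]
        )
        results, skipped = stratified_ci(df, "region")
        assert skipped["a"] == "fewer than 2 distinct wealth scores"
        assert "b" in results

    def test_unknown_stratum_column(self, small_survey):
        with pytest.raises(KeyError):
            stratified_ci(small_survey, "not_a_column")
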