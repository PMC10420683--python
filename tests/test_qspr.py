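"""Univariate linear fitting, screening and prediction from published
coefficients."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topoindex import (PublishedEquationSet, correlation_screen, fit_linear,
                       published_equations, table1)
from topoindex.fixtures import compound_groups


def normal_equations(x, y):
    """Independent OLS oracle: solve X'X b = X'y directly."""
    X = np.column_stack([np.ones_like(x), x])
    b = np.linalg.solve(X.T @ X, X.T @ y)
    return b[1], b[0]  # slope, intercept


class TestFitLinear:
    def test_perfect_line(self):
        x = np.arange(5.0)
        m = fit_linear(x, 2.0 * x + 1.0)
        assert m.slope == pytest.approx(2.0, abs=1e-12)
        assert m.intercept == pytest.approx(1.0, abs=1e-12)
        assert m.r == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            x = rng.normal(scale=rng.uniform(0.5, 100), size=n)
            y = rng.normal(scale=rng.uniform(0.5, 100), size=n)
            m = fit_linear(x, y)
            slope, intercept = normal_equations(x, y)
            assert m.slope == pytest.approx(slope, abs=1e-10 * max(1, abs(slope)))
            assert m.intercept == pytest.approx(intercept,
                                                abs=1e-10 * max(1, abs(intercept)))

    def test_null_slope_small(self):
        rng = np.random.default_rng(99)
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        m = fit_linear(x, y)
        se = np.sqrt((1 - m.r**2) / (m.n - 2)) * np.std(y, ddof=1) / np.std(x, ddof=1)
        assert abs(m.slope) < 3 * se

    def test_scale_equivariance(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=20)
        y = rng.normal(size=20) + 0.5 * x
        base = fit_linear(x, y)
        scaled = fit_linear(x, 7.0 * y)
        assert scaled.slope == pytest.approx(7.0 * base.slope, rel=1e-12)
        assert scaled.intercept == pytest.approx(7.0 * base.intercept, rel=1e-12)
        assert scaled.r == pytest.approx(base.r, abs=1e-12)
        assert scaled.p == pytest.approx(base.p, rel=1e-9)

    @given(seed=st.integers(0, 2**31 - 1),
           scale=st.floats(0.1, 1e3),
           shift=st.floats(-1e3, 1e3))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_affine_response_equivariance(self, seed, scale, shift):
        """Mapping y -> scale*y + shift maps (slope, intercept) affinely and
        leaves |r| and p unchanged."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12) + x
        base = fit_linear(x, y)
        moved = fit_linear(x, scale * y + shift)
        assert moved.slope == pytest.approx(scale * base.slope, rel=1e-9)
        assert moved.intercept == pytest.approx(scale * base.intercept + shift,
                                                rel=1e-9, abs=1e-9)
        assert abs(moved.r) == pytest.approx(abs(base.r), abs=1e-12)
        assert moved.p == pytest.approx(base.p, rel=1e-6)

    def test_pairwise_missing_handling(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        y = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        m = fit_linear(x, y)
        assert m.n == 3

    def test_low_n_flag(self):
        m = fit_linear([1.0, 2.0, 3.0], [1.1, 1.9, 3.2])
        assert m.n == 3 and m.low_n

    @pytest.mark.parametrize("x, y, match", [
        ([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "constant"),
        ([1.0, 2.0], [1.0, 2.0], ">= 3"),
    ])
    def test_errors(self, x, y, match):
        with pytest.raises(ValueError, match=match):
            fit_linear(x, y)


class TestScreen:
    def test_planted_pair_ranks_first(self):
        rng = np.random.default_rng(7)
        n = 30
        x = rng.uniform(0, 100, size=n)
        idx = pd.DataFrame(
            {"planted": x, **{f"junk{i}": rng.normal(size=n) for i in range(10)}},
            index=[f"c{i}" for i in range(n)])
        props = pd.DataFrame({"y": 2.0 * x + rng.normal(scale=1.0, size=n)},
                             index=idx.index)
        models = correlation_screen(idx, props, alpha=0.05)
        assert models[0].index == "planted"
        assert abs(models[0].r) > 0.99

    def test_alpha_one_returns_every_fittable_pair(self):
        rng = np.random.default_rng(3)
        idx = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"),
                           index=[f"c{i}" for i in range(8)])
        props = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("xyz"),
                             index=idx.index)
        models = correlation_screen(idx, props, alpha=1.0)
        assert len(models) == 4 * 3

    def test_group_separation(self):
        rng = np.random.default_rng(5)
        idx = pd.DataFrame({"i": rng.normal(size=10)},
                           index=[f"c{i}" for i in range(10)])
        props = pd.DataFrame({"p": rng.normal(size=10)}, index=idx.index)
        groups = {f"c{i}": ("g1" if i < 5 else "g2") for i in range(10)}
        models = correlation_screen(idx, props, alpha=1.0, groups=groups)
        assert sorted(m.group for m in models) == ["g1", "g2"]
        assert all(m.n == 5 for m in models)

    def test_no_shared_rows(self):
        idx = pd.DataFrame({"i": [1.0, 2.0, 3.0]}, index=list("abc"))
        props = pd.DataFrame({"p": [1.0, 2.0, 3.0]}, index=list("xyz"))
        with pytest.raises(ValueError, match="shared"):
            correlation_screen(idx, props)


class TestPublishedEquations:
    def test_transcription_complete(self):
        eqs = published_equations()
        assert len(eqs) == 82
        assert sorted(eqs.eq_no) == list(range(1, 83))
        assert (eqs.eq_no <= 37).sum() == 37   # partition-coefficient + R_MW set
        assert (eqs.eq_no >= 38).sum() == 45   # physicochemical-property set
        # the printed r always carries the sign of the slope
        assert np.all(np.sign(eqs.r) == np.sign(eqs.slope))

    def test_intercept_readoff(self):
        eqs = PublishedEquationSet()
        assert eqs.predict(1, 0.0) == pytest.approx(-1.060)

    @pytest.mark.parametrize("eq_no, x, expected", [
        (1, 76.804, -0.600),   # published W of allopurinol
        (30, 218.0, 0.363),    # published Mv of oxypurinol
    ])
    def test_prediction_arithmetic(self, eq_no, x, expected):
        assert PublishedEquationSet().predict(eq_no, x) == pytest.approx(
            expected, abs=5e-4)

    def test_unknown_equation(self):
        with pytest.raises(KeyError):
            PublishedEquationSet().predict(999, 1.0)

    def test_noiseless_round_trip_recovers_every_equation(self):
        """Data generated exactly from a published equation, with the study
        group's published index values as x, refits to the same coefficients."""
        t1 = table1()
        groups = compound_groups()
        eqs = published_equations()
        for eq in eqs.itertuples():
            members = [c for c in t1.index if groups[c] == eq.group]
            x = t1.loc[members, eq.index].astype(float).values
            y = eq.intercept + eq.slope * x
            m = fit_linear(x, y, property=eq.property, index=eq.index)
            assert m.slope == pytest.approx(eq.slope, abs=1e-9 * max(1, abs(eq.slope)))
            assert m.intercept == pytest.approx(eq.intercept,
                                                abs=1e-9 * max(1, abs(eq.intercept)))
            assert abs(m.r) == pytest.approx(1.0, abs=1e-12)
            assert np.sign(m.r) == np.sign(eq.slope)

    def test_predict_all_respects_groups(self):
        t1 = table1().drop(columns="group")
        pred = PublishedEquationSet().predict_all(t1, groups=compound_groups())
        eq1 = pred[(pred.eq_no == 1)]
        assert set(eq1.compound) == {"Allopurinol", "Oxypurinol", "Febuxostat"}
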