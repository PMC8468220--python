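"""Pearson/partial correlations and the Benjamini-Hochberg family logic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from sleepcortex.association import (
    bh_adjust,
    format_significant_table,
    partial_pearson,
    pearson,
    run_family,
)
from sleepcortex.errors import DegenerateInputError, SpecError
from sleepcortex.spectral import CLUSTER_NAMES, INDEX_NAMES


def _t_sf_numeric(t_val, df):
    """Survival function of Student's t by numeric integration of its density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    dens = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    tail, _ = quad(dens, t_val, np.inf)
    return tail


def _pair_with_exact_r(r, n, rng):
    """Construct (x, y) whose sample Pearson correlation is exactly r."""
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    e = e - e.mean()
    e -= x * (e @ x) / (x @ x)  # orthogonalize
    e /= e.std()
    return x, r * x + math.sqrt(1 - r**2) * e


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert (r, p) == (1.0, 0.0)
        r, p = pearson(x, -3 * x + 7)
        assert (r, p) == (-1.0, 0.0)

    def test_zero_correlation_gives_p_one(self, rng):
        x, y = _pair_with_exact_r(0.0, 23, rng)
        r, p = pearson(x, y)
        assert abs(r) < 1e-12
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("r_target,n", [(0.55, 23), (-0.67, 23), (0.3, 12)])
    def test_p_matches_numeric_t_cdf_oracle(self, r_target, n, rng):
        x, y = _pair_with_exact_r(r_target, n, rng)
        r, p = pearson(x, y)
        assert r == pytest.approx(r_target, abs=1e-12)
        t = abs(r) * math.sqrt(n - 2) / math.sqrt(1 - r**2)
        assert p == pytest.approx(2 * _t_sf_numeric(t, n - 2), abs=1e-6)
        if (r_target, n) == (0.55, 23):
            assert p == pytest.approx(0.0066, abs=2e-4)

    def test_p_symmetric_and_monotone_in_effect_size(self, rng):
        ps = []
        for r_target in (0.2, 0.4, 0.6, 0.8):
            _, p_pos = pearson(*_pair_with_exact_r(r_target, 23, rng))
            _, p_neg = pearson(*_pair_with_exact_r(-r_target, 23, rng))
            assert p_pos == pytest.approx(p_neg, rel=1e-9)
            ps.append(p_pos)
        assert ps == sorted(ps, reverse=True)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError, match="variance"):
            pearson(np.ones(10), np.arange(10.0))
        with pytest.raises(DegenerateInputError, match="4"):
            pearson(np.arange(3.0), np.arange(3.0))

    def test_missing_values_reduce_pairwise(self, rng):
        x = rng.standard_normal(10)
        y = 2 * x + rng.standard_normal(10) * 0.1
        x_nan = x.copy()
        x_nan[3] = np.nan
        with pytest.warns(UserWarning, match="incomplete"):
            r_red, _ = pearson(x_nan, y)
        keep = np.arange(10) != 3
        assert r_red == pytest.approx(pearson(x[keep], y[keep])[0])


def _bh_brute_force(p):
    """Literal step-up definition: adj(i) = min_{j>=i} p_(j) * m / j, capped."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = [
        min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
        for i in range(m)
    ]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBHAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.04, 0.03, 0.02]), [0.02, 0.04, 0.04, 0.04]
        )

    def test_ties_and_identity(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(SpecError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8)
    )
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_adjust(p), _bh_brute_force(p), atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        for _ in range(50):
            p = rng.random(18)
            assert np.all(bh_adjust(p) >= p - 1e-15)


def _partial_brute_force(x, y, cov):
    """Residual-of-residuals via explicit normal equations."""
    n = len(x)
    d = np.column_stack([np.ones(n), cov])
    beta_x = np.linalg.solve(d.T @ d, d.T @ x)
    beta_y = np.linalg.solve(d.T @ d, d.T @ y)
    rx, ry = x - d @ beta_x, y - d @ beta_y
    r = (rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry))
    df = n - 2 - cov.shape[1]
    t = r * math.sqrt(df) / math.sqrt(1 - r**2)
    return r, 2 * _t_sf_numeric(abs(t), df)


class TestPartialPearson:
    def test_orthogonal_covariates_leave_r_unchanged(self, rng):
        n = 24
        x, y = _pair_with_exact_r(0.5, n, rng)
        cov = rng.standard_normal((n, 2))
        basis = np.column_stack([np.ones(n), x, y])
        cov -= basis @ np.linalg.lstsq(basis, cov, rcond=None)[0]
        r_plain, _ = pearson(x, y)
        r_part, _ = partial_pearson(x, y, cov)
        assert r_part == pytest.approx(r_plain, abs=1e-12)

    def test_confound_is_removed(self, rng):
        n = 23
        age = rng.normal(73, 6, n)
        x = rng.standard_normal(n)
        r_part, p = partial_pearson(
            x, age.copy(), np.column_stack([age, rng.integers(0, 2, n)])
        )
        assert r_part == 0.0 and p == 1.0

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        cov = np.column_stack([rng.normal(70, 5, 6), [0, 1, 0, 1, 1, 0]])
        r, p = partial_pearson(x, y, cov)
        r_bf, p_bf = _partial_brute_force(x, y, cov)
        assert r == pytest.approx(r_bf, abs=1e-10)
        assert p == pytest.approx(p_bf, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 23
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(n),
                "y": rng.standard_normal(n),
                "age": rng.normal(73, 6, n),
                "sex": rng.integers(0, 2, n).astype(float),
            }
        )
        r, p = partial_pearson(df["x"], df["y"], df[["age", "sex"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["age", "sex"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_constant_covariate_dropped_with_warning(self, rng):
        x, y = rng.standard_normal((2, 12))
        cov = np.column_stack([np.ones(12), rng.standard_normal(12)])
        with pytest.warns(UserWarning, match="constant"):
            r, p = partial_pearson(x, y, cov)
        r_ref, p_ref = partial_pearson(x, y, cov[:, 1:])
        assert r == pytest.approx(r_ref)


def _random_indexes(rng, n=23):
    cols = pd.MultiIndex.from_product([INDEX_NAMES, CLUSTER_NAMES])
    return pd.DataFrame(
        rng.standard_normal((n, 18)), columns=cols,
        index=[f"S{i:02d}" for i in range(n)],
    )


class TestRunFamily:
    def test_family_shape_and_invariants(self, rng):
        idx = _random_indexes(rng)
        thick = pd.Series(rng.standard_normal(23), index=idx.index)
        records = run_family("precuneus", "R", thick, idx)
        assert len(records) == 18
        for rec in records:
            assert abs(rec.r) <= 1
            assert rec.p_fdr >= rec.p_unc - 1e-15
            assert rec.significant == (rec.p_fdr <= 0.05)
            assert rec.n == 23

    def test_planted_exact_relation_is_significant(self, rng):
        idx = _random_indexes(rng)
        thick = 2.0 * idx[("NREM_sigma", "parietal")] + 1.0
        records = run_family("precuneus", "R", thick, idx)
        hit = next(
            r for r in records if (r.index_name, r.cluster) == ("NREM_sigma", "parietal")
        )
        assert hit.r == pytest.approx(1.0)
        assert hit.p_fdr == 0.0
        assert hit.significant

    def test_subject_permutation_invariance(self, rng):
        idx = _random_indexes(rng)
        thick = pd.Series(rng.standard_normal(23), index=idx.index)
        perm = rng.permutation(23)
        rec1 = run_family("cuneus", "L", thick, idx)
        rec2 = run_family("cuneus", "L", thick.iloc[perm], idx.iloc[perm])
        for a, b in zip(rec1, rec2):
            assert a.r == pytest.approx(b.r, rel=1e-12)
            assert a.p_fdr == pytest.approx(b.p_fdr, rel=1e-9)


class TestTable2Formatting:
    def test_empty_when_nothing_significant(self, rng):
        idx = _random_indexes(rng)
        thick = pd.Series(rng.standard_normal(23), index=idx.index)
        records = run_family("insula", "L", thick, idx)
        for r in records:
            r.significant = False
        assert len(format_significant_table(records)) == 0

    def test_rounding_rules(self, rng):
        idx = _random_indexes(rng)
        thick = pd.Series(rng.standard_normal(23), index=idx.index)
        records = run_family("insula", "L", thick, idx)
        rec = records[0]
        rec.significant = True
        rec.r, rec.p_unc = -0.6789, 0.00035
        table = format_significant_table(records)
        assert len(table) == 1
        assert table.loc[0, "r"] == "-0.68"
        assert table.loc[0, "p"] == "0.00035"
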