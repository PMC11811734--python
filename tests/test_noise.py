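"""CV, DM, group differences, sensitivity calls and calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scxaa.datamodel import CellMatrix
from scxaa.noise import (
    calibrate_inflation,
    classify_sensitivity,
    compute_cv,
    compute_dm,
    dm_difference,
    housekeeping_overlap,
    select_top_fraction,
)


def _matrix(rows: dict) -> CellMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"c{i}" for i in range(df.shape[1])]
    return CellMatrix(values=df, unit="FPKM")


class TestComputeCv:
    def test_hand_value(self):
        m = _matrix({"g": [0.0, 4.0]})
        out = compute_cv(m)
        assert out.loc["g", "mean_fpkm"] == pytest.approx(2.0)
        assert out.loc["g", "cv"] == pytest.approx(np.sqrt(2.0))  # sd(ddof=1)=2.83

    def test_zero_mean_is_nan(self):
        out = compute_cv(_matrix({"g": [0.0, 0.0], "h": [1.0, 3.0]}))
        assert np.isnan(out.loc["g", "cv"])
        assert np.isfinite(out.loc["h", "cv"])

    def test_needs_two_cells(self):
        with pytest.raises(ValueError, match="2 cells"):
            compute_cv(_matrix({"g": [1.0]}))

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_cv_scale_invariant(self, scale):
        vals = np.array([1.0, 2.0, 5.0])
        m1 = _matrix({"g": vals})
        m2 = _matrix({"g": vals * scale})
        assert compute_cv(m2).loc["g", "cv"] == pytest.approx(
            compute_cv(m1).loc["g", "cv"], rel=1e-9
        )


def _dm_oracle(table: pd.DataFrame, window: int) -> np.ndarray:
    """O(n^2) reference DM implementation on a (mean_fpkm, cv) table."""
    order = np.lexsort((table.index.to_numpy(), table["mean_fpkm"].to_numpy()))
    cvs = table["cv"].to_numpy()[order]
    n = len(cvs)
    half = window // 2
    expected_sorted = np.empty(n)
    for i in range(n):
        start = min(max(i - half, 0), n - window - 1)
        idx = [j for j in range(start, start + window + 1) if j != i]
        expected_sorted[i] = np.median(cvs[idx])
    expected = np.empty(n)
    expected[order] = expected_sorted
    return table["cv"].to_numpy() - expected


class TestComputeDm:
    def _table(self, means, cvs):
        return pd.DataFrame(
            {"mean_fpkm": means, "cv": cvs},
            index=[f"g{i}" for i in range(len(means))],
        )

    def test_hand_worked_window_two(self):
        t = self._table([1, 2, 3, 4, 5], [1.0, 2.0, 1.5, 3.0, 2.5])
        out = compute_dm(t, window=2)
        np.testing.assert_allclose(
            out["dm"].to_numpy(), [-0.75, 0.75, -1.0, 1.0, 0.25]
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for n, window in [(150, 100), (200, 50), (103, 100)]:
            t = self._table(rng.lognormal(1, 2, n), rng.lognormal(0.5, 0.5, n))
            np.testing.assert_allclose(
                compute_dm(t, window)["dm"].to_numpy(), _dm_oracle(t, window)
            )

    def test_nan_cv_excluded_but_kept_in_output(self):
        rng = np.random.default_rng(3)
        t = self._table(rng.lognormal(1, 1, 60), rng.lognormal(0, 0.3, 60))
        t.loc["g5", "cv"] = np.nan
        out = compute_dm(t, window=50)
        assert np.isnan(out.loc["g5", "dm"])
        assert out["dm"].notna().sum() == 59

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        t = self._table(rng.lognormal(1, 1, 120), rng.lognormal(0, 0.4, 120))
        shifted = t.copy()
        shifted["cv"] = shifted["cv"] + 5.0
        np.testing.assert_allclose(
            compute_dm(shifted, 100)["dm"].to_numpy(),
            compute_dm(t, 100)["dm"].to_numpy(),
            atol=1e-12,
        )

    def test_constant_cv_gives_zero_dm(self):
        t = self._table(np.arange(1.0, 121.0), np.full(120, 1.3))
        assert np.allclose(compute_dm(t, 100)["dm"].to_numpy(), 0.0)

    @pytest.mark.parametrize("window", [0, 3, -2])
    def test_bad_window_rejected(self, window):
        t = self._table(np.arange(1.0, 11.0), np.ones(10))
        with pytest.raises(ValueError, match="even"):
            compute_dm(t, window)

    def test_too_few_genes_rejected(self):
        t = self._table(np.arange(1.0, 11.0), np.ones(10))
        with pytest.raises(ValueError, match="window\\+1"):
            compute_dm(t, 10)


class TestSelectTopFraction:
    def test_hand_example(self):
        x = np.array([0.5, 3.0, 2.0])  # 2/3 above 1
        a = np.array([0.2, 0.4, 5.0, 6.0])  # 2/4 above 1 -> f = 0.5
        ix, ia, f = select_top_fraction(x, a, 1.0)
        assert f == pytest.approx(0.5)
        assert sorted(x[ix]) == [2.0, 3.0]  # round(1.5) -> 2 genes
        assert sorted(a[ia]) == [5.0, 6.0]

    def test_zero_fraction(self):
        ix, ia, f = select_top_fraction(np.array([0.1]), np.array([5.0]), 1.0)
        assert f == 0.0 and len(ix) == 0 and len(ia) == 0


class TestDmDifference:
    def _tables(self, shift=0.0, n=300, seed=0):
        rng = np.random.default_rng(seed)
        a = pd.DataFrame(
            {"mean_fpkm": rng.lognormal(1, 1, n), "dm": rng.normal(0, 0.2, n)}
        )
        x = pd.DataFrame(
            {"mean_fpkm": rng.lognormal(1, 1, n // 3),
             "dm": rng.normal(shift, 0.2, n // 3)}
        )
        return x, a

    def test_recovers_shift(self):
        x, a = self._tables(shift=0.3)
        res = dm_difference(x, a, threshold=0.0, seed=1)
        assert res.difference == pytest.approx(0.3, abs=0.08)
        assert res.ci_low < res.difference < res.ci_high

    def test_antisymmetric_point_estimate(self):
        x, a = self._tables(shift=0.3)
        fwd = dm_difference(x, a, n_boot=0)
        rev = dm_difference(a, x, n_boot=0)
        assert fwd.difference == pytest.approx(-rev.difference)

    def test_null_ci_covers_zero_about_90pct(self):
        hits = 0
        trials = 60
        for s in range(trials):
            x, a = self._tables(shift=0.0, n=120, seed=100 + s)
            res = dm_difference(x, a, n_boot=200, seed=s)
            hits += res.ci_low <= 0.0 <= res.ci_high
        assert 0.78 <= hits / trials <= 1.0  # nominal 0.90

    def test_deterministic_under_seed(self):
        x, a = self._tables(shift=0.1)
        r1 = dm_difference(x, a, seed=42)
        r2 = dm_difference(x, a, seed=42)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_empty_group_rejected(self):
        x, a = self._tables()
        with pytest.raises(ValueError, match="empty"):
            dm_difference(x.iloc[:0], a)


class TestClassifySensitivity:
    def test_strict_boundary(self):
        t = pd.DataFrame({"dm": [1.0, 1.01, 0.5, -2.0]}, index=list("abcd"))
        calls, _ = classify_sensitivity(t)
        assert calls.loc["a", "call"] == "sensitive"  # DM == 1 is not > 1
        assert calls.loc["b", "call"] == "insensitive"

    def test_quotient(self):
        t = pd.DataFrame(
            {
                "dm": [2.0, 2.0, 2.0, 0.0, 0.0] + [2.0, 2.0, 0.0, 0.0, 0.0],
                "chromosome_class": ["X"] * 5 + ["autosome"] * 5,
            }
        )
        _, summary = classify_sensitivity(t)
        assert summary.attrs["x_over_a_quotient"] == pytest.approx(0.6 / 0.4)


class TestHousekeepingOverlap:
    def _table(self, means, dms):
        return pd.DataFrame(
            {"mean_fpkm": means, "dm": dms},
            index=[f"g{i}" for i in range(len(means))],
        )

    def test_universal_quantifier(self):
        t1 = self._table([5.0, 5.0, 1.0], [0.5, 2.0, 0.1])
        t2 = self._table([5.0, 1.0, 5.0], [0.2, 0.2, 0.2])
        out = housekeeping_overlap({"lung": t1, "testis": t2})
        # only g0 exceeds 2 in both tissues
        assert out.attrs["n_housekeeping_genes"] == 1
        lung = out[out["tissue"] == "lung"].iloc[0]
        assert lung["n_housekeeping"] == 1
        assert lung["fraction_sensitive"] == pytest.approx(1.0)  # dm 0.5 <= 1

    def test_empty_set_flagged(self):
        t1 = self._table([5.0], [0.5])
        t2 = self._table([1.0], [0.5])
        out = housekeeping_overlap({"a": t1, "b": t2})
        assert out.attrs["empty_housekeeping_set"]

    def test_requires_tables(self):
        with pytest.raises(ValueError):
            housekeeping_overlap({})


class TestCalibrateInflation:
    FACTORS = np.array([1.0, 1.05, 1.10])
    DIFFS = np.array([0.0, 0.1, 0.25])

    def test_node_inversion(self):
        est = calibrate_inflation(0.1, self.FACTORS, self.DIFFS)
        assert est.percent == pytest.approx(5.0)
        assert not est.extrapolated

    def test_interpolation(self):
        est = calibrate_inflation(0.175, self.FACTORS, self.DIFFS)
        assert est.percent == pytest.approx(7.5)

    def test_extrapolation_clamped_and_flagged(self):
        est = calibrate_inflation(0.5, self.FACTORS, self.DIFFS)
        assert est.percent == pytest.approx(10.0)
        assert est.extrapolated

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            calibrate_inflation(0.1, self.FACTORS, np.array([0.0, 0.3, 0.2]))
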