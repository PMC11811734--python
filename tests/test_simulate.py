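"""Synthetic-data generator: transform algebra, dropout, model datasets,
and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scxaa.simulate import (
    GeneratorConfig,
    build_model_datasets,
    degrade_to_cell,
    degrade_to_matrix,
    fit_generator_to_real,
    generate_bulk_profile,
    iter_model_datasets,
    sc_transform,
)


class TestScTransform:
    def test_printed_constants(self):
        assert sc_transform(1.0) == pytest.approx(2.0 ** 3.75)
        assert sc_transform(1.0) == pytest.approx(13.454, abs=1e-3)

    def test_halving_compresses_to_2_pow_minus_slope(self):
        for x in (0.1, 1.0, 7.3, 1234.5):
            assert sc_transform(x / 2) / sc_transform(x) == pytest.approx(2 ** -0.26)

    def test_identity_when_slope_one_intercept_zero(self):
        x = np.array([0.25, 1.0, 42.0])
        np.testing.assert_allclose(sc_transform(x, 1.0, 0.0), x)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sc_transform(0.0)

    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.floats(min_value=1e-6, max_value=1e6))
    def test_order_preserving(self, a, b):
        if a == b:
            return
        lo, hi = sorted([a, b])
        assert sc_transform(lo) < sc_transform(hi)

    @given(st.floats(min_value=1e-4, max_value=1e4),
           st.floats(min_value=0.05, max_value=1.0))
    def test_log2_gap_of_twofold_change_equals_slope(self, x, slope):
        gap = np.log2(sc_transform(x, slope, 3.75)) - np.log2(sc_transform(x / 2, slope, 3.75))
        assert gap == pytest.approx(slope, rel=1e-9)


class TestGenerateBulkProfile:
    CFG = GeneratorConfig(n_autosomal_genes=300, n_x_genes=40, n_cells=5, seed=7)

    def test_deterministic_under_seed(self):
        p1, _ = generate_bulk_profile(self.CFG)
        p2, _ = generate_bulk_profile(self.CFG)
        pd.testing.assert_series_equal(p1.values, p2.values)

    def test_x_values_are_subset_of_autosomal_values(self):
        profile, ann = generate_bulk_profile(self.CFG)
        a_vals = sorted(profile.values.loc[ann.autosomal_genes])
        for v in profile.values.loc[ann.x_genes]:
            assert v in a_vals

    def test_degenerate_sd_gives_constant_profile(self):
        cfg = GeneratorConfig(n_autosomal_genes=50, n_x_genes=5, bulk_log2_sd=0.0)
        profile, _ = generate_bulk_profile(cfg)
        assert profile.values.nunique() == 1

    def test_too_many_x_genes_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_autosomal_genes=10, n_x_genes=11)


class TestDegrade:
    def test_no_dropout_limit_equals_elementwise_transform(self, rng):
        cfg = GeneratorConfig(
            n_autosomal_genes=100, n_x_genes=10,
            detected_fraction_mean=1.0, detected_fraction_sd=0.0,
        )
        profile, _ = generate_bulk_profile(cfg)
        cell = degrade_to_cell(profile, cfg, rng)
        np.testing.assert_allclose(
            cell.values.to_numpy(), sc_transform(profile.values.to_numpy())
        )

    def test_exact_gene_count_at_fixed_fraction(self, rng):
        cfg = GeneratorConfig(
            n_autosomal_genes=9000, n_x_genes=1000,
            detected_fraction_mean=0.15, detected_fraction_sd=0.0,
        )
        profile, _ = generate_bulk_profile(cfg)
        cell = degrade_to_cell(profile, cfg, rng)
        assert int((cell.values > 0).sum()) == 1500  # round(0.15 * 10,000)

    def test_detected_genes_more_expressed_than_dropped(self, rng):
        cfg = GeneratorConfig(n_autosomal_genes=900, n_x_genes=100, n_cells=20)
        profile, _ = generate_bulk_profile(cfg)
        cells = degrade_to_matrix(profile, cfg, cfg.n_cells, rng)
        bulk = profile.values.to_numpy()
        detected = cells.values.to_numpy() > 0
        for c in range(cells.n_cells):
            assert bulk[detected[:, c]].mean() >= bulk[~detected[:, c]].mean()

    def test_zeros_only_from_dropout(self, rng):
        cfg = GeneratorConfig(n_autosomal_genes=200, n_x_genes=20)
        profile, _ = generate_bulk_profile(cfg)
        cell = degrade_to_cell(profile, cfg, rng)
        nonzero = cell.values[cell.values > 0]
        # every detected value is a transformed bulk value, hence > 0
        assert (nonzero > 0).all()


class TestModelDatasets:
    CFG = GeneratorConfig(n_autosomal_genes=400, n_x_genes=50, n_cells=3, seed=3)

    def test_noncompensated_bulk_is_exact_halving(self):
        rep = next(iter_model_datasets(self.CFG, "noncompensated", 1, "bulk"))
        ann = rep.annotation
        x_vals = np.sort(rep.bulk.values.loc[ann.x_genes].to_numpy())
        a_vals = np.sort(rep.bulk.values.loc[ann.autosomal_genes].to_numpy())
        # each halved X value is exactly half of some autosomal donor value
        for v in x_vals:
            assert np.isclose(a_vals, 2 * v).any()

    def test_compensated_bulk_ratio_near_one(self):
        reps = build_model_datasets(self.CFG, "compensated", 30, "bulk")
        ratios = []
        for rep in reps:
            ann = rep.annotation
            ratios.append(
                np.median(rep.bulk.values.loc[ann.x_genes])
                / np.median(rep.bulk.values.loc[ann.autosomal_genes])
            )
        assert np.median(ratios) == pytest.approx(1.0, abs=0.15)

    def test_shape_contract(self):
        reps = build_model_datasets(self.CFG, "noncompensated", 2, "sc")
        assert len(reps) == 2
        for rep in reps:
            assert rep.cells.n_cells == 3
            assert rep.cells.n_genes == 450
            assert rep.truth.model == "noncompensated"

    def test_bitwise_reproducible(self):
        r1 = next(iter_model_datasets(self.CFG, "compensated", 1, "sc"))
        r2 = next(iter_model_datasets(self.CFG, "compensated", 1, "sc"))
        pd.testing.assert_frame_equal(r1.cells.values, r2.cells.values)


class TestFitGeneratorToReal:
    def test_recovers_compression_parameters(self, rng):
        cfg = GeneratorConfig(
            n_autosomal_genes=2700, n_x_genes=300, n_cells=100, seed=11
        )
        profile, _ = generate_bulk_profile(cfg)
        cells = degrade_to_matrix(profile, cfg, 100, rng)
        fitted = fit_generator_to_real(profile, cells)
        assert fitted.compression_slope == pytest.approx(0.26, abs=0.05)
        assert fitted.compression_intercept == pytest.approx(3.75, abs=0.5)
        assert fitted.detected_fraction_mean == pytest.approx(0.15, abs=0.05)

    def test_identity_transform_recovered(self, rng):
        cfg = GeneratorConfig(
            n_autosomal_genes=450, n_x_genes=50, compression_slope=1.0,
            compression_intercept=0.0, detected_fraction_mean=1.0,
            detected_fraction_sd=0.0,
        )
        profile, _ = generate_bulk_profile(cfg)
        cells = degrade_to_matrix(profile, cfg, 10, rng)
        fitted = fit_generator_to_real(profile, cells)
        assert fitted.compression_slope == pytest.approx(1.0, abs=1e-6)
        assert fitted.compression_intercept == pytest.approx(0.0, abs=1e-6)

    def test_detection_frequency_is_a_count(self, rng):
        cfg = GeneratorConfig(n_autosomal_genes=270, n_x_genes=30, n_cells=100)
        profile, _ = generate_bulk_profile(cfg)
        cells = degrade_to_matrix(profile, cfg, 100, rng)
        fitted = fit_generator_to_real(profile, cells)
        g = cells.gene_ids[0]
        expected = (cells.values.loc[g] > 0).mean()
        assert fitted.empirical_detection_weights.loc[g] == pytest.approx(expected)

    def test_requires_overlap(self, small_matrix):
        import pandas as pd
        from scxaa.datamodel import ExpressionProfile
        bulk = ExpressionProfile("b", pd.Series({"a1": 1.0, "a2": 2.0}))
        with pytest.raises(ValueError, match="jointly detected|2 cells"):
            fit_generator_to_real(bulk, small_matrix)
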