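"""Preprocessing: MA transform, print-tip loess, scale normalization,
kNN imputation and per-array standardization."""

import numpy as np
import pandas as pd
import pytest

from aptrisk.preprocess import (compute_ma, knn_impute, preprocess_spot_tables,
                                printtip_loess, scale_normalize,
                                spots_to_matrix, standardize_arrays)
from aptrisk.simulate import CohortConfig, generate_cohort


def _spot_table(f_red, b_red, f_green, b_green, flags=None, block=None):
    n = len(f_red)
    return pd.DataFrame({
        "Block": block if block is not None else np.ones(n, dtype=int),
        "Row": np.arange(n) + 1,
        "Column": np.ones(n, dtype=int),
        "ID": [f"f{i}" for i in range(n)],
        "F635": f_red, "B635": b_red,
        "F532": f_green, "B532": b_green,
        "Flags": flags if flags is not None else np.zeros(n, dtype=int),
    })


class TestComputeMA:
    def test_equal_channels_give_zero_m(self):
        spot = _spot_table([150], [50], [130], [30])
        ma = compute_ma(spot)
        assert ma["M"].iloc[0] == pytest.approx(0.0)
        assert ma["A"].iloc[0] == pytest.approx(np.log2(100))

    def test_fourfold_ratio(self):
        spot = _spot_table([450], [50], [130], [30])
        ma = compute_ma(spot)
        assert ma["M"].iloc[0] == pytest.approx(2.0)
        assert ma["A"].iloc[0] == pytest.approx((np.log2(400) + np.log2(100)) / 2)

    def test_nonpositive_intensity_masks_only_that_spot(self):
        spot = _spot_table([40, 150], [50, 50], [130, 130], [30, 30])
        ma = compute_ma(spot)
        assert np.isnan(ma["M"].iloc[0])
        assert ma["M"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_bad_flag_masks(self):
        spot = _spot_table([150, 150], [50, 50], [130, 130], [30, 30],
                           flags=[-50, 0])
        ma = compute_ma(spot)
        assert np.isnan(ma["M"].iloc[0]) and not np.isnan(ma["M"].iloc[1])

    def test_all_masked_is_an_error(self):
        spot = _spot_table([40], [50], [130], [30])
        with pytest.raises(ValueError, match="no usable spots"):
            compute_ma(spot)


class TestPrinttipLoess:
    def test_constant_m_removed(self):
        rng = np.random.default_rng(0)
        ma = pd.DataFrame({"feature_id": [f"f{i}" for i in range(60)],
                           "block": 1, "M": 3.7,
                           "A": rng.uniform(6, 14, 60)})
        out = printtip_loess(ma)
        assert np.abs(out["M"]).max() < 1e-6

    def test_injected_linear_bias_removed_per_decile(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(6, 14, 600)
        m = 0.8 * a - 5 + rng.normal(0, 0.1, 600)
        ma = pd.DataFrame({"feature_id": [f"f{i}" for i in range(600)],
                           "block": 1, "M": m, "A": a})
        out = printtip_loess(ma)
        deciles = pd.qcut(a, 10, labels=False)
        med = pd.Series(out["M"].to_numpy()).groupby(deciles).median()
        assert np.abs(med).max() < 0.05

    def test_blocks_corrected_independently(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(6, 14, 400)
        block = np.r_[np.ones(200, int), 2 * np.ones(200, int)]
        bias = np.where(block == 1, 0.5 * a - 4, -0.5 * a + 4)
        m = bias + rng.normal(0, 0.05, 400)
        ma = pd.DataFrame({"feature_id": [f"f{i}" for i in range(400)],
                           "block": block, "M": m, "A": a})
        out = printtip_loess(ma)
        for b in (1, 2):
            resid = out.loc[out["block"] == b, "M"]
            aa = a[block == b]
            # no residual A-trend within either block
            assert abs(np.corrcoef(resid, aa)[0, 1]) < 0.15
            assert abs(resid.median()) < 0.05

    def test_small_block_falls_back_to_whole_array(self, caplog):
        rng = np.random.default_rng(3)
        a = rng.uniform(6, 14, 104)
        block = np.r_[np.ones(100, int), 2 * np.ones(4, int)]
        ma = pd.DataFrame({"feature_id": [f"f{i}" for i in range(104)],
                           "block": block, "M": 0.3 * a,
                           "A": a})
        with caplog.at_level("WARNING"):
            out = printtip_loess(ma)
        assert "falling back" in caplog.text
        assert np.isfinite(out["M"]).all()

    def test_masked_spots_untouched(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(6, 14, 50)
        m = rng.normal(0, 1, 50)
        m[7] = np.nan
        ma = pd.DataFrame({"feature_id": [f"f{i}" for i in range(50)],
                           "block": 1, "M": m, "A": a})
        out = printtip_loess(ma)
        assert np.isnan(out["M"].iloc[7])


class TestScaleNormalize:
    def test_two_columns_mads_equalized(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 400)
        mat = pd.DataFrame({"s1": base, "s2": 4 * rng.normal(0, 1, 400)})
        out = scale_normalize(mat)

        def mad(v):
            return np.median(np.abs(v - np.median(v)))

        assert mad(out["s1"]) == pytest.approx(mad(out["s2"]), abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.normal(0, [1, 2, 5], (300, 3)))
        once = scale_normalize(mat)
        twice = scale_normalize(once)
        pd.testing.assert_frame_equal(once, twice, atol=1e-12, rtol=0)

    def test_equal_mads_is_identity(self):
        rng = np.random.default_rng(7)
        col = rng.normal(0, 1, 200)
        mat = pd.DataFrame({"a": col, "b": np.r_[col[100:], col[:100]]})
        out = scale_normalize(mat)
        assert np.allclose(out.to_numpy(), mat.to_numpy(), atol=1e-12)

    def test_zero_mad_names_sample(self):
        mat = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            scale_normalize(mat)

    def test_missing_ignored_in_mad(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame({"a": rng.normal(0, 1, 100),
                            "b": rng.normal(0, 2, 100)})
        mat.iloc[:10, 0] = np.nan
        out = scale_normalize(mat)
        assert out["a"].isna().sum() == 10  # mask untouched


class TestKnnImpute:
    def test_identical_rows_share_value(self):
        mat = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (5, 1)))
        mat.iloc[0, 1] = np.nan
        out = knn_impute(mat, k=3)
        assert out.iloc[0, 1] == pytest.approx(2.0)

    def test_three_by_three_matches_bruteforce_nearest_row(self):
        mat = pd.DataFrame([[1.0, 2.0, np.nan],
                            [1.1, 2.1, 5.0],
                            [9.0, 9.0, 9.0]])
        # brute force: distances over jointly observed columns 0,1
        d_1 = np.sqrt((1.0 - 1.1) ** 2 + (2.0 - 2.1) ** 2)
        d_2 = np.sqrt((1.0 - 9.0) ** 2 + (2.0 - 9.0) ** 2)
        assert d_1 < d_2
        out = knn_impute(mat, k=1)
        assert out.iloc[0, 2] == pytest.approx(5.0)

    def test_donor_missing_target_column_is_skipped(self):
        mat = pd.DataFrame([[1.0, 2.0, np.nan],
                            [1.05, 2.05, np.nan],
                            [1.5, 2.5, 7.0],
                            [9.0, 9.0, 9.0]])
        out = knn_impute(mat, k=1)
        # nearest row (1) lacks column 2; next nearest with a value is row 2
        assert out.iloc[0, 2] == pytest.approx(7.0)
        assert out.iloc[1, 2] == pytest.approx(7.0)

    def test_clears_missing_mask(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(rng.normal(size=(30, 8)))
        mask = rng.uniform(size=mat.shape) < 0.1
        mat = mat.mask(mask)
        out = knn_impute(mat, k=5)
        assert not out.isna().any().any()

    def test_knn_beats_row_mean_on_structured_data(self):
        """Masked-entry experiment: hide observed entries, compare RMSE."""
        rng = np.random.default_rng(10)
        latent = rng.normal(size=(4, 25))
        loadings = rng.normal(size=(40, 4))
        truth = loadings @ latent + 0.2 * rng.normal(size=(40, 25))
        mat = pd.DataFrame(truth.copy())
        hide = rng.uniform(size=mat.shape) < 0.05
        mat = mat.mask(hide)
        imputed = knn_impute(mat, k=5).to_numpy()
        knn_rmse = np.sqrt(np.mean((imputed[hide] - truth[hide]) ** 2))
        row_mean = np.nanmean(mat.to_numpy(), axis=1)
        rm_rmse = np.sqrt(np.mean(
            (np.take(row_mean, np.nonzero(hide)[0]) - truth[hide]) ** 2))
        assert knn_rmse < rm_rmse

    def test_row_with_no_observations_rejected(self):
        mat = pd.DataFrame([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="no observed"):
            knn_impute(mat, k=1)


class TestStandardizeArrays:
    def test_hand_column(self):
        mat = pd.DataFrame({"s": [1.0, 2.0, 3.0]})
        out = standardize_arrays(mat)
        assert np.allclose(out["s"], [-1.0, 0.0, 1.0])

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(11)
        col = rng.normal(size=50)
        col = (col - col.mean()) / col.std(ddof=1)
        mat = pd.DataFrame({"s": col, "t": rng.normal(size=50)})
        out = standardize_arrays(mat)
        assert np.allclose(out["s"], col, atol=1e-12)

    def test_postconditions(self):
        rng = np.random.default_rng(12)
        mat = pd.DataFrame(rng.normal(3, 7, size=(40, 5)))
        out = standardize_arrays(mat)
        assert np.abs(out.mean(axis=0)).max() < 1e-12
        assert np.abs(out.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_zero_variance_names_sample(self):
        mat = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize_arrays(mat)


class TestFullChain:
    def test_chain_deterministic_and_improves_signal_recovery(self):
        cfg = CohortConfig(n_samples=10, n_features=400, n_blocks=4,
                           dye_bias=(-8.0, 0.8), block_sd=0.5,
                           noise_sd=0.2, missing_rate=0.05, seed=13)
        spots, clin, _ = generate_cohort(cfg)
        import dataclasses

        from aptrisk.simulate import generate_expression_cohort
        clean_cfg = dataclasses.replace(cfg, dye_bias=(0.0,), block_sd=0.0,
                                        noise_sd=0.0, missing_rate=0.0)
        z, _, _ = generate_expression_cohort(clean_cfg)  # same seed: same z

        processed = preprocess_spot_tables(spots)
        processed2 = preprocess_spot_tables(spots)
        pd.testing.assert_frame_equal(processed, processed2)

        raw = spots_to_matrix([compute_ma(s) for s in spots])
        common = processed.index
        zc = z.loc[common].to_numpy().ravel()
        r_post = np.corrcoef(processed.loc[common].to_numpy().ravel(), zc)[0, 1]
        raw_filled = raw.loc[common].to_numpy()
        obs = np.isfinite(raw_filled)
        r_pre = np.corrcoef(raw_filled[obs], z.loc[common].to_numpy()[obs])[0, 1]
        assert r_post > r_pre
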