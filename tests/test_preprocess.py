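"""Filtering rules, imputation, flow normalization, configuration, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dielscreen as ds

from conftest import tiny_table


class TestBlankFilter:
    def _table(self, sample_mean, blank_mean):
        return tiny_table(
            np.full((1, 4), sample_mean), n_blanks=2, blank_value=blank_mean
        )

    @pytest.mark.parametrize(
        "sample_mean,blank_mean,kept",
        [
            (160.0, 100.0, True),   # 1.6x >= 1.5x
            (140.0, 100.0, False),  # 1.4x < 1.5x
            (150.0, 100.0, True),   # boundary is inclusive
            (5.0, 0.0, True),       # absent from blanks -> always kept
        ],
    )
    def test_rule_boundaries(self, sample_mean, blank_mean, kept):
        out = ds.blank_filter(self._table(sample_mean, blank_mean))
        assert out.n_features == (1 if kept else 0)

    def test_no_blanks_is_an_error(self):
        with pytest.raises(ds.ValidationError, match="blank"):
            ds.blank_filter(tiny_table(np.ones((1, 4))))


class TestDetectionFrequencyFilter:
    @pytest.mark.parametrize(
        "n_detects,kept",
        [(62, True), (61, False)],  # 62/72 = 86.1% >= 85%; 61/72 = 84.7%
    )
    def test_72_sample_boundaries(self, n_detects, kept):
        vals = np.zeros((1, 72))
        vals[0, :n_detects] = 100.0
        out = ds.detection_frequency_filter(tiny_table(vals))
        assert out.n_features == (1 if kept else 0)

    def test_exact_threshold_is_kept(self):
        # a feature detected in exactly 85% of samples is retained
        vals = np.zeros((1, 20))
        vals[0, :17] = 1.0
        assert ds.detection_frequency_filter(tiny_table(vals)).n_features == 1

    def test_threshold_one_requires_full_detection(self):
        vals = np.ones((1, 10))
        vals[0, 0] = 0.0
        out = ds.detection_frequency_filter(tiny_table(vals), threshold=1.0)
        assert out.n_features == 0


class TestVarianceFilter:
    def test_constant_trajectory_removed(self):
        assert ds.variance_filter(tiny_table(np.full((1, 10), 100.0))).n_features == 0

    def test_two_sample_rsd_hand_value(self):
        # sd([10, 20], n-1) = 7.0711, mean = 15 -> RSD 47.1% > 45%
        assert ds.variance_filter(tiny_table(np.array([[10.0, 20.0]]))).n_features == 1

    def test_is_like_rsd_030_removed(self):
        rng = np.random.default_rng(0)
        sigma = np.sqrt(np.log1p(0.30**2))
        vals = 1000 * rng.lognormal(-0.5 * sigma**2, sigma, size=(1, 72))
        emp = vals.std(ddof=1) / vals.mean()
        assert emp <= 0.45  # IS-level variation sits below the threshold
        assert ds.variance_filter(tiny_table(vals)).n_features == 0

    def test_nondetects_excluded_and_lt2_detects_removed(self):
        vals = np.array([[0.0, 0.0, 10.0], [0.0, 0.0, 0.0], [5.0, 0.0, 50.0]])
        out = ds.variance_filter(tiny_table(vals))
        # row0: 1 detect -> removed; row1: 0 detects -> removed;
        # row2: detects {5, 50} -> RSD 115% -> kept
        assert list(out.feature_ids) == ["F002"]


class TestImputation:
    def test_quarter_of_feature_minimum(self):
        vals = np.array([[400.0, 800.0, 1200.0, 0.0]])
        out = ds.impute_nondetects(tiny_table(vals))
        assert out.intensities.iloc[0, 3] == 100.0  # 400 / 4

    def test_detected_values_unchanged(self):
        vals = np.array([[400.0, 800.0, 1200.0, 600.0]])
        out = ds.impute_nondetects(tiny_table(vals))
        np.testing.assert_array_equal(out.intensities.to_numpy(), vals)

    def test_minimum_is_per_feature(self):
        vals = np.array([[400.0, 800.0, 0.0], [40.0, 80.0, 0.0]])
        out = ds.impute_nondetects(tiny_table(vals))
        assert out.intensities.iloc[0, 2] == 100.0
        assert out.intensities.iloc[1, 2] == 10.0

    def test_all_nondetect_feature_is_an_error(self):
        with pytest.raises(ds.ValidationError, match="no detected"):
            ds.impute_nondetects(tiny_table(np.zeros((1, 4))))


class TestFlowNormalize:
    def test_constant_flow_is_identity(self):
        t = tiny_table(np.array([[1.0, 2.0, 3.0, 4.0]]), flow=np.full(4, 500.0))
        out = ds.flow_normalize(t)
        np.testing.assert_allclose(out.intensities.to_numpy(), t.intensities.to_numpy())

    def test_load_transformation_proportionality(self):
        flow = np.array([100.0, 100.0, 200.0, 100.0])
        t = tiny_table(np.array([[10.0, 10.0, 10.0, 10.0]]), flow=flow)
        out = ds.flow_normalize(t).intensities.to_numpy()[0]
        np.testing.assert_allclose(out, 10.0 * flow / flow.mean())

    def test_divide_direction_inverts(self):
        flow = np.array([100.0, 100.0, 200.0, 100.0])
        t = tiny_table(np.array([[10.0, 10.0, 10.0, 10.0]]), flow=flow)
        out = ds.flow_normalize(t, direction="divide").intensities.to_numpy()[0]
        np.testing.assert_allclose(out, 10.0 * flow.mean() / flow)

    def test_missing_flow_is_an_error(self):
        t = tiny_table(np.ones((1, 4)))
        with pytest.raises(ds.ValidationError, match="flow"):
            ds.flow_normalize(t)


class TestAssembleConfiguration:
    def test_hourly_average_of_identical_days(self):
        cfg = ds.SyntheticConfig(
            noise_rsd=0.0, is_rsd=0.0, nondetect_rate=0.0,
            rain_event=False, n_noise_features=0, n_internal_standards=0,
            n_blanks=0, seed=0,
        )
        table, _ = ds.generate_dataset(cfg)
        avg = ds.assemble_configuration(
            table, ds.SampleConfigurationSpec(mode="hourly_average")
        )["hourly_average"]
        day1 = ds.assemble_configuration(
            table, ds.SampleConfigurationSpec(mode="per_day")
        )["day1"]
        np.testing.assert_allclose(avg.to_numpy(), day1.to_numpy(), rtol=1e-12)

    def test_randomized_is_deterministic_and_multiset_preserving(self, default_dataset):
        _, table, _ = default_dataset
        spec = ds.SampleConfigurationSpec(mode="randomized", seed=9)
        r1 = ds.assemble_configuration(table, spec)["randomized"]
        r2 = ds.assemble_configuration(table, spec)["randomized"]
        pd.testing.assert_frame_equal(r1, r2)
        cont = ds.assemble_configuration(
            table, ds.SampleConfigurationSpec(mode="continuous_72h")
        )["continuous_72h"]
        for fid in table.feature_ids[:5]:
            assert sorted(r1.loc[fid]) == sorted(cont.loc[fid])

    def test_randomized_requires_seed(self):
        with pytest.raises(ds.ValidationError, match="seed"):
            ds.SampleConfigurationSpec(mode="randomized")

    def test_missing_hours_reported(self, default_dataset):
        _, table, _ = default_dataset
        keep = [s for s in table.sample_meta.index if s != "D2H05"]
        crippled = ds.FeatureTable(
            table.intensities[keep],
            table.feature_meta.copy(),
            table.sample_meta.loc[keep],
        )
        with pytest.raises(ds.ValidationError, match=r"\(2, 5\)"):
            ds.assemble_configuration(
                crippled, ds.SampleConfigurationSpec(mode="continuous_72h")
            )

    def test_continuous_is_day_major_hour_minor(self, default_dataset):
        _, table, _ = default_dataset
        cont = ds.assemble_configuration(
            table, ds.SampleConfigurationSpec(mode="continuous_72h")
        )["continuous_72h"]
        assert list(cont.columns[:3]) == ["D1H00", "D1H01", "D1H02"]
        assert list(cont.columns[-2:]) == ["D3H22", "D3H23"]


class TestScaling:
    def test_log2_powers_give_unit_steps(self):
        z = ds.scale_trajectory(pd.Series([2.0, 4.0, 8.0]))  # log2 -> 1, 2, 3
        np.testing.assert_allclose(z.to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mean_zero_sd_one_and_gain_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(mean=5, sigma=1, size=(3, 24))
        x[0] = x[1] * rng.uniform(0.5, 2.0)  # enforce one non-constant dup
        Z = ds.scale_trajectories(pd.DataFrame(x))
        np.testing.assert_allclose(Z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=1, ddof=1), 1.0, atol=1e-9)
        gain = rng.uniform(0.1, 10.0)
        Z2 = ds.scale_trajectories(pd.DataFrame(x * gain))
        np.testing.assert_allclose(Z.to_numpy(), Z2.to_numpy(), atol=1e-9)

    def test_constant_trajectory_is_an_error(self):
        with pytest.raises(ds.ValidationError, match="constant"):
            ds.scale_trajectories(pd.DataFrame([[5.0, 5.0, 5.0]]))

    def test_nonpositive_values_are_an_error(self):
        with pytest.raises(ds.ValidationError, match="impute"):
            ds.scale_trajectories(pd.DataFrame([[0.0, 1.0, 2.0]]))


def test_pipeline_removes_designed_noise(default_dataset, preprocessed):
    _, _, truth = default_dataset
    surviving = truth.loc[preprocessed.table.feature_ids]
    n_noise_in = (truth == "noise").sum()
    n_noise_out = (surviving == "noise").sum()
    assert n_noise_out <= 0.05 * n_noise_in
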