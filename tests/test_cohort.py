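"""Cohort I/O, ratio features, truncation, standardization, encoding, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cevvo.cohort import (ALL_CHANNELS, DEFAULT_FRACTIONS, CohortFormatError,
                          CohortValidationError, PatientRecord, apply_scaler,
                          build_samples, derive_ratio_features, encode_static,
                          fit_scaler, read_cohort, standardize_length,
                          truncate_runs, unscale, write_cohort)
from conftest import binning_oracle


def _assert_records_equal(a, b):
    assert a.patient_id == b.patient_id
    assert a.outcome == b.outcome
    assert a.channels == b.channels
    np.testing.assert_allclose(a.times, b.times)
    np.testing.assert_allclose(a.perfusion, b.perfusion, rtol=1e-12)
    for f in ("age", "sex", "bmi", "cause", "ventilation_type",
              "reinfusion_size", "drainage_size"):
        assert getattr(a, f) == getattr(b, f)


class TestIO:
    def test_roundtrip_preserves_records(self, tiny_cohort, tmp_path):
        sp, pp = tmp_path / "s.csv", tmp_path / "p.csv"
        write_cohort(tiny_cohort, sp, pp, manifest_path=tmp_path / "m.json")
        back = read_cohort(sp, pp)
        assert len(back) == len(tiny_cohort)
        by_id = {r.patient_id: r for r in back}
        for rec in tiny_cohort:
            _assert_records_equal(rec, by_id[rec.patient_id])

    def test_missing_column_is_format_error(self, tiny_cohort, tmp_path):
        sp, pp = tmp_path / "s.csv", tmp_path / "p.csv"
        write_cohort(tiny_cohort, sp, pp)
        df = pd.read_csv(sp).drop(columns=["bmi"])
        df.to_csv(sp, index=False)
        with pytest.raises(CohortFormatError, match="bmi"):
            read_cohort(sp, pp)

    def test_orphan_perfusion_rows_rejected(self, tiny_cohort, tmp_path):
        sp, pp = tmp_path / "s.csv", tmp_path / "p.csv"
        write_cohort(tiny_cohort, sp, pp)
        perf = pd.read_csv(pp)
        perf.loc[0, "patient_id"] = "ghost"
        perf.to_csv(pp, index=False)
        with pytest.raises(CohortValidationError, match="ghost"):
            read_cohort(sp, pp)

    def test_unknown_categorical_level_names_field(self, tiny_cohort, tmp_path):
        sp, pp = tmp_path / "s.csv", tmp_path / "p.csv"
        write_cohort(tiny_cohort, sp, pp)
        df = pd.read_csv(sp)
        df.loc[0, "ventilation_type"] = "telepathy"
        df.to_csv(sp, index=False)
        with pytest.raises(CohortValidationError, match="ventilation_type"):
            read_cohort(sp, pp)

    def test_missing_numeric_imputed_with_warning(self, tiny_cohort, tmp_path):
        sp, pp = tmp_path / "s.csv", tmp_path / "p.csv"
        write_cohort(tiny_cohort, sp, pp)
        df = pd.read_csv(sp)
        df.loc[0, "age"] = np.nan
        df.to_csv(sp, index=False)
        with pytest.warns(UserWarning, match="age"):
            back = read_cohort(sp, pp)
        assert back[0].age == pytest.approx(df["age"].median())


class TestRatioFeatures:
    def _record(self, flow, sweep, bmi=25.0):
        k = len(flow)
        perf = np.column_stack([
            np.full(k, 15.0), np.full(k, -60.0), np.asarray(flow, float),
            np.full(k, 3000.0), np.asarray(sweep, float),
            np.arange(1, k + 1) * 120.0,
        ])
        return PatientRecord(
            patient_id="x", outcome=1, age=50, sex="female", bmi=bmi,
            cause="other", arrest_pre_ecmo=0, shock_pre_ecmo=0,
            reinfusion_site="right_ij", drainage_site="femoral",
            reinfusion_size=21, drainage_size=25,
            ventilation_type="volume_control",
            times=np.arange(1, k + 1) * 120.0, perfusion=perf)

    def test_ratio_arithmetic(self):
        rec = derive_ratio_features(self._record([5.0, 5.0], [4.0, 4.0]))
        assert rec.channels == ALL_CHANNELS
        i_fb = rec.channels.index("flow_per_bmi")
        i_sf = rec.channels.index("sweep_per_flow")
        np.testing.assert_allclose(rec.perfusion[:, i_fb], 0.2)
        np.testing.assert_allclose(rec.perfusion[:, i_sf], 0.8)

    def test_zero_flow_gives_zero_ratio_not_inf(self):
        rec = derive_ratio_features(self._record([0.0, 5.0], [2.0, 4.0]))
        col = rec.perfusion[:, rec.channels.index("sweep_per_flow")]
        np.testing.assert_allclose(col, [0.0, 0.8])

    def test_original_channels_untouched(self):
        base = self._record([3.0, 4.0], [2.0, 6.0])
        rec = derive_ratio_features(base)
        np.testing.assert_array_equal(rec.perfusion[:, :6], base.perfusion)


class TestTruncation:
    def test_count_is_patients_times_fractions(self, tiny_cohort):
        runs = truncate_runs(tiny_cohort)
        assert len(runs) == len(tiny_cohort) * len(DEFAULT_FRACTIONS)

    def test_full_fraction_is_identity(self, tiny_cohort):
        (run,) = truncate_runs(tiny_cohort[:1], fractions=[1.0])
        np.testing.assert_array_equal(run.values, tiny_cohort[0].perfusion)

    def test_prefix_definition(self, tiny_cohort):
        rec = tiny_cohort[0]
        k = rec.times.size
        (run,) = truncate_runs([rec], fractions=[0.1])
        assert run.times.size == int(np.ceil(0.1 * k))
        np.testing.assert_array_equal(run.values, rec.perfusion[:run.times.size])

    def test_end_day_nondecreasing_in_fraction(self, tiny_cohort):
        runs = truncate_runs(tiny_cohort)
        for pid in {r.patient_id for r in tiny_cohort}:
            mine = sorted((r for r in runs if r.patient_id == pid),
                          key=lambda r: r.truncation_fraction)
            days = [r.end_day for r in mine]
            assert days == sorted(days)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_fraction_rejected(self, tiny_cohort, bad):
        with pytest.raises(ValueError):
            truncate_runs(tiny_cohort, fractions=[bad])


class TestStandardizeLength:
    def test_identity_when_lengths_match(self, rng):
        x = rng.normal(size=(16, 3))
        np.testing.assert_allclose(standardize_length(x, 16), x)

    def test_dense_slots_average(self, rng):
        x = rng.normal(size=(20, 2))
        out = standardize_length(x, 10)
        np.testing.assert_allclose(out, (x[0::2] + x[1::2]) / 2)

    def test_empty_series_is_zero_matrix(self):
        out = standardize_length(np.empty((0, 4)), 7)
        np.testing.assert_array_equal(out, np.zeros((7, 4)))

    def test_matches_binning_oracle_on_random_inputs(self, rng):
        for _ in range(1000):
            K = int(rng.integers(0, 40))
            V = int(rng.integers(1, 4))
            T = int(rng.integers(1, 30))
            x = rng.normal(size=(K, V))
            np.testing.assert_allclose(standardize_length(x, T),
                                       binning_oracle(x, T), atol=1e-12)

    def test_sparse_series_forward_fills(self):
        x = np.array([[1.0], [5.0]])
        out = standardize_length(x, 6)
        # points land on slots 0 and 3; gaps carry the previous value
        np.testing.assert_allclose(out.ravel(), [1, 1, 1, 5, 5, 5])


class TestStaticEncoding:
    def test_width_and_determinism(self, tiny_cohort):
        vec = encode_static(tiny_cohort[0])
        assert vec.shape == (32,)
        np.testing.assert_array_equal(vec, encode_static(tiny_cohort[0]))

    def test_outcome_not_encoded(self, tiny_cohort):
        from dataclasses import replace
        rec = tiny_cohort[0]
        flipped = replace(rec, outcome=1 - rec.outcome)
        np.testing.assert_array_equal(encode_static(rec), encode_static(flipped))

    def test_unknown_level_rejected(self, tiny_cohort):
        from dataclasses import replace
        bad = replace(tiny_cohort[0], cause="bad_vibes")
        with pytest.raises(CohortValidationError, match="cause"):
            encode_static(bad)

    def test_row_order_invariance_through_io(self, tiny_cohort, tmp_path):
        sp, pp = tmp_path / "s.csv", tmp_path / "p.csv"
        write_cohort(tiny_cohort, sp, pp)
        pd.read_csv(sp).iloc[::-1].to_csv(sp, index=False)
        pd.read_csv(pp).iloc[::-1].to_csv(pp, index=False)
        back = {r.patient_id: r for r in read_cohort(sp, pp)}
        for rec in tiny_cohort:
            np.testing.assert_allclose(encode_static(back[rec.patient_id]),
                                       encode_static(rec), rtol=1e-12)


class TestScaler:
    def test_train_min_max_map_to_unit_interval(self, tiny_samples):
        params = fit_scaler(tiny_samples)
        scaled = apply_scaler(params, tiny_samples)
        stacked = np.concatenate([s.series for s in scaled])
        raw = np.concatenate([s.series for s in tiny_samples])
        for v in range(stacked.shape[1]):
            if raw[:, v].max() > raw[:, v].min():
                assert stacked[:, v].min() == pytest.approx(0.0)
                assert stacked[:, v].max() == pytest.approx(1.0)

    def test_constant_feature_maps_to_zero(self, tiny_samples):
        from dataclasses import replace
        frozen = [replace(s, series=np.full_like(s.series, 3.3))
                  for s in tiny_samples[:4]]
        params = fit_scaler(frozen)
        out = apply_scaler(params, frozen)
        assert all(np.all(s.series == 0.0) for s in out)

    def test_no_clipping_outside_training_range(self, tiny_samples):
        from dataclasses import replace
        params = fit_scaler(tiny_samples[:6])
        hot = replace(tiny_samples[0],
                      series=tiny_samples[0].series + 1e4)
        (out,) = apply_scaler(params, [hot])
        assert out.series.max() > 1.0

    def test_unfitted_params_raise(self, tiny_samples):
        from cevvo.cohort import ScalerParams
        with pytest.raises(RuntimeError):
            apply_scaler(ScalerParams(), tiny_samples)

    def test_scale_unscale_roundtrip(self, tiny_samples):
        params = fit_scaler(tiny_samples)
        scaled = apply_scaler(params, tiny_samples)
        for orig, sc in zip(tiny_samples[:5], scaled[:5]):
            back = unscale(params, sc.series)
            span = params.series_max > params.series_min
            np.testing.assert_allclose(back[:, span], orig.series[:, span],
                                       atol=1e-12, rtol=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(1, 60), st.integers(1, 40), st.integers(0, 2 ** 32 - 1))
def test_standardize_spans_full_grid(K, T, seed):
    """Slot 0 is always filled and no trailing gap is left unfilled."""
    x = np.random.default_rng(seed).normal(size=(K, 1))
    out = standardize_length(x, T)
    assert out.shape == (T, 1)
    assert out[0, 0] == pytest.approx(np.mean(x[(np.arange(K) * T) // K == 0]))
    # last slot equals the mean of the points mapped at/before it (ffill)
    assert np.isfinite(out).all()


def test_pipeline_sample_counts_and_shapes(tiny_cohort):
    samples = build_samples(tiny_cohort, fractions=(0.5, 1.0), T=16)
    assert len(samples) == 2 * len(tiny_cohort)
    assert all(s.series.shape == (16, 8) for s in samples)
    assert all(s.static_vec.shape == (32,) for s in samples)
    assert all(s.end_day >= 0 for s in samples)
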