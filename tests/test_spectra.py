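"""Preprocessing chain: acquisition arithmetic, lactate referencing,
weight normalization, bucketing and unit-variance scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netmet.spectra import (AcquisitionParams, ReferencingError, Spectrum,
                            bucket, build_bucket_table, cpmg_total_length,
                            fid_acquisition_time, normalize_by_weight,
                            read_spectrum, reference_to_lactate,
                            scale_unit_variance, write_spectrum)

STEP = 0.0005


def _axis(lo=0.6, hi=8.0):
    return np.arange(lo, hi + STEP / 2, STEP)


def _doublet(center, split=0.014, gamma=0.001, amp=100.0, axis=None):
    x = _axis() if axis is None else axis
    y = np.zeros_like(x)
    for c in (center - split / 2, center + split / 2):
        y += amp * gamma**2 / ((x - c) ** 2 + gamma**2)
    return Spectrum(ppm=x, intensity=y, weight_mg=17.0, sample_id="d")


class TestAcquisitionArithmetic:
    def test_printed_protocol_values(self):
        acq = AcquisitionParams()
        assert cpmg_total_length(acq) == pytest.approx(0.09348)
        assert fid_acquisition_time(acq) == pytest.approx(2.307, abs=5e-4)

    def test_degenerate_inputs(self):
        assert cpmg_total_length(AcquisitionParams(n_loops=0)) == 0
        assert fid_acquisition_time(AcquisitionParams(n_points=0)) == 0

    def test_simple_arithmetic_cases(self):
        assert cpmg_total_length(
            AcquisitionParams(n_loops=100, inter_pulse_delay_s=1e-3)
        ) == pytest.approx(0.1)
        assert fid_acquisition_time(
            AcquisitionParams(n_points=8192, sweep_width_ppm=10,
                              spectrometer_freq_MHz=500)
        ) == pytest.approx(0.8192)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        loops=st.integers(1, 10000),
        delay=st.floats(1e-6, 1e-2),
        npts=st.integers(1, 10**6),
        sw=st.floats(1.0, 30.0),
        freq=st.floats(100.0, 1200.0),
    )
    def test_matches_hand_formula(self, loops, delay, npts, sw, freq):
        acq = AcquisitionParams(n_loops=loops, inter_pulse_delay_s=delay,
                                n_points=npts, sweep_width_ppm=sw,
                                spectrometer_freq_MHz=freq)
        assert cpmg_total_length(acq) == pytest.approx(loops * delay)
        assert fid_acquisition_time(acq) == pytest.approx(
            npts / (2 * sw * freq))


class TestReferencing:
    def test_misplaced_doublet_lands_on_target(self):
        s = reference_to_lactate(_doublet(1.35))
        mask = (s.ppm > 1.2) & (s.ppm < 1.5)
        peak_region = s.ppm[mask][np.argsort(s.intensity[mask])[-2:]]
        assert peak_region.mean() == pytest.approx(1.33, abs=2 * STEP)

    def test_doublet_already_on_target_is_untouched(self):
        s0 = _doublet(1.33)
        s = reference_to_lactate(s0)
        assert abs(s.meta["referencing_shift_ppm"]) <= STEP
        np.testing.assert_allclose(s.intensity, s0.intensity)

    def test_flat_spectrum_raises(self):
        x = _axis()
        flat = Spectrum(ppm=x, intensity=np.zeros_like(x), weight_mg=17.0)
        with pytest.raises(ReferencingError):
            reference_to_lactate(flat)

    def test_singlet_has_no_plausible_splitting(self):
        x = _axis()
        y = 100 * 0.001**2 / ((x - 1.33) ** 2 + 0.001**2)
        with pytest.raises(ReferencingError):
            reference_to_lactate(Spectrum(ppm=x, intensity=y, weight_mg=17.0))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(delta=st.floats(-0.05, 0.05))
    def test_translation_equivariance(self, delta):
        base = _doublet(1.36)
        shifted = Spectrum(ppm=base.ppm + delta, intensity=base.intensity,
                           weight_mg=base.weight_mg)
        a = reference_to_lactate(base)
        b = reference_to_lactate(shifted)
        np.testing.assert_allclose(a.ppm, b.ppm, atol=1.5 * STEP)


class TestWeightNormalization:
    def test_divides_by_weight_once(self):
        s = _doublet(1.33)
        n1 = normalize_by_weight(s)
        np.testing.assert_allclose(n1.intensity, s.intensity / 17.0)
        n2 = normalize_by_weight(n1)  # idempotent via state flag
        np.testing.assert_allclose(n2.intensity, n1.intensity)

    def test_weight_one_is_identity(self):
        x = _axis()
        s = Spectrum(ppm=x, intensity=np.ones_like(x), weight_mg=1.0)
        np.testing.assert_allclose(normalize_by_weight(s).intensity,
                                   s.intensity)

    def test_weight_ratio_propagates(self):
        a = _doublet(1.33)
        b = Spectrum(ppm=a.ppm, intensity=a.intensity, weight_mg=34.0)
        ra = normalize_by_weight(a).intensity
        rb = normalize_by_weight(b).intensity
        np.testing.assert_allclose(ra, 2 * rb)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(ppm=_axis(), intensity=np.zeros_like(_axis()),
                     weight_mg=0.0)


class TestBucketing:
    def test_default_range_yields_680_buckets(self):
        edges, values = bucket(_doublet(1.33))
        assert len(values) == 680
        assert edges[0] == pytest.approx(7.50)
        assert edges[-1] == pytest.approx(0.70)

    def test_constant_intensity_fills_buckets_uniformly(self):
        x = _axis()
        s = Spectrum(ppm=x, intensity=np.ones_like(x), weight_mg=1.0)
        _, values = bucket(s)
        np.testing.assert_allclose(values, 0.01, rtol=1e-9)

    def test_uncovered_range_raises(self):
        x = _axis(1.0, 5.0)
        s = Spectrum(ppm=x, intensity=np.ones_like(x), weight_mg=1.0)
        with pytest.raises(ValueError, match="cover"):
            bucket(s)

    def test_width_must_divide_range(self):
        with pytest.raises(ValueError, match="divide"):
            bucket(_doublet(1.33), 0.70, 7.50, 0.013)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_bucket_sum_conserves_total_integral(self, seed):
        rng = np.random.default_rng(seed)
        x = _axis()
        y = rng.normal(size=x.shape).cumsum() * 0.01 + rng.normal(size=x.shape)
        s = Spectrum(ppm=x, intensity=y, weight_mg=1.0)
        _, values = bucket(s)
        total = np.trapezoid(
            np.interp(np.linspace(0.70, 7.50, 13601), x, y),
            np.linspace(0.70, 7.50, 13601),
        )
        # conservation against the cumulative integral itself
        from netmet.spectra import _cumulative_integral
        F = _cumulative_integral(s)
        exact = F(7.50) - F(0.70)
        assert values.sum() == pytest.approx(exact, rel=1e-9, abs=1e-12)
        assert values.sum() == pytest.approx(total, rel=5e-3, abs=1e-6)


class TestScaling:
    def _table(self, values):
        from netmet.spectra import BucketTable
        n = values.shape[1]
        bounds = np.column_stack([np.arange(n), np.arange(n) + 1])[::-1]
        return BucketTable(sample_ids=[f"s{i}" for i in range(len(values))],
                           bucket_bounds=bounds.astype(float), values=values)

    def test_columns_become_unit_variance(self):
        rng = np.random.default_rng(0)
        t = scale_unit_variance(self._table(rng.normal(size=(10, 4))))
        np.testing.assert_allclose(t.values.std(axis=0, ddof=1), 1.0)
        np.testing.assert_allclose(t.values.mean(axis=0), 0.0, atol=1e-12)

    def test_constant_column_zeroed_and_flagged(self):
        vals = np.random.default_rng(1).normal(size=(8, 3))
        vals[:, 1] = 5.0
        t = scale_unit_variance(self._table(vals))
        assert np.all(t.values[:, 1] == 0)
        assert list(t.meta["zero_variance_columns"]) == [1]

    def test_scaling_is_idempotent(self):
        vals = np.random.default_rng(2).normal(size=(6, 3))
        once = scale_unit_variance(self._table(vals))
        twice = scale_unit_variance(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            scale_unit_variance(self._table(np.ones((1, 3))))


def test_spectrum_text_roundtrip(tmp_path):
    s = _doublet(1.33)
    s.meta["note"] = "synthetic"
    write_spectrum(s, tmp_path / "s.txt")
    back = read_spectrum(tmp_path / "s.txt")
    np.testing.assert_allclose(back.ppm, s.ppm, atol=1e-6)
    assert back.weight_mg == s.weight_mg
    assert back.meta["note"] == "synthetic"


def test_descending_axis_is_normalized_to_ascending():
    x = _axis()
    s = Spectrum(ppm=x[::-1], intensity=np.arange(len(x), dtype=float),
                 weight_mg=1.0)
    assert s.ppm[0] < s.ppm[-1]
    assert s.intensity[0] == len(x) - 1
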