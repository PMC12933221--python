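from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hrmsqc import (
    EIC,
    QCConfig,
    Run,
    Spectrum,
    accept_peak,
    estimate_baseline_noise,
    extract_eic,
    find_apex,
    measure_compound,
    measure_mass_error,
    smooth_eic,
)
from hrmsqc.synthetic import ScenarioConfig, simulate_run

T0 = datetime(2024, 1, 1, tzinfo=timezone.utc)


def _eic(values, dt=1.0, t_start=0.0):
    values = np.asarray(values, float)
    return EIC(
        rts=t_start + dt * np.arange(values.size),
        intensities=values,
        target_mz=124.0807,
        ppm_window=20.0,
    )


def _run_from_scans(scan_data, dt=1.0):
    """scan_data: list of (mz_array, intensity_array) per MS1 scan."""
    spectra = [
        Spectrum(1, i * dt, np.asarray(mz, float), np.asarray(inten, float))
        for i, (mz, inten) in enumerate(scan_data)
    ]
    return Run(path="mem", acquired_at=T0, sample_type="sample", spectra=spectra)


def _savgol_quadratic_oracle(y):
    """Independent least-squares oracle: fit a quadratic to each 5-point
    window and evaluate at the point's own position (asymmetric fits at
    the edges)."""
    y = np.asarray(y, float)
    n = y.size
    out = np.empty(n)
    for i in range(n):
        lo = min(max(i - 2, 0), n - 5)
        xs = np.arange(lo, lo + 5)
        coeffs = np.polyfit(xs, y[lo : lo + 5], 2)
        out[i] = np.polyval(coeffs, i)
    return out


class TestSmoothing:
    def test_classic_interior_weights_from_impulse(self):
        # one pass over an impulse exposes the (-3, 12, 17, 12, -3)/35 kernel
        # at the interior points (the outer two points use asymmetric fits)
        sm = smooth_eic(_eic([0, 0, 0, 0, 35, 0, 0, 0, 0]), passes=1)
        np.testing.assert_allclose(
            sm.intensities[2:7], [-3.0, 12.0, 17.0, 12.0, -3.0], atol=1e-9
        )

    @pytest.mark.parametrize("passes", [1, 2])
    @pytest.mark.parametrize(
        "coeffs", [(7.0, 0.0, 0.0), (0.0, 1.0, 0.0), (2.0, -3.0, 0.5)]
    )
    def test_polynomials_up_to_degree_two_are_fixed_points(self, passes, coeffs):
        x = np.arange(11.0)
        a, b, c = coeffs
        y = a + b * x + c * x * x
        sm = smooth_eic(_eic(y), passes=passes)
        np.testing.assert_allclose(sm.intensities, y, atol=1e-9)

    def test_matches_least_squares_oracle_on_noise(self):
        rng = np.random.default_rng(42)
        y = rng.uniform(0, 1000, 40)
        sm = smooth_eic(_eic(y), passes=1)
        np.testing.assert_allclose(sm.intensities, _savgol_quadratic_oracle(y), atol=1e-8)

    @given(st.integers(0, 2**31 - 1), st.integers(5, 60))
    def test_length_preserved(self, seed, n):
        y = np.random.default_rng(seed).uniform(0, 100, n)
        assert len(smooth_eic(_eic(y))) == n

    def test_short_series_returned_unsmoothed_and_flagged(self):
        e = _eic([1, 2, 3])
        sm = smooth_eic(e)
        assert not sm.smoothed
        np.testing.assert_array_equal(sm.intensities, e.intensities)


class TestExtractEic:
    def test_window_is_ppm_relative_and_inclusive(self):
        mz0 = 124.0807
        edge = mz0 * (1 + 20e-6)  # exactly on the boundary
        beyond = mz0 * (1 + 21e-6)
        run = _run_from_scans([([mz0, edge, beyond], [10.0, 5.0, 100.0])])
        eic = extract_eic(run, mz0, ppm=20.0, rt_center=0.0, half_window=5.0)
        assert eic.intensities[0] == 15.0  # boundary in, 21 ppm out, in-window summed

    def test_zero_intensity_scans_give_zero_eic_of_full_length(self):
        run = _run_from_scans([([100.0], [0.0])] * 7)
        eic = extract_eic(run, 100.0, 20.0, rt_center=3.0, half_window=3.0)
        assert len(eic) == 7
        assert not eic.intensities.any()

    def test_no_scans_in_window_gives_empty_eic(self):
        run = _run_from_scans([([100.0], [1.0])])
        eic = extract_eic(run, 100.0, 20.0, rt_center=500.0, half_window=5.0)
        assert len(eic) == 0


class TestFindApex:
    def test_gaussian_apex_within_one_scan_interval(self):
        t = np.arange(0, 60.0, 0.5)
        y = 1e5 * np.exp(-((t - 30.2) ** 2) / (2 * 9.0))
        eic = EIC(rts=t, intensities=y, target_mz=100.0, ppm_window=20.0)
        apex_rt, _ = find_apex(smooth_eic(eic), expected_rt=30.0, search_half=13.5)
        assert abs(apex_rt - 30.2) <= 0.5

    def test_all_zero_eic_gives_none(self):
        assert find_apex(_eic([0, 0, 0, 0, 0]), 2.0, 5.0) is None

    def test_tie_breaks_to_earlier_rt(self):
        eic = _eic([0, 5, 0, 5, 0])
        apex_rt, idx = find_apex(eic, 2.0, 5.0)
        assert (apex_rt, idx) == (1.0, 1)

    def test_search_window_respected(self):
        eic = _eic([1, 1, 1, 1, 100])  # max outside +/-2 s of expected 1.0
        apex_rt, _ = find_apex(eic, expected_rt=1.0, search_half=2.0)
        assert apex_rt <= 3.0


class TestBaselineNoise:
    def _eic_with_windows(self, pre, post, between=None):
        # apex at t=100; pre window [70, 85), post (115, 130]
        rts, vals = [], []
        for i, v in enumerate(pre):
            rts.append(70.0 + i * (15.0 / len(pre)))
            vals.append(v)
        rts.append(100.0)
        vals.append(between if between is not None else 1000.0)
        for i, v in enumerate(post):
            rts.append(130.0 - (len(post) - 1 - i) * (15.0 / len(post)))
            vals.append(v)
        return EIC(np.array(rts), np.array(vals, float), 100.0, 20.0)

    def test_quieter_window_supplies_baseline_and_noise(self, cfg):
        eic = self._eic_with_windows([10, 12, 11, 10], [50, 10, 55, 12])
        baseline, noise, ok = estimate_baseline_noise(eic, 100.0, cfg)
        assert ok
        assert noise == pytest.approx(2.0)       # pre-window max-min
        assert baseline == pytest.approx(10.75)  # mean of the quieter window

    def test_constant_windows(self, cfg):
        eic = self._eic_with_windows([5, 5, 5], [5, 5, 5])
        baseline, noise, ok = estimate_baseline_noise(eic, 100.0, cfg)
        assert (baseline, noise, ok) == (5.0, 0.0, True)

    def test_coeluting_peak_in_post_window_ignored(self, cfg):
        # isobaric co-elution raises the post-window spread; pre wins
        eic = self._eic_with_windows([100, 102, 101, 100], [100, 5000, 9000, 400])
        baseline, noise, _ = estimate_baseline_noise(eic, 100.0, cfg)
        assert noise == pytest.approx(2.0)
        assert baseline == pytest.approx(100.75)

    def test_single_point_window_excluded(self, cfg):
        eic = self._eic_with_windows([7], [20, 30, 25, 20])
        baseline, noise, ok = estimate_baseline_noise(eic, 100.0, cfg)
        assert ok and noise == pytest.approx(10.0) and baseline == pytest.approx(23.75)

    def test_both_windows_missing_flags_low_confidence(self, cfg):
        eic = _eic([1000.0], t_start=100.0)
        baseline, noise, ok = estimate_baseline_noise(eic, 100.0, cfg)
        assert (baseline, noise, ok) == (0.0, 0.0, False)


class TestAcceptance:
    def _window(self, n_above, baseline=0.0, noise=10.0, n_total=19):
        vals = [baseline + 2 * noise + 1.0] * n_above
        vals += [baseline] * (n_total - n_above)
        return _eic(vals)

    def test_good_peak_accepted(self, cfg):
        accepted, sn, pts = accept_peak(100.0, 0.0, 10.0, self._window(7), cfg)
        assert accepted and sn == pytest.approx(10.0) and pts == 7

    def test_low_sn_rejected_despite_points(self, cfg):
        accepted, sn, _ = accept_peak(40.0, 0.0, 10.0, self._window(9), cfg)
        assert not accepted and sn == pytest.approx(4.0)

    def test_too_few_points_rejected_despite_sn(self, cfg):
        accepted, _, pts = accept_peak(100.0, 0.0, 10.0, self._window(4), cfg)
        assert not accepted and pts == 4

    def test_zero_noise_treated_as_infinite_sn(self, cfg):
        accepted, sn, _ = accept_peak(100.0, 0.0, 0.0, self._window(6, noise=0.0), cfg)
        assert accepted and sn == float("inf")

    @given(st.floats(51.0, 1e6))
    def test_monotone_in_height(self, cfg, height):
        window = self._window(7)
        base, _, _ = accept_peak(51.0, 0.0, 10.0, window, cfg)
        bigger, _, _ = accept_peak(height, 0.0, 10.0, window, cfg)
        assert base and bigger  # raising height never flips accepted -> rejected


class TestMassError:
    def _run_at_ppm(self, ppm_offset, mz0=124.0807, n=5):
        mz = mz0 * (1 + ppm_offset * 1e-6)
        return _run_from_scans([([mz], [100.0])] * n)

    def test_plus_ten_ppm(self, cfg):
        mean_mz, err = measure_mass_error(self._run_at_ppm(10.0), 2.0, 124.0807, cfg)
        assert err == pytest.approx(10.0, abs=0.05)
        assert (mean_mz - 124.0807) * 1000 == pytest.approx(1.24, abs=0.01)  # mDa

    def test_exact_mass_gives_zero(self, cfg):
        _, err = measure_mass_error(self._run_at_ppm(0.0), 2.0, 124.0807, cfg)
        assert err == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(-15.0, 15.0))
    def test_sign_convention_symmetric(self, cfg, e):
        _, err = measure_mass_error(self._run_at_ppm(e), 2.0, 124.0807, cfg)
        assert err == pytest.approx(e, rel=1e-6, abs=1e-6)

    def test_most_intense_centroid_per_scan_wins(self, cfg):
        mz0 = 200.0
        scans = [([mz0 * (1 + 5e-6), mz0 * (1 + 9e-6)], [10.0, 900.0])] * 5
        _, err = measure_mass_error(_run_from_scans(scans), 2.0, mz0, cfg)
        assert err == pytest.approx(9.0, abs=1e-6)

    def test_no_qualifying_centroid_returns_none(self, cfg):
        run = _run_from_scans([([300.0], [5.0])] * 5)
        assert measure_mass_error(run, 2.0, 124.0807, cfg) is None


class TestMeasureCompound:
    def test_nominal_run_detects_all_standards(self, standards, cfg):
        run = simulate_run(ScenarioConfig(seed=5), 1, standards)
        ms = [measure_compound(run, s, cfg=cfg) for s in standards]
        assert all(m.detected for m in ms)
        for m, s in zip(ms, standards):
            assert abs(m.apex_rt - s.expected_rt) < 5.0
            assert m.height > 0
            assert abs(m.mass_error) < 2.0

    def test_height_is_smoothed_apex_minus_baseline(self, standards, cfg):
        run = simulate_run(ScenarioConfig(seed=5), 1, standards)
        m = measure_compound(run, standards[0], cfg=cfg)
        assert m.height >= 0
        # reported height consistent with a ~1e5-count peak over a ~500 baseline
        assert 0.5e5 < m.height + m.baseline < 2e5

    def test_shift_beyond_search_window_not_detected(self, standards, cfg):
        lido = next(s for s in standards if s.identifier == "lidocaine_d10")
        run = simulate_run(ScenarioConfig(seed=5), 1, standards)
        m = measure_compound(run, lido, corrected_rt=lido.expected_rt - 40.0, cfg=cfg)
        assert not m.detected

    def test_empty_run_all_undetected(self, standards, cfg):
        empty = Run(path="e", acquired_at=T0, sample_type="sample", spectra=[])
        ms = [measure_compound(empty, s, cfg=cfg) for s in standards]
        assert not any(m.detected for m in ms)
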