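"""Preprocessing chain: OD conversion, motion flagging, band-pass filter,
DPF, and MBLL inversion — each checked against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vrnirs.errors import InvalidInputError, InvalidParameterError
from vrnirs.optics import (
    WAVELENGTHS_NM,
    ExtinctionTable,
    dpf_for_age,
    mbll_forward,
)
from vrnirs.preprocess import (
    FilterParams,
    MotionParams,
    OpticalDensitySeries,
    RawRecording,
    bandpass_filter,
    detect_motion_artifacts,
    intensity_to_od,
    od_to_hemoglobin,
    run_preprocessing,
)

FS = 10.0


def _recording(intensity, **kw):
    return RawRecording(intensity=intensity, sampling_rate=FS, events=[],
                        subject_age=47.0, **kw)


def _od_series(x_single_channel):
    """Wrap a 1-D array as a (1 ch, 2 wl, T) OD series (both wavelengths
    identical)."""
    od = np.stack([x_single_channel, x_single_channel])[None, :, :]
    mask = np.zeros((1, x_single_channel.size), dtype=bool)
    return OpticalDensitySeries(od, mask, FS)


class TestIntensityToOD:
    def test_constant_intensity_gives_zero_od(self):
        raw = _recording(np.full((8, 2, 100), 3.7))
        assert np.allclose(intensity_to_od(raw).od, 0.0)

    def test_half_mean_sample_gives_ln2(self):
        # one sample at mean/2 once the record mean is taken into account
        I = np.full(1000, 2.0)
        I[500] = 1.0  # mean = 1.999; construct exactly: use analytic check below
        raw = _recording(np.tile(I, (8, 2, 1)))
        od = intensity_to_od(raw).od
        expected = -np.log(1.0 / I.mean())
        assert od[0, 0, 500] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(np.log(2), abs=2e-3)

    @given(arrays(float, 64, elements=st.floats(0.1, 10.0)))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_sample_by_sample(self, samples):
        raw = _recording(np.tile(samples, (8, 2, 1)))
        od = intensity_to_od(raw).od
        mean = samples.mean()
        brute = np.array([-np.log(s / mean) for s in samples])
        assert np.max(np.abs(od[3, 1] - brute)) < 1e-12

    def test_nonpositive_intensity_names_channel_and_sample(self):
        I = np.ones((8, 2, 50))
        I[2, 0, 7] = -1.0
        with pytest.raises(InvalidInputError, match="channel 3.*sample 7"):
            intensity_to_od(_recording(I))

    def test_od_time_mean_nonnegative(self, rng):
        # Jensen: mean of -log(I/mean I) >= 0
        I = rng.uniform(0.5, 2.0, (8, 2, 400))
        od = intensity_to_od(_recording(I)).od
        assert np.all(od.mean(axis=2) >= -1e-12)


def brute_force_motion_mask(x, fs, p: MotionParams):
    """Direct window scan implementing the flagging rule."""
    n = x.size
    w = int(round(p.t_motion * fs))
    pad = int(round(p.t_mask * fs))
    d = np.diff(x)
    sd_record = d.std()
    flagged = np.zeros(n, bool)
    for start in range(n - w + 1):
        win = x[start:start + w]
        hit = (win.max() - win.min()) > p.amp_thresh
        if not hit and sd_record > 0 and w >= 3:
            hit = np.std(d[start:start + w - 1]) > p.sd_thresh * sd_record
        if hit:
            flagged[start:start + w] = True
    out = np.zeros(n, bool)
    for i in np.nonzero(flagged)[0]:
        out[max(i - pad, 0):i + pad + 1] = True
    return out


class TestMotionDetection:
    def test_constant_od_gives_empty_mask(self):
        mask = detect_motion_artifacts(_od_series(np.zeros(500)))
        assert not mask.any()

    def test_step_above_amplitude_threshold_masks_step_plus_1s(self):
        x = np.zeros(600)
        x[300:] = 0.2  # > 0.1 OD criterion
        mask = detect_motion_artifacts(_od_series(x))[0]
        assert mask[300]
        # covers at least +/- t_mask around the jump
        assert mask[300 - 10] and mask[300 + 10]
        assert not mask[0] and not mask[-1]

    def test_amplitude_boundary_is_strict_inequality(self):
        # SD criterion disabled (huge sd_thresh) to isolate the amp rule
        p = MotionParams(sd_thresh=1e9)
        for step, expect in ((0.1, False), (0.1 + 1e-6, True)):
            x = np.zeros(600)
            x[300:] += step
            mask = detect_motion_artifacts(_od_series(x), p)[0]
            brute = brute_force_motion_mask(x, FS, p)
            assert np.array_equal(mask, brute)
            assert mask.any() == expect

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_oracle_on_random_signals(self, seed):
        r = np.random.default_rng(seed)
        x = np.cumsum(r.normal(0, 0.01, 300))
        x[r.integers(50, 250)] += r.uniform(0.05, 0.3)
        p = MotionParams()
        mask = detect_motion_artifacts(_od_series(x), p)[0]
        assert np.array_equal(mask, brute_force_motion_mask(x, FS, p))

    def test_mask_monotone_in_thresholds(self, rng):
        x = np.cumsum(rng.normal(0, 0.02, 400))
        loose = detect_motion_artifacts(_od_series(x), MotionParams())
        tight = detect_motion_artifacts(
            _od_series(x), MotionParams(amp_thresh=0.05, sd_thresh=2.5))
        assert np.all(tight | ~loose)  # loose mask subset of tight mask

    def test_window_shorter_than_two_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            detect_motion_artifacts(_od_series(np.zeros(100)),
                                    MotionParams(t_motion=0.1))


def butterworth_two_pass_gain(f, params: FilterParams):
    """Analytic |H|^2 magnitude oracle for the forward-backward band-pass
    (product of the low- and high-cut Butterworth responses, squared)."""
    lo = 1.0 / (1.0 + (params.low_cut / f) ** (2 * params.order))
    hi = 1.0 / (1.0 + (f / params.high_cut) ** (2 * params.order))
    return lo * hi  # one-pass power response == two-pass amplitude response


class TestBandpassFilter:
    def _tone_response(self, f):
        t = np.arange(int(3000 * FS)) / FS
        x = np.sin(2 * np.pi * f * t)
        out = bandpass_filter(_od_series(x)).od[0, 0]
        # the 0.01 Hz edge's poles ring for hundreds of seconds: keep the
        # central third only
        core = slice(int(1000 * FS), int(2000 * FS))
        return np.sqrt(np.mean(out[core] ** 2)) / np.sqrt(0.5)

    def test_dc_offset_removed(self):
        out = bandpass_filter(_od_series(np.full(2000, 5.0))).od
        assert np.max(np.abs(out)) < 5.0 * 1e-2  # > 40 dB attenuation at DC

    def test_cardiac_tone_attenuated_at_least_60db(self):
        amp = self._tone_response(1.0)
        assert amp < 1e-3
        # consistent with the analytic two-pass magnitude oracle
        analytic = butterworth_two_pass_gain(1.0, FilterParams())
        assert amp < 10 * analytic + 1e-6

    def test_midband_tone_preserved_within_5pct(self):
        amp = self._tone_response(0.05)
        analytic = butterworth_two_pass_gain(0.05, FilterParams())
        assert abs(amp - 1.0) < 0.05
        assert amp == pytest.approx(analytic, abs=0.02)

    def test_output_length_and_mask_preserved(self, rng):
        x = rng.normal(size=777)
        series = _od_series(x)
        series.motion_mask[0, 5:10] = True
        out = bandpass_filter(series)
        assert out.od.shape == series.od.shape
        assert np.array_equal(out.motion_mask, series.motion_mask)

    def test_idempotent_in_band(self, rng):
        x = rng.normal(size=6000)
        once = bandpass_filter(_od_series(x))
        twice = bandpass_filter(once)
        core = slice(1000, 5000)
        num = np.linalg.norm(twice.od[0, 0, core] - once.od[0, 0, core])
        den = np.linalg.norm(once.od[0, 0, core])
        # re-filtering changes energy only near the band edges
        assert num / den < 0.35

    def test_high_cut_at_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            bandpass_filter(_od_series(np.zeros(100)),
                            FilterParams(high_cut=5.0))


class TestDpf:
    @pytest.mark.parametrize("wl", WAVELENGTHS_NM)
    def test_monotone_increasing_in_age(self, wl):
        assert dpf_for_age(60, wl) > dpf_for_age(30, wl)

    def test_cohort_age_band_values_are_compact(self):
        # ages spanning the cohort (mean 46.8, SD 11.86)
        ages = np.linspace(46.8 - 2 * 11.86, 46.8 + 2 * 11.86, 25)
        for wl, (lo, hi) in {760.0: (6.0, 7.5), 850.0: (5.0, 6.4)}.items():
            vals = [dpf_for_age(a, wl) for a in ages]
            assert lo < min(vals) and max(vals) < hi

    def test_continuity_in_age(self):
        for wl in WAVELENGTHS_NM:
            assert abs(dpf_for_age(50 + 1e-6, wl) - dpf_for_age(50, wl)) < 1e-4

    def test_unsupported_wavelength_rejected(self):
        with pytest.raises(InvalidParameterError):
            dpf_for_age(50, 690.0)

    def test_age_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            dpf_for_age(10, 760.0)


class TestMbll:
    def test_zero_od_gives_zero_concentrations(self):
        series = _od_series(np.zeros(50))
        hb = od_to_hemoglobin(series, age=47.0)
        assert np.allclose(hb.hbo, 0) and np.allclose(hb.hbr, 0)

    def test_forward_inverse_round_trip_exact(self, rng):
        hbo = rng.normal(0, 0.5, (8, 200))
        hbr = rng.normal(0, 0.2, (8, 200))
        od = mbll_forward(hbo, hbr, age=35.0, pathlength_cm=3.5)
        series = OpticalDensitySeries(od, np.zeros((8, 200), bool), FS)
        hb = od_to_hemoglobin(series, age=35.0, pathlength=3.5)
        assert np.max(np.abs(hb.hbo - hbo)) < 1e-9
        assert np.max(np.abs(hb.hbr - hbr)) < 1e-9

    def test_doubling_pathlength_halves_concentrations(self, rng):
        od = _od_series(rng.normal(0, 0.01, 100))
        hb1 = od_to_hemoglobin(od, age=47.0, pathlength=3.5)
        hb2 = od_to_hemoglobin(od, age=47.0, pathlength=7.0)
        assert np.allclose(hb2.hbo, hb1.hbo / 2)

    def test_singular_extinction_table_rejected(self):
        from vrnirs.errors import ConfigurationError

        bad = ExtinctionTable({760.0: {"hbo": 1.0, "hbr": 2.0},
                               850.0: {"hbo": 2.0, "hbr": 4.0}})
        with pytest.raises(ConfigurationError):
            bad.matrix()


class TestRunPreprocessing:
    def test_clean_recording_is_valid_with_zero_mask(self, quiet_recording):
        hb, qc = run_preprocessing(quiet_recording)
        assert qc.valid and qc.masked_fraction == 0.0

    def test_excluded_spans_above_ceiling_flag_invalid(self):
        I = np.ones((8, 2, 1000)) + 1e-6 * np.sin(np.arange(1000))
        raw = _recording(I, excluded_spans=[(0.0, 60.0)])  # 60% of 100 s
        hb, qc = run_preprocessing(raw)
        assert not qc.valid
        assert qc.masked_fraction == pytest.approx(0.6, abs=0.01)

    def test_filter_order_commutes_with_mbll(self, quiet_recording):
        # band-pass on OD then MBLL == MBLL then band-pass (linear maps)
        from vrnirs.preprocess import filter_timeseries

        od = intensity_to_od(quiet_recording)
        hb_a = od_to_hemoglobin(bandpass_filter(od), quiet_recording.subject_age)
        hb_b = od_to_hemoglobin(od, quiet_recording.subject_age)
        hbo_b = filter_timeseries(hb_b.hbo, FilterParams(), FS)
        assert np.max(np.abs(hb_a.hbo - hbo_b)) < 1e-9
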