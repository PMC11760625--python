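import numpy as np
import pytest

from oracles import (
    bruteforce_ampd_peaks,
    bruteforce_lms_zero_pattern,
    exhaustive_local_maxima,
    printed_index_zero_pattern,
)

from lfpseg.ampde import (
    AMPDEParams,
    LMSMatrix,
    _local_max_mask,
    ampde_detect,
    compute_lms,
    detect_peaks_lms,
    detrend_linear,
    lms_peaks,
    select_scale,
)
from lfpseg.core import DataError, LFPRecord, ParameterError


class TestDetrend:
    def test_exact_ramp_vanishes(self):
        x = 3.0 + 0.5 * np.arange(50)
        np.testing.assert_allclose(detrend_linear(x), 0.0, atol=1e-10)

    def test_projection_idempotence(self, rng):
        x = detrend_linear(rng.standard_normal(200))
        np.testing.assert_allclose(detrend_linear(x), x, atol=1e-10)

    def test_sine_recovered_from_ramp(self):
        t = np.arange(400)
        x = np.sin(2 * np.pi * t / 40) + 0.01 * t + 2.0
        out = detrend_linear(x)
        slope = np.polyfit(t, out, 1)[0]
        assert abs(slope) < 1e-10

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            detrend_linear(np.array([1.0]))


class TestComputeLMS:
    def test_triangle_apex_column_all_zero(self):
        x = np.array([0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0], dtype=float)
        lms = compute_lms(x)
        assert lms.values.shape == (5, 11)  # L = ceil(11/2) - 1
        assert (lms.values[:, 5] == 0).all()
        # brute-force double loop agrees cell by cell on the zero pattern
        for k in range(1, 6):
            expected = bruteforce_lms_zero_pattern(list(x), k)
            np.testing.assert_array_equal(lms.values[k - 1] == 0.0, expected)

    def test_monotone_sequence_has_no_zero_cells(self):
        lms = compute_lms(np.arange(20, dtype=float))
        assert not (lms.values == 0).any()

    def test_nonzero_cells_in_alpha_band(self, rng):
        alpha = 1.0
        lms = compute_lms(rng.standard_normal(40), alpha=alpha)
        nz = lms.values[lms.values != 0]
        assert ((nz >= alpha) & (nz <= alpha + 1)).all()

    def test_seed_contract(self, rng):
        x = rng.standard_normal(60)
        a = compute_lms(x, rng_seed=1)
        b = compute_lms(x, rng_seed=1)
        c = compute_lms(x, rng_seed=2)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.values == 0, c.values == 0)
        assert not np.array_equal(a.values, c.values)

    def test_short_segment_rejected(self):
        with pytest.raises(DataError):
            compute_lms(np.ones(3))


class TestScaleSelection:
    def test_zero_row_is_minimal(self, rng):
        values = rng.random((6, 30)) + 1.0
        values[2] = 0.0
        ss = select_scale(LMSMatrix(values, 1.0, 0))
        assert ss.lambda_scale == 3

    def test_tie_breaks_to_lower_scale(self):
        values = np.ones((4, 10))
        values[1] = 0.5
        values[3] = 0.5
        ss = select_scale(LMSMatrix(values, 1.0, 0))
        assert ss.lambda_scale == 2

    @pytest.mark.parametrize("period", [20, 50])
    def test_sine_selects_half_period(self, period):
        """For a periodic signal the winning scale sits at half the period
        (checked against the brute-force transcription as well)."""
        t = np.arange(5 * period)
        x = np.sin(2 * np.pi * t / period)
        _, _, lam, _ = lms_peaks(detrend_linear(x), 1.0, 0)
        assert abs(lam - period // 2) <= 1


class TestDetectPeaks:
    def test_triangle_single_apex(self):
        x = np.array([0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0], dtype=float)
        lms = compute_lms(x)
        lam = select_scale(lms).lambda_scale
        assert detect_peaks_lms(lms, lam) == [5]

    def test_monotone_segment_empty(self):
        lms = compute_lms(np.arange(30, dtype=float))
        lam = select_scale(lms).lambda_scale
        assert detect_peaks_lms(lms, lam) == []

    def test_lambda_out_of_range(self):
        lms = compute_lms(np.arange(10, dtype=float))
        with pytest.raises(ParameterError):
            detect_peaks_lms(lms, 99)

    def test_sine_peaks_at_crests(self):
        """Peaks coincide with the three-point maxima of a sine, except in
        the lambda-sample dead zone at the segment edges (boundary cells of
        the scalogram are nonzero by definition)."""
        period = 20
        t = np.arange(105)
        x = np.sin(2 * np.pi * (t - 10) / period)
        peaks, _, lam, _ = lms_peaks(x, 1.0, 0)
        crests = exhaustive_local_maxima(list(x))
        expected = [c for c in crests if lam <= c <= len(x) - lam - 1]
        assert len(peaks) == len(expected)
        assert all(abs(p - c) <= 1 for p, c in zip(peaks, expected))

    def test_lean_path_matches_materialized(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.standard_normal(int(r.integers(10, 150)))
            lms = compute_lms(x, 1.0, seed)
            ss = select_scale(lms)
            peaks, gamma, lam, _ = lms_peaks(x, 1.0, seed)
            assert lam == ss.lambda_scale
            np.testing.assert_allclose(gamma, ss.gamma)
            assert peaks == detect_peaks_lms(lms, lam)


class TestBruteForceEquivalence:
    def test_windowless_peaks_match_transcription(self):
        """Vectorized scan equals a literal double-loop transcription of the
        scalogram rules on short random signals of several shapes."""
        for seed in range(40):
            r = np.random.default_rng(seed)
            n = int(r.integers(10, 201))
            kind = seed % 3
            if kind == 0:
                x = r.standard_normal(n)
            elif kind == 1:
                x = np.cumsum(r.standard_normal(n))
            else:
                x = np.sin(2 * np.pi * np.arange(n) / max(8, n // 5))
                x = x + 0.3 * r.standard_normal(n)
            peaks, _, _, _ = lms_peaks(x, 1.0, seed)
            assert peaks == bruteforce_ampd_peaks(x, 1.0, seed)

    def test_printed_indexing_is_a_unit_shift(self, rng):
        """The alternative one-based neighbor indexing produces the same
        zero pattern shifted by one sample."""
        x = rng.standard_normal(60)
        for k in (1, 2, 5, 10):
            centered = bruteforce_lms_zero_pattern(list(x), k)
            printed = printed_index_zero_pattern(list(x), k)
            assert printed[1:] == centered[:-1]


class TestWindowedDetect:
    def test_sine_windowed_peaks(self):
        """Windowed detection finds every crest outside each window's
        lambda-sample edge dead zone, one detection per crest."""
        fs, f0, win = 100.0, 1.0, 2.0
        n = 1000
        x = np.sin(2 * np.pi * f0 * (np.arange(n) / fs - 0.01))
        rec = LFPRecord(x, fs)
        params = AMPDEParams(window_s=win, use_notch=False, use_bandpass=False)
        peaks = ampde_detect(rec, params)
        crest_times = [(0.26 + k) for k in range(10)]
        w = int(win * fs)
        lam = int(fs / f0) // 2  # half the period, per the scale-selection law
        expected = [
            c for c in crest_times
            if lam <= (int(c * fs) % w) <= w - lam - 1
        ]
        assert len(peaks) == len(expected)
        for p, c in zip(peaks, expected):
            assert p.time_s == pytest.approx(c, abs=2 / fs)
            assert p.zscore == 0.0

    def test_peaks_seed_independent_for_structured_signal(self, rng):
        """The scalogram's zero cells depend only on the data, so when the
        scale selection is unambiguous (a clear dominant rhythm) the peak
        output does not change with the random draws."""
        t = np.arange(600) / 100.0
        x = np.sin(2 * np.pi * 5.0 * t) + 0.05 * rng.standard_normal(600)
        rec = LFPRecord(x, 100.0)
        times = []
        for seed in (0, 1, 99):
            params = AMPDEParams(window_s=2.0, rng_seed=seed,
                                 use_notch=False, use_bandpass=False)
            times.append([p.time_s for p in ampde_detect(rec, params)])
        assert times[0] == times[1] == times[2]
        assert times[0]

    def test_short_record_is_single_truncated_window(self, rng):
        x = rng.standard_normal(50)
        x[25] += 10.0
        rec = LFPRecord(x, 100.0)
        params = AMPDEParams(window_s=2.0, use_notch=False, use_bandpass=False)
        peaks = ampde_detect(rec, params)
        assert any(p.time_s == pytest.approx(0.25) for p in peaks)

    def test_empty_band_validation(self):
        with pytest.raises(ParameterError):
            AMPDEParams(band_lo_hz=30.0, band_hi_hz=10.0)

    def test_complexity_counter_quadratic_in_window(self):
        counts = []
        sizes = [64, 128, 256, 512]
        for n in sizes:
            r = np.random.default_rng(2)
            _, _, _, ops = lms_peaks(r.standard_normal(n))
            counts.append(ops)
        slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.2)
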