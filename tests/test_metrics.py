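import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nprrquant as q
from nprrquant.traces import DFFTrace


def _trace(protocol, dff):
    return DFFTrace(frames=protocol.frame_times(), dff=np.asarray(dff, float),
                    baseline_value=100.0, baseline_window=(0, 28))


class TestTrialPeaks:
    def test_flat_trace_zero_peak_first_frame_tie(self, protocol):
        tm = q.trial_peaks(_trace(protocol, np.zeros(259)), protocol)
        assert np.all(tm.peaks == 0.0)
        assert np.all(tm.latencies == 0.0)

    def test_triangular_bump(self, protocol):
        frames = protocol.frame_times()
        dff = np.zeros(frames.size)
        for on, off in protocol.trial_windows():
            apex = on + 6
            sel = (frames >= on) & (frames <= off)
            dff[sel] = 1.2 * np.maximum(0, 1 - np.abs(frames[sel] - apex) / 6.0)
        tm = q.trial_peaks(_trace(protocol, dff), protocol)
        np.testing.assert_allclose(tm.peaks, 1.2)
        np.testing.assert_allclose(tm.latencies, 6.0)

    def test_post_offset_maxima_ignored(self, protocol):
        frames = protocol.frame_times()
        dff = np.zeros(frames.size)
        on, off = protocol.trial_windows()[0]
        dff[frames == on + 3] = 0.5
        dff[frames == off + 5] = 2.0  # in the ISI: must not be the peak
        tm = q.trial_peaks(_trace(protocol, dff), protocol)
        assert tm.peaks[0] == pytest.approx(0.5)
        assert tm.latencies[0] == pytest.approx(3.0)

    def test_window_outside_recording_raises(self):
        p = q.make_protocol(1, 18.0, 42.0, 70.0, pre_window=5.0, post_window=5.0)
        short = DFFTrace(frames=np.arange(10.0), dff=np.zeros(10),
                         baseline_value=1.0, baseline_window=(0, 3))
        with pytest.raises(ValueError):
            q.trial_peaks(short, p)


class TestIntervalIntegrals:
    def test_constant_window_exact(self, protocol):
        tm = q.interval_integrals(_trace(protocol, np.full(259, 0.3)), protocol)
        np.testing.assert_allclose(tm.trial_integrals, 0.3 * 18.0)
        expected_iv = 0.3 * np.array([42.0, 42.0, 42.0, 258.0 - 228.0])
        np.testing.assert_allclose(tm.interval_integrals, expected_iv)

    def test_linear_ramp_exact(self, protocol):
        frames = protocol.frame_times()
        tm = q.interval_integrals(_trace(protocol, 0.01 * frames), protocol)
        for (lo, hi), got in zip(protocol.trial_windows(), tm.trial_integrals):
            assert got == pytest.approx(0.005 * (hi**2 - lo**2))

    def test_reporter_vs_calcium_interval_sign_contrast(
        self, protocol, noiseless_nprr_trace, noiseless_gcamp_trace
    ):
        nprr = q.interval_integrals(noiseless_nprr_trace, protocol)
        gcamp = q.interval_integrals(noiseless_gcamp_trace, protocol)
        assert np.all(nprr.interval_integrals < 0)
        assert np.all(gcamp.interval_integrals >= 0)

    @given(c=st.floats(0.1, 10.0))
    def test_linearity_of_peaks_and_integrals(self, c, protocol,
                                              noiseless_nprr_trace):
        base_p = q.trial_peaks(noiseless_nprr_trace, protocol)
        base_i = q.interval_integrals(noiseless_nprr_trace, protocol)
        scaled = noiseless_nprr_trace.copy_with(c * noiseless_nprr_trace.dff)
        sp = q.trial_peaks(scaled, protocol)
        si = q.interval_integrals(scaled, protocol)
        np.testing.assert_allclose(sp.peaks, c * base_p.peaks, rtol=1e-9)
        np.testing.assert_allclose(sp.latencies, base_p.latencies)
        np.testing.assert_allclose(si.trial_integrals, c * base_i.trial_integrals,
                                   rtol=1e-9)
        np.testing.assert_allclose(si.interval_integrals,
                                   c * base_i.interval_integrals, rtol=1e-9)


class TestSegmentPhases:
    def test_flat_trace_flagged_undefined(self, protocol):
        seg = q.segment_phases(_trace(protocol, np.zeros(259)), protocol)
        assert all(ph.undefined for ph in seg.trials)

    def test_falling_onset_precedes_offset(self, protocol, noiseless_nprr_trace):
        seg = q.segment_phases(noiseless_nprr_trace, protocol)
        for ph, (on, off) in zip(seg.trials, protocol.trial_windows()):
            assert ph.falling_onset is not None
            assert ph.falling_onset < off  # positive lead time

    def test_handbuilt_piecewise_breakpoints(self):
        """Rise 0->1 over 4 s, plateau to 10 s, fall to -0.3 by 16 s, back to
        0 by 30 s: segmentation recovers the known breakpoints within 1 frame."""
        p = q.make_protocol(1, 12.0, 30.0, 70.0, pre_window=10.0, post_window=30.0)
        frames = p.frame_times()
        on = 10.0
        t = frames - on
        dff = np.zeros(frames.size)
        dff[(t >= 0) & (t < 4)] = t[(t >= 0) & (t < 4)] / 4.0
        dff[(t >= 4) & (t < 10)] = 1.0
        fall = (t >= 10) & (t < 16)
        dff[fall] = 1.0 - 1.3 * (t[fall] - 10) / 6.0
        rec = (t >= 16) & (t < 30)
        dff[rec] = -0.3 + 0.3 * (t[rec] - 16) / 14.0
        seg = q.segment_phases(
            DFFTrace(frames=frames, dff=dff, baseline_value=1.0,
                     baseline_window=(0, 8)),
            p, eps=0.05,
        )
        ph = seg.trials[0]
        assert not ph.undefined
        assert abs(ph.rising[1] - (on + 4)) <= 1.0 + 1e-9  # peak near end of rise
        assert abs(ph.falling_onset - (on + 10)) <= 1.0 + 1e-9
        lo, hi = ph.undershoot_interval
        assert lo >= on + 12  # inside the ISI
        assert ph.recovery_flag

    def test_too_few_frames_raises(self):
        p = q.make_protocol(1, 3.0, 10.0, 70.0, pre_window=5.0, post_window=5.0,
                            frame_interval=1.0)
        tr = DFFTrace(frames=p.frame_times(), dff=np.zeros(p.frame_times().size),
                      baseline_value=1.0, baseline_window=(0, 3))
        with pytest.raises(ValueError, match="fewer than 5"):
            q.segment_phases(tr, p)


class TestFrequencyResponse:
    def test_normalization(self):
        fr = q.normalize_frequency_response({70.0: 0.8, 35.0: 0.4})
        assert fr.normalized[70.0] == pytest.approx(100.0)
        assert fr.normalized[35.0] == pytest.approx(50.0)

    def test_missing_or_nonpositive_reference_raises(self):
        with pytest.raises(ValueError):
            q.normalize_frequency_response({35.0: 0.4})
        with pytest.raises(ValueError):
            q.normalize_frequency_response({70.0: 0.0, 35.0: 0.4})

    def test_scale_invariance(self):
        peaks = {1.0: 0.01, 30.0: 0.2, 70.0: 0.9}
        a = q.normalize_frequency_response(peaks)
        b = q.normalize_frequency_response({f: 7.3 * v for f, v in peaks.items()})
        for f in peaks:
            assert a.normalized[f] == pytest.approx(b.normalized[f])

    def test_logistic_titration_monotone(self):
        """Peaks from the frequency-titration simulation are non-decreasing
        in stimulation frequency after normalization."""
        peaks = {}
        for f in (1.0, 5.0, 10.0, 20.0, 30.0, 50.0, 70.0):
            p = q.make_protocol(1, 18.0, 42.0, f)
            params = q.TraceSimParams(noise_sd=0.0)
            d = q.nprr_dff_noiseless(p, params)
            tr = DFFTrace(frames=p.frame_times(), dff=d, baseline_value=100.0,
                          baseline_window=(0, 28))
            peaks[f] = q.trial_peaks(tr, p).peaks[0]
        fr = q.normalize_frequency_response(peaks)
        ordered = [fr.normalized[f] for f in sorted(fr.normalized)]
        assert all(a <= b + 1e-12 for a, b in zip(ordered, ordered[1:]))
        assert fr.normalized[70.0] == pytest.approx(100.0)


class TestBoutonIBIRatio:
    def _traces(self, protocol, value):
        return [_trace(protocol, np.full(259, value))]

    def test_constant_ratio_two(self, protocol):
        res = q.bouton_ibi_ratio(self._traces(protocol, 2.0),
                                 self._traces(protocol, 1.0), protocol)
        np.testing.assert_allclose(res.ratios, 2.0)
        np.testing.assert_allclose(res.excluded_fraction, 0.0)

    def test_identical_classes_ratio_one(self, protocol):
        res = q.bouton_ibi_ratio(self._traces(protocol, 0.7),
                                 self._traces(protocol, 0.7), protocol)
        np.testing.assert_allclose(res.ratios, 1.0)

    def test_matches_brute_force_with_exclusions(self, protocol):
        rng = np.random.default_rng(11)
        frames = protocol.frame_times()
        b = [_trace(protocol, rng.normal(0.5, 0.3, frames.size)) for _ in range(3)]
        i = [_trace(protocol, rng.normal(0.05, 0.1, frames.size)) for _ in range(2)]
        res = q.bouton_ibi_ratio(b, i, protocol, floor=0.01)
        bm = np.mean([t.dff for t in b], axis=0)
        im = np.mean([t.dff for t in i], axis=0)
        for k, (lo, hi) in enumerate(protocol.trial_windows()):
            sel = (frames >= lo) & (frames <= hi)
            keep = im[sel] >= 0.01
            expect = np.mean(bm[sel][keep] / im[sel][keep])
            assert res.ratios[k] == pytest.approx(expect)
            assert res.excluded_fraction[k] == pytest.approx(
                1 - keep.sum() / sel.sum()
            )

    def test_all_frames_excluded_flagged(self, protocol):
        res = q.bouton_ibi_ratio(self._traces(protocol, 1.0),
                                 self._traces(protocol, -0.5), protocol)
        assert np.all(res.undefined)
        assert np.all(np.isnan(res.ratios))
        assert np.all(res.excluded_fraction == 1.0)

    def test_empty_class_raises(self, protocol):
        with pytest.raises(ValueError):
            q.bouton_ibi_ratio([], self._traces(protocol, 1.0), protocol)
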