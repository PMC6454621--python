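import numpy as np
import pytest
from scipy import signal as sp_signal

from mngpipe import preprocess as pp
from mngpipe.protocols import make_protocol
from mngpipe.session import RecordingSession
from mngpipe.synthesis import (default_templates, generate_ground_truth_trains,
                               synthesize_session, band_limited_noise)

FS = 10_000.0


class TestBandpass:
    def _analytic_gain(self, freq):
        sos = sp_signal.butter(3, (700, 2000), btype="bandpass", fs=FS,
                               output="sos")
        w, h = sp_signal.sosfreqz(sos, worN=[freq], fs=FS)
        # forward-backward filtering squares the magnitude response
        return float(np.abs(h[0]) ** 2)

    def test_dc_input_suppressed(self):
        y = pp.bandpass_filter(np.ones(20_000))
        assert np.abs(y).max() < 1e-6

    @pytest.mark.parametrize("freq", [1200.0, 100.0])
    def test_sinusoid_gain_matches_transfer_function(self, freq):
        t = np.arange(int(2 * FS)) / FS
        y = pp.bandpass_filter(np.sin(2 * np.pi * freq * t))
        mid = y[5000:-5000]
        measured = np.abs(mid).max()
        assert measured == pytest.approx(self._analytic_gain(freq), rel=0.01,
                                         abs=1e-9)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            pp.bandpass_filter(np.zeros(100), fs=3000.0)


class TestBlanking:
    def test_quiet_signal_untouched(self):
        x = 0.1 * np.sin(np.arange(1000))
        y, times = pp.blank_artifacts(x, threshold=1.0)
        np.testing.assert_array_equal(x, y)
        assert times.size == 0

    def test_single_impulse_blanks_centered_4_ms(self):
        x = np.zeros(10_000)
        i0 = 5000
        x[i0] = 5.0
        y, times = pp.blank_artifacts(x, threshold=1.0)
        half = int(0.002 * FS)
        assert not y[i0 - half:i0 + half + 1].any()
        assert times[0] == pytest.approx(i0 / FS)

    def test_two_events_1_ms_apart_merge_to_5_ms(self):
        x = np.ones(10_000) * 0.01
        x[5000] = 5.0
        x[5010] = 5.0       # 1 ms later
        y, _ = pp.blank_artifacts(x, threshold=1.0)
        zeroed = np.flatnonzero(y == 0.0)
        # interval union oracle: [5000-20, 5000+20] U [5010-20, 5010+20]
        expected = np.arange(5000 - 20, 5010 + 21)
        np.testing.assert_array_equal(zeroed, expected)

    def test_positive_threshold_required(self):
        with pytest.raises(ValueError):
            pp.blank_artifacts(np.zeros(10), threshold=0.0)


class TestDetectAndSort:
    def test_pure_noise_yields_no_units(self, rng):
        x = band_limited_noise(int(30 * FS), 0.05, rng)
        units = pp.detect_and_sort(pp.bandpass_filter(x))
        # false positives below 1 spike/s means no cluster can survive
        assert units == []

    def test_two_units_recovered_at_high_snr(self):
        from tests.conftest import build_session

        sess, trains = build_session("isotonic", 5, n_units=2, reps=2,
                                     noise_sd=0.04)
        units, _ = pp.sort_session(sess)
        assert len(units) == 2
        # each unit tracks one distinct ground-truth train ...
        for u in units:
            rec = max(
                np.mean(np.min(np.abs(gt[:, None] - u.spike_times[None, :]),
                               axis=1) < 5e-4)
                for gt in trains)
            assert rec >= 0.9
        # ... and >= 95% of all true spikes are matched within +/-0.5 ms
        all_sorted = np.sort(np.concatenate([u.spike_times for u in units]))
        pooled = np.mean([np.min(np.abs(all_sorted - t)) < 5e-4
                          for gt in trains for t in gt])
        assert pooled >= 0.95

    def test_single_template_yields_single_unit(self):
        from tests.conftest import build_session

        sess, _ = build_session("isotonic", 6, n_units=1, reps=1,
                                noise_sd=0.04)
        units, _ = pp.sort_session(sess)
        assert len(units) == 1

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pp.detect_and_sort(np.array([]))


class TestFiringRate:
    def test_empty_train_is_silent(self):
        t = np.arange(0, 1, 0.001)
        assert not pp.estimate_firing_rate([], t).any()

    def test_periodic_train_interior_rate(self):
        spikes = np.arange(0.05, 10.0, 0.1)      # strict 10 Hz
        t = np.array([5.0])
        assert pp.estimate_firing_rate(spikes, t)[0] == pytest.approx(10.0)

    def test_direct_count_oracle(self):
        fr = pp.estimate_firing_rate([0.01, 0.02, 0.03], np.array([0.02]))
        assert fr[0] == pytest.approx(30.0)

    def test_rate_integral_conserves_spike_count(self, rng):
        spikes = np.sort(rng.uniform(0.2, 9.8, size=200))
        t = np.arange(0, 10, 0.001)
        fr = pp.estimate_firing_rate(spikes, t)
        assert np.trapezoid(fr, t) == pytest.approx(200, abs=0.1 * 20 + 2)

    def test_positive_width_required(self):
        with pytest.raises(ValueError):
            pp.estimate_firing_rate([0.1], np.array([0.0]), kernel_width=0)


class TestSnr:
    def test_identical_statistics_give_unity(self, rng):
        x = rng.standard_normal(int(2 * FS))
        rep = pp.compute_snr(x, [(0.0, 1.0)], [(1.0, 2.0)])
        assert rep.snr == pytest.approx(1.0, rel=0.2)

    def test_hand_computed_interval_maxima(self):
        # activity 100 ms maxima {2, 4}; rest maxima {1, 1} -> SNR 3
        x = np.zeros(int(0.4 * FS))
        x[500] = 2.0
        x[1500] = 4.0
        x[2500] = 1.0
        x[3500] = 1.0
        rep = pp.compute_snr(x, [(0.0, 0.2)], [(0.2, 0.4)])
        assert rep.snr == pytest.approx(3.0)
        assert rep.n_act == 2 and rep.n_rest == 2

    def test_zero_rest_raises(self):
        x = np.zeros(int(0.4 * FS))
        x[100] = 1.0
        with pytest.raises(ZeroDivisionError):
            pp.compute_snr(x, [(0.0, 0.2)], [(0.2, 0.4)])

    def test_monotone_in_activity_amplitude(self, rng):
        x = rng.standard_normal(int(2 * FS))
        base = pp.compute_snr(x, [(0.0, 1.0)], [(1.0, 2.0)]).snr
        x2 = x.copy()
        x2[:int(FS)] *= 2.0
        boosted = pp.compute_snr(x2, [(0.0, 1.0)], [(1.0, 2.0)]).snr
        assert boosted >= base


class TestMostCorrelatedMuscle:
    def test_identical_channel_wins_with_r_one(self, rng):
        env = np.abs(rng.standard_normal(1000)).cumsum()
        noisy = env + 5 * rng.standard_normal(1000)
        idx, r = pp.most_correlated_muscle(env, [noisy, env.copy()])
        assert idx == 1 and r == pytest.approx(1.0)

    def test_sign_matters(self, rng):
        env = rng.standard_normal(1000)
        idx, r = pp.most_correlated_muscle(env, [-env, env])
        assert idx == 1 and r == pytest.approx(1.0)

    def test_known_mixture_correlation(self, rng):
        env = rng.standard_normal(200_000)
        noise = rng.standard_normal(200_000)
        mixed = 0.8 * env + noise
        expected = 0.8 / np.sqrt(0.8 ** 2 + 1.0)
        idx, r = pp.most_correlated_muscle(env, [mixed, noise])
        assert idx == 0
        assert r == pytest.approx(expected, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pp.most_correlated_muscle(np.ones(10), [np.arange(10.0)])


class TestSelectTrials:
    def _isotonic_session(self, pressures, mng=None):
        proto = make_protocol("isotonic", [4.0], len(pressures))
        n = int(round(proto.total_duration * FS))
        if mng is None:
            mng = np.zeros(n)
            # give every repetition strong activity, rests quiet noise
            rng = np.random.default_rng(0)
            mng += 0.01 * rng.standard_normal(n)
            for a, b in proto.cue_times:
                mng[int(a * FS):int(b * FS)] += \
                    0.2 * rng.standard_normal(int((b - a) * FS))
        t_p = np.arange(int(round(proto.total_duration * 10))) / 10.0
        pressure = np.zeros_like(t_p)
        for (a, b), held in zip(proto.cue_times, pressures):
            pressure[(t_p >= a) & (t_p < b)] = held
        return RecordingSession(mng=mng, semg=[np.zeros(n)],
                                pressure=pressure, protocol=proto)

    def test_low_snr_excludes_even_with_perfect_pressure(self):
        # repetition quieter than rest -> SNR < 1 -> excluded despite a
        # perfectly held pressure
        sess = self._isotonic_session([4.0])
        rng_l = np.random.default_rng(1)
        quiet = 0.02 * rng_l.standard_normal(len(sess.mng))
        a, b = sess.protocol.cue_times[0]
        quiet[int(a * FS):int(b * FS)] *= 0.5
        sel = pp.select_trials(sess, filtered_mng=quiet)
        assert sel.snr[0] < 1.0
        assert sel.pressure_ok == [True]
        assert sel.included == []

    def test_pressure_tolerance_rule(self):
        # 4.3/4.0 kPa = 7.5% error -> in; 2.5/2.0 = 25% -> out
        sess = self._isotonic_session([4.3, 4.0 * 1.25])
        sel = pp.select_trials(sess)
        assert sel.pressure_ok == [True, False]
        assert 0 in sel.included and 1 not in sel.included

    def test_missing_pressure_channel_rejected(self):
        sess = self._isotonic_session([4.0])
        sess.pressure = np.array([])
        with pytest.raises(ValueError, match="pressure"):
            pp.select_trials(sess)

    def test_isokinetic_timing_rule(self):
        # sEMG envelope peaking at the cue transition passes, an early
        # peak (>10% of the repetition before the transition) fails
        proto = make_protocol("isokinetic", [26.0], 2)
        n = int(round(proto.total_duration * FS))
        rng = np.random.default_rng(2)
        mng = 0.01 * rng.standard_normal(n)
        semg = 0.001 * rng.standard_normal(n)
        for i, (a, b) in enumerate(proto.cue_times):
            mng[int(a * FS):int(b * FS)] += \
                0.2 * rng.standard_normal(int((b - a) * FS))
            peak_t = b - 0.05 if i == 0 else a + 0.4 * (b - a)
            j = int(peak_t * FS)
            semg[j - 2000:j + 2000] += 5.0 * np.hanning(4000) * \
                rng.standard_normal(4000)
        sess = RecordingSession(mng=mng, semg=[semg],
                                pressure=np.zeros(int(proto.total_duration
                                                      * 10)),
                                protocol=proto)
        sel = pp.select_trials(sess)
        assert sel.timing_ok == [True, False]


def test_envelope_is_positive_and_slow(rng):
    x = band_limited_noise(int(5 * FS), 1.0, rng)
    env = pp.envelope(x)
    assert (env > -1e-9).all()
    # 2 Hz second-order low-pass leaves no appreciable power at 50+ Hz
    spec = np.abs(np.fft.rfft(env - env.mean()))
    freqs = np.fft.rfftfreq(len(env), 1 / FS)
    assert spec[freqs > 50].max() < 0.05 * spec.max()
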