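import numpy as np
import pytest
from scipy import signal as sps

from physioscore.design import Epoch
from physioscore.eda import (
    EdaConfig,
    TtpScorer,
    TtpStatus,
    bandpass_eda,
    bandpass_sos,
    condition_epoch,
    find_candidates,
    score_epoch,
    select_ttp_pair,
)

from conftest import FS, make_detection_signal, make_scr_epoch

# frequency-response oracle: the zero-phase (forward-backward) gain of the
# designed sections is |H(f)|^2 evaluated independently with sosfreqz


def designed_gain(config, freq_hz):
    hp, lp = bandpass_sos(config)
    g = 1.0
    for sos in (hp, lp):
        _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=config.fs_hz)
        g *= np.abs(h[0]) ** 2
    return g


def measured_gain(config, freq_hz, dur_s=600.0):
    """Steady-state gain measured by quadrature projection of the filtered
    sinusoid (rejects the slow edge transients of the 0.005 Hz stage)."""
    t = np.arange(int(dur_s * config.fs_hz)) / config.fs_hz
    x = np.sin(2 * np.pi * freq_hz * t)
    y = bandpass_eda(x, config)
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    z = np.exp(-2j * np.pi * freq_hz * t[mid])
    return 2 * np.abs(np.mean(y[mid] * z))


class TestBandpass:
    def test_dc_removed(self, eda_config):
        out = bandpass_eda(np.full(100_000, 5.0), eda_config)
        assert np.abs(out).max() < 1e-6

    def test_passband_gain_at_0p1hz(self, eda_config):
        assert designed_gain(eda_config, 0.1) == pytest.approx(1.0, abs=0.05)
        assert measured_gain(eda_config, 0.1) == pytest.approx(1.0, abs=0.05)

    def test_stopband_gain_at_5hz(self, eda_config):
        assert designed_gain(eda_config, 5.0) < 0.1
        assert measured_gain(eda_config, 5.0, dur_s=60.0) < 0.1

    def test_nonfinite_rejected_with_index(self, eda_config):
        x = np.zeros(10_000)
        x[1234] = np.nan
        with pytest.raises(ValueError, match="1234"):
            bandpass_eda(x, eda_config)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EdaConfig(hp_hz=2.0, lp_hz=1.0)
        with pytest.raises(ValueError):
            EdaConfig(min_ttp_uS=0.0)


class TestConditionEpoch:
    def test_linear_ramp_annihilated(self, eda_config):
        ramp = np.linspace(3.0, 4.0, 5500)
        out = condition_epoch(Epoch(samples=ramp), eda_config)
        assert np.abs(out).max() < 1e-9

    def test_window_min_is_zero_before_smoothing(self, rng):
        # a one-sample smoothing window makes the smoothing stage an identity,
        # exposing the rescaled signal directly
        cfg = EdaConfig(smooth_window_s=1.0 / FS)
        x = rng.normal(5.0, 0.1, 5500)
        out = condition_epoch(Epoch(samples=x), cfg)
        assert out.min() == pytest.approx(0.0, abs=1e-12)

    def test_output_is_ten_seconds(self, rng, eda_config):
        out = condition_epoch(Epoch(samples=rng.normal(size=5500)), eda_config)
        assert out.size == 5000


class TestFindCandidates:
    def _oracle(self, x):
        minima = [i for i in range(1, len(x) - 1) if x[i] < x[i - 1] and x[i] < x[i + 1]]
        maxima = [i for i in range(1, len(x) - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]
        return minima, maxima

    def test_flat_signal_has_no_extrema(self):
        minima, maxima = find_candidates(np.ones(100))
        assert minima.size == 0 and maxima.size == 0

    def test_monotone_signal_has_no_interior_max(self):
        _, maxima = find_candidates(np.linspace(0, 1, 100))
        assert maxima.size == 0

    def test_single_bump(self):
        x = make_detection_signal(2.0, 2.0, 0.5)
        minima, maxima = find_candidates(x)
        assert maxima.size == 1
        assert minima.size == 1

    def test_matches_exhaustive_three_point_scan(self, rng):
        for _ in range(20):
            x = np.cumsum(rng.normal(size=300))
            minima, maxima = find_candidates(x)
            omin, omax = self._oracle(x)
            assert list(minima) == omin
            assert list(maxima) == omax


class TestSelectTtpPair:
    def _run(self, trough_s, lag_s, ttp=0.42):
        x = make_detection_signal(trough_s, lag_s, ttp)
        minima, maxima = find_candidates(x)
        return select_ttp_pair(minima, maxima, x)

    def test_valid_pair_detected(self):
        m = self._run(1.8, 2.1, ttp=0.42)
        assert m.status is TtpStatus.VALID
        assert m.trough_time_s == pytest.approx(1.8, abs=0.01)
        assert m.peak_time_s - m.trough_time_s == pytest.approx(2.1, abs=0.02)
        assert m.ttp_uS == pytest.approx(0.42, rel=0.01)

    def test_early_trough_is_no_response(self):
        m = self._run(0.5, 2.0)
        assert m.status is TtpStatus.NO_RESPONSE

    def test_first_qualifying_pair_wins(self):
        # two bumps, both qualifying: troughs at 1.2 and 2.0 s
        x1 = make_detection_signal(1.2, 1.3, 0.3, window_s=4.0)
        x2 = make_detection_signal(0.6, 1.4, 0.5, window_s=6.0)
        x = np.concatenate([x1, x2 + x1[-1] - x2[0]])
        minima, maxima = find_candidates(x)
        m = select_ttp_pair(minima, maxima, x)
        assert m.status is TtpStatus.VALID
        assert m.trough_time_s == pytest.approx(1.2, abs=0.02)

    def test_amplitude_threshold_is_strict(self):
        below = self._run(2.0, 2.0, ttp=0.009)
        at = self._run(2.0, 2.0, ttp=0.010)
        assert below.status is TtpStatus.BELOW_THRESHOLD
        assert at.status is TtpStatus.VALID

    def test_no_preceding_minimum_forms_no_pair(self):
        # monotone rise from sample 0 to a peak, then decay: max has no
        # preceding interior minimum
        t = np.arange(5000) / FS
        x = np.sin(np.pi * np.minimum(t, 4.0) / 4.0)
        minima, maxima = find_candidates(x)
        m = select_ttp_pair(minima, maxima, x)
        assert m.status is TtpStatus.NO_RESPONSE

    def test_valid_measurement_invariants(self):
        m = self._run(2.9, 3.0, ttp=0.8)
        assert m.status is TtpStatus.VALID
        eps = 1e-9
        assert 1.0 - eps <= m.trough_time_s <= 3.0 + eps
        assert 1.0 - eps <= m.peak_time_s - m.trough_time_s <= 3.0 + eps
        assert m.ttp_uS >= 0.01
        assert m.peak_uS > m.trough_uS


class TestClosedLoop:
    def test_amplitude_fidelity_noise_free(self):
        """Noise-free SCRs in [0.02, 2] uS recovered within 10%."""
        for amp in (0.02, 0.1, 0.5, 2.0):
            ep = make_scr_epoch(amp, latency_s=1.8)
            m = score_epoch(ep)
            assert m.status is TtpStatus.VALID
            assert abs(m.ttp_uS - amp) / amp < 0.1

    def test_pipeline_scales_linearly(self):
        ep1 = make_scr_epoch(0.2, latency_s=2.0)
        ep3 = Epoch(samples=3.0 * ep1.samples)
        m1, m3 = score_epoch(ep1), score_epoch(ep3)
        assert m3.ttp_uS == pytest.approx(3.0 * m1.ttp_uS, rel=1e-9)
        assert m3.trough_time_s == m1.trough_time_s
        assert m3.peak_time_s == m1.peak_time_s

    def test_flat_epoch_never_valid(self, rng):
        ep = Epoch(samples=5.0 + rng.normal(0, 1e-4, 5500))
        m = score_epoch(ep)
        assert m.status in (TtpStatus.NO_RESPONSE, TtpStatus.BELOW_THRESHOLD)


class TestScorerEstimator:
    def test_get_set_params_roundtrip(self):
        s = TtpScorer(min_ttp_uS=0.02)
        assert s.get_params()["min_ttp_uS"] == 0.02
        s.set_params(lp_hz=0.8)
        assert s._config().lp_hz == 0.8

    def test_transform_returns_one_row_per_epoch(self):
        eps = np.stack([make_scr_epoch(0.5, 1.8).samples,
                        make_scr_epoch(0.3, 2.2).samples])
        out = TtpScorer().fit().transform(eps)
        assert len(out) == 2
        assert (out["status"] == "valid").all()
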