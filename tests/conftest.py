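"""Shared fixtures: noise-free SCR epochs and constructed detection signals."""

import numpy as np
import pytest

from physioscore.design import Epoch
from physioscore.eda import EdaConfig, bandpass_eda
from physioscore.simulate import GenConfig, ScrParams, TonicParams, scr_kernel

FS = 500.0


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def eda_config():
    return EdaConfig()


def make_scr_epoch(amp_uS, latency_s, fs=FS, tonic_level=5.0, config=None,
                   segment_s=40.0, onset_s=20.0):
    """Band-pass-filtered epoch containing one noise-free SCR.

    Builds a longer carrier trace (so the whole-recording filter behaves as
    on real data), adds a single bi-exponential SCR at ``onset + latency``,
    filters, and cuts the 11-s epoch starting 1 s before the onset.
    """
    config = config or EdaConfig(fs_hz=fs)
    n = int(segment_s * fs)
    t = np.arange(n) / fs
    trace = tonic_level + amp_uS * scr_kernel(t - (onset_s + latency_s))
    filtered = bandpass_eda(trace, config)
    i0 = int(round((onset_s - 1.0) * fs))
    return Epoch(samples=filtered[i0 : i0 + int(11 * fs)], fs_hz=fs)


def make_detection_signal(trough_s, lag_s, ttp, fs=FS, window_s=10.0, pre_level=0.25):
    """Processed-stage signal with a strict minimum at ``trough_s`` and a
    strict maximum ``lag_s`` later, with peak-minus-trough exactly ``ttp``.

    A declining ramp runs into the trough, a raised cosine climbs to the
    peak, and a gentle ramp decays to the end, so the only interior extrema
    are the constructed pair.
    """
    n = int(round(window_s * fs))
    t = np.arange(n) / fs
    t_pk = trough_s + lag_s
    s = np.empty(n)
    pre = t < trough_s
    s[pre] = pre_level * (trough_s - t[pre]) / max(trough_s, 1e-6)
    rise = (t >= trough_s) & (t <= t_pk)
    s[rise] = ttp * 0.5 * (1 - np.cos(np.pi * (t[rise] - trough_s) / lag_s))
    post = t > t_pk
    s[post] = ttp - 0.3 * ttp * (t[post] - t_pk) / window_s
    return s


@pytest.fixture
def tiny_study_config():
    return GenConfig(n_subjects=3, trials_per_subject=4, seed=11)


def noise_free_config(seed=0, **scr_kwargs):
    """Generator config with tonic drift, wander and noise switched off."""
    scr = ScrParams(amp_cv=0.0, latency_sd_s=0.0, response_prob=1.0, **scr_kwargs)
    tonic = TonicParams(level_uS=5.0, drift_slope_uS_per_min=0.0,
                        slow_wave_amp_uS=0.0, noise_sd_uS=0.0)
    return GenConfig(seed=seed, scr=scr, tonic=tonic)
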