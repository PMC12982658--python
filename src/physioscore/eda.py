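"""Electrodermal trough-to-peak (TTP) amplitude scoring.

The pipeline follows the event-related TTP scoring convention for skin
conductance: the whole recording is band-pass filtered (0.005-1.0 Hz) to
strip tonic drift and high-frequency noise, each 11-s epoch is linearly
detrended, baseline-corrected against its first second, rescaled so the
10-s analysis window has minimum zero, and lightly smoothed before local
extrema are detected.  For each local maximum the nearest preceding local
minimum is its candidate trough; the first trough-peak pair with the trough
1-3 s after time 0 and the peak 1-3 s after the trough defines the response,
and its amplitude is the peak-minus-trough difference.  Amplitudes below
0.01 uS do not count as a discrete response and are flagged for exclusion.

All filters are applied zero-phase (forward-backward) so trough and peak
latencies are not shifted by filter group delay.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .design import Epoch, extract_epoch
from .smoothing import moving_average

__all__ = [
    "EdaConfig",
    "TtpStatus",
    "TtpMeasurement",
    "bandpass_eda",
    "condition_epoch",
    "find_candidates",
    "select_ttp_pair",
    "score_epoch",
    "TtpScorer",
]

_EPS = 1e-9  # tolerance for closed-interval window checks on the sample grid


class TtpStatus(str, enum.Enum):
    VALID = "valid"
    NO_RESPONSE = "no_response"
    BELOW_THRESHOLD = "below_threshold"


@dataclass
class EdaConfig:
    """Tunable parameters of the electrodermal pipeline.

    ``smooth_window_s`` realizes the pre-detection smoothing (nominal
    smoothing factor 0.1) as a centered moving average of 0.1 s; see the
    methods note for why a window this short is required to preserve
    trough/peak geometry.  Windows are closed intervals in seconds;
    ``min_ttp_uS`` is a strict lower bound (an amplitude exactly at the
    bound is retained).
    """

    hp_hz: float = 0.005
    lp_hz: float = 1.0
    smooth_window_s: float = 0.1
    trough_window_s: tuple[float, float] = (1.0, 3.0)
    peak_lag_window_s: tuple[float, float] = (1.0, 3.0)
    min_ttp_uS: float = 0.01
    fs_hz: float = 500.0
    filter_order: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.hp_hz < self.lp_hz < self.fs_hz / 2:
            raise ValueError(
                f"need 0 < hp_hz < lp_hz < fs/2, got {self.hp_hz}, {self.lp_hz}, fs={self.fs_hz}"
            )
        for name in ("trough_window_s", "peak_lag_window_s"):
            lo, hi = getattr(self, name)
            if not hi > lo >= 0:
                raise ValueError(f"{name} must be a positive-length window, got {(lo, hi)}")
        if self.min_ttp_uS <= 0:
            raise ValueError(f"min_ttp_uS must be > 0, got {self.min_ttp_uS}")
        if self.smooth_window_s <= 0:
            raise ValueError(f"smooth_window_s must be > 0, got {self.smooth_window_s}")


@dataclass
class TtpMeasurement:
    """A scored (or rejected) trough-to-peak response for one epoch.

    Times are seconds from time 0 (end of the baseline second).  For a
    valid measurement the trough falls in the trough window, the peak lag
    in the lag window, the amplitude is at least the minimum response
    amplitude and the peak strictly exceeds the trough.
    """

    status: TtpStatus
    trough_time_s: float = np.nan
    trough_uS: float = np.nan
    peak_time_s: float = np.nan
    peak_uS: float = np.nan
    ttp_uS: float = np.nan

    def as_dict(self) -> dict:
        d = {
            "trough_time_s": self.trough_time_s,
            "trough_uS": self.trough_uS,
            "peak_time_s": self.peak_time_s,
            "peak_uS": self.peak_uS,
            "ttp_uS": self.ttp_uS,
            "status": self.status.value,
        }
        return d


def bandpass_sos(config: EdaConfig) -> tuple[np.ndarray, np.ndarray]:
    """Second-order sections of the high-pass and low-pass Butterworth stages."""
    hp = sps.butter(config.filter_order, config.hp_hz, "highpass", fs=config.fs_hz, output="sos")
    lp = sps.butter(config.filter_order, config.lp_hz, "lowpass", fs=config.fs_hz, output="sos")
    return hp, lp


def _check_finite(trace: np.ndarray) -> np.ndarray:
    trace = np.asarray(trace, dtype=float)
    bad = np.flatnonzero(~np.isfinite(trace))
    if bad.size:
        raise ValueError(f"non-finite sample at index {bad[0]}")
    return trace


def bandpass_eda(trace: np.ndarray, config: EdaConfig | None = None) -> np.ndarray:
    """Zero-phase 0.005-1.0 Hz band-pass applied to the whole recording."""
    config = config or EdaConfig()
    trace = _check_finite(trace)
    hp, lp = bandpass_sos(config)
    out = sps.sosfiltfilt(hp, trace)
    out = sps.sosfiltfilt(lp, out)
    return out


def condition_epoch(epoch: Epoch, config: EdaConfig | None = None) -> np.ndarray:
    """Detrend, baseline-correct, rescale and smooth one epoch.

    In order: linear detrend over the full 11-s epoch; subtraction of the
    mean of the baseline second; restriction to the 10-s analysis window;
    subtraction of the window minimum (so the pre-smoothing minimum is
    exactly 0); centered moving-average smoothing.  Returns the processed
    10-s signal.
    """
    config = config or EdaConfig()
    x = sps.detrend(np.asarray(epoch.samples, dtype=float), type="linear")
    x = x - x[: epoch.n_baseline].mean()
    win = x[epoch.n_baseline :]
    win = win - win.min()
    n_smooth = int(round(config.smooth_window_s * config.fs_hz))
    return moving_average(win, n_smooth)


def find_candidates(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local minima and maxima of a processed signal.

    A sample is a strict extremum when it is strictly below (above) both
    neighbours; endpoints are never extrema.  Both arrays are in time order.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    left, mid, right = x[:-2], x[1:-1], x[2:]
    minima = np.flatnonzero((mid < left) & (mid < right)) + 1
    maxima = np.flatnonzero((mid > left) & (mid > right)) + 1
    return minima, maxima


def select_ttp_pair(
    minima: np.ndarray,
    maxima: np.ndarray,
    amplitudes: np.ndarray,
    config: EdaConfig | None = None,
) -> TtpMeasurement:
    """Pick the first valid trough-peak pair and compute its amplitude.

    Peaks are visited in time order; each peak's trough is the nearest
    preceding local minimum.  The first pair whose trough time lies in the
    (closed) trough window and whose peak lag lies in the (closed) lag
    window is scored.  If no pair qualifies the epoch is ``no_response``;
    if the scored amplitude is strictly below ``min_ttp_uS`` the epoch is
    ``below_threshold``.
    """
    config = config or EdaConfig()
    amplitudes = np.asarray(amplitudes, dtype=float)
    minima = np.asarray(minima, dtype=int)
    maxima = np.asarray(maxima, dtype=int)
    t_lo, t_hi = config.trough_window_s
    l_lo, l_hi = config.peak_lag_window_s
    for pk in maxima:
        prev = minima[minima < pk]
        if prev.size == 0:
            continue
        tr = prev[-1]
        t_tr = tr / config.fs_hz
        t_pk = pk / config.fs_hz
        lag = t_pk - t_tr
        if not (t_lo - _EPS <= t_tr <= t_hi + _EPS):
            continue
        if not (l_lo - _EPS <= lag <= l_hi + _EPS):
            continue
        ttp = amplitudes[pk] - amplitudes[tr]
        if ttp <= 0:
            continue
        status = TtpStatus.VALID if ttp >= config.min_ttp_uS else TtpStatus.BELOW_THRESHOLD
        return TtpMeasurement(
            status=status,
            trough_time_s=t_tr,
            trough_uS=amplitudes[tr],
            peak_time_s=t_pk,
            peak_uS=amplitudes[pk],
            ttp_uS=ttp,
        )
    return TtpMeasurement(status=TtpStatus.NO_RESPONSE)


def score_epoch(epoch: Epoch, config: EdaConfig | None = None) -> TtpMeasurement:
    """Condition one epoch and score its trough-to-peak response."""
    config = config or EdaConfig()
    processed = condition_epoch(epoch, config)
    minima, maxima = find_candidates(processed)
    return select_ttp_pair(minima, maxima, processed, config)


class TtpScorer(TransformerMixin, BaseEstimator):
    """Transformer turning event-locked EDA epochs into TTP measurements.

    The scorer is stateless (``fit`` is a no-op kept for pipeline
    compatibility).  ``transform`` expects a 2-D array of already band-pass
    filtered epochs, one per row, each ``round(duration_s * fs_hz)`` samples
    long, and returns one measurement row per epoch.
    ``score_recording`` runs the whole chain (whole-recording band-pass,
    epoching at each event onset, per-epoch scoring) from a signal table
    and an events table.

    Parameters mirror :class:`EdaConfig`.
    """

    def __init__(
        self,
        hp_hz: float = 0.005,
        lp_hz: float = 1.0,
        smooth_window_s: float = 0.1,
        trough_window_s: tuple[float, float] = (1.0, 3.0),
        peak_lag_window_s: tuple[float, float] = (1.0, 3.0),
        min_ttp_uS: float = 0.01,
        fs_hz: float = 500.0,
        filter_order: int = 2,
    ):
        self.hp_hz = hp_hz
        self.lp_hz = lp_hz
        self.smooth_window_s = smooth_window_s
        self.trough_window_s = trough_window_s
        self.peak_lag_window_s = peak_lag_window_s
        self.min_ttp_uS = min_ttp_uS
        self.fs_hz = fs_hz
        self.filter_order = filter_order

    def _config(self) -> EdaConfig:
        return EdaConfig(
            hp_hz=self.hp_hz,
            lp_hz=self.lp_hz,
            smooth_window_s=self.smooth_window_s,
            trough_window_s=tuple(self.trough_window_s),
            peak_lag_window_s=tuple(self.peak_lag_window_s),
            min_ttp_uS=self.min_ttp_uS,
            fs_hz=self.fs_hz,
            filter_order=self.filter_order,
        )

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X) -> pd.DataFrame:
        """Score a stack of filtered epochs (rows) into TTP measurements."""
        cfg = self._config()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        rows = []
        for row in X:
            ep = Epoch(samples=row, fs_hz=cfg.fs_hz)
            rows.append(score_epoch(ep, cfg).as_dict())
        return pd.DataFrame(rows)

    def score_recording(self, signals: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
        """Score every event of one subject's recording.

        ``signals`` must hold ``time_s`` and ``eda_uS`` columns sampled at
        ``fs_hz``; ``events`` one row per question with an ``onset`` column
        (seconds).  Returns the per-trial output table with identification
        columns carried over from the events.
        """
        cfg = self._config()
        trace = bandpass_eda(signals["eda_uS"].to_numpy(), cfg)
        out = []
        for _, ev in events.iterrows():
            label = f"subject {ev.get('subject')} trial {ev.get('trial')} question {ev.get('question')}"
            ep = extract_epoch(trace, cfg.fs_hz, float(ev["onset"]), label=label)
            m = score_epoch(ep, cfg).as_dict()
            for col in ("subject", "trial", "question", "condition"):
                if col in ev.index:
                    m[col] = ev[col]
            out.append(m)
        df = pd.DataFrame(out)
        lead = [c for c in ("subject", "trial", "question", "condition") if c in df.columns]
        return df[lead + [c for c in df.columns if c not in lead]]
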