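"""Synthetic-study generator with recorded ground truth.

Emits complete synthetic studies — per-subject physiological recordings,
a BIDS-style events table and ground-truth tables — with the statistical
structure the analysis pipeline assumes:

* EDA: a tonic level with slow drift and a slow sinusoidal wander, plus
  one phasic skin conductance response per question (with a configurable
  response probability).  SCRs use the standard bi-exponential kernel
  ``exp(-t/tau_d) - exp(-t/tau_r)`` normalized to unit peak; amplitudes are
  Gamma-distributed around condition-dependent means, latencies Gaussian.
* fEMG: stationary band-limited (20-120 Hz) Gaussian background of small
  RMS plus one amplitude-modulated burst per question whose duration is
  condition-dependent for the experimental question.
* Ratings: Truth mean plus condition deltas, a Gaussian per-subject offset
  and Gaussian residual, clipped to the 0-100 scale.  Default deltas follow
  the reported Deception and Uncertainty effects so that simulations
  exercise realistic effect sizes.

The design is 20 trials x 3 questions per subject with the four feedback
types (Probability x Valence) assigned uniformly at random per trial, and a
configurable probability that the participant self-rates the trial 'best'
(so the retention filter has work to do).  Everything is deterministic given
the seed; per-subject streams are spawned from one seed sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .design import (
    Condition,
    FeedbackType,
    Probability,
    Valence,
    label_condition,
    write_events,
    write_signals,
)

__all__ = [
    "ScrParams",
    "TonicParams",
    "EmgSimParams",
    "RatingParams",
    "GenConfig",
    "scr_kernel",
    "scr_peak_time",
    "simulate_eda_trial",
    "simulate_emg_trial",
    "simulate_ratings",
    "simulate_subject",
    "iter_subjects",
    "simulate_study",
    "FEEDBACK_TYPES",
]

FEEDBACK_TYPES = [
    FeedbackType(Probability.CERTAIN, Valence.NEGATIVE),    # Deception
    FeedbackType(Probability.CERTAIN, Valence.POSITIVE),    # Truth
    FeedbackType(Probability.UNCERTAIN, Valence.NEGATIVE),  # Uncertainty
    FeedbackType(Probability.UNCERTAIN, Valence.POSITIVE),  # Uncertainty
]


@dataclass
class ScrParams:
    """Phasic SCR shape and condition-dependent amplitude model."""

    tau_rise_s: float = 0.75
    tau_decay_s: float = 3.0
    latency_mean_s: float = 1.8
    latency_sd_s: float = 0.4
    amp_means_uS: dict = field(
        default_factory=lambda: {"Deception": 0.50, "Uncertainty": 0.40, "Truth": 0.30}
    )
    amp_cv: float = 0.4
    response_prob: float = 0.85
    control_amp_uS: float = 0.35  # condition-independent mean for questions 1-2


@dataclass
class TonicParams:
    """Tonic EDA level, drift, slow wander and measurement noise."""

    level_uS: float = 5.0
    drift_slope_uS_per_min: float = 0.05
    slow_wave_amp_uS: float = 0.10
    slow_wave_period_s: float = 90.0
    noise_sd_uS: float = 0.003


@dataclass
class EmgSimParams:
    """Facial-EMG background and burst model.

    Defaults reflect surface facial EMG at rest (a floor of a few
    microvolts RMS) against expressive bursts of ~0.15 mV, i.e. a contrast
    of roughly 75:1, which is what makes the relative 45%-of-mean threshold
    usable (see the methods note).
    """

    background_rms_mV: float = 0.002
    burst_amp_mV: float = 0.15
    band_hz: tuple[float, float] = (20.0, 120.0)
    burst_dur_means_s: dict = field(
        default_factory=lambda: {
            "corrugator": {"Deception": 3.5, "Uncertainty": 3.0, "Truth": 2.5},
            "zygomaticus": {"Deception": 2.8, "Uncertainty": 2.8, "Truth": 2.8},
        }
    )
    burst_dur_cv: float = 0.25
    burst_min_s: float = 0.5
    burst_max_s: float = 8.5
    control_burst_s: float = 2.5  # mean for questions 1-2
    ramp_s: float = 0.02


@dataclass
class RatingParams:
    """Self-confidence generative model (Truth mean + condition deltas)."""

    mean_truth: float = 70.0
    delta_deception: float = -10.516
    delta_uncertainty: float = -4.491
    subject_sd: float = 10.0
    residual_sd: float = 15.0

    def condition_mean(self, condition) -> float:
        c = Condition(condition)
        if c is Condition.DECEPTION:
            return self.mean_truth + self.delta_deception
        if c is Condition.UNCERTAINTY:
            return self.mean_truth + self.delta_uncertainty
        return self.mean_truth


@dataclass
class GenConfig:
    """Full synthetic-study configuration (design + signal models)."""

    n_subjects: int = 32
    trials_per_subject: int = 20
    questions_per_trial: int = 3
    fs_hz: float = 500.0
    seed: int = 0
    p_best: float = 0.8
    lead_in_s: float = 10.0
    question_spacing_s: float = 15.0
    inter_trial_gap_s: float = 5.0
    scr: ScrParams = field(default_factory=ScrParams)
    tonic: TonicParams = field(default_factory=TonicParams)
    emg: EmgSimParams = field(default_factory=EmgSimParams)
    ratings: RatingParams = field(default_factory=RatingParams)

    @property
    def trial_len_s(self) -> float:
        return self.questions_per_trial * self.question_spacing_s + self.inter_trial_gap_s

    @property
    def recording_len_s(self) -> float:
        return self.lead_in_s + self.trials_per_subject * self.trial_len_s + 15.0

    def question_onset_s(self, trial: int, question: int) -> float:
        """Onset of question ``question`` (1-based) in trial ``trial`` (1-based)."""
        return (
            self.lead_in_s
            + (trial - 1) * self.trial_len_s
            + (question - 1) * self.question_spacing_s
        )


# ---------------------------------------------------------------------------
# signal primitives

def scr_kernel(t: np.ndarray, tau_rise_s: float = 0.75, tau_decay_s: float = 3.0) -> np.ndarray:
    """Unit-peak bi-exponential SCR kernel, zero for t < 0.

    The analytic peak time is ``tau_d*tau_r/(tau_d - tau_r) * ln(tau_d/tau_r)``.
    """
    if not tau_decay_s > tau_rise_s > 0:
        raise ValueError(
            f"need tau_decay > tau_rise > 0, got {tau_decay_s}, {tau_rise_s}"
        )
    t = np.asarray(t, dtype=float)
    k = np.zeros_like(t)
    m = t >= 0
    k[m] = np.exp(-t[m] / tau_decay_s) - np.exp(-t[m] / tau_rise_s)
    tp = scr_peak_time(tau_rise_s, tau_decay_s)
    peak = np.exp(-tp / tau_decay_s) - np.exp(-tp / tau_rise_s)
    return k / peak


def scr_peak_time(tau_rise_s: float, tau_decay_s: float) -> float:
    """Closed-form time of the kernel maximum."""
    return tau_decay_s * tau_rise_s / (tau_decay_s - tau_rise_s) * np.log(tau_decay_s / tau_rise_s)


def _band_noise(n: int, rng: np.random.Generator, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band``."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, "bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    s = y.std()
    return y / s if s > 0 else y


def _burst_profile(n: int, i0: int, i1: int, fs: float, ramp_s: float) -> np.ndarray:
    """Rectangular amplitude profile with short raised-cosine edges."""
    prof = np.zeros(n)
    prof[i0:i1] = 1.0
    nr = int(round(ramp_s * fs))
    if nr > 1 and i1 - i0 > 2 * nr:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        prof[i0 : i0 + nr] = ramp
        prof[i1 - nr : i1] = ramp[::-1]
    return prof


# ---------------------------------------------------------------------------
# per-trial simulators

def simulate_eda_trial(
    config: GenConfig,
    condition: Condition | str,
    rng: np.random.Generator,
    segment_s: float = 15.0,
    onset_s: float = 2.0,
) -> tuple[np.ndarray, dict]:
    """One EDA segment containing (at most) one event-locked SCR.

    Returns the trace and the ground truth (response presence, amplitude,
    latency).  The question onset sits at ``onset_s`` within the segment so
    an 11-s epoch with a 1-s baseline fits.
    """
    cond = Condition(condition)
    scr, tonic, fs = config.scr, config.tonic, config.fs_hz
    n = int(round(segment_s * fs))
    t = np.arange(n) / fs
    trace = (
        tonic.level_uS
        + tonic.drift_slope_uS_per_min / 60.0 * t
        + tonic.slow_wave_amp_uS * np.sin(2 * np.pi * t / tonic.slow_wave_period_s)
    )
    present = bool(rng.random() < scr.response_prob)
    amp = np.nan
    latency = np.nan
    if present:
        mean = scr.amp_means_uS[cond.value]
        if scr.amp_cv > 0:
            k = 1.0 / scr.amp_cv**2
            amp = float(rng.gamma(k, mean / k))
        else:
            amp = float(mean)
        latency = float(rng.normal(scr.latency_mean_s, scr.latency_sd_s))
        trace = trace + amp * scr_kernel(t - (onset_s + latency), scr.tau_rise_s, scr.tau_decay_s)
    if tonic.noise_sd_uS > 0:
        trace = trace + rng.normal(0, tonic.noise_sd_uS, n)
    truth = {"scr_present": present, "scr_amp_uS": amp, "scr_latency_s": latency}
    return trace, truth


def simulate_emg_trial(
    config: GenConfig,
    condition: Condition | str,
    muscle: str,
    rng: np.random.Generator,
    segment_s: float = 15.0,
    onset_s: float = 2.0,
) -> tuple[np.ndarray, dict]:
    """One fEMG segment with background plus one burst of known duration."""
    cond = Condition(condition)
    emg, fs = config.emg, config.fs_hz
    n = int(round(segment_s * fs))
    trace = emg.background_rms_mV * _band_noise(n, rng, fs, emg.band_hz)
    mean_d = emg.burst_dur_means_s[muscle][cond.value]
    if emg.burst_dur_cv > 0:
        k = 1.0 / emg.burst_dur_cv**2
        dur = float(rng.gamma(k, mean_d / k))
    else:
        dur = float(mean_d)
    dur = float(np.clip(dur, emg.burst_min_s, min(emg.burst_max_s, 9.0)))
    # place the burst inside the scored 10-s window (starts 1 s after onset)
    start = onset_s + 1.0 + rng.uniform(0.5, max(0.51, 9.5 - dur))
    i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
    carrier = _band_noise(n, rng, fs, emg.band_hz)
    trace = trace + emg.burst_amp_mV * carrier * _burst_profile(n, i0, i1, fs, emg.ramp_s)
    truth = {"burst_dur_s": dur, "burst_start_s": start}
    return trace, truth


def simulate_ratings(
    config: GenConfig,
    conditions,
    subject_offset: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Self-confidence ratings for a sequence of trial conditions.

    Returns the clipped 0-100 ratings and the number of clipped values.
    """
    r = config.ratings
    means = np.array([r.condition_mean(c) for c in conditions], dtype=float)
    raw = means + subject_offset + rng.normal(0, r.residual_sd, len(means))
    clipped = np.clip(raw, 0.0, 100.0)
    return clipped, int(np.sum(raw != clipped))


# ---------------------------------------------------------------------------
# whole-subject / whole-study simulation

def simulate_subject(
    config: GenConfig, subject_id: str, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one subject's recording, events and ground truth."""
    fs = config.fs_hz
    n = int(round(config.recording_len_s * fs))
    t = np.arange(n) / fs
    tonic, scr, emg = config.tonic, config.scr, config.emg

    eda = (
        tonic.level_uS
        + tonic.drift_slope_uS_per_min / 60.0 * t
        + tonic.slow_wave_amp_uS * np.sin(2 * np.pi * t / tonic.slow_wave_period_s)
    )
    if tonic.noise_sd_uS > 0:
        eda = eda + rng.normal(0, tonic.noise_sd_uS, n)
    channels = {
        "corrugator": emg.background_rms_mV * _band_noise(n, rng, fs, emg.band_hz),
        "zygomaticus": emg.background_rms_mV * _band_noise(n, rng, fs, emg.band_hz),
    }

    subj_offset = rng.normal(0, config.ratings.subject_sd)
    events_rows, truth_rows = [], []
    for trial in range(1, config.trials_per_subject + 1):
        fb = FEEDBACK_TYPES[rng.integers(len(FEEDBACK_TYPES))]
        cond = label_condition(fb)
        rating, _ = simulate_ratings(config, [cond], subj_offset, rng)
        rating = float(rating[0])
        self_rating = "best" if rng.random() < config.p_best else "worst"
        for q in range(1, config.questions_per_trial + 1):
            onset = config.question_onset_s(trial, q)
            experimental = q == config.questions_per_trial
            # --- EDA response
            present = bool(rng.random() < scr.response_prob)
            amp, latency = np.nan, np.nan
            if present:
                mean = scr.amp_means_uS[cond.value] if experimental else scr.control_amp_uS
                if scr.amp_cv > 0:
                    kk = 1.0 / scr.amp_cv**2
                    amp = float(rng.gamma(kk, mean / kk))
                else:
                    amp = float(mean)
                latency = float(rng.normal(scr.latency_mean_s, scr.latency_sd_s))
                eda += amp * scr_kernel(t - (onset + latency), scr.tau_rise_s, scr.tau_decay_s)
            # --- EMG bursts
            burst_durs = {}
            for muscle, ch in channels.items():
                mean_d = (
                    emg.burst_dur_means_s[muscle][cond.value]
                    if experimental
                    else emg.control_burst_s
                )
                if emg.burst_dur_cv > 0:
                    kk = 1.0 / emg.burst_dur_cv**2
                    dur = float(rng.gamma(kk, mean_d / kk))
                else:
                    dur = float(mean_d)
                dur = float(np.clip(dur, emg.burst_min_s, min(emg.burst_max_s, 9.0)))
                start = onset + 1.0 + rng.uniform(0.5, max(0.51, 9.5 - dur))
                i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
                carrier = _band_noise(i1 - i0 + 2 * int(fs), rng, fs, emg.band_hz)
                seg = np.zeros(n)
                j0 = max(i0 - int(fs), 0)
                j1 = min(j0 + carrier.size, n)
                seg[j0:j1] = carrier[: j1 - j0]
                ch += emg.burst_amp_mV * seg * _burst_profile(n, i0, i1, fs, emg.ramp_s)
                burst_durs[muscle] = dur
            events_rows.append(
                {
                    "onset": onset,
                    "duration": 11.0,
                    "subject": subject_id,
                    "trial": trial,
                    "question": q,
                    "probability": fb.probability.value,
                    "valence": fb.valence.value,
                    "self_rating": self_rating,
                    "self_confidence": rating,
                }
            )
            truth_rows.append(
                {
                    "subject": subject_id,
                    "trial": trial,
                    "question": q,
                    "condition": cond.value,
                    "scr_present": present,
                    "scr_amp_uS": amp,
                    "scr_latency_s": latency,
                    "corr_burst_s": burst_durs["corrugator"],
                    "zygo_burst_s": burst_durs["zygomaticus"],
                    "rating": rating,
                }
            )
    signals = pd.DataFrame(
        {
            "time_s": t,
            "eda_uS": eda,
            "corr_mV": channels["corrugator"],
            "zygo_mV": channels["zygomaticus"],
        }
    )
    return signals, pd.DataFrame(events_rows), pd.DataFrame(truth_rows)


def iter_subjects(config: GenConfig):
    """Yield ``(subject_id, signals, events, truth)`` one subject at a time.

    Subject streams are spawned from the config seed, so results are
    deterministic and memory stays bounded for full-size studies.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    for i, ss in enumerate(seeds):
        sid = f"sub-{i + 1:02d}"
        rng = np.random.default_rng(ss)
        signals, events, truth = simulate_subject(config, sid, rng)
        yield sid, signals, events, truth


def simulate_study(config: GenConfig, out_dir=None):
    """Simulate the full study.

    With ``out_dir`` set, writes one signal CSV per subject plus a single
    events TSV and ground-truth CSV, and returns the paths.  Without it,
    returns ``(signals_by_subject, events, truth)`` in memory (intended for
    reduced-size configs).
    """
    all_events, all_truth = [], []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sid, signals, events, truth in iter_subjects(config):
            p = out / f"{sid}_signals.csv"
            write_signals(signals, p, float_format="%.5f")
            paths[sid] = p
            all_events.append(events)
            all_truth.append(truth)
        events = pd.concat(all_events, ignore_index=True)
        truth = pd.concat(all_truth, ignore_index=True)
        write_events(events, out / "events.tsv")
        truth.to_csv(out / "ground_truth.csv", index=False)
        return {"signals": paths, "events": out / "events.tsv", "truth": out / "ground_truth.csv"}
    signals_by_subject = {}
    for sid, signals, events, truth in iter_subjects(config):
        signals_by_subject[sid] = signals
        all_events.append(events)
        all_truth.append(truth)
    return (
        signals_by_subject,
        pd.concat(all_events, ignore_index=True),
        pd.concat(all_truth, ignore_index=True),
    )
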