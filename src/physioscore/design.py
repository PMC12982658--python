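"""Experimental design vocabulary, trial retention and event-locked epoching.

The study design crosses feedback *Probability* (Certain / Uncertain) with
feedback *Valence* (Positive / Negative).  Certain-Negative feedback followed
by a positive self-presentation defines Deception, Certain-Positive defines
Truth, and both Uncertain cells define Uncertainty regardless of valence.
Each trial ends with three questions posed to the participant; question 3 is
the experimental question, questions 1-2 serve as controls.

Signals are epoched into 11-s windows time-locked to question onset: one
second of baseline followed by a 10-s analysis window.  "Time 0" of the
analysis window is the end of the baseline second.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Probability",
    "Valence",
    "Condition",
    "FeedbackType",
    "TrialEvent",
    "Epoch",
    "EpochOutOfRangeError",
    "label_condition",
    "label_conditions",
    "retain_trials",
    "extract_epoch",
    "read_events",
    "write_events",
    "read_signals",
    "write_signals",
    "EVENT_COLUMNS",
    "SIGNAL_COLUMNS",
]

EVENT_COLUMNS = [
    "onset",
    "duration",
    "subject",
    "trial",
    "question",
    "probability",
    "valence",
    "self_rating",
    "self_confidence",
]

SIGNAL_COLUMNS = ["time_s", "eda_uS", "corr_mV", "zygo_mV"]


class Probability(str, enum.Enum):
    """Probability attached to the performance feedback."""

    CERTAIN = "Certain"
    UNCERTAIN = "Uncertain"


class Valence(str, enum.Enum):
    """Valence of the performance feedback."""

    POSITIVE = "Positive"
    NEGATIVE = "Negative"


class Condition(str, enum.Enum):
    """Analysis condition derived from the feedback type."""

    DECEPTION = "Deception"
    UNCERTAINTY = "Uncertainty"
    TRUTH = "Truth"


@dataclass(frozen=True)
class FeedbackType:
    """One of the four Probability x Valence feedback combinations."""

    probability: Probability
    valence: Valence

    def __post_init__(self) -> None:
        object.__setattr__(self, "probability", Probability(self.probability))
        object.__setattr__(self, "valence", Valence(self.valence))


@dataclass
class TrialEvent:
    """A single question event within a trial.

    ``onset_s`` is measured from the start of the recording.
    ``self_rating`` is the participant's binary performance self-rating
    ('best' or 'worst'); ``self_confidence`` is the 0-100 VAS rating of
    how convincing they believe they were.
    """

    subject_id: str
    trial_index: int
    question_index: int
    onset_s: float
    feedback: FeedbackType
    self_rating: str
    self_confidence: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if not 0.0 <= self.self_confidence <= 100.0:
            raise ValueError(
                f"self_confidence must lie in [0, 100], got {self.self_confidence}"
            )
        if self.self_rating not in ("best", "worst"):
            raise ValueError(f"self_rating must be 'best' or 'worst', got {self.self_rating!r}")

    @property
    def condition(self) -> Condition:
        return label_condition(self.feedback)


@dataclass
class Epoch:
    """An event-locked signal segment: 1-s baseline + 10-s analysis window."""

    samples: np.ndarray
    fs_hz: float = 500.0
    baseline_s: float = 1.0
    duration_s: float = 11.0
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = int(round(self.duration_s * self.fs_hz))
        if self.samples.ndim != 1 or self.samples.size != expected:
            raise ValueError(
                f"epoch must hold {expected} samples "
                f"({self.duration_s} s at {self.fs_hz} Hz), got shape {self.samples.shape}"
            )

    @property
    def n_baseline(self) -> int:
        return int(round(self.baseline_s * self.fs_hz))

    @property
    def baseline(self) -> np.ndarray:
        """The baseline second preceding time 0."""
        return self.samples[: self.n_baseline]

    @property
    def analysis_window(self) -> np.ndarray:
        """The post-baseline analysis window (time 0 onwards)."""
        return self.samples[self.n_baseline :]


class EpochOutOfRangeError(ValueError):
    """The requested epoch window does not fit inside the recording."""


def label_condition(feedback: FeedbackType) -> Condition:
    """Map a feedback type onto its analysis condition.

    Certain-Negative -> Deception, Certain-Positive -> Truth, and both
    Uncertain cells -> Uncertainty (valence is ignored under uncertainty).
    """
    fb = feedback if isinstance(feedback, FeedbackType) else FeedbackType(*feedback)
    if fb.probability is Probability.UNCERTAIN:
        return Condition.UNCERTAINTY
    if fb.valence is Valence.NEGATIVE:
        return Condition.DECEPTION
    return Condition.TRUTH


def label_conditions(events: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of an events table with a ``condition`` column added."""
    out = events.copy()
    out["condition"] = [
        label_condition(FeedbackType(Probability(p), Valence(v))).value
        for p, v in zip(out["probability"], out["valence"])
    ]
    return out


def retain_trials(trials):
    """Keep only trials the participant rated as among the best.

    Only positively self-rated trials can carry the self-enhancing behavior
    the analysis targets, so negatively rated trials are dropped before any
    statistics.  Accepts either a sequence of :class:`TrialEvent` or an
    events :class:`~pandas.DataFrame` with a ``self_rating`` column; order
    is preserved and the operation is idempotent.
    """
    if isinstance(trials, pd.DataFrame):
        return trials[trials["self_rating"] == "best"].copy()
    return [t for t in trials if t.self_rating == "best"]


def extract_epoch(
    trace: np.ndarray,
    fs_hz: float,
    onset_s: float,
    baseline_s: float = 1.0,
    duration_s: float = 11.0,
    label: str | None = None,
) -> Epoch:
    """Cut the event-locked epoch ``[onset - baseline, onset + duration - baseline)``.

    ``onset_s`` is the question onset; the epoch starts one baseline second
    earlier so that the first ``fs_hz`` samples are the baseline.  The window
    is half-open on a 0-based sample grid with the onset snapped to the
    nearest sample, so the sample count is exactly
    ``round(duration_s * fs_hz)``.

    Raises
    ------
    EpochOutOfRangeError
        If the window does not fit in the trace; the message names ``label``
        when given so the offending trial can be identified.
    """
    trace = np.asarray(trace, dtype=float)
    if onset_s < 0:
        raise EpochOutOfRangeError(f"onset_s must be >= 0, got {onset_s}")
    n = int(round(duration_s * fs_hz))
    start = int(round((onset_s - baseline_s) * fs_hz))
    stop = start + n
    if start < 0 or stop > trace.size:
        who = f" for {label}" if label else ""
        raise EpochOutOfRangeError(
            f"epoch [{onset_s - baseline_s:.3f}, {onset_s - baseline_s + duration_s:.3f}) s"
            f"{who} exceeds trace of {trace.size / fs_hz:.3f} s"
        )
    return Epoch(
        samples=trace[start:stop],
        fs_hz=fs_hz,
        baseline_s=baseline_s,
        duration_s=duration_s,
        label=label,
    )


def read_events(path) -> pd.DataFrame:
    """Read a BIDS-events-style tab-separated events table."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} is missing columns {missing}")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, columns=[c for c in EVENT_COLUMNS if c in events.columns] + [c for c in events.columns if c not in EVENT_COLUMNS])


def read_signals(path) -> pd.DataFrame:
    """Read a per-subject signal CSV (time_s, eda_uS, corr_mV, zygo_mV)."""
    df = pd.read_csv(path)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signal file {path} is missing columns {missing}")
    return df


def write_signals(signals: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    signals.to_csv(path, index=False, float_format=float_format)
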