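"""End-to-end study analysis: scoring -> trial table -> mixed-model report.

Glues the signal scorers and the inference layer together the way the study
analyzes its recordings: score every question epoch, keep experimental-
question trials the participant self-rated positively, winsorize each
measure across the pooled retained trials, drop invalid/below-threshold TTP
trials, reflect fEMG durations for the Gamma model, and fit the per-measure
mixed models with FDR-corrected pairwise contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import label_conditions, retain_trials
from .eda import TtpScorer, TtpStatus
from .emg import EmgDurationScorer, Muscle
from .stats import (
    fit_gamma_glme,
    fit_lme,
    transform_femg,
    uncertainty_valence_control,
    winsorize,
)

__all__ = ["score_subject", "score_study", "analyze_trial_table", "MEASURES"]

MEASURES = ("self_confidence", "ttp", "corr_duration", "zygo_duration")


def score_subject(
    signals: pd.DataFrame,
    events: pd.DataFrame,
    eda_scorer: TtpScorer | None = None,
    emg_scorer: EmgDurationScorer | None = None,
) -> pd.DataFrame:
    """Score one subject's recording into a per-question trial table."""
    eda_scorer = eda_scorer or TtpScorer()
    emg_scorer = emg_scorer or EmgDurationScorer()
    events = label_conditions(events)
    eda = eda_scorer.score_recording(signals, events)
    out = events.copy()
    out["ttp_uS"] = eda["ttp_uS"].to_numpy()
    out["ttp_status"] = eda["status"].to_numpy()
    for muscle, col in ((Muscle.CORRUGATOR, "corr_duration_s"), (Muscle.ZYGOMATICUS, "zygo_duration_s")):
        d = emg_scorer.score_recording(signals, events, muscle)
        out[col] = d["duration_s"].to_numpy()
    return out


def score_study(subject_iter, eda_scorer=None, emg_scorer=None) -> pd.DataFrame:
    """Score an iterable of ``(subject_id, signals, events, *rest)`` tuples."""
    tables = []
    for item in subject_iter:
        _, signals, events = item[0], item[1], item[2]
        tables.append(score_subject(signals, events, eda_scorer, emg_scorer))
    return pd.concat(tables, ignore_index=True)


def _measure_frame(kept: pd.DataFrame, column: str) -> pd.DataFrame:
    df = kept[["subject", "condition", "probability", "valence", column]].copy()
    df = df.rename(columns={column: "value"})
    return df.dropna(subset=["value"])


def analyze_trial_table(
    table: pd.DataFrame,
    question: int = 3,
    alpha: float = 0.05,
    apply_winsorize: bool = True,
    valence_control: bool = True,
) -> dict:
    """Run the full inference chain on a scored trial table.

    ``question`` selects which question's epochs are analyzed (3 is the
    experimental question; 1-2 reproduce the control-question analyses).
    Returns a JSON-serializable nested report with retention/exclusion
    tallies, the uncertainty-valence control tests, per-measure omnibus
    tests, coefficients and FDR-corrected pairwise contrasts.
    """
    if "condition" not in table.columns:
        table = label_conditions(table)
    t = table[table["question"] == question]
    kept = retain_trials(t)
    report: dict = {
        "question": question,
        "retention": {
            "n_total": int(len(t)),
            "n_kept": int(len(kept)),
            "n_dropped": int(len(t) - len(kept)),
            "dropped_per_subject": {
                str(s): int(v)
                for s, v in (t[t["self_rating"] != "best"].groupby("subject").size().items())
            },
        },
        "measures": {},
    }

    # --- self-confidence ratings (linear mixed model)
    df = _measure_frame(kept, "self_confidence")
    if apply_winsorize:
        df["value"] = winsorize(df["value"].to_numpy())
    m = fit_lme(df)
    report["measures"]["self_confidence"] = m.summary()

    # --- trough-to-peak amplitude (Gamma log link)
    valid = kept[kept["ttp_status"] == TtpStatus.VALID.value]
    df = _measure_frame(valid, "ttp_uS")
    excl = kept["ttp_status"].value_counts().to_dict()
    if apply_winsorize and len(df):
        df["value"] = winsorize(df["value"].to_numpy())
    entry = {"exclusions": {str(k): int(v) for k, v in excl.items()}}
    if valence_control:
        ctrl = uncertainty_valence_control(df, family="gamma", alpha=alpha)
        entry["valence_control"] = {
            "contrast": ctrl["contrast"],
            "significant": ctrl["significant"],
        }
    m = fit_gamma_glme(df)
    entry.update(m.summary())
    report["measures"]["ttp"] = entry

    # --- fEMG durations (reflected, Gamma log link)
    for column, name in (("corr_duration_s", "corr_duration"), ("zygo_duration_s", "zygo_duration")):
        df = _measure_frame(kept, column)
        if apply_winsorize:
            df["value"] = winsorize(df["value"].to_numpy())
        vals, flags = transform_femg(df["value"].to_numpy(), return_flags=True)
        df["value"] = vals
        entry = {"n_support_violations": int(flags.sum())}
        df = df[~flags]
        if valence_control:
            ctrl = uncertainty_valence_control(df, family="gamma", alpha=alpha)
            entry["valence_control"] = {
                "contrast": ctrl["contrast"],
                "significant": ctrl["significant"],
            }
        m = fit_gamma_glme(df)
        entry.update(m.summary())
        report["measures"][name] = entry

    return jsonable(report)


def jsonable(obj):
    """Recursively convert numpy scalars/arrays so json.dump accepts the report."""
    if isinstance(obj, dict):
        return {k: jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
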