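"""Trial-level inference: winsorization, mixed models, contrasts and FDR.

Self-confidence ratings are analyzed with a linear mixed model (random
subject intercept, REML); trough-to-peak amplitudes and transformed fEMG
durations with a Gamma log-link mixed model (see :mod:`physioscore.glmm`).
Condition enters as the single fixed effect with Truth as the reference
level, so the Deception and Uncertainty coefficients are directly the
Deception-vs-Truth and Uncertainty-vs-Truth effects; the third pairwise
comparison is the difference of the two.  Pairwise comparisons are single-df
Wald F-tests (numerically t^2) with residual denominator degrees of freedom,
corrected across the three condition pairs by Benjamini-Hochberg FDR.

Before modelling, each measure is winsorized across the pooled retained
trials: values above its 95th percentile are collapsed to the 95th
percentile and values below its 1st percentile to the 1st percentile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .glmm import fit_gamma_glmm

__all__ = [
    "winsorize",
    "Winsorizer",
    "transform_femg",
    "fdr_adjust",
    "partial_eta_sq",
    "ConditionLinearMixedModel",
    "ConditionGammaMixedModel",
    "fit_lme",
    "fit_gamma_glme",
    "pairwise_contrasts",
    "uncertainty_valence_control",
    "DegenerateDesignError",
]


class DegenerateDesignError(ValueError):
    """The design has too few conditions or subjects to fit the model."""


# ---------------------------------------------------------------------------
# outlier handling

def winsorize(
    values, lower_pct: float = 1.0, upper_pct: float = 95.0, method: str = "linear"
) -> np.ndarray:
    """Collapse the tails of ``values`` to the 1st / 95th percentiles.

    The caps are deliberately asymmetric (95th above, 1st below).  The
    percentile convention is exposed via ``method`` (any convention
    :func:`numpy.percentile` accepts); the default linearly interpolates
    between order statistics.  Rank order is always preserved
    (non-strictly).  Note that under interpolating conventions the
    operation is only approximately idempotent — capping the tails moves
    the sample percentiles themselves — whereas order-statistic
    conventions such as ``"lower"`` are exactly idempotent.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("winsorize requires at least one value")
    lo, hi = np.percentile(values, [lower_pct, upper_pct], method=method)
    return np.clip(values, lo, hi)


class Winsorizer(TransformerMixin, BaseEstimator):
    """Column-wise winsorizing transformer.

    ``fit`` learns the per-column 1st and 95th percentile caps;
    ``transform`` clips to them, so a fitted transformer applies the
    training caps to new data.
    """

    def __init__(self, lower_pct: float = 1.0, upper_pct: float = 95.0, method: str = "linear"):
        self.lower_pct = lower_pct
        self.upper_pct = upper_pct
        self.method = method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit Winsorizer on empty input")
        self.lower_ = np.percentile(X, self.lower_pct, axis=0, method=self.method)
        self.upper_ = np.percentile(X, self.upper_pct, axis=0, method=self.method)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.clip(X, self.lower_, self.upper_)


def transform_femg(values, max_duration_s: float = 10.0, return_flags: bool = False):
    """Reflect fEMG durations (x -> 10 - x) so longer activity maps to
    smaller positive values suitable for a Gamma model.

    Durations exactly at the window length map to 0, which violates the
    Gamma support; those entries are flagged so the caller can exclude
    them.  Values above the window length are rejected.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values > max_duration_s + 1e-12):
        bad = float(values[values > max_duration_s + 1e-12][0])
        raise ValueError(f"duration {bad} exceeds the {max_duration_s}-s window")
    out = max_duration_s - values
    if return_flags:
        return out, out <= 0.0
    return out


# ---------------------------------------------------------------------------
# multiple testing and effect size

def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared approximated from an F statistic.

    Uses F*df1 / (F*df1 + df2).  This is the standard ANOVA-style
    approximation; for mixed models it understates effect sizes computed
    from variance components, so treat it as a rough magnitude only.
    """
    if F < 0:
        raise ValueError(f"F must be >= 0, got {F}")
    return F * df1 / (F * df1 + df2)


# ---------------------------------------------------------------------------
# mixed models

_REFERENCE = "Truth"


def _design(table: pd.DataFrame, value_col, condition_col, subject_col, reference):
    value = np.asarray(table[value_col], dtype=float)
    cond = np.asarray(table[condition_col]).astype(str)
    groups = np.asarray(table[subject_col])
    levels = sorted(set(cond))
    if len(levels) < 2:
        raise DegenerateDesignError(
            f"need at least 2 condition levels, got {levels}"
        )
    if len(set(groups)) < 2:
        raise DegenerateDesignError("need at least 2 subjects")
    if reference in levels:
        levels = [reference] + [l for l in levels if l != reference]
    X = np.column_stack([np.ones(len(cond))] + [(cond == l).astype(float) for l in levels[1:]])
    names = ["Intercept"] + [f"{l}-{levels[0]}" for l in levels[1:]]
    return value, X, names, groups, levels


class _ConditionMixedModelBase(BaseEstimator):
    """Shared surface of the condition-effect mixed models."""

    def __init__(self, reference: str = _REFERENCE, value_col: str = "value",
                 condition_col: str = "condition", subject_col: str = "subject"):
        self.reference = reference
        self.value_col = value_col
        self.condition_col = condition_col
        self.subject_col = subject_col

    # subclasses set: params_, bse_, cov_params_, df_resid_, nobs_,
    # random_intercept_var_, exog_names_, levels_

    def _finish(self):
        """Coefficient table, omnibus Wald F over condition terms, eta_p^2."""
        t = self.params_ / self.bse_
        p = 2 * spstats.t.sf(np.abs(t), self.df_resid_)
        self.coef_ = pd.DataFrame(
            {"term": self.exog_names_, "beta": self.params_, "se": self.bse_,
             "t": t, "df": self.df_resid_, "p": p}
        )
        q = len(self.exog_names_) - 1
        L = np.zeros((q, len(self.exog_names_)))
        for i in range(q):
            L[i, i + 1] = 1.0
        est = L @ self.params_
        V = L @ self.cov_params_ @ L.T
        F = float(est @ np.linalg.solve(V, est)) / q
        self.omnibus_ = {
            "F": F, "df1": q, "df2": self.df_resid_,
            "p": float(spstats.f.sf(F, q, self.df_resid_)),
        }
        self.eta_p_sq_ = partial_eta_sq(F, q, self.df_resid_)
        return self

    def pairwise_contrasts(self, fdr: bool = True) -> pd.DataFrame:
        """All pairwise condition comparisons as single-df Wald F-tests.

        Each contrast is a linear combination of the fitted coefficients;
        its F statistic equals the squared t.  Raw p-values are BH-FDR
        adjusted across the family of pairwise comparisons.
        """
        levels = self.levels_
        basis = {levels[0]: np.zeros(len(self.exog_names_))}
        for i, l in enumerate(levels[1:]):
            e = np.zeros(len(self.exog_names_))
            e[i + 1] = 1.0
            basis[l] = e
        rows = []
        for i in range(1, len(levels)):
            for j in range(i):
                a, b = levels[i], levels[j]
                c = basis[a] - basis[b]
                est = float(c @ self.params_)
                se = float(np.sqrt(c @ self.cov_params_ @ c))
                t = est / se
                F = t * t
                p = float(spstats.f.sf(F, 1, self.df_resid_))
                rows.append({"pair": f"{a}-{b}", "beta": est, "se": se, "t": t,
                             "F": F, "df": self.df_resid_, "p_raw": p})
        out = pd.DataFrame(rows)
        if fdr:
            out["p_fdr"] = fdr_adjust(out["p_raw"].to_numpy())
        return out

    def summary(self) -> dict:
        """JSON-serializable fit report."""
        return {
            "omnibus": self.omnibus_,
            "partial_eta_sq": self.eta_p_sq_,
            "coefficients": self.coef_.to_dict(orient="records"),
            "contrasts": self.pairwise_contrasts().to_dict(orient="records"),
            "random_intercept_var": self.random_intercept_var_,
            "nobs": self.nobs_,
        }


class ConditionLinearMixedModel(_ConditionMixedModelBase):
    """Linear mixed model ``value ~ condition + (1 | subject)`` fitted by REML.

    Used for self-confidence ratings.  Estimation is delegated to
    statsmodels' ``MixedLM``; tests use residual degrees of freedom
    (``nobs - n_fixed_effects``).
    """

    def fit(self, table: pd.DataFrame):
        import warnings

        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        y, X, names, groups, levels = _design(
            table, self.value_col, self.condition_col, self.subject_col, self.reference
        )
        with warnings.catch_warnings():
            # boundary estimates (sigma_b -> 0) are expected under null
            # simulations and are not an error for Wald inference
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)  # singular cov_re at sigma_b -> 0
            res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        k = X.shape[1]
        self.params_ = np.asarray(res.fe_params, dtype=float)
        self.cov_params_ = np.asarray(res.cov_params())[:k, :k]
        self.bse_ = np.sqrt(np.diag(self.cov_params_))
        self.exog_names_ = names
        self.levels_ = levels
        self.nobs_ = int(len(y))
        self.df_resid_ = int(len(y) - k)
        self.random_intercept_var_ = float(np.asarray(res.cov_re)[0, 0])
        self.residual_var_ = float(res.scale)
        self.converged_ = bool(res.converged)
        return self._finish()


class ConditionGammaMixedModel(_ConditionMixedModelBase):
    """Gamma log-link mixed model ``log E[value] ~ condition + (1 | subject)``.

    Used for TTP amplitudes and transformed fEMG durations; coefficients
    are on the log scale.  Values must be strictly positive.
    """

    def __init__(self, reference: str = _REFERENCE, value_col: str = "value",
                 condition_col: str = "condition", subject_col: str = "subject",
                 n_nodes: int = 15):
        super().__init__(reference, value_col, condition_col, subject_col)
        self.n_nodes = n_nodes

    def fit(self, table: pd.DataFrame):
        y, X, names, groups, levels = _design(
            table, self.value_col, self.condition_col, self.subject_col, self.reference
        )
        res = fit_gamma_glmm(y, X, groups, exog_names=names, n_nodes=self.n_nodes)
        self.result_ = res
        self.params_ = res.params
        self.cov_params_ = res.cov_params
        self.bse_ = res.bse
        self.exog_names_ = names
        self.levels_ = levels
        self.nobs_ = res.nobs
        self.df_resid_ = res.df_resid
        self.random_intercept_var_ = res.sigma_b**2
        self.shape_ = res.shape
        self.converged_ = res.converged
        return self._finish()


def fit_lme(table: pd.DataFrame, **kwargs) -> ConditionLinearMixedModel:
    """Fit the ratings linear mixed model; thin wrapper over the estimator."""
    return ConditionLinearMixedModel(**kwargs).fit(table)


def fit_gamma_glme(table: pd.DataFrame, **kwargs) -> ConditionGammaMixedModel:
    """Fit the Gamma log-link mixed model; thin wrapper over the estimator."""
    return ConditionGammaMixedModel(**kwargs).fit(table)


def pairwise_contrasts(fit: _ConditionMixedModelBase, fdr: bool = True) -> pd.DataFrame:
    """Pairwise condition contrasts of a fitted model (functional form)."""
    return fit.pairwise_contrasts(fdr=fdr)


def uncertainty_valence_control(
    table: pd.DataFrame,
    family: str = "gamma",
    alpha: float = 0.05,
    value_col: str = "value",
    subject_col: str = "subject",
) -> dict:
    """Test the two Uncertain sub-conditions before merging them.

    The Uncertain-Positive and Uncertain-Negative cells differ in valence,
    so they are merged into a single Uncertainty level only after the same
    mixed-model machinery finds no significant difference between them.
    ``table`` must carry ``probability`` and ``valence`` columns; rows with
    ``probability == 'Uncertain'`` enter the control model with valence as
    the (two-level) condition.

    Returns a dict with the sub-condition model, the Positive-Negative
    contrast, the merge decision, and — when merged — the full table with
    a 3-level ``condition`` column.
    """
    unc = table[table["probability"] == "Uncertain"].copy()
    unc["condition"] = unc["valence"].astype(str)
    cls = ConditionGammaMixedModel if family == "gamma" else ConditionLinearMixedModel
    model = cls(reference="Negative", value_col=value_col, subject_col=subject_col)
    model.fit(unc)
    contrast = model.pairwise_contrasts(fdr=False).iloc[0].to_dict()
    significant = contrast["p_raw"] < alpha
    merged = None
    if not significant:
        from .design import label_conditions

        merged = label_conditions(table)
    return {
        "model": model,
        "contrast": contrast,
        "significant": bool(significant),
        "merged": merged,
    }
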