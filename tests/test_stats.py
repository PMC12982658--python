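import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physioscore.stats import (
    ConditionLinearMixedModel,
    DegenerateDesignError,
    Winsorizer,
    fdr_adjust,
    fit_lme,
    partial_eta_sq,
    transform_femg,
    uncertainty_valence_control,
    winsorize,
)

# ---------------------------------------------------------------------------
# brute-force oracles


def winsorize_oracle(values, lower_pct=1.0, upper_pct=95.0):
    """Sort-based percentile (linear interpolation) + explicit capping."""
    v = np.asarray(values, dtype=float)
    srt = np.sort(v)
    n = len(srt)

    def pct(q):
        h = (n - 1) * q / 100.0
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

    lo, hi = pct(lower_pct), pct(upper_pct)
    return np.array([min(max(x, lo), hi) for x in v])


def bh_oracle(p):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestWinsorize:
    def test_integers_1_to_100_match_oracle(self):
        v = np.arange(1, 101, dtype=float)
        np.testing.assert_allclose(winsorize(v), winsorize_oracle(v))

    def test_constant_sequence_unchanged(self):
        v = np.full(17, 3.3)
        np.testing.assert_array_equal(winsorize(v), v)

    def test_matches_oracle_on_random_vectors(self, rng):
        for n in (1, 2, 5, 30, 500):
            v = rng.normal(size=n) * 10
            np.testing.assert_allclose(winsorize(v), winsorize_oracle(v), atol=1e-12)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_rank_preserving_and_idempotence(self, vals):
        v = np.array(vals)
        w = winsorize(v)
        # non-strict rank preservation (any convention)
        for i in range(len(v)):
            for j in range(len(v)):
                if v[i] < v[j]:
                    assert w[i] <= w[j] + 1e-12
        # order-statistic convention: exactly idempotent
        wl = winsorize(v, method="lower")
        np.testing.assert_array_equal(winsorize(wl, method="lower"), wl)
        # interpolating convention: approximately idempotent once the tails
        # hold a few points (for tiny n the interpolated percentile sits well
        # inside the sample, so re-capping keeps contracting)
        if len(v) >= 25:
            span = np.ptp(w) if np.ptp(w) > 0 else 1.0
            assert np.max(np.abs(winsorize(w) - w)) <= 0.05 * span + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            winsorize([])

    def test_winsorizer_estimator_applies_training_caps(self, rng):
        X = rng.normal(size=(200, 2))
        w = Winsorizer().fit(X)
        out = w.transform(np.array([[1e9, -1e9]]))
        assert out[0, 0] == pytest.approx(np.percentile(X[:, 0], 95))
        assert out[0, 1] == pytest.approx(np.percentile(X[:, 1], 1))


class TestTransformFemg:
    @pytest.mark.parametrize("x, expected", [(3.2, 6.8), (0.0, 10.0), (10.0, 0.0)])
    def test_reflection(self, x, expected):
        assert transform_femg([x])[0] == pytest.approx(expected)

    def test_full_window_flagged_as_support_violation(self):
        vals, flags = transform_femg([10.0, 3.0], return_flags=True)
        assert flags.tolist() == [True, False]

    def test_above_window_rejected(self):
        with pytest.raises(ValueError):
            transform_femg([10.5])


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.3]), [0.3])

    def test_hand_worked_three_values(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2, 0.2]), [0.2] * 4)

    def test_matches_oracle_exhaustively_small(self, rng):
        for m in range(1, 7):
            for _ in range(200):
                p = np.round(rng.random(m), 3)
                np.testing.assert_allclose(fdr_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_rank_and_capped(self, rng):
        p = rng.random(25)
        adj = fdr_adjust(p)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestPartialEtaSq:
    def test_zero_f_gives_zero(self):
        assert partial_eta_sq(0.0, 2, 300) == 0.0

    def test_reference_arithmetic(self):
        assert partial_eta_sq(5.845, 2, 376) == pytest.approx(0.0302, abs=5e-4)

    def test_limit_approaches_one(self):
        assert partial_eta_sq(1e9, 2, 300) > 0.999


# ---------------------------------------------------------------------------
# mixed models


def make_ratings_table(rng, n_sub=24, n_trials=18, deltas=(-10.516, -4.491),
                       subject_sd=10.0, residual_sd=15.0, mean_truth=70.0):
    conds = np.array(["Truth", "Deception", "Uncertainty"])
    rows = []
    for s in range(n_sub):
        off = rng.normal(0, subject_sd)
        cs = rng.integers(0, 3, n_trials)
        for c in cs:
            mu = mean_truth + (0, deltas[0], deltas[1])[c]
            rows.append({"subject": f"s{s}", "condition": conds[c],
                         "value": mu + off + rng.normal(0, residual_sd)})
    return pd.DataFrame(rows)


class TestLinearMixedModel:
    def test_recovers_condition_effects(self, rng):
        df = make_ratings_table(rng, n_sub=40, n_trials=30)
        m = fit_lme(df)
        coef = m.coef_.set_index("term")
        assert coef.loc["Deception-Truth", "beta"] == pytest.approx(-10.516, abs=2.5)
        assert coef.loc["Uncertainty-Truth", "beta"] == pytest.approx(-4.491, abs=2.5)
        assert m.omnibus_["p"] < 0.01
        assert m.omnibus_["df1"] == 2
        assert 25 < m.random_intercept_var_ < 400

    def test_contrast_linear_combination_identity(self, rng):
        df = make_ratings_table(rng)
        m = fit_lme(df)
        c = m.pairwise_contrasts().set_index("pair")
        coef = m.coef_.set_index("term")
        assert c.loc["Uncertainty-Deception", "beta"] == pytest.approx(
            coef.loc["Uncertainty-Truth", "beta"] - coef.loc["Deception-Truth", "beta"], rel=1e-9
        )

    def test_single_df_f_equals_t_squared(self, rng):
        df = make_ratings_table(rng)
        c = fit_lme(df).pairwise_contrasts()
        np.testing.assert_allclose(c["F"], c["t"] ** 2, rtol=1e-12)

    def test_fdr_bounds(self, rng):
        c = fit_lme(make_ratings_table(rng)).pairwise_contrasts()
        assert np.all(c["p_fdr"] >= c["p_raw"])
        assert np.all(c["p_fdr"] <= 1.0)

    def test_no_effect_gives_small_f(self, rng):
        df = make_ratings_table(rng, deltas=(0.0, 0.0), subject_sd=0.1, residual_sd=1.0,
                                n_sub=30, n_trials=30)
        m = fit_lme(df)
        assert m.omnibus_["p"] > 0.001  # typically far from significant

    def test_label_permutation_invariance(self, rng):
        df = make_ratings_table(rng)
        m1 = fit_lme(df)
        swap = {"Truth": "Deception", "Deception": "Truth", "Uncertainty": "Uncertainty"}
        df2 = df.assign(condition=df["condition"].map(swap))
        m2 = fit_lme(df2)
        # omnibus F is invariant under relabeling of condition levels
        assert m2.omnibus_["F"] == pytest.approx(m1.omnibus_["F"], rel=1e-6)
        c1 = m1.pairwise_contrasts().set_index("pair")
        c2 = m2.pairwise_contrasts().set_index("pair")
        assert c2.loc["Uncertainty-Deception", "beta"] == pytest.approx(
            c1.loc["Uncertainty-Truth", "beta"], rel=1e-6
        )

    def test_single_condition_rejected(self, rng):
        df = make_ratings_table(rng)
        with pytest.raises(DegenerateDesignError):
            fit_lme(df[df["condition"] == "Truth"])

    def test_single_subject_rejected(self, rng):
        df = make_ratings_table(rng)
        with pytest.raises(DegenerateDesignError):
            fit_lme(df[df["subject"] == "s0"])


class TestValenceControl:
    def _table(self, rng, valence_effect=0.0, n_sub=24, n_trials=16):
        rows = []
        for s in range(n_sub):
            b = rng.normal(0, 0.3)
            for _ in range(n_trials):
                prob = "Uncertain" if rng.random() < 0.5 else "Certain"
                val = "Positive" if rng.random() < 0.5 else "Negative"
                eta = np.log(0.4) + b
                if prob == "Uncertain" and val == "Positive":
                    eta += valence_effect
                rows.append({"subject": f"s{s}", "probability": prob, "valence": val,
                             "value": rng.gamma(6.25, np.exp(eta) / 6.25)})
        return pd.DataFrame(rows)

    def test_identical_subconditions_merge(self, rng):
        out = uncertainty_valence_control(self._table(rng))
        assert not out["significant"]
        assert set(out["merged"]["condition"]) == {"Deception", "Uncertainty", "Truth"}

    def test_large_valence_effect_detected(self, rng):
        out = uncertainty_valence_control(self._table(rng, valence_effect=0.5, n_sub=32))
        assert out["significant"]
        assert out["merged"] is None
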