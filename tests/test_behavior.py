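"""Behavioural layer: exclusion bookkeeping, fear-side decision mapping,
repeated-measures ANOVA against a first-principles oracle, post hocs."""

import numpy as np
import pandas as pd
import pytest
from _reference import ref_rm_anova

from ensemble_ddm.behavior import (
    ExclusionReport,
    decision_proportions,
    filter_rts,
    pairwise_posthoc,
    rm_anova_3x3,
)


def trials(rows):
    return pd.DataFrame(rows, columns=["subject_id", "attn", "stim", "choice", "rt_s"])


class TestFilter:
    def test_nothing_excluded_below_ceiling(self):
        df = trials([(1, "general", "neutral", "upper", 1.0)] * 5)
        kept, report = filter_rts(df)
        assert len(kept) == 5 and report.excluded == 0

    def test_ten_percent_excluded(self):
        rts = [0.5] * 9 + [4.5]
        df = trials([(1, "general", "neutral", "upper", rt) for rt in rts])
        kept, report = filter_rts(df)
        assert len(kept) == 9
        assert report.excluded == 1
        assert report.exclusion_rate == pytest.approx(0.10)

    def test_nonpositive_rt_rejected(self):
        df = trials([(1, "general", "neutral", "upper", 0.0)])
        with pytest.raises(ValueError):
            filter_rts(df)

    def test_cohort_scale_bookkeeping(self):
        # 95 subjects x 900 trials with 443 slow trials leaves 85,057
        report = ExclusionReport(presented=95 * 900, excluded=443)
        assert report.valid == 85_057
        assert report.exclusion_rate == pytest.approx(0.0052, abs=5e-5)


class TestDecisionProportions:
    def test_all_fear_side(self):
        df = trials([(1, "general", "neutral", "upper", 0.5)] * 10)
        out = decision_proportions(df)
        assert out.loc[0, "fear_side_proportion"] == 1.0

    def test_not_happy_fraction(self):
        rows = [(1, "happy", "neutral", "upper", 0.5)] * 6 + [
            (1, "happy", "neutral", "lower", 0.5)
        ] * 4
        out = decision_proportions(trials(rows))
        assert out.loc[0, "fear_side_proportion"] == pytest.approx(0.6)

    def test_happy_choice_never_counts_fear_side(self):
        # "Happy" is the lower boundary under happy-attention; a block of
        # pure happy choices must register zero fear-side decisions
        rows = [(1, "happy", "neutral", "lower", 0.5)] * 10
        out = decision_proportions(trials(rows))
        assert out.loc[0, "fear_side_proportion"] == 0.0

    def test_excluded_trials_tracked_per_cell(self):
        rows = [(1, "general", "neutral", "upper", 0.5)] * 8 + [
            (1, "general", "neutral", "upper", 5.0)
        ] * 2
        out = decision_proportions(trials(rows))
        assert out.loc[0, "n_valid"] == 8 and out.loc[0, "n_excluded"] == 2

    def test_empty_cell_is_nan_not_zero(self):
        rows = [(1, "general", "neutral", "upper", 5.0)] * 3  # all excluded
        out = decision_proportions(trials(rows))
        assert np.isnan(out.loc[0, "fear_side_proportion"])
        assert np.isnan(out.loc[0, "mean_rt"])

    def test_trial_order_invariance(self, rng):
        rows = [
            (s, a, st, rng.choice(["upper", "lower"]), rng.uniform(0.3, 1.0))
            for s in (1, 2)
            for a in ("general", "fear", "happy")
            for st in ("neutral", "fearful", "happy")
            for _ in range(6)
        ]
        df = trials(rows)
        shuffled = df.sample(frac=1, random_state=0)
        a = decision_proportions(df).sort_values(["subject_id", "attn", "stim"]).reset_index(drop=True)
        b = decision_proportions(shuffled).sort_values(["subject_id", "attn", "stim"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


def long_from_cube(values):
    """(subjects, 3, 3) cube -> long-format cell table."""
    n = values.shape[0]
    rows = []
    for s in range(n):
        for i, stim in enumerate(("neutral", "fearful", "happy")):
            for j, attn in enumerate(("general", "fear", "happy")):
                rows.append((s + 1, stim, attn, values[s, i, j]))
    return pd.DataFrame(rows, columns=["subject_id", "stim", "attn", "value"])


class TestRmAnova:
    def test_matches_first_principles_oracle(self, rng):
        values = rng.normal(size=(14, 3, 3))
        res = rm_anova_3x3(long_from_cube(values), compute_eta_ci=False)
        ref = ref_rm_anova(values)
        for key, label in (("a", "stim"), ("b", "attn"), ("ab", "interaction")):
            ss_e, ss_err, F, df1, df2 = ref[key]
            eff = res.effects[label]
            assert eff.F == pytest.approx(F, abs=1e-9, rel=1e-9)
            assert (eff.df_num, eff.df_den) == (df1, df2)
            assert eff.eta_p2 == pytest.approx(ss_e / (ss_e + ss_err), abs=1e-9)

    def test_degrees_of_freedom_match_design(self, rng):
        n = 11
        res = rm_anova_3x3(long_from_cube(rng.normal(size=(n, 3, 3))), compute_eta_ci=False)
        assert (res.effects["stim"].df_num, res.effects["stim"].df_den) == (2, 2 * (n - 1))
        assert (res.effects["interaction"].df_num, res.effects["interaction"].df_den) == (
            4,
            4 * (n - 1),
        )

    def test_no_condition_variance_gives_zero_F(self, rng):
        # per-subject stimulus profiles c_s * q_i with sum(c) = 0: the
        # stimulus marginal means are flat, so SS_stim = 0 exactly while
        # the subject-by-stimulus error term is positive
        n = 8
        c = rng.normal(size=n)
        c -= c.mean()
        q = np.array([1.0, -0.5, 2.0])
        offsets = rng.normal(size=n)
        values = offsets[:, None, None] + (c[:, None] * q[None, :])[:, :, None] * np.ones(
            (1, 1, 3)
        )
        values = values + rng.normal(0, 1e-9, values.shape)  # break exact B degeneracy
        res = rm_anova_3x3(long_from_cube(values), compute_eta_ci=False)
        assert res.effects["stim"].F < 1e-6

    def test_eta_ci_brackets_point_estimate(self, rng):
        values = rng.normal(size=(12, 3, 3)) + rng.normal(size=(1, 3, 1))
        res = rm_anova_3x3(long_from_cube(values))
        for eff in res.effects.values():
            lo, hi = eff.eta_ci90
            assert 0.0 <= lo <= hi <= 1.0
            assert lo <= eff.eta_p2 + 1e-9

    def test_interaction_type_one_error_calibrated(self, rng):
        """Additive generators (no true interaction) must reject at ~alpha."""
        n_rep, n_subj, hits = 400, 10, 0
        for _ in range(n_rep):
            base = (
                rng.normal(size=(n_subj, 1, 1))
                + rng.normal(size=(1, 3, 1))
                + rng.normal(size=(1, 1, 3))
                + rng.normal(size=(n_subj, 3, 3))
            )
            res = rm_anova_3x3(long_from_cube(base), compute_eta_ci=False)
            hits += res.effects["interaction"].p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) < 3 * se + 1e-9

    def test_incomplete_subject_dropped_with_warning(self, rng):
        df = long_from_cube(rng.normal(size=(5, 3, 3)))
        df = df[~((df["subject_id"] == 5) & (df["attn"] == "fear"))]
        with pytest.warns(UserWarning, match="incomplete"):
            res = rm_anova_3x3(df, compute_eta_ci=False)
        assert res.n_subjects == 4 and res.dropped_subjects == [5]

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            rm_anova_3x3(long_from_cube(rng.normal(size=(2, 3, 3))))


class TestPosthoc:
    def test_identical_conditions_null_contrast(self, rng):
        values = np.repeat(rng.normal(size=(9, 1, 3)), 3, axis=1)
        out = pairwise_posthoc(long_from_cube(values), "stim")
        for c in out:
            assert c.t == 0.0 and c.cohens_d == 0.0 and not c.capped

    def test_hand_computed_contrast(self):
        # subjects' stim marginal means differ by exactly [1, 2, 3, 4]
        rows = []
        diffs = [1.0, 2.0, 3.0, 4.0]
        for s, d in enumerate(diffs, start=1):
            for j, attn in enumerate(("general", "fear", "happy")):
                rows.append((s, "neutral", attn, 10.0 + d))
                rows.append((s, "fearful", attn, 10.0))
                rows.append((s, "happy", attn, 10.0))
        df = pd.DataFrame(rows, columns=["subject_id", "stim", "attn", "value"])
        out = {c.pair: c for c in pairwise_posthoc(df, "stim")}
        c = out[("fearful", "neutral")]
        mean_d, sd_d = -np.mean(diffs), np.std(diffs, ddof=1)
        assert c.t == pytest.approx(mean_d / (sd_d / 2))  # n = 4
        assert c.cohens_d == pytest.approx(mean_d / sd_d)
        assert c.df == 3

    def test_tukey_adjustment_not_anticonservative(self, rng):
        values = rng.normal(size=(10, 3, 3))
        for c in pairwise_posthoc(long_from_cube(values), "attn"):
            assert c.p_tukey >= c.p_raw - 1e-12

    def test_zero_variance_difference_capped(self):
        values = np.zeros((5, 3, 3))
        values[:, 1, :] = 1.0  # constant offset, zero difference variance
        out = {c.pair: c for c in pairwise_posthoc(long_from_cube(values), "stim")}
        c = out[("fearful", "neutral")]
        assert c.capped and abs(c.t) >= 1e6
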