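"""Posterior predictive checks and parameter recovery."""

import numpy as np
import pytest

from ensemble_ddm.ddm import DDMParams, choice_prob_upper
from ensemble_ddm.models import build_model, model_spec
from ensemble_ddm.ppc import posterior_predict, ppc_report, recover
from ensemble_ddm.sampler import HierarchicalPosterior, fit
from ensemble_ddm.simulate import CohortTruth, generate_cohort


@pytest.fixture(scope="module")
def fitted_small():
    rng = np.random.default_rng(77)
    df, _ = generate_cohort(4, 40, rng, attn_conditions=("general",), dt=1e-3)
    df = df[df["rt_s"] <= 4.0].reset_index(drop=True)
    model = build_model(model_spec(1), df)
    post = fit(model, iterations=600, burn_in=300, thin=2, seed=17)
    return model, post


def collapsed_posterior(model, values: dict) -> HierarchicalPosterior:
    """A posterior whose every draw equals the given subject values."""
    n_stored, n_chains = 50, 2
    S = model.n_subjects
    subject_draws = {
        fam: np.broadcast_to(values[fam], (n_chains, n_stored, S)).copy()
        for fam in model.family_names()
    }
    group = {}
    for fam in model.family_names():
        group[f"mu_{fam}"] = np.full((n_chains, n_stored), float(np.mean(values[fam])))
        group[f"sigma_{fam}"] = np.full((n_chains, n_stored), 0.1)
    return HierarchicalPosterior(
        group_draws=group,
        subject_draws=subject_draws,
        deviance=np.zeros((n_chains, n_stored)),
        config={},
        family_transforms={f.name: f.transform for f in model.families},
        subject_ids=list(model.subject_ids),
    )


class TestPosteriorPredict:
    def test_replicate_count(self, fitted_small, rng):
        model, post = fitted_small
        reps = posterior_predict(post, model, n_rep=60, rng=rng)
        assert len(reps) == 60

    def test_small_rep_count_warns(self, fitted_small, rng):
        model, post = fitted_small
        with pytest.warns(UserWarning, match="coarse"):
            posterior_predict(post, model, n_rep=10, rng=rng)

    def test_collapsed_posterior_matches_closed_form(self, fitted_small, rng):
        """With the posterior collapsed onto known parameters the predictive
        choice proportion must equal the analytic absorption probability."""
        model, _ = fitted_small
        S = model.n_subjects
        values = {
            "v_neutral": np.full(S, 0.1),
            "v_fearful": np.full(S, 0.7),
            "v_happy": np.full(S, -0.5),
            "a": np.full(S, np.log(1.5)),
            "t_er": np.full(S, np.log(0.15)),
        }
        post = collapsed_posterior(model, values)
        reps = posterior_predict(post, model, n_rep=60, rng=rng)
        pooled = {}
        for stim, v in (("neutral", 0.1), ("fearful", 0.7), ("happy", -0.5)):
            ups = np.concatenate(
                [
                    (r[r["stim"].astype(str) == stim]["choice"] == "upper").to_numpy()
                    for r in reps
                ]
            )
            prob = choice_prob_upper(DDMParams(v=v, a=1.5, w=0.5, t_er=0.15))
            se = np.sqrt(prob * (1 - prob) / ups.size)
            assert abs(ups.mean() - prob) < 4 * se
            pooled[stim] = ups.mean()
        assert pooled["fearful"] > pooled["neutral"] > pooled["happy"]

    def test_rts_exceed_nondecision_time(self, fitted_small, rng):
        model, post = fitted_small
        reps = posterior_predict(post, model, n_rep=60, rng=rng)
        t_er = np.exp(post.pooled("mu_t_er").mean())
        assert all(r["rt_s"].median() >= t_er for r in reps)


class TestPPCReport:
    def test_self_consistency(self, fitted_small, rng):
        """Data simulated from the fitted model should sit inside its own
        predictive intervals for most cells."""
        model, post = fitted_small
        reps = posterior_predict(post, model, n_rep=120, rng=rng)
        report = ppc_report(model.df, reps)
        assert report.n_rep == 120
        assert report.coverage_rate >= 2 / 3

    def test_quantiles_monotone(self, fitted_small, rng):
        model, post = fitted_small
        report = ppc_report(model.df, posterior_predict(post, model, n_rep=60, rng=rng))
        for cell in report.cells:
            for b in ("upper", "lower"):
                q = [x for x in cell.predicted_rt_quantiles[b] if np.isfinite(x)]
                assert q == sorted(q)

    def test_json_round_trip(self, fitted_small, rng):
        import json

        model, post = fitted_small
        report = ppc_report(model.df, posterior_predict(post, model, n_rep=60, rng=rng))
        parsed = json.loads(report.to_json())
        assert parsed["n_rep"] == 60
        assert len(parsed["cells"]) == 3  # one per stimulus condition


class TestRecovery:
    def test_report_structure_and_determinism(self):
        truth = CohortTruth()
        kw = dict(n_subjects=5, trials_per_cell=30, seed=9,
                  iterations=400, burn_in=200, thin=2)
        rep1 = recover(model_spec(1), truth, **kw)
        rep2 = recover(model_spec(1), truth, **kw)
        assert {r.family for r in rep1.rows} == {
            "v_neutral", "v_fearful", "v_happy", "a", "t_er",
        }
        assert 0.0 <= rep1.coverage_rate <= 1.0
        for a, b in zip(rep1.rows, rep2.rows):
            assert a.posterior_mean == b.posterior_mean

    def test_zero_drift_truth_recovers_symmetric_signs(self):
        """With zero generating drifts the recovered condition drifts must
        not share a systematic sign."""
        truth = CohortTruth(v_by_stim={"fearful": 0.0, "neutral": 0.0, "happy": 0.0})
        signs = []
        for seed in (1, 2, 3):
            rep = recover(model_spec(1), truth, n_subjects=5, trials_per_cell=30,
                          seed=seed, iterations=400, burn_in=200, thin=2)
            signs += [np.sign(r.posterior_mean) for r in rep.rows if r.family.startswith("v_")]
        assert len(set(signs)) > 1

    def test_generating_values_attached(self):
        truth = CohortTruth()
        rep = recover(model_spec(4, "general_plus_fear"), truth,
                      n_subjects=4, trials_per_cell=25, seed=3,
                      iterations=300, burn_in=150, thin=2)
        gen = {r.family: r.generating_value for r in rep.rows}
        assert gen["a_general"] == pytest.approx(1.46)
        assert gen["a_fear"] == pytest.approx(1.55)
        assert gen["v_fearful"] == pytest.approx(0.55)

    def test_happy_arm_flips_drift_signs(self):
        """In the happy-coded analysis the fearful-stimulus drift points to
        the lower (fearful) boundary, so its generating value is negative."""
        truth = CohortTruth().with_boundaries({"general": 1.48, "happy": 1.40})
        rep = recover(model_spec(4, "general_plus_happy"), truth,
                      n_subjects=4, trials_per_cell=25, seed=3,
                      iterations=300, burn_in=150, thin=2)
        gen = {r.family: r.generating_value for r in rep.rows}
        assert gen["v_fearful"] == pytest.approx(-0.55)
        assert gen["v_happy"] == pytest.approx(0.40)
        assert gen["a_happy"] == pytest.approx(1.40)
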