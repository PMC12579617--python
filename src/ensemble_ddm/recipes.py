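"""Standard recovery experiments for the emotion-ensemble task.

These wire together the cohort generator, the model specifications and the
sampler into the two canonical validation studies for this task family:

* Model 1 recovery — general-attention data generated with the
  stimulus-dependent group drifts as ground truth; checks that the
  posterior group drift means land on the generating values.
* Model 4 recovery and selection — general plus one specific-attention
  condition generated with attention-dependent boundary separations;
  checks that DIC prefers the boundary model over the drift and
  starting-point alternatives and that both boundary values are recovered.

The default generating values are the group-level estimates typical of
this task (see :class:`ensemble_ddm.simulate.CohortTruth`); the reduced
MCMC protocol (2 chains x 2,000 iterations, burn-in 1,000, thin 2) keeps a
run at desk scale while storing the same 500 draws per chain as the full
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compare import ComparisonReport, compare_models
from .models import build_model, model_spec, select_dataset
from .ppc import RecoveryReport, recover
from .sampler import fit
from .simulate import CohortTruth, generate_cohort

#: Boundary-separation ground truths per analysis arm, as estimated for
#: this task: caution rises under fear-attention and falls under
#: happy-attention relative to the general-attention baseline of the same
#: analysis.
FEAR_ARM_BOUNDARIES = {"general": 1.46, "fear": 1.55}
HAPPY_ARM_BOUNDARIES = {"general": 1.48, "happy": 1.40}

DESK_MCMC = dict(iterations=2000, burn_in=1000, thin=2, n_chains=2)


def model1_recovery(
    seed: int,
    n_subjects: int = 20,
    trials_per_cell: int = 100,
    truth: CohortTruth | None = None,
    **mcmc,
) -> RecoveryReport:
    """Recover the stimulus-dependent group drifts with Model 1.

    Simulates ``n_subjects`` subjects x ``trials_per_cell`` general-task
    trials per stimulus condition and fits Model 1 at the desk-scale MCMC
    protocol (override via keyword arguments).
    """
    truth = truth or CohortTruth()
    cfg = {**DESK_MCMC, **mcmc}
    return recover(
        model_spec(1),
        truth,
        n_subjects=n_subjects,
        trials_per_cell=trials_per_cell,
        seed=seed,
        **cfg,
    )


def model4_recovery(
    seed: int,
    dataset: str = "general_plus_fear",
    n_subjects: int = 20,
    trials_per_cell: int = 100,
    truth: CohortTruth | None = None,
    **mcmc,
) -> RecoveryReport:
    """Recover the attention-dependent boundary separations with Model 4."""
    if truth is None:
        arm = FEAR_ARM_BOUNDARIES if dataset == "general_plus_fear" else HAPPY_ARM_BOUNDARIES
        truth = CohortTruth().with_boundaries(arm)
    cfg = {**DESK_MCMC, **mcmc}
    return recover(
        model_spec(4, dataset),
        truth,
        n_subjects=n_subjects,
        trials_per_cell=trials_per_cell,
        seed=seed,
        **cfg,
    )


@dataclass
class SelectionReplicate:
    report: ComparisonReport
    winner: str
    boundary_estimates: dict[str, float] = field(default_factory=dict)


def model_selection_experiment(
    seed: int,
    dataset: str = "general_plus_fear",
    n_subjects: int = 20,
    trials_per_cell: int = 100,
    truth: CohortTruth | None = None,
    **mcmc,
) -> SelectionReplicate:
    """One replicate of the Model 2-4 comparison on data generated under
    the boundary-separation mechanism."""
    if truth is None:
        arm = FEAR_ARM_BOUNDARIES if dataset == "general_plus_fear" else HAPPY_ARM_BOUNDARIES
        truth = CohortTruth().with_boundaries(arm)
    cfg = {**DESK_MCMC, **mcmc}
    ss = np.random.SeedSequence(seed)
    gen_ss, *fit_ss = ss.spawn(4)
    rng = np.random.default_rng(gen_ss)
    specs = {f"model{m}": model_spec(m, dataset) for m in (2, 3, 4)}
    df, _ = generate_cohort(
        n_subjects,
        trials_per_cell,
        rng,
        truth=truth,
        attn_conditions=specs["model4"].attn_conditions,
        dt=1e-3,
    )
    df = df[df["rt_s"] <= 4.0].reset_index(drop=True)
    fits = {}
    for (name, spec), fseed in zip(specs.items(), fit_ss):
        model = build_model(spec, df)
        fits[name] = (fit(model, seed=fseed, **cfg), model)
    report = compare_models(fits)
    post4 = fits["model4"][0]
    estimates = {
        fam: post4.group_estimate(fam)
        for fam in post4.subject_draws
        if fam.startswith("a_")
    }
    return SelectionReplicate(report, report.winner, estimates)
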