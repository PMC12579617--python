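"""Synthetic trial-level behaviour for the emotion-ensemble task.

Choices and reaction times are generated from a drift-diffusion process
whose parameters follow the structure selected by the winning models of
this task family: the drift rate depends on the stimulus-emotion condition
(bottom-up evidence) and the boundary separation on the attention condition
(top-down caution), with an unbiased starting point.

All generated data use a single canonical boundary coding, "fear side up":
the upper boundary is the fear-consistent decision in every attention
condition ("Fearful" under general and fear-attention instructions,
"Not Happy" under happy-attention).  The mapping from boundaries to
response labels is carried in a sidecar dictionary so that analyses that
prefer the happy decision on the upper boundary can recode without
hand-flipping drift signs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .ddm import DEFAULT_DT, simulate_trials
from .stimuli import ATTN_CONDITIONS, STIM_CONDITIONS, AttnCondition

#: Response label attached to each boundary per attention condition under
#: the canonical fear-side-up coding.
CANONICAL_LABELS: dict[str, dict[str, str]] = {
    "general": {"upper": "Fearful", "lower": "Happy"},
    "fear": {"upper": "Fearful", "lower": "Not Fearful"},
    "happy": {"upper": "Not Happy", "lower": "Happy"},
}

TRIAL_COLUMNS = ["subject_id", "attn", "stim", "choice", "rt_s"]


@dataclass(frozen=True)
class CohortTruth:
    """Group-level generating parameters and between-subject spreads.

    Group locations are on the natural scale (drifts in fear-side-up
    coding); between-subject standard deviations apply on the scales the
    hierarchical model uses (identity for v, log for a and t_er, logit
    for w).  Defaults are the group-level estimates typical of this task:
    strong fear-ward drift with extreme fearful evidence, near-zero drift
    for neutral ensembles, happy-ward drift with extreme happy evidence;
    raised caution under fear-attention and lowered caution under
    happy-attention.  The non-decision time is set so that closed-form mean
    decision times plus t_er land on the sub-700-ms reaction times this
    task produces.
    """

    v_by_stim: Mapping[str, float] = field(
        default_factory=lambda: {"fearful": 0.55, "neutral": 0.02, "happy": -0.40}
    )
    a_by_attn: Mapping[str, float] = field(
        default_factory=lambda: {"general": 1.46, "fear": 1.55, "happy": 1.40}
    )
    t_er: float = 0.13
    w_by_attn: Mapping[str, float] = field(
        default_factory=lambda: {a: 0.5 for a in ATTN_CONDITIONS}
    )
    sd_v: float = 0.3
    sd_log_a: float = 0.15
    sd_log_t: float = 0.05
    sd_logit_w: float = 0.0

    def with_boundaries(self, a_by_attn: Mapping[str, float]) -> "CohortTruth":
        return replace(self, a_by_attn=dict(a_by_attn))


@dataclass
class SubjectParams:
    v_by_stim: dict[str, float]
    a_by_attn: dict[str, float]
    t_er: float
    w_by_attn: dict[str, float]


def draw_subject_params(
    truth: CohortTruth,
    n_subjects: int,
    rng: np.random.Generator,
    center: bool = True,
) -> list[SubjectParams]:
    """Draw per-subject parameters around the group truth.

    With ``center=True`` (default) the sampled between-subject deviations
    are re-centred to mean zero on each transformed scale, so the realised
    cohort average equals the generating group value exactly.  This removes
    cohort-level sampling noise from recovery studies, whose estimand is
    the group location itself; set it to False to emulate a fresh draw from
    the population.
    """

    def deviations(sd: float) -> np.ndarray:
        d = rng.normal(0.0, sd, size=n_subjects) if sd > 0 else np.zeros(n_subjects)
        if center and sd > 0:
            d -= d.mean()
        return d

    dev_v = {s: deviations(truth.sd_v) for s in truth.v_by_stim}
    dev_a = {a: deviations(truth.sd_log_a) for a in truth.a_by_attn}
    dev_t = deviations(truth.sd_log_t)
    dev_w = {a: deviations(truth.sd_logit_w) for a in truth.w_by_attn}

    def logit(p: float) -> float:
        return float(np.log(p / (1.0 - p)))

    out = []
    for i in range(n_subjects):
        out.append(
            SubjectParams(
                v_by_stim={s: truth.v_by_stim[s] + dev_v[s][i] for s in truth.v_by_stim},
                a_by_attn={
                    a: float(np.exp(np.log(truth.a_by_attn[a]) + dev_a[a][i]))
                    for a in truth.a_by_attn
                },
                t_er=float(np.exp(np.log(truth.t_er) + dev_t[i])),
                w_by_attn={
                    a: float(1.0 / (1.0 + np.exp(-(logit(truth.w_by_attn[a]) + dev_w[a][i]))))
                    for a in truth.w_by_attn
                },
            )
        )
    return out


def generate_cohort(
    n_subjects: int,
    trials_per_cell: int,
    rng: np.random.Generator,
    truth: CohortTruth | None = None,
    attn_conditions: Sequence[AttnCondition] = ATTN_CONDITIONS,
    center: bool = True,
    dt: float = DEFAULT_DT,
) -> tuple[pd.DataFrame, list[SubjectParams]]:
    """Simulate a cohort of subjects on the ensemble task.

    Produces ``trials_per_cell`` trials for every (attention, stimulus)
    cell listed, per subject.  Returns the trial table (canonical
    fear-side-up choice coding) and the realised subject parameters.
    """
    truth = truth or CohortTruth()
    missing = [a for a in attn_conditions if a not in truth.a_by_attn]
    if missing:
        raise ValueError(f"no generating boundary separation for attention {missing}")
    subjects = draw_subject_params(truth, n_subjects, rng, center=center)

    rows_subj, rows_attn, rows_stim = [], [], []
    v_arr, a_arr, w_arr, t_arr = [], [], [], []
    for sid, sp in enumerate(subjects, start=1):
        for attn in attn_conditions:
            for stim in STIM_CONDITIONS:
                rows_subj.extend([sid] * trials_per_cell)
                rows_attn.extend([attn] * trials_per_cell)
                rows_stim.extend([stim] * trials_per_cell)
                v_arr.extend([sp.v_by_stim[stim]] * trials_per_cell)
                a_arr.extend([sp.a_by_attn[attn]] * trials_per_cell)
                w_arr.extend([sp.w_by_attn[attn]] * trials_per_cell)
                t_arr.extend([sp.t_er] * trials_per_cell)

    rt, upper, _ = simulate_trials(
        np.array(v_arr), np.array(a_arr), np.array(w_arr), np.array(t_arr), rng, dt=dt
    )
    df = pd.DataFrame(
        {
            "subject_id": np.array(rows_subj),
            "attn": pd.Categorical(rows_attn, categories=list(ATTN_CONDITIONS)),
            "stim": pd.Categorical(rows_stim, categories=list(STIM_CONDITIONS)),
            "choice": np.where(upper, "upper", "lower"),
            "rt_s": rt,
        }
    )
    return df, subjects


def write_trials_csv(df: pd.DataFrame, fh: IO[str], sidecar: IO[str] | None = None) -> None:
    """Write the trial table; the sidecar records the boundary-label mapping."""
    df.to_csv(fh, index=False, columns=TRIAL_COLUMNS)
    if sidecar is not None:
        json.dump({"boundary_labels": CANONICAL_LABELS, "coding": "fear_upper"}, sidecar, indent=2)


def read_trials_csv(fh: IO[str] | str) -> pd.DataFrame:
    df = pd.read_csv(fh)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    return df
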