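"""Emotion-ensemble stimulus structure and pseudorandomised sessions.

A trial presents eight face morphs arranged on an annulus, each indexed by
an integer emotion value (EV) from 0 (anchoring fearful) to 100 (anchoring
happy).  Neutral ensembles draw eight distinct EVs from a truncated
Gaussian (mean 50, SD 10, bounds 30-70); the fearful and happy conditions
replace two randomly chosen faces with the extreme pairs {0, 10} and
{90, 100} respectively.

A session consists of a general-attention phase (trials_per_condition
trials for each of the three stimulus conditions, 300 by default) followed
by a specific-attention phase of twice as many trials split between
alternating fear- and happy-attention blocks.  Within each phase the trial
order is pseudorandomised so that no (actor, stimulus-condition) pair
repeats on more than three consecutive trials.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal, Sequence

import numpy as np

StimCondition = Literal["neutral", "fearful", "happy"]
AttnCondition = Literal["general", "fear", "happy"]

STIM_CONDITIONS: tuple[StimCondition, ...] = ("neutral", "fearful", "happy")
ATTN_CONDITIONS: tuple[AttnCondition, ...] = ("general", "fear", "happy")

EV_MEAN = 50.0
EV_SD = 10.0
EV_BOUNDS = (30, 70)
FEARFUL_EXTREMES = (0, 10)
HAPPY_EXTREMES = (90, 100)
N_FACES = 8
N_ACTORS = 5
MAX_RUN_LENGTH = 3


class RunLengthInfeasibleError(RuntimeError):
    """Raised when no ordering can satisfy the run-length constraint."""


@dataclass(frozen=True)
class EnsembleTrial:
    """One ensemble presentation."""

    actor_id: int
    stim_condition: StimCondition
    evs: tuple[int, ...]
    replaced_positions: frozenset[int] = frozenset()
    annulus_order: tuple[int, ...] = tuple(range(N_FACES))

    def __post_init__(self) -> None:
        if not 1 <= self.actor_id <= N_ACTORS:
            raise ValueError(f"actor_id must be in 1..{N_ACTORS}, got {self.actor_id}")
        if len(self.evs) != N_FACES:
            raise ValueError(f"a trial carries exactly {N_FACES} EVs")


@dataclass(frozen=True)
class SessionTrial:
    task_phase: Literal["general", "specific"]
    attn_condition: AttnCondition
    block: int
    ensemble: EnsembleTrial


@dataclass
class SessionDesign:
    trials: list[SessionTrial]
    block_order: list[AttnCondition] = field(default_factory=list)

    @property
    def general_trials(self) -> list[SessionTrial]:
        return [t for t in self.trials if t.task_phase == "general"]

    @property
    def specific_trials(self) -> list[SessionTrial]:
        return [t for t in self.trials if t.task_phase == "specific"]


def sample_neutral_evs(rng: np.random.Generator) -> list[int]:
    """Eight distinct integer EVs from Normal(50, 10) truncated to [30, 70].

    Each EV is an independent continuous draw, rejected outside the bounds,
    then rounded to the nearest integer; collisions with already-sampled
    values are redrawn (41 integers are available, so the loop terminates).
    """
    chosen: list[int] = []
    seen: set[int] = set()
    lo, hi = EV_BOUNDS
    while len(chosen) < N_FACES:
        x = rng.normal(EV_MEAN, EV_SD)
        if x < lo or x > hi:
            continue
        ev = int(round(x))
        if ev in seen:
            continue
        seen.add(ev)
        chosen.append(ev)
    return chosen


def make_trial(
    stim_condition: StimCondition, actor_id: int, rng: np.random.Generator
) -> EnsembleTrial:
    """Build one ensemble trial for the given stimulus condition and actor."""
    if stim_condition not in STIM_CONDITIONS:
        raise ValueError(f"unknown stimulus condition {stim_condition!r}")
    evs = sample_neutral_evs(rng)
    annulus = tuple(int(i) for i in rng.permutation(N_FACES))
    if stim_condition == "neutral":
        return EnsembleTrial(actor_id, stim_condition, tuple(evs), frozenset(), annulus)
    extremes = FEARFUL_EXTREMES if stim_condition == "fearful" else HAPPY_EXTREMES
    positions = rng.choice(N_FACES, size=2, replace=False)
    values = list(extremes)
    rng.shuffle(values)
    for pos, val in zip(positions, values):
        evs[pos] = val
    return EnsembleTrial(
        actor_id, stim_condition, tuple(evs), frozenset(int(p) for p in positions), annulus
    )


def ensemble_mean_ev(trial: EnsembleTrial) -> float:
    """Arithmetic mean EV over the eight faces."""
    return float(np.mean(trial.evs))


def _max_run(keys: Sequence[tuple]) -> int:
    best = run = 1
    for prev, cur in zip(keys, keys[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if keys else 0


def _pseudorandom_order(
    labels: list, rng: np.random.Generator, max_retries: int
) -> list:
    """Uniform shuffle conditioned on run lengths <= MAX_RUN_LENGTH.

    Resamples the permutation until the constraint holds; with five actors
    and three conditions violations are rare, so plain rejection is both
    exactly uniform on the constrained set and fast.
    """
    order = list(labels)
    for _ in range(max_retries):
        rng.shuffle(order)
        if _max_run([(a, s) for a, s in order]) <= MAX_RUN_LENGTH:
            return order
    raise RunLengthInfeasibleError(
        f"no ordering with runs <= {MAX_RUN_LENGTH} found in {max_retries} attempts"
    )


def build_session(
    rng: np.random.Generator,
    trials_per_condition: int = 100,
    max_retries: int = 10_000,
) -> SessionDesign:
    """Generate a full two-phase session for one subject.

    The general phase carries ``trials_per_condition`` trials per stimulus
    condition under general attention; the specific phase doubles the trial
    count, split between alternating fear- and happy-attention blocks (two
    blocks per attention condition when the counts divide evenly, one
    otherwise).  The first specific-phase attention condition is randomised,
    standing in for the counterbalancing across subjects.
    """
    if trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")

    def phase_labels() -> list[tuple[int, StimCondition]]:
        labels = [
            (int(rng.integers(1, N_ACTORS + 1)), stim)
            for stim in STIM_CONDITIONS
            for _ in range(trials_per_condition)
        ]
        return _pseudorandom_order(labels, rng, max_retries)

    trials: list[SessionTrial] = []
    for actor, stim in phase_labels():
        trials.append(SessionTrial("general", "general", 0, make_trial(stim, actor, rng)))

    first: list[AttnCondition] = ["fear", "happy"]
    rng.shuffle(first)
    n_attn = 3 * trials_per_condition  # trials per attention condition
    blocks_per_attn = 2 if n_attn % 2 == 0 else 1
    block_len = n_attn // blocks_per_attn
    block_order: list[AttnCondition] = []
    for b in range(blocks_per_attn):
        for attn in first:
            block_order.append(attn)

    for _ in range(max_retries):
        per_attn = {attn: phase_labels() for attn in ("fear", "happy")}
        specific: list[SessionTrial] = []
        cursor = {"fear": 0, "happy": 0}
        for block_idx, attn in enumerate(block_order, start=1):
            start = cursor[attn]
            for actor, stim in per_attn[attn][start : start + block_len]:
                specific.append(
                    SessionTrial("specific", attn, block_idx, make_trial(stim, actor, rng))
                )
            cursor[attn] = start + block_len
        keys = [(t.ensemble.actor_id, t.ensemble.stim_condition) for t in specific]
        if _max_run(keys) <= MAX_RUN_LENGTH:
            return SessionDesign(trials + specific, block_order)
    raise RunLengthInfeasibleError(
        f"specific phase: no block assembly with runs <= {MAX_RUN_LENGTH} "
        f"found in {max_retries} attempts"
    )


def session_trial_counts(trials_per_condition: int = 100) -> dict[str, int]:
    """Trial bookkeeping for one subject's session under the stated design."""
    general = 3 * trials_per_condition
    specific = 2 * general
    return {"general": general, "specific": specific, "total": general + specific}


def write_sessions_csv(
    sessions: Iterable[tuple[int, SessionDesign]], fh: IO[str]
) -> None:
    """Write sessions as CSV, one row per trial.

    Columns: subject_id, phase, block, trial_index, attn, stim, actor,
    ev_1..ev_8 (UTF-8, header row, '.' decimal separator).
    """
    writer = csv.writer(fh)
    writer.writerow(
        ["subject_id", "phase", "block", "trial_index", "attn", "stim", "actor"]
        + [f"ev_{i}" for i in range(1, N_FACES + 1)]
    )
    for subject_id, design in sessions:
        for idx, t in enumerate(design.trials):
            writer.writerow(
                [
                    subject_id,
                    t.task_phase,
                    t.block,
                    idx,
                    t.attn_condition,
                    t.ensemble.stim_condition,
                    t.ensemble.actor_id,
                ]
                + list(t.ensemble.evs)
            )
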