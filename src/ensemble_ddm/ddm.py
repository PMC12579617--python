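"""Diffusion-process kernel: first-passage density, trial simulation, and
closed-form oracles for choice probability and mean decision time.

The model is the plain four-parameter drift-diffusion model: evidence X(t)
starts at z = w*a, drifts at rate v with unit diffusion coefficient, and the
decision is made when X first hits 0 (lower boundary) or a (upper boundary).
Observed response time adds a non-decision component t_er.  No across-trial
parameter variability is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from ._wfpt import simulate_paths, wfpt_logpdf_arr

Boundary = Literal["upper", "lower"]

#: Default absolute truncation error of the density series.
DEFAULT_EPS = 1e-10

#: Default Euler step (seconds) for path simulation.
DEFAULT_DT = 1e-4

#: Default wall-clock cap (seconds of decision time) for a simulated path.
DEFAULT_MAX_TIME = 30.0


@dataclass(frozen=True)
class DDMParams:
    """One diffusion parameterisation.

    Parameters
    ----------
    v:
        Drift rate (evidence units per second).  Positive values drive the
        process toward the upper boundary.
    a:
        Boundary separation (> 0).
    w:
        Relative starting point in (0, 1); the absolute start is z = w * a
        and w = 0.5 is the unbiased midpoint.
    t_er:
        Non-decision time in seconds (>= 0), added to every first-passage
        time.

    The diffusion coefficient is fixed at 1, which sets the scale of v and a.
    """

    v: float
    a: float
    w: float = 0.5
    t_er: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not (0.0 < self.w < 1.0):
            raise ValueError(f"relative start point must lie in (0,1), got w={self.w}")
        if self.t_er < 0:
            raise ValueError(f"non-decision time must be >= 0, got t_er={self.t_er}")

    @property
    def z(self) -> float:
        """Absolute starting point."""
        return self.w * self.a


class SimulatedTrial(NamedTuple):
    boundary: Boundary
    rt: float
    capped: bool


def wfpt_logpdf(t, boundary: Boundary, params: DDMParams, eps: float = DEFAULT_EPS):
    """Log of the defective first-passage density at observed time ``t``.

    ``t`` may be a scalar or array; values at or below ``t_er`` give -inf.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    n = tt.size
    up = np.full(n, boundary == "upper")
    out = wfpt_logpdf_arr(
        tt.ravel(),
        up,
        np.full(n, params.v),
        np.full(n, params.a),
        np.full(n, params.w),
        np.full(n, params.t_er),
        eps,
    )
    out = out.reshape(tt.shape)
    return out if np.ndim(t) else float(out[0])


def wfpt_pdf(t, boundary: Boundary, params: DDMParams, eps: float = DEFAULT_EPS):
    """Defective first-passage density (per second) at observed time ``t``.

    The density is defective: integrating over t in (t_er, inf) gives the
    probability of absorption at ``boundary``, not 1.
    """
    return np.exp(wfpt_logpdf(t, boundary, params, eps=eps))


def choice_prob_upper(params: DDMParams) -> float:
    """Closed-form probability of absorption at the upper boundary.

    (1 - exp(-2 v a w)) / (1 - exp(-2 v a)) for v != 0, continuous limit w
    at v = 0.  Evaluated piecewise so large |v a| does not overflow.
    """
    v, a, w = params.v, params.a, params.w
    if abs(v) * a < 1e-9:
        return w
    if v > 0:
        # exponents are negative: direct form is stable
        return math.expm1(-2.0 * v * a * w) / math.expm1(-2.0 * v * a)
    # v < 0: use the complement of the reflected process
    return 1.0 - math.expm1(2.0 * v * a * (1.0 - w)) / math.expm1(2.0 * v * a)


def mean_decision_time(params: DDMParams) -> float:
    """Closed-form unconditional mean first-passage (decision) time.

    Derived from the optional-stopping identity E[X_T] = z + v E[T]:
    E[T] = (a * P(upper) - z) / v for v != 0, and z (a - z) for v = 0.
    Excludes the non-decision time.
    """
    v, a, z = params.v, params.a, params.z
    if abs(v) < 1e-9:
        return z * (a - z)
    return (a * choice_prob_upper(params) - z) / v


def simulate_trial(
    params: DDMParams,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    max_time: float = DEFAULT_MAX_TIME,
) -> SimulatedTrial:
    """Simulate a single trial; see :func:`simulate_trials` for the batch form."""
    rt, up, capped = _simulate_arrays(
        np.array([params.v]),
        np.array([params.a]),
        np.array([params.w]),
        np.array([params.t_er]),
        rng,
        dt,
        max_time,
    )
    return SimulatedTrial("upper" if up[0] else "lower", float(rt[0]), bool(capped[0]))


def simulate_trials(
    v,
    a,
    w,
    t_er,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    max_time: float = DEFAULT_MAX_TIME,
    on_cap: Literal["resample", "keep"] = "resample",
    max_resample_rounds: int = 20,
):
    """Simulate one trial per element of the (broadcast) parameter arrays.

    Returns ``(rt, upper, capped)``.  With ``on_cap='resample'`` (default),
    paths that hit the time cap are re-simulated with fresh noise; with
    ``'keep'`` they are returned flagged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v, a, w, t_er = np.broadcast_arrays(
        np.asarray(v, float), np.asarray(a, float), np.asarray(w, float), np.asarray(t_er, float)
    )
    rt, up, capped = _simulate_arrays(
        v.ravel().copy(), a.ravel().copy(), w.ravel().copy(), t_er.ravel().copy(), rng, dt, max_time
    )
    if on_cap == "resample":
        rounds = 0
        while capped.any():
            rounds += 1
            if rounds > max_resample_rounds:
                raise RuntimeError(
                    f"{int(capped.sum())} paths still capped after "
                    f"{max_resample_rounds} resampling rounds (max_time={max_time}s)"
                )
            idx = np.flatnonzero(capped)
            r2, u2, c2 = _simulate_arrays(
                v.ravel()[idx], a.ravel()[idx], w.ravel()[idx], t_er.ravel()[idx], rng, dt, max_time
            )
            rt[idx], up[idx], capped[idx] = r2, u2, c2
    shape = v.shape
    return rt.reshape(shape), up.reshape(shape), capped.reshape(shape)


def _simulate_arrays(v, a, w, t_er, rng, dt, max_time):
    seed = int(rng.integers(0, 2**31 - 1))
    return simulate_paths(v, a, w, t_er, dt, max_time, seed)
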