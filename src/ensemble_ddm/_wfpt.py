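"""Numba kernels for the Wiener first-passage-time density and path simulation.

Everything here works on flat float64 arrays so the hierarchical sampler can
evaluate thousands of trial likelihoods per call.  The density uses the
standard dual series expansions of the first-passage density of a drifting
Brownian motion between two absorbing boundaries (diffusion coefficient
fixed at 1): a small-time expansion in images of the start point and a
large-time eigenfunction expansion, with the branch and term count chosen
per evaluation so the truncation error of the normalised density is below
``eps``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Floor applied to the dimensionless density before taking the log;
# corresponds to log-densities around -667, far below anything a sane
# parameter proposal produces, but keeps the sampler's arithmetic finite.
_DENSITY_FLOOR = 1e-290


@njit(cache=True)
def f0_lower(u, w, eps):
    """Density of first passage at the LOWER boundary for v=0, a=1, start w,
    evaluated at normalised time u = t / a**2.  Truncation error <= eps."""
    if u <= 0.0:
        return 0.0
    # required number of terms for the small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * u)))
        lo = math.sqrt(u) + 1.0
        if ks < lo:
            ks = lo
    else:
        ks = 2.0
    # required number of terms for the large-time expansion
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (math.pi * math.pi * u))
        lo = 1.0 / (math.pi * math.sqrt(u))
        if kl < lo:
            kl = lo
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    if ks < kl:
        kk = int(math.ceil(ks))
        half = (kk - 1) // 2
        s = 0.0
        for k in range(-half, kk - half):
            x = w + 2.0 * k
            s += x * math.exp(-x * x / (2.0 * u))
        return s / math.sqrt(2.0 * math.pi * u * u * u)
    else:
        kk = int(math.ceil(kl))
        s = 0.0
        for k in range(1, kk + 1):
            s += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
        return math.pi * s


@njit(cache=True)
def wfpt_logpdf_arr(rt, upper, v, a, w, ter, eps):
    """Trial-wise log first-passage density.

    ``upper`` selects the boundary per trial; the upper-boundary density is
    the lower-boundary density of the sign-flipped process (v -> -v,
    w -> 1 - w).  Returns -inf where rt <= ter.
    """
    n = rt.size
    out = np.empty(n)
    for i in range(n):
        t = rt[i] - ter[i]
        if t <= 0.0 or a[i] <= 0.0 or w[i] <= 0.0 or w[i] >= 1.0:
            out[i] = -np.inf
            continue
        vv = v[i]
        ww = w[i]
        if upper[i]:
            vv = -vv
            ww = 1.0 - ww
        u = t / (a[i] * a[i])
        f0 = f0_lower(u, ww, eps)
        if f0 < _DENSITY_FLOOR:
            f0 = _DENSITY_FLOOR
        out[i] = math.log(f0) - 2.0 * math.log(a[i]) - vv * a[i] * ww - vv * vv * t / 2.0
    return out


@njit(cache=True)
def simulate_paths(v, a, w, ter, dt, max_time, seed):
    """Euler-Maruyama diffusion paths with Brownian-bridge absorption.

    Each step proposes x' = x + v dt + sqrt(dt) N(0,1).  If the endpoint is
    inside the corridor, the path may still have crossed a boundary within
    the step; the bridge crossing probabilities exp(-2(a-x)(a-x')/dt) and
    exp(-2 x x'/dt) account for that, removing the O(sqrt(dt)) boundary
    overshoot bias of the naive scheme.  Observed crossings interpolate the
    crossing instant linearly; bridge crossings use the step midpoint.

    Returns (rt, upper, capped); capped paths carry rt = max_time + ter and
    an arbitrary boundary, and should be resampled or dropped by the caller.
    """
    np.random.seed(seed)
    n = v.size
    rt = np.empty(n)
    upper = np.empty(n, np.bool_)
    capped = np.zeros(n, np.bool_)
    sq = math.sqrt(dt)
    for i in range(n):
        ai = a[i]
        vi = v[i]
        x = w[i] * ai
        t = 0.0
        while True:
            xn = x + vi * dt + sq * np.random.standard_normal()
            t += dt
            if xn >= ai:
                frac = (ai - x) / (xn - x)
                rt[i] = t - dt + frac * dt + ter[i]
                upper[i] = True
                break
            if xn <= 0.0:
                frac = x / (x - xn)
                rt[i] = t - dt + frac * dt + ter[i]
                upper[i] = False
                break
            pu = math.exp(-2.0 * (ai - x) * (ai - xn) / dt)
            pl = math.exp(-2.0 * x * xn / dt)
            uu = np.random.random()
            if uu < pu:
                rt[i] = t - 0.5 * dt + ter[i]
                upper[i] = True
                break
            elif uu < pu + pl:
                rt[i] = t - 0.5 * dt + ter[i]
                upper[i] = False
                break
            if t >= max_time:
                rt[i] = max_time + ter[i]
                upper[i] = xn > 0.5 * ai
                capped[i] = True
                break
            x = xn
    return rt, upper, capped
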