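"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (plain
numpy/math, fixed large truncation orders, brute-force sums of squares) so
it shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def ref_f0_small(u: float, w: float, K: int = 60) -> float:
    """Small-time image expansion of the v=0, a=1 lower-boundary density."""
    s = sum((w + 2 * k) * math.exp(-((w + 2 * k) ** 2) / (2 * u)) for k in range(-K, K + 1))
    return s / math.sqrt(2 * math.pi * u**3)


def ref_f0_large(u: float, w: float, K: int = 200) -> float:
    """Large-time eigenfunction expansion of the same density."""
    s = sum(
        k * math.exp(-(k**2) * math.pi**2 * u / 2) * math.sin(k * math.pi * w)
        for k in range(1, K + 1)
    )
    return math.pi * s


def ref_wfpt_pdf(t, boundary, v, a, w, t_er=0.0):
    """First-passage density via both expansions at high truncation order.

    The two series are required to agree, which also guards the oracle
    itself against truncation mistakes.
    """
    tt = t - t_er
    if tt <= 0:
        return 0.0
    if boundary == "upper":
        v, w = -v, 1.0 - w
    u = tt / a**2
    small, large = ref_f0_small(u, w), ref_f0_large(u, w)
    if max(small, large) > 1e-12:
        assert abs(small - large) <= 1e-7 * max(1.0, max(small, large)), (small, large)
    f0 = 0.5 * (small + large)
    return f0 / a**2 * math.exp(-v * a * w - v**2 * tt / 2)


def ref_choice_prob_upper(v, a, w):
    if abs(v) < 1e-12:
        return w
    return (1 - math.exp(-2 * v * a * w)) / (1 - math.exp(-2 * v * a))


def ref_rm_anova(values: np.ndarray):
    """Brute-force sums-of-squares decomposition of a two-way fully
    within-subject design.

    ``values`` has shape (n_subjects, levels_a, levels_b), one observation
    per cell.  Each effect is tested against its own subject-by-effect
    interaction.  Returns {effect: (ss_effect, ss_error, F, df1, df2)}.
    """
    n, p, q = values.shape
    grand = values.mean()
    subj = values.mean(axis=(1, 2))
    am = values.mean(axis=(0, 2))
    bm = values.mean(axis=(0, 1))
    sa = values.mean(axis=2)  # subject x A
    sb = values.mean(axis=1)  # subject x B
    ab = values.mean(axis=0)  # A x B

    ss_a = n * q * np.sum((am - grand) ** 2)
    ss_b = n * p * np.sum((bm - grand) ** 2)
    ss_ab = n * np.sum((ab - am[:, None] - bm[None, :] + grand) ** 2)
    ss_sa = q * np.sum((sa - subj[:, None] - am[None, :] + grand) ** 2)
    ss_sb = p * np.sum((sb - subj[:, None] - bm[None, :] + grand) ** 2)
    resid = (
        values
        - sa[:, :, None]
        - sb[:, None, :]
        - ab[None, :, :]
        + subj[:, None, None]
        + am[None, :, None]
        + bm[None, None, :]
        - grand
    )
    ss_sab = np.sum(resid**2)

    out = {}
    for name, ss_e, ss_err, df1 in (
        ("a", ss_a, ss_sa, p - 1),
        ("b", ss_b, ss_sb, q - 1),
        ("ab", ss_ab, ss_sab, (p - 1) * (q - 1)),
    ):
        df2 = df1 * (n - 1)
        F = (ss_e / df1) / (ss_err / df2) if ss_err > 0 else float("nan")
        out[name] = (ss_e, ss_err, F, df1, df2)
    return out


def truncnorm_int_mass(lo=30, hi=70, mean=50.0, sd=10.0):
    """Probability of each integer EV under the generation scheme: a
    continuous truncated Normal draw rounded to the nearest integer."""
    from scipy import stats

    z = stats.norm.cdf(hi, mean, sd) - stats.norm.cdf(lo, mean, sd)
    masses = {}
    for ev in range(lo, hi + 1):
        a = max(ev - 0.5, lo)
        b = min(ev + 0.5, hi)
        masses[ev] = (stats.norm.cdf(b, mean, sd) - stats.norm.cdf(a, mean, sd)) / z
    return masses
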