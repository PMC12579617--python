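"""Model selection and posterior hypothesis testing.

DIC is computed in the Spiegelhalter form: DIC = D-bar + pD with
pD = D-bar - D(theta-bar), where D-bar is the mean stored deviance and
theta-bar the posterior mean of the subject-level parameters on the
sampling (transformed) scale.  Convergence uses the classic Gelman-Rubin
potential scale reduction factor; directional hypotheses use the q-value,
the posterior probability that one parameter exceeds another, declared
significant two-tailed when min(q, 1-q) < .025.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import BuiltModel
from .sampler import HierarchicalPosterior

Q_SIGNIFICANCE = 0.025
RHAT_THRESHOLD = 1.1


@dataclass
class DICResult:
    mean_deviance: float
    p_d: float
    dic: float


@dataclass
class QTest:
    pair: tuple[str, str]
    direction: str
    q: float
    significant: bool


@dataclass
class ComparisonReport:
    dics: dict[str, DICResult]
    winner: str
    rhat: dict[str, dict[str, float]]
    q_tests: list[QTest] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "models": {
                k: {"mean_deviance": d.mean_deviance, "p_d": d.p_d, "dic": d.dic}
                for k, d in self.dics.items()
            },
            "winner": self.winner,
            "rhat": self.rhat,
            "q_tests": [
                {
                    "pair": list(t.pair),
                    "direction": t.direction,
                    "q": t.q,
                    "significant": t.significant,
                }
                for t in self.q_tests
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def dic_from_deviance(deviance: np.ndarray, deviance_at_mean: float) -> DICResult:
    """DIC from a stored deviance trace and the deviance at the posterior mean."""
    dev = np.asarray(deviance, float).reshape(-1)
    if dev.size == 0:
        raise ValueError("empty deviance trace")
    if dev.size < 100:
        warnings.warn(f"only {dev.size} stored draws for DIC; estimate is noisy", stacklevel=2)
    dbar = float(dev.mean())
    pd_ = dbar - float(deviance_at_mean)
    if pd_ < 0:
        warnings.warn(
            f"negative effective parameter count pD={pd_:.2f}; "
            "posterior may be multimodal or poorly mixed",
            stacklevel=2,
        )
    return DICResult(dbar, pd_, dbar + pd_)


def dic(post: HierarchicalPosterior, model: BuiltModel) -> DICResult:
    """DIC of a fitted hierarchical model."""
    theta_bar = {
        fam: post.subject_draws[fam].mean(axis=(0, 1)) for fam in post.subject_draws
    }
    return dic_from_deviance(post.deviance, model.deviance(theta_bar))


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Classic potential scale reduction factor R-hat.

    ``chains`` has shape (n_chains, n_draws) with at least two chains of
    equal length >= 10.  With ``split=True`` each chain is halved first
    (the split-chain refinement, off by default to match the classic
    statistic).
    """
    x = np.asarray(chains, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("gelman_rubin requires >= 2 chains of equal length")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = x.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful R-hat")
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def convergence_table(post: HierarchicalPosterior) -> dict[str, float]:
    """R-hat per group-level parameter."""
    return {name: gelman_rubin(arr) for name, arr in post.group_draws.items()}


def q_value(samples_a: np.ndarray, samples_b: np.ndarray) -> float:
    """Posterior probability that parameter A exceeds parameter B.

    Computed as the fraction of paired pooled draws with a > b; exact ties
    count half.  Two-tailed significance at min(q, 1-q) < .025.
    """
    a = np.asarray(samples_a, float).reshape(-1)
    b = np.asarray(samples_b, float).reshape(-1)
    if a.size == 0 or b.size == 0:
        raise ValueError("q_value requires non-empty draw vectors")
    if a.size != b.size:
        raise ValueError("q_value pairs draws; vectors must have equal length")
    return float(np.mean(a > b) + 0.5 * np.mean(a == b))


def q_significant(q: float, alpha: float = Q_SIGNIFICANCE) -> bool:
    return min(q, 1.0 - q) < alpha


def compare_models(
    fits: dict[str, tuple[HierarchicalPosterior, BuiltModel]],
    q_pairs: list[tuple[str, str]] | None = None,
) -> ComparisonReport:
    """DIC comparison across fitted models plus optional q-tests.

    ``q_pairs`` lists (parameter_a, parameter_b) group-mean names evaluated
    on the winning model's posterior, e.g. ``[("mu_a_fear", "mu_a_general")]``.
    """
    dics = {k: dic(p, m) for k, (p, m) in fits.items()}
    winner = min(dics, key=lambda k: dics[k].dic)
    rhat = {k: convergence_table(p) for k, (p, _) in fits.items()}
    tests: list[QTest] = []
    if q_pairs:
        post = fits[winner][0]
        for pa, pb in q_pairs:
            q = q_value(post.pooled(pa), post.pooled(pb))
            tests.append(QTest((pa, pb), f"{pa} > {pb}", q, q_significant(q)))
    return ComparisonReport(dics, winner, rhat, tests)
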