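"""Metropolis-within-Gibbs sampler for the hierarchical DDM.

The posterior factorises into subject-level DDM parameters (which carry the
trial likelihood) and group-level means and SDs (which see only the subject
values).  Updates per iteration:

* subject-level values, one parameter family at a time, with per-subject
  Gaussian random-walk proposals evaluated in a single vectorised
  first-passage-density call across all subjects;
* group means by exact conjugate Normal draws;
* group SDs by random-walk Metropolis on the log scale under Half-Normal
  priors.

Proposal scales adapt toward ~44% acceptance during burn-in and are frozen
afterwards, so the post-burn-in chain is a valid Markov chain.  The
deviance (-2 log likelihood over all trials) is cached trial-wise and
recorded with every stored draw for DIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .models import BuiltModel, Family

_TARGET_ACCEPT = 0.44
_ADAPT_BATCH = 25

_INIT_SCALES = {"identity": 0.25, "log": 0.08, "logit": 0.2}


@dataclass
class HierarchicalPosterior:
    """Posterior chains for every group- and subject-level parameter.

    ``group_draws`` maps ``mu_<family>`` / ``sigma_<family>`` to arrays of
    shape (n_chains, n_stored) on the sampling (transformed) scale;
    ``subject_draws`` maps family names to (n_chains, n_stored, n_subjects).
    """

    group_draws: dict[str, np.ndarray]
    subject_draws: dict[str, np.ndarray]
    deviance: np.ndarray
    config: dict
    family_transforms: dict[str, str]
    subject_ids: list

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def n_stored(self) -> int:
        return self.deviance.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Post-burn-in draws pooled across chains."""
        return self.group_draws[name].reshape(-1)

    def group_estimate(self, family: str) -> float:
        """Posterior group location of a family, mapped to the natural scale.

        For log/logit families this is the back-transformed posterior mean
        of the group mean, i.e. the estimated group median on the natural
        scale, matching how the generating group values are specified.
        """
        mu = float(self.pooled(f"mu_{family}").mean())
        tr = self.family_transforms[family]
        if tr == "log":
            return float(np.exp(mu))
        if tr == "logit":
            return float(1.0 / (1.0 + np.exp(-mu)))
        return mu

    def summary(self, include_subjects: bool = False) -> pd.DataFrame:
        """Mean, SD and 2.5/50/97.5 percentiles per parameter (pooled)."""
        rows = {}
        for name, arr in self.group_draws.items():
            rows[name] = arr.reshape(-1)
        if include_subjects:
            for fam, arr in self.subject_draws.items():
                for j, sid in enumerate(self.subject_ids):
                    rows[f"{fam}[{sid}]"] = arr[:, :, j].reshape(-1)
        out = []
        for name, x in rows.items():
            q = np.percentile(x, [2.5, 50.0, 97.5])
            out.append((name, x.mean(), x.std(ddof=1) if x.size > 1 else 0.0, q[0], q[1], q[2]))
        return pd.DataFrame(
            out, columns=["parameter", "mean", "sd", "q2.5", "median", "q97.5"]
        ).set_index("parameter")

    def rhat(self) -> pd.DataFrame:
        """Gelman-Rubin potential scale reduction per stored parameter."""
        from .compare import gelman_rubin

        rows = [(name, gelman_rubin(arr)) for name, arr in self.group_draws.items()]
        for fam, arr in self.subject_draws.items():
            for j, sid in enumerate(self.subject_ids):
                rows.append((f"{fam}[{sid}]", gelman_rubin(arr[:, :, j])))
        return pd.DataFrame(rows, columns=["parameter", "rhat"]).set_index("parameter")

    def max_rhat(self) -> float:
        return float(self.rhat()["rhat"].max())

    def converged(self, threshold: float = 1.1) -> bool:
        return self.max_rhat() <= threshold

    # ---------------------------------------------------------------- io
    def to_csv(self, fh: IO[str] | str | Path) -> None:
        """Long-format export: chain, draw, parameter, value."""
        recs = []
        for name, arr in self.group_draws.items():
            for c in range(self.n_chains):
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "draw": np.arange(self.n_stored),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        pd.concat(recs, ignore_index=True).to_csv(fh, index=False)

    def meta_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "family_transforms": self.family_transforms,
                "subject_ids": [int(s) for s in self.subject_ids],
            },
            indent=2,
        )


def _initial_values(model: BuiltModel, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Heuristic per-subject starting values with chain-level jitter.

    a starts near a typical boundary separation, t_er below each subject's
    fastest response, and each drift family at the value implied by the
    subject's choice fraction through the closed-form absorption
    probability at the midpoint start.
    """
    S = model.n_subjects
    x: dict[str, np.ndarray] = {}
    min_rt = np.full(S, np.inf)
    np.minimum.at(min_rt, model.subj_idx, model.rt)
    a0 = np.full(S, 1.5) * np.exp(rng.normal(0, 0.05, S))
    for fam in model.families:
        if fam.kind == "a":
            x[fam.name] = np.log(a0) + rng.normal(0, 0.05, S)
        elif fam.kind == "t":
            x[fam.name] = np.log(np.minimum(0.6 * min_rt, 0.4)) + rng.normal(0, 0.05, S)
        elif fam.kind == "w":
            x[fam.name] = rng.normal(0, 0.1, S)
        elif fam.kind == "v":
            if fam.is_delta:
                x[fam.name] = rng.normal(0, 0.05, S)
                continue
            num = np.zeros(S)
            den = np.zeros(S)
            s_idx = model.subj_idx[fam.trial_idx]
            np.add.at(num, s_idx, model.upper[fam.trial_idx].astype(float))
            np.add.at(den, s_idx, 1.0)
            p = np.clip(num / np.maximum(den, 1.0), 0.1, 0.9)
            # p_upper = 1 / (1 + exp(-v a)) at w = 0.5  =>  v = logit(p) / a
            x[fam.name] = np.log(p / (1 - p)) / a0 + rng.normal(0, 0.1, S)
    return x


def _run_chain(model: BuiltModel, iterations, burn_in, thin, rng):
    S = model.n_subjects
    fams = model.families
    x = _initial_values(model, rng)
    mu = {f.name: float(np.mean(x[f.name])) for f in fams}
    sigma = {f.name: max(float(np.std(x[f.name])), 0.1) for f in fams}

    cur_ll = model.loglik_trials(x)
    if not np.isfinite(cur_ll.sum()):
        # re-initialise a handful of times before giving up
        for _ in range(20):
            x = _initial_values(model, rng)
            cur_ll = model.loglik_trials(x)
            if np.isfinite(cur_ll.sum()):
                break
        else:
            raise RuntimeError("could not find a finite-density initial state")

    scales = {f.name: np.full(S, _INIT_SCALES[f.transform]) for f in fams}
    sig_scales = {f.name: 0.3 for f in fams}
    acc_counts = {f.name: np.zeros(S) for f in fams}
    sig_acc = {f.name: 0.0 for f in fams}

    # per-trial natural-scale parameter caches, refreshed incrementally
    v_t, a_t, w_t, ter_t = model.trial_params(x)
    kind_cache = {"v": v_t, "a": a_t, "w": w_t, "t": ter_t}

    n_stored = (iterations - burn_in) // thin
    stored_group = {
        name: np.empty(n_stored)
        for f in fams
        for name in (f"mu_{f.name}", f"sigma_{f.name}")
    }
    stored_subj = {f.name: np.empty((n_stored, S)) for f in fams}
    stored_dev = np.empty(n_stored)

    from ._wfpt import wfpt_logpdf_arr

    store_i = 0
    for it in range(iterations):
        adapting = it < burn_in
        for f in fams:
            name = f.name
            m = f.trial_idx
            s_m = model.subj_idx[m]
            prop = x[name] + scales[name] * rng.standard_normal(S)

            if f.kind == "v":
                if f.is_delta:
                    pv = v_t[m] - x[name][s_m] + prop[s_m]
                else:
                    pv = prop[s_m]
                    for di in model._delta_fams:
                        dfam = fams[di]
                        if dfam.name != name:
                            sel = np.isin(m, dfam.trial_idx)
                            if sel.any():
                                pv = pv + np.where(sel, x[dfam.name][s_m], 0.0)
                new_ll = wfpt_logpdf_arr(
                    model.rt[m], model.upper[m], pv, a_t[m], w_t[m], ter_t[m], model.eps
                )
            elif f.kind == "a":
                pa = np.exp(prop[s_m])
                new_ll = wfpt_logpdf_arr(
                    model.rt[m], model.upper[m], v_t[m], pa, w_t[m], ter_t[m], model.eps
                )
            elif f.kind == "w":
                pw = 1.0 / (1.0 + np.exp(-prop[s_m]))
                new_ll = wfpt_logpdf_arr(
                    model.rt[m], model.upper[m], v_t[m], a_t[m], pw, ter_t[m], model.eps
                )
            else:
                pt = np.exp(prop[s_m])
                new_ll = wfpt_logpdf_arr(
                    model.rt[m], model.upper[m], v_t[m], a_t[m], w_t[m], pt, model.eps
                )

            d_ll = np.zeros(S)
            np.add.at(d_ll, s_m, new_ll - cur_ll[m])
            d_prior = ((x[name] - mu[name]) ** 2 - (prop - mu[name]) ** 2) / (
                2.0 * sigma[name] ** 2
            )
            accept = np.log(rng.random(S)) < d_ll + d_prior
            if accept.any():
                x[name] = np.where(accept, prop, x[name])
                acc_m = accept[s_m]
                cur_ll[m] = np.where(acc_m, new_ll, cur_ll[m])
                if f.kind == "v":
                    if f.is_delta:
                        v_t[m] = np.where(acc_m, pv, v_t[m])
                    else:
                        v_t[m] = np.where(acc_m, pv, v_t[m])
                elif f.kind == "a":
                    a_t[m] = np.where(acc_m, pa, a_t[m])
                elif f.kind == "w":
                    w_t[m] = np.where(acc_m, pw, w_t[m])
                else:
                    ter_t[m] = np.where(acc_m, pt, ter_t[m])
            if adapting:
                acc_counts[name] += accept

            # group mean: conjugate Normal draw
            m0, s0 = model.prior_mu_params(f)
            prec = 1.0 / s0**2 + S / sigma[name] ** 2
            mean = (m0 / s0**2 + x[name].sum() / sigma[name] ** 2) / prec
            mu[name] = mean + rng.standard_normal() / np.sqrt(prec)

            # group SD: log-scale random walk under Half-Normal prior
            ssq = float(np.sum((x[name] - mu[name]) ** 2))
            hn = model.prior_sigma_scale(f)
            u = np.log(sigma[name])
            u_prop = u + sig_scales[name] * rng.standard_normal()

            def logpost(uu):
                sig = np.exp(uu)
                return -S * uu - ssq / (2.0 * sig**2) - sig**2 / (2.0 * hn**2) + uu

            if np.log(rng.random()) < logpost(u_prop) - logpost(u):
                sigma[name] = float(np.exp(u_prop))
                if adapting:
                    sig_acc[name] += 1.0

        if adapting and (it + 1) % _ADAPT_BATCH == 0:
            delta = min(0.25, ((it + 1) / _ADAPT_BATCH) ** -0.5)
            for f in fams:
                rate = acc_counts[f.name] / _ADAPT_BATCH
                scales[f.name] *= np.exp(delta * (rate - _TARGET_ACCEPT))
                acc_counts[f.name][:] = 0.0
                srate = sig_acc[f.name] / _ADAPT_BATCH
                sig_scales[f.name] *= np.exp(delta * (srate - _TARGET_ACCEPT))
                sig_acc[f.name] = 0.0

        if it >= burn_in and (it - burn_in) % thin == 0 and store_i < n_stored:
            for f in fams:
                stored_group[f"mu_{f.name}"][store_i] = mu[f.name]
                stored_group[f"sigma_{f.name}"][store_i] = sigma[f.name]
                stored_subj[f.name][store_i] = x[f.name]
            stored_dev[store_i] = -2.0 * float(cur_ll.sum())
            store_i += 1

    return stored_group, stored_subj, stored_dev


def fit(
    model: BuiltModel,
    iterations: int = 5000,
    burn_in: int = 2500,
    thin: int = 5,
    n_chains: int = 2,
    seed: int | np.random.SeedSequence = 0,
) -> HierarchicalPosterior:
    """Draw posterior samples for a built model.

    Defaults follow the reference analysis protocol: 5,000 iterations with
    a 2,500-sample burn-in and a thin of five, run as two independent
    chains so the Gelman-Rubin diagnostic is well defined.
    """
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    if thin < 1 or n_chains < 1:
        raise ValueError("thin and n_chains must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = ss.spawn(n_chains)
    groups, subjs, devs = [], [], []
    for c in range(n_chains):
        g, s, d = _run_chain(model, iterations, burn_in, thin, np.random.default_rng(child[c]))
        groups.append(g)
        subjs.append(s)
        devs.append(d)
    group_draws = {
        name: np.stack([g[name] for g in groups]) for name in groups[0]
    }
    subject_draws = {
        name: np.stack([s[name] for s in subjs]) for name in subjs[0]
    }
    return HierarchicalPosterior(
        group_draws=group_draws,
        subject_draws=subject_draws,
        deviance=np.stack(devs),
        config={
            "iterations": iterations,
            "burn_in": burn_in,
            "thin": thin,
            "n_chains": n_chains,
            "seed": str(ss.entropy),
            "model_id": model.spec.model_id,
            "dataset": model.spec.dataset,
        },
        family_transforms={f.name: f.transform for f in model.families},
        subject_ids=list(model.subject_ids),
    )


def posterior_summary(post: HierarchicalPosterior, include_subjects: bool = False) -> pd.DataFrame:
    """Posterior mean, SD and central percentiles per group parameter."""
    if post.n_stored == 0:
        raise ValueError("posterior holds no stored draws")
    return post.summary(include_subjects=include_subjects)
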