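"""Hierarchical model specifications and the trial-level likelihood.

Four competing specifications capture the candidate mechanisms:

* Model 1 (general-attention trials only): drift rate varies by the
  stimulus-emotion condition, starting point fixed at the midpoint,
  one boundary separation and non-decision time per subject.  Upper
  boundary = fearful decision.
* Models 2-4 (general trials plus one specific-attention condition):
  all keep the stimulus-dependent drift; Model 2 additionally lets drift
  depend on the attention condition, Model 3 lets the starting point
  depend on it, Model 4 lets the boundary separation depend on it.

The fear-attention analyses put the fearful decision on the upper
boundary; the happy-attention analyses put the happy decision there.  The
recoding from the canonical stored coding (fear side up) happens here, so
drift-sign conventions never need hand-flipping downstream.

Subject-level parameters are modelled as Normal on transformed scales
(identity for v, log for a and t_er, logit for w) around group means, with
group standard deviations per parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._wfpt import wfpt_logpdf_arr
from .ddm import DEFAULT_EPS
from .stimuli import STIM_CONDITIONS

Dataset = Literal["general_only", "general_plus_fear", "general_plus_happy"]
Transform = Literal["identity", "log", "logit"]
Kind = Literal["v", "a", "w", "t"]

#: Maximum reaction time (s) admitted into a fit; slower trials are assumed
#: to reflect lapses and must be filtered out beforehand.
RT_CEILING = 4.0

_DATASET_ATTN = {
    "general_only": ("general",),
    "general_plus_fear": ("general", "fear"),
    "general_plus_happy": ("general", "happy"),
}


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative group priors on the transformed scales.

    ``mu_loc``/``mu_scale`` parameterise the Normal prior of the group mean
    of each parameter family; ``sigma_scale`` the Half-Normal prior of the
    group SD.  Defaults are broad relative to the parameter magnitudes this
    task produces.
    """

    mu: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "v": (0.0, 5.0),
            "a": (float(np.log(1.5)), 1.0),
            "t": (float(np.log(0.3)), 1.0),
            "w": (0.0, 1.0),
        }
    )
    sigma_scale: dict[str, float] = field(
        default_factory=lambda: {"v": 1.0, "a": 1.0, "t": 1.0, "w": 1.0}
    )


@dataclass(frozen=True)
class ModelSpec:
    """Which DDM parameters depend on which experimental factors."""

    model_id: int
    dataset: Dataset
    depends: dict[str, tuple[str, ...]]
    w_fixed: float | None = 0.5
    drift_structure: Literal["crossed", "additive"] = "crossed"

    @property
    def attn_conditions(self) -> tuple[str, ...]:
        return _DATASET_ATTN[self.dataset]

    @property
    def upper_is_fear_side(self) -> bool:
        """True when the analysis puts the fear-consistent decision on top."""
        return self.dataset != "general_plus_happy"


def model_spec(
    model_id: int,
    dataset: Dataset | None = None,
    drift_structure: Literal["crossed", "additive"] = "crossed",
) -> ModelSpec:
    """Construct one of the four canonical model specifications."""
    if model_id == 1:
        if dataset not in (None, "general_only"):
            raise ValueError("Model 1 is defined on the general-attention trials only")
        return ModelSpec(1, "general_only", {"v": ("stim",)}, w_fixed=0.5)
    if model_id not in (2, 3, 4):
        raise ValueError(f"model_id must be 1..4, got {model_id}")
    if dataset not in ("general_plus_fear", "general_plus_happy"):
        raise ValueError("Models 2-4 require dataset 'general_plus_fear' or 'general_plus_happy'")
    if model_id == 2:
        dep = ("stim", "attn") if drift_structure == "crossed" else ("stim", "+attn")
        return ModelSpec(2, dataset, {"v": dep}, w_fixed=0.5, drift_structure=drift_structure)
    if model_id == 3:
        return ModelSpec(3, dataset, {"v": ("stim",), "w": ("attn",)}, w_fixed=None)
    return ModelSpec(4, dataset, {"v": ("stim",), "a": ("attn",)}, w_fixed=0.5)


@dataclass
class Family:
    """One group of subject-level parameters sharing a hierarchical prior."""

    name: str
    kind: Kind
    transform: Transform
    trial_idx: np.ndarray  # trial indices whose likelihood this family enters
    is_delta: bool = False  # additive drift offset rather than a cell value

    def to_natural(self, x):
        if self.transform == "identity":
            return x
        if self.transform == "log":
            return np.exp(x)
        return 1.0 / (1.0 + np.exp(-x))


class BuiltModel:
    """Data bound to a specification: index arrays plus the log-likelihood."""

    def __init__(
        self,
        spec: ModelSpec,
        df: pd.DataFrame,
        priors: PriorSpec | None = None,
        min_trials: int = 10,
        drop_sparse_subjects: bool = True,
        data_coding: Literal["fear_upper", "happy_upper"] = "fear_upper",
        eps: float = DEFAULT_EPS,
    ):
        self.spec = spec
        self.priors = priors or PriorSpec()
        self.eps = eps

        allowed = set(spec.attn_conditions)
        bad = set(df["attn"].astype(str)) - allowed
        if bad:
            raise ValueError(
                f"trials with attention condition(s) {sorted(bad)} are outside "
                f"dataset {spec.dataset!r}; filter before building"
            )
        if (df["rt_s"] > RT_CEILING).any():
            raise ValueError(
                f"reaction times above the {RT_CEILING}s ceiling present; apply filter_rts first"
            )
        if (df["rt_s"] <= 0).any():
            raise ValueError("non-positive reaction times present")

        df = df.copy()
        counts = df.groupby("subject_id", observed=True)["rt_s"].size()
        sparse = counts[counts < min_trials].index.tolist()
        if sparse:
            warnings.warn(
                f"subjects {sparse} have fewer than {min_trials} valid trials"
                + ("; dropping" if drop_sparse_subjects else ""),
                stacklevel=2,
            )
            if drop_sparse_subjects:
                df = df[~df["subject_id"].isin(sparse)]
        if df.empty:
            raise ValueError("no trials left to fit")

        self.df = df.reset_index(drop=True)
        subj_codes, self.subject_ids = pd.factorize(self.df["subject_id"], sort=True)
        self.subj_idx = subj_codes.astype(np.int64)
        self.n_subjects = len(self.subject_ids)
        self.n_trials = len(self.df)
        self.rt = self.df["rt_s"].to_numpy(float)

        upper_raw = self.df["choice"].astype(str).to_numpy() == "upper"
        flip = (data_coding == "fear_upper") != spec.upper_is_fear_side
        self.upper = upper_raw ^ flip

        attn = self.df["attn"].astype(str).to_numpy()
        stim = self.df["stim"].astype(str).to_numpy()
        self.families: list[Family] = []
        self._fam_by_kind: dict[str, list[int]] = {"v": [], "a": [], "w": [], "t": []}
        self._delta_fams: list[int] = []

        def add(name, kind, transform, mask, is_delta=False):
            fam = Family(name, kind, transform, np.flatnonzero(mask), is_delta)
            self._fam_by_kind[kind].append(len(self.families))
            if is_delta:
                self._delta_fams.append(len(self.families))
            self.families.append(fam)

        all_mask = np.ones(self.n_trials, bool)
        v_dep = spec.depends.get("v", ())
        if v_dep == ("stim", "attn"):
            for a_ in spec.attn_conditions:
                for s_ in STIM_CONDITIONS:
                    add(f"v_{s_}_{a_}", "v", "identity", (stim == s_) & (attn == a_))
        elif v_dep == ("stim", "+attn"):
            for s_ in STIM_CONDITIONS:
                add(f"v_{s_}", "v", "identity", stim == s_)
            extra = spec.attn_conditions[1]
            add(f"dv_{extra}", "v", "identity", attn == extra, is_delta=True)
        else:
            for s_ in STIM_CONDITIONS:
                add(f"v_{s_}", "v", "identity", stim == s_)

        if spec.depends.get("a") == ("attn",):
            for a_ in spec.attn_conditions:
                add(f"a_{a_}", "a", "log", attn == a_)
        else:
            add("a", "a", "log", all_mask)

        if spec.w_fixed is None:
            for a_ in spec.attn_conditions:
                add(f"w_{a_}", "w", "logit", attn == a_)
        self.w_fixed = spec.w_fixed

        add("t_er", "t", "log", all_mask)

        # per-trial family index for each parameter kind
        self.trial_fam = {}
        for kind in ("v", "a", "w", "t"):
            fams = [i for i in self._fam_by_kind[kind] if not self.families[i].is_delta]
            if not fams:
                continue
            idx = np.full(self.n_trials, -1, np.int64)
            for i in fams:
                idx[self.families[i].trial_idx] = i
            if (idx < 0).any():
                raise RuntimeError(f"uncovered trials for parameter kind {kind}")
            self.trial_fam[kind] = idx

    # ------------------------------------------------------------------
    def family(self, name: str) -> Family:
        for f in self.families:
            if f.name == name:
                return f
        raise KeyError(name)

    def family_names(self) -> list[str]:
        return [f.name for f in self.families]

    def trial_params(self, x: dict[str, np.ndarray]):
        """Assemble per-trial (v, a, w, ter) on the natural scale from
        subject-level transformed values ``x[family_name][subject]``."""
        s = self.subj_idx
        v = np.empty(self.n_trials)
        for i in self._fam_by_kind["v"]:
            fam = self.families[i]
            if fam.is_delta:
                continue
            v[fam.trial_idx] = x[fam.name][s[fam.trial_idx]]
        for i in self._delta_fams:
            fam = self.families[i]
            v[fam.trial_idx] += x[fam.name][s[fam.trial_idx]]
        a = np.empty(self.n_trials)
        for i in self._fam_by_kind["a"]:
            fam = self.families[i]
            a[fam.trial_idx] = np.exp(x[fam.name][s[fam.trial_idx]])
        if self.w_fixed is not None:
            w = np.full(self.n_trials, self.w_fixed)
        else:
            w = np.empty(self.n_trials)
            for i in self._fam_by_kind["w"]:
                fam = self.families[i]
                w[fam.trial_idx] = 1.0 / (1.0 + np.exp(-x[fam.name][s[fam.trial_idx]]))
        (ti,) = self._fam_by_kind["t"]
        ter = np.exp(x[self.families[ti].name][s])
        return v, a, w, ter

    def loglik_trials(self, x: dict[str, np.ndarray]) -> np.ndarray:
        """Per-trial log-likelihood under subject-level values ``x``."""
        v, a, w, ter = self.trial_params(x)
        return wfpt_logpdf_arr(self.rt, self.upper, v, a, w, ter, self.eps)

    def loglik(self, x: dict[str, np.ndarray]) -> float:
        return float(self.loglik_trials(x).sum())

    def deviance(self, x: dict[str, np.ndarray]) -> float:
        return -2.0 * self.loglik(x)

    def prior_mu_params(self, fam: Family) -> tuple[float, float]:
        return self.priors.mu[fam.kind]

    def prior_sigma_scale(self, fam: Family) -> float:
        return self.priors.sigma_scale[fam.kind]


def build_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    priors: PriorSpec | None = None,
    min_trials: int = 10,
    drop_sparse_subjects: bool = True,
    data_coding: Literal["fear_upper", "happy_upper"] = "fear_upper",
) -> BuiltModel:
    """Bind trial records to a model specification.

    ``data`` must be restricted to the specification's dataset (general
    trials plus at most one specific-attention condition) and already pass
    the reaction-time ceiling filter.
    """
    return BuiltModel(
        spec,
        data,
        priors=priors,
        min_trials=min_trials,
        drop_sparse_subjects=drop_sparse_subjects,
        data_coding=data_coding,
    )


def select_dataset(df: pd.DataFrame, dataset: Dataset) -> pd.DataFrame:
    """Restrict a full-cohort trial table to the conditions a model uses."""
    return df[df["attn"].astype(str).isin(_DATASET_ATTN[dataset])].reset_index(drop=True)
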