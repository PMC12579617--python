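"""End-to-end orchestration: configuration, seeding, logging, artifacts.

A run executes simulate -> filter -> fit (each requested model) -> compare
-> posterior predictive check -> behavioural statistics, writing every
artifact under one output directory.  The run is reproducible from the
configuration and its single seed: per-stage child seeds are derived
deterministically by spawning a ``numpy`` SeedSequence in a fixed order
(data, then one per model fit, then PPC), so any stage can be re-run in
isolation with the same child seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import behavior as bh
from .compare import compare_models
from .models import build_model, model_spec, select_dataset
from .ppc import posterior_predict, ppc_report
from .sampler import fit
from .simulate import CANONICAL_LABELS, CohortTruth, generate_cohort


class TruthConfig(BaseModel):
    v_by_stim: dict[str, float] = {"fearful": 0.55, "neutral": 0.02, "happy": -0.40}
    a_by_attn: dict[str, float] = {"general": 1.46, "fear": 1.55, "happy": 1.40}
    t_er: float = 0.13
    sd_v: float = 0.3
    sd_log_a: float = 0.15
    sd_log_t: float = 0.05

    def to_truth(self) -> CohortTruth:
        return CohortTruth(
            v_by_stim=self.v_by_stim,
            a_by_attn=self.a_by_attn,
            t_er=self.t_er,
            sd_v=self.sd_v,
            sd_log_a=self.sd_log_a,
            sd_log_t=self.sd_log_t,
        )


class SamplerConfig(BaseModel):
    iterations: int = 2000
    burn_in: int = 1000
    thin: int = 2
    n_chains: int = 2


class RunConfig(BaseModel):
    """Fully serialisable description of one pipeline run."""

    seed: int = 0
    n_subjects: int = 8
    trials_per_cell: int = 50
    truth: TruthConfig = Field(default_factory=TruthConfig)
    sampler: SamplerConfig = Field(default_factory=SamplerConfig)
    models: list[int] = [2, 3, 4]
    dataset: Literal["general_only", "general_plus_fear", "general_plus_happy"] = (
        "general_plus_fear"
    )
    ppc_reps: int = 100
    out_dir: str = "run_output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stage failures are recorded in the structured log and re-raised after
    partial outputs are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    (out / "config.yaml").write_text(yaml.safe_dump(config.model_dump()))

    def log(stage: str, **kw) -> None:
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"stage": stage, **stamp, **kw}) + "\n")

    ss = np.random.SeedSequence(config.seed)
    data_ss, ppc_ss, *fit_ss = ss.spawn(2 + len(config.models))

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # record, keep partial outputs, re-raise
            log(name, status="failed", error=str(exc))
            raise
        log(name, status="ok", seconds=round(time.perf_counter() - t0, 3))
        return result

    # --- simulate -----------------------------------------------------
    def _simulate():
        rng = np.random.default_rng(data_ss)
        df, _ = generate_cohort(
            config.n_subjects,
            config.trials_per_cell,
            rng,
            truth=config.truth.to_truth(),
            dt=1e-3,
        )
        df.to_csv(out / "trials.csv", index=False)
        (out / "trials_coding.json").write_text(
            json.dumps({"boundary_labels": CANONICAL_LABELS, "coding": "fear_upper"}, indent=2)
        )
        return df

    raw = stage("simulate", _simulate)

    # --- filter -------------------------------------------------------
    def _filter():
        kept, report = bh.filter_rts(raw)
        (out / "exclusion.json").write_text(json.dumps(report.to_dict(), indent=2))
        return kept

    kept = stage("filter", _filter)

    # --- fits ---------------------------------------------------------
    fits = {}
    for m, fseed in zip(config.models, fit_ss):
        def _fit(m=m, fseed=fseed):
            spec = model_spec(m, None if m == 1 else config.dataset)
            data = select_dataset(kept, spec.dataset)
            model = build_model(spec, data)
            post = fit(
                model,
                iterations=config.sampler.iterations,
                burn_in=config.sampler.burn_in,
                thin=config.sampler.thin,
                n_chains=config.sampler.n_chains,
                seed=fseed,
            )
            post.to_csv(out / f"fit_model{m}.csv")
            (out / f"fit_model{m}_meta.json").write_text(post.meta_json())
            return post, model

        fits[f"model{m}"] = stage(f"fit_model{m}", _fit)

    # --- compare ------------------------------------------------------
    def _compare():
        report = compare_models(fits)
        (out / "comparison.json").write_text(report.to_json())
        return report

    comparison = stage("compare", _compare)

    # --- posterior predictive check on the winner ---------------------
    def _ppc():
        post, model = fits[comparison.winner]
        reps = posterior_predict(
            post, model, n_rep=config.ppc_reps, rng=np.random.default_rng(ppc_ss)
        )
        report = ppc_report(model.df, reps)
        (out / "ppc.json").write_text(report.to_json())
        return report

    stage("ppc", _ppc)

    # --- behavioural statistics ---------------------------------------
    def _behavior():
        report = bh.behavior_report(raw)
        (out / "behavior.json").write_text(json.dumps(report, indent=2))
        return report

    stage("behavior", _behavior)

    return out
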