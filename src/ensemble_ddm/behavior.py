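"""Behavioural statistics layer.

Covers the decision-proportion mapping (fear-consistent choices:
"Fearful" under general and fear-attention instructions, "Not Happy" under
happy-attention), the reaction-time ceiling exclusion, subject-by-condition
summaries, the 3 (stimulus emotion) x 3 (attention) repeated-measures
ANOVA with partial eta squared and its 90% confidence interval, and
pairwise post hoc contrasts with Tukey-adjusted p-values and Cohen's d.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

RT_CEILING = 4.0


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping of the reaction-time ceiling exclusion."""

    presented: int
    excluded: int

    @property
    def valid(self) -> int:
        return self.presented - self.excluded

    @property
    def exclusion_rate(self) -> float:
        return self.excluded / self.presented if self.presented else float("nan")

    def to_dict(self) -> dict:
        return {
            "presented": self.presented,
            "excluded": self.excluded,
            "valid": self.valid,
            "exclusion_rate": self.exclusion_rate,
        }


def filter_rts(records: pd.DataFrame, ceiling: float = RT_CEILING):
    """Drop trials slower than the ceiling (4 s by default).

    Returns (kept records, :class:`ExclusionReport`).
    """
    if (records["rt_s"] <= 0).any():
        raise ValueError("reaction times must be positive")
    keep = records["rt_s"] <= ceiling
    return records[keep].reset_index(drop=True), ExclusionReport(len(records), int((~keep).sum()))


def decision_proportions(
    records: pd.DataFrame,
    fear_side: str | dict[str, str] = "upper",
    ceiling: float = RT_CEILING,
) -> pd.DataFrame:
    """Per subject x attention x stimulus summary of choices and RTs.

    ``fear_side`` names the boundary that carries the fear-consistent
    decision, either globally or per attention condition; with the
    canonical coding it is the upper boundary everywhere ("Fearful" in the
    general- and fear-attention conditions, "Not Happy" under
    happy-attention, each complementary to its opposing label).

    Cells with no valid trials yield NaN, never a silent zero.
    """
    df = records.copy()
    df["attn"] = df["attn"].astype(str)
    df["stim"] = df["stim"].astype(str)
    if isinstance(fear_side, str):
        side = pd.Series(fear_side, index=df.index)
    else:
        side = df["attn"].map(fear_side)
        if side.isna().any():
            raise ValueError("fear_side mapping misses some attention conditions")
    df["fear_choice"] = df["choice"].astype(str).to_numpy() == side.to_numpy()
    df["valid"] = df["rt_s"] <= ceiling

    def agg(g: pd.DataFrame) -> pd.Series:
        valid = g[g["valid"]]
        n_valid = len(valid)
        return pd.Series(
            {
                "fear_side_proportion": valid["fear_choice"].mean() if n_valid else np.nan,
                "mean_rt": valid["rt_s"].mean() if n_valid else np.nan,
                "n_valid": n_valid,
                "n_excluded": len(g) - n_valid,
            }
        )

    out = (
        df.groupby(["subject_id", "attn", "stim"], observed=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["n_valid"] = out["n_valid"].astype(int)
    out["n_excluded"] = out["n_excluded"].astype(int)
    return out


@dataclass
class EffectResult:
    F: float
    df_num: float
    df_den: float
    p: float
    eta_p2: float
    eta_ci90: tuple[float, float]


@dataclass
class Contrast:
    pair: tuple[str, str]
    t: float
    df: int
    p_raw: float
    p_tukey: float
    cohens_d: float
    capped: bool = False


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    n_subjects: int
    dropped_subjects: list = field(default_factory=list)
    posthoc: dict[str, list[Contrast]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "dropped_subjects": list(self.dropped_subjects),
            "effects": {
                k: {
                    "F": e.F,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "p": e.p,
                    "eta_p2": e.eta_p2,
                    "eta_ci90": list(e.eta_ci90),
                }
                for k, e in self.effects.items()
            },
            "posthoc": {
                f: [
                    {
                        "pair": list(c.pair),
                        "t": c.t,
                        "df": c.df,
                        "p_raw": c.p_raw,
                        "p_tukey": c.p_tukey,
                        "cohens_d": c.cohens_d,
                    }
                    for c in cs
                ]
                for f, cs in self.posthoc.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _eta_ci(F: float, df1: float, df2: float, level: float = 0.90) -> tuple[float, float]:
    """Confidence interval for partial eta squared via noncentral-F inversion."""
    alpha = 1.0 - level
    total = df1 + df2 + 1

    def eta(lam):
        return lam / (lam + total)

    def bound(prob):
        # find lambda with ncf.cdf(F; df1, df2, lambda) == prob
        if stats.ncf.cdf(F, df1, df2, 0.0) < prob:
            return 0.0
        hi = 10.0
        while stats.ncf.cdf(F, df1, df2, hi) > prob:
            hi *= 2.0
            if hi > 1e7:
                return eta(hi)
        lam = optimize.brentq(lambda l: stats.ncf.cdf(F, df1, df2, l) - prob, 0.0, hi)
        return eta(lam)

    return (bound(1.0 - alpha / 2.0), bound(alpha / 2.0))


def rm_anova_3x3(
    cells: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject_id",
    factors: tuple[str, str] = ("stim", "attn"),
    eta_ci_level: float = 0.90,
    compute_eta_ci: bool = True,
) -> AnovaResult:
    """Two-way fully within-subject ANOVA.

    ``cells`` is long-format with one row per subject x factor-level cell
    (aggregate trials first).  Subjects with missing cells are removed
    listwise with a logged warning.  Each effect is tested against its own
    subject-by-effect interaction error term (classical repeated-measures
    decomposition, no sphericity correction); partial eta squared is
    SS_effect / (SS_effect + SS_error) with a noncentral-F confidence
    interval.
    """
    from statsmodels.stats.anova import AnovaRM

    f1, f2 = factors
    df = cells[[subject, f1, f2, dv]].copy()
    for c in (f1, f2):
        df[c] = df[c].astype(str)
    n_cells = df[f1].nunique() * df[f2].nunique()
    counts = df.groupby(subject, observed=True).size()
    complete = counts[counts == n_cells].index
    dropped = sorted(set(counts.index) - set(complete))
    if df[dv].isna().any():
        bad = df.loc[df[dv].isna(), subject].unique().tolist()
        dropped = sorted(set(dropped) | set(bad))
        complete = [s for s in complete if s not in set(bad)]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} subject(s) with incomplete cells", stacklevel=2)
        df = df[df[subject].isin(complete)]
    n = df[subject].nunique()
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 complete subjects")

    fitted = AnovaRM(df, depvar=dv, subject=subject, within=[f1, f2]).fit()
    tbl = fitted.anova_table
    effects = {}
    name_map = {f1: f1, f2: f2, f"{f1}:{f2}": "interaction"}
    for key, label in name_map.items():
        F = float(tbl.loc[key, "F Value"])
        d1 = float(tbl.loc[key, "Num DF"])
        d2 = float(tbl.loc[key, "Den DF"])
        p = float(tbl.loc[key, "Pr > F"])
        eta = (F * d1) / (F * d1 + d2)
        ci = _eta_ci(F, d1, d2, eta_ci_level) if compute_eta_ci else (float("nan"), float("nan"))
        effects[label] = EffectResult(F, d1, d2, p, eta, ci)
    return AnovaResult(effects, n, dropped)


def pairwise_posthoc(
    cells: pd.DataFrame,
    factor: str,
    dv: str = "value",
    subject: str = "subject_id",
    t_cap: float = 1e6,
) -> list[Contrast]:
    """Pairwise paired-t contrasts on one factor's marginal means.

    Marginal means collapse over the other factor within subject.  Cohen's
    d uses the SD of the paired differences; the Tukey-adjusted p comes
    from the studentized range distribution over the factor's level count.
    Zero-variance differences report a capped t with a flag instead of inf.
    """
    df = cells.copy()
    df[factor] = df[factor].astype(str)
    marg = df.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    levels = list(marg.columns)
    k = len(levels)
    n = len(marg)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            d = (marg[levels[i]] - marg[levels[j]]).to_numpy()
            mean_d = d.mean()
            sd_d = d.std(ddof=1)
            capped = False
            if sd_d == 0:
                t = 0.0 if mean_d == 0 else np.sign(mean_d) * t_cap
                capped = mean_d != 0
            else:
                t = mean_d / (sd_d / np.sqrt(n))
            dfree = n - 1
            p_raw = 2 * stats.t.sf(abs(t), dfree)
            p_tukey = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, dfree))
            out.append(
                Contrast(
                    pair=(levels[i], levels[j]),
                    t=float(t),
                    df=int(dfree),
                    p_raw=float(min(p_raw, 1.0)),
                    p_tukey=float(min(p_tukey, 1.0)),
                    cohens_d=float(mean_d / sd_d) if sd_d > 0 else 0.0,
                    capped=capped,
                )
            )
    return out


def behavior_report(records: pd.DataFrame, fear_side="upper") -> dict:
    """Full behavioural analysis: exclusion, summaries, two ANOVAs, post hocs."""
    kept, excl = filter_rts(records)
    summaries = decision_proportions(records, fear_side=fear_side)
    result = {"exclusion": excl.to_dict()}
    for dv, label in (("fear_side_proportion", "choice"), ("mean_rt", "rt")):
        anova = rm_anova_3x3(summaries, dv=dv)
        anova.posthoc = {
            fac: pairwise_posthoc(summaries, fac, dv=dv) for fac in ("stim", "attn")
        }
        result[label] = anova.to_dict()
    result["cell_summaries"] = summaries.to_dict(orient="records")
    return result
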