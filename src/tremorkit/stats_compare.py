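"""Within-subject comparison of outcomes across vibration conditions.

Each outcome is compared across the three vibration intensities (none / low
/ high) with a random-intercept linear mixed-effects model

    value ~ condition + (1 | participant)

fitted by REML (statsmodels MixedLM), with "none" as the reference level.
The main effect of condition is tested, by default, with a Wald F statistic
on the two condition terms against an F distribution whose denominator
degrees of freedom follow the containment rule
(n_obs - n_participants - n_condition_terms); for the balanced
one-observation-per-cell design this reduces to the exact
(g - 1)(k - 1)-df repeated-measures F and is well calibrated at small n.
A likelihood-ratio test on ML refits is available via ``method="lrt"``.
Post hoc all-pairs contrasts use the studentized-range (Tukey) adjustment
on the model's estimated marginal means.

Repetitions within a participant x task x condition cell are averaged
before fitting by default (``average_repetitions``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import CONDITIONS

__all__ = [
    "LmmResult",
    "TukeyResult",
    "descriptive_summary",
    "fit_lmm",
    "tukey_posthoc",
    "analyze_all",
]


@dataclass
class LmmResult:
    outcome: str
    task: str | None
    fe_params: dict[str, float]  # intercept + condition effects vs "none"
    fe_cov: np.ndarray  # covariance of the condition-effect block (incl. intercept)
    fe_names: list[str]
    intercept_var: float
    resid_var: float
    stat: float
    df_num: int
    df_den: float
    p_value: float
    method: str
    converged: bool
    degenerate: bool
    n_obs: int
    n_groups: int
    levels: list[str] = field(default_factory=list)


@dataclass
class TukeyResult:
    contrasts: pd.DataFrame  # columns: contrast, estimate, se, p_unadj, p_adj, lower, upper
    df: float
    k: int


def _prepare(
    table: pd.DataFrame,
    outcome_name: str | None = None,
    task: str | None = None,
    average_repetitions: bool = True,
) -> pd.DataFrame:
    df = table.copy()
    if outcome_name is not None and "outcome" in df.columns:
        df = df[df["outcome"] == outcome_name]
    if task is not None and "task" in df.columns:
        df = df[df["task"] == task]
    df = df.dropna(subset=["value"])
    if average_repetitions:
        keys = [c for c in ("participant", "task", "condition") if c in df.columns]
        df = df.groupby(keys, as_index=False, observed=True)["value"].mean()
    return df


def descriptive_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean (sample SD) per task x condition for each outcome.

    Missing values are excluded; singleton groups report an NA SD.  Returns
    one row per (task, condition, outcome) with n, n_missing, mean, sd.
    """
    if table.empty:
        raise ValueError("empty trial table")
    df = table.copy()
    keys = [c for c in ("task", "condition", "outcome") if c in df.columns]
    g = df.groupby(keys, observed=True)["value"]
    out = g.agg(
        n=lambda s: int(s.notna().sum()),
        n_missing=lambda s: int(s.isna().sum()),
        mean="mean",
        sd=lambda s: s.std(ddof=1),
    ).reset_index()
    return out


def _containment_df(n_obs: int, n_groups: int, df_num: int) -> float:
    return float(n_obs - n_groups - df_num)


def fit_lmm(
    table: pd.DataFrame,
    outcome_name: str | None = None,
    task: str | None = None,
    method: str = "f",
    average_repetitions: bool = True,
) -> LmmResult:
    """Fit value ~ condition + (1 | participant) and test the main effect.

    ``method`` is ``"f"`` (Wald F with containment denominator df, default)
    or ``"lrt"`` (likelihood ratio on ML refits against chi-square).
    Non-convergence is flagged, never raised; an exactly-degenerate table
    (zero residual variance) short-circuits to the closed-form fit.
    """
    import statsmodels.formula.api as smf

    df = _prepare(table, outcome_name, task, average_repetitions)
    if df["participant"].nunique() < 2:
        raise ValueError("need >= 2 participants")
    levels = [c for c in CONDITIONS if c in set(df["condition"])]
    if len(levels) < 2:
        raise ValueError("need >= 2 observed condition levels")
    df = df.assign(condition=pd.Categorical(df["condition"], categories=levels))
    df_num = len(levels) - 1
    n_obs, n_groups = len(df), df["participant"].nunique()
    dfden = _containment_df(n_obs, n_groups, df_num)
    label = outcome_name or "value"

    # Degenerate case: within-participant values identical across conditions
    piv = df.pivot_table(index="participant", columns="condition", values="value", observed=True)
    resid0 = piv.sub(piv.mean(axis=1), axis=0)
    if np.allclose(resid0.to_numpy(dtype=float), 0.0, atol=1e-12):
        names = [f"condition[{lv}]" for lv in levels[1:]]
        means = piv.mean(axis=0)
        fe = {"Intercept": float(means.iloc[0])}
        fe.update({nm: float(means[lv] - means.iloc[0]) for nm, lv in zip(names, levels[1:])})
        return LmmResult(
            outcome=label, task=task, fe_params=fe,
            fe_cov=np.zeros((df_num, df_num)), fe_names=names,
            intercept_var=float(piv.mean(axis=1).var(ddof=1)) if n_groups > 1 else 0.0,
            resid_var=0.0, stat=float("nan"), df_num=df_num, df_den=dfden,
            p_value=float("nan"), method=method, converged=True, degenerate=True,
            n_obs=n_obs, n_groups=n_groups, levels=levels,
        )

    formula = "value ~ C(condition)"
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["participant"])
            res = model.fit(reml=True)
            converged = bool(res.converged)
        except Exception:
            return LmmResult(
                outcome=label, task=task, fe_params={}, fe_cov=np.empty((0, 0)),
                fe_names=[], intercept_var=float("nan"), resid_var=float("nan"),
                stat=float("nan"), df_num=df_num, df_den=dfden, p_value=float("nan"),
                method=method, converged=False, degenerate=False,
                n_obs=n_obs, n_groups=n_groups, levels=levels,
            )
        exog_names = list(res.model.exog_names)
        cond_names = [nm for nm in exog_names if nm != "Intercept"]
        idx = [exog_names.index(nm) for nm in cond_names]
        beta = np.asarray(res.fe_params)[idx]
        cov_full = np.asarray(res.cov_params())
        V = cov_full[np.ix_(idx, idx)]
        if method == "f":
            try:
                stat = float(beta @ np.linalg.solve(V, beta)) / df_num
                p = float(sstats.f.sf(stat, df_num, dfden))
            except np.linalg.LinAlgError:
                stat, p, converged = float("nan"), float("nan"), False
        elif method == "lrt":
            try:
                r1 = smf.mixedlm(formula, df, groups=df["participant"]).fit(reml=False)
                r0 = smf.mixedlm("value ~ 1", df, groups=df["participant"]).fit(reml=False)
                stat = float(max(2.0 * (r1.llf - r0.llf), 0.0))
                p = float(sstats.chi2.sf(stat, df_num))
            except Exception:
                stat, p, converged = float("nan"), float("nan"), False
        else:
            raise ValueError("method must be 'f' or 'lrt'")
        re_var = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
        fe = {nm: float(v) for nm, v in zip(exog_names, np.asarray(res.fe_params))}
    return LmmResult(
        outcome=label, task=task, fe_params=fe, fe_cov=V, fe_names=cond_names,
        intercept_var=max(re_var, 0.0), resid_var=float(res.scale),
        stat=stat, df_num=df_num, df_den=dfden, p_value=p, method=method,
        converged=converged, degenerate=False, n_obs=n_obs, n_groups=n_groups,
        levels=levels,
    )


def tukey_posthoc(result: LmmResult, alpha: float = 0.05) -> TukeyResult:
    """All-pairs condition contrasts with studentized-range adjustment.

    Contrast estimates and standard errors come from the fitted model's
    fixed effects; the reference distribution uses the containment
    denominator df.  With two levels the adjustment degenerates to the
    unadjusted t test.
    """
    if not result.converged and not result.degenerate:
        raise ValueError("cannot run post hoc contrasts on a non-converged model")
    levels = result.levels
    k = len(levels)
    dfden = result.df_den
    # effect of level j relative to reference, as a coefficient vector
    names = result.fe_names
    eff = {levels[0]: np.zeros(len(names))}
    for j, lv in enumerate(levels[1:]):
        v = np.zeros(len(names))
        v[j] = 1.0
        eff[lv] = v
    beta = np.array([result.fe_params.get(nm, 0.0) for nm in names])
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            c = eff[b] - eff[a]
            est = float(c @ beta)
            var = float(c @ result.fe_cov @ c) if result.fe_cov.size else 0.0
            se = float(np.sqrt(max(var, 0.0)))
            if se > 0 and dfden > 0:
                tstat = est / se
                p_unadj = float(2.0 * sstats.t.sf(abs(tstat), dfden))
                q = abs(tstat) * np.sqrt(2.0)
                if k > 2:
                    p_adj = float(sstats.studentized_range.sf(q, k, dfden))
                    qcrit = float(sstats.studentized_range.ppf(1.0 - alpha, k, dfden))
                    half = qcrit / np.sqrt(2.0) * se
                else:
                    p_adj = p_unadj
                    half = float(sstats.t.ppf(1.0 - alpha / 2.0, dfden)) * se
                p_adj = min(max(p_adj, p_unadj), 1.0)
                lower, upper = est - half, est + half
            else:  # degenerate: no residual variability
                p_unadj = p_adj = 1.0 if est == 0 else 0.0
                lower = upper = est
            rows.append(
                dict(contrast=f"{b}-{a}", estimate=est, se=se,
                     p_unadj=p_unadj, p_adj=p_adj, lower=lower, upper=upper)
            )
    return TukeyResult(contrasts=pd.DataFrame(rows), df=dfden, k=k)


def analyze_all(
    tablet_metrics: pd.DataFrame,
    accel_features: pd.DataFrame | None = None,
    tablet_outcomes: tuple[str, ...] = (
        "duration", "pause_count", "pause_time", "mean_velocity", "peak_count",
    ),
    accel_outcomes: tuple[str, ...] = (
        "acc_x_normalized_peaks", "acc_y_normalized_peaks", "acc_z_normalized_peaks",
    ),
    method: str = "f",
    average_repetitions: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Fit one model + Tukey contrasts per (task, outcome).

    Returns (results, descriptives, report_text).  ``results`` has one row
    per task x outcome x contrast carrying the main-effect test alongside.
    """
    long_rows = []
    key_cols = ["participant", "task", "condition", "repetition"]
    for col in key_cols:
        if col not in tablet_metrics.columns:
            raise ValueError(f"tablet metrics table lacks key column {col!r}")
    for out in tablet_outcomes:
        if out not in tablet_metrics.columns:
            raise ValueError(f"tablet metrics table lacks outcome column {out!r}")
        sub = tablet_metrics[key_cols + [out]].rename(columns={out: "value"})
        long_rows.append(sub.assign(outcome=out))
    if accel_features is not None:
        missing = [c for c in key_cols if c not in accel_features.columns]
        if missing:
            raise ValueError(f"accel features table lacks key columns {missing}")
        for out in accel_outcomes:
            if out in accel_features.columns:
                sub = accel_features[key_cols + [out]].rename(columns={out: "value"})
                long_rows.append(sub.assign(outcome=out))
    long = pd.concat(long_rows, ignore_index=True)
    descr = descriptive_summary(long)

    rows = []
    for (task, outcome), _ in long.groupby(["task", "outcome"], observed=True):
        try:
            res = fit_lmm(long, outcome_name=outcome, task=task, method=method,
                          average_repetitions=average_repetitions)
        except ValueError:
            continue
        if res.converged or res.degenerate:
            try:
                tk = tukey_posthoc(res).contrasts
            except ValueError:
                tk = pd.DataFrame()
        else:
            tk = pd.DataFrame()
        base = dict(task=task, outcome=outcome, n_obs=res.n_obs,
                    n_participants=res.n_groups, method=res.method,
                    main_stat=res.stat, main_p=res.p_value,
                    intercept_var=res.intercept_var, resid_var=res.resid_var,
                    converged=res.converged)
        if tk.empty:
            rows.append(dict(base, contrast="", estimate=np.nan, se=np.nan,
                             p_unadj=np.nan, p_adj=np.nan, lower=np.nan, upper=np.nan))
        else:
            for _, r in tk.iterrows():
                rows.append(dict(base, **r.to_dict()))
    results = pd.DataFrame(rows)

    lines = ["Within-subject comparison across vibration conditions", ""]
    main = results.drop_duplicates(subset=["task", "outcome"])
    n_sig = int((main["main_p"] < 0.05).sum())
    lines.append(f"Fitted {len(main)} task x outcome mixed models "
                 f"({main['n_participants'].max()} participants).")
    lines.append(f"Main effects with p < 0.05: {n_sig} of {len(main)}.")
    for _, r in main.iterrows():
        flag = " *" if (np.isfinite(r["main_p"]) and r["main_p"] < 0.05) else ""
        stat = f"{r['main_stat']:.3f}" if np.isfinite(r["main_stat"]) else "NA"
        pval = f"{r['main_p']:.4f}" if np.isfinite(r["main_p"]) else "NA"
        lines.append(f"  {r['task']:<12s} {r['outcome']:<28s} stat={stat:>8s} p={pval}{flag}")
    report = "\n".join(lines) + "\n"
    return results, descr, report
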