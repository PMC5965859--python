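"""Mating-behavior metrics: censored latency, duration, contingency tests,
behavioral plasticity and the physiology-behavior regressions.

Conventions follow the four-hour mating screen: males that never court get a
latency equal to the screen length (14,400 s) and stay in latency analyses;
pairs that did not mate are excluded from duration analyses. Behavioral
plasticity for a line is the control-male mean courtship duration minus the
acclimated-male mean, over control-female pairings only, so negative values
mean acclimation lengthened courtship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coldsong.cold_tolerance import DataError


@dataclass(frozen=True)
class BehavioralPlasticityResult:
    line: str
    control_mean_duration: float
    acclimated_mean_duration: float

    @property
    def plasticity(self) -> float:
        return self.control_mean_duration - self.acclimated_mean_duration

    @property
    def missing(self) -> bool:
        return np.isnan(self.control_mean_duration) or \
            np.isnan(self.acclimated_mean_duration)


def apply_latency_censoring(obs: pd.DataFrame) -> pd.DataFrame:
    """Enforce the screen's censoring rules; idempotent.

    Non-courting males get ``latency_s = screen_length_s`` and remain in the
    latency analysis; unmated pairs get a missing ``duration_s`` so they drop
    out of duration analyses.
    """
    obs = obs.copy()
    if (obs["latency_s"] > obs["screen_length_s"]).any():
        raise DataError("latency exceeds screen length")
    not_courted = ~obs["courted"].astype(bool)
    obs.loc[not_courted, "latency_s"] = obs.loc[not_courted, "screen_length_s"]
    obs.loc[~obs["mated"].astype(bool), "duration_s"] = np.nan
    return obs


def duration_table(obs: pd.DataFrame) -> pd.DataFrame:
    """Mated pairs only — the rows eligible for duration analyses."""
    obs = apply_latency_censoring(obs)
    return obs[obs["mated"].astype(bool) & obs["duration_s"].notna()]


def behavioral_plasticity(obs: pd.DataFrame, line: str,
                          female_filter: str = "control_only",
                          ) -> BehavioralPlasticityResult:
    """Plasticity = control-male mean duration - acclimated-male mean duration.

    Means are over mated pairs only; with the default filter only
    control-female pairings enter. An empty arm yields NaN means and a result
    flagged ``missing`` rather than a zero.
    """
    df = duration_table(obs)
    df = df[df["line"] == line]
    if female_filter == "control_only":
        df = df[df["female_trt"] == "control"]
    elif female_filter is not None:
        raise ValueError(f"unknown female_filter {female_filter!r}")
    means = df.groupby("male_trt")["duration_s"].mean()
    return BehavioralPlasticityResult(
        line,
        float(means.get("control", np.nan)),
        float(means.get("acclimated", np.nan)),
    )


def mating_contingency(obs: pd.DataFrame) -> pd.DataFrame:
    """2x2 counts of male treatment (rows) x mated status (columns)."""
    if obs["male_trt"].nunique() < 2:
        raise DataError("both male treatments must be present")
    mated = obs["mated"].astype(bool)
    table = pd.crosstab(obs["male_trt"], mated)
    table = table.reindex(index=["control", "acclimated"],
                          columns=[True, False], fill_value=0)
    table.columns = ["mated", "unmated"]
    return table


def chi_square_test(table: pd.DataFrame | np.ndarray,
                    continuity: bool = True) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table.

    Yates continuity correction is applied iff ``continuity`` (default on,
    mirroring R's ``chisq.test`` default for 2x2 tables). Returns
    (statistic, df, p).
    """
    counts = np.asarray(table, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DataError("degenerate margin: a row or column total is zero")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=continuity)
    return float(stat), int(df), float(p)


def behavior_model_summary(obs: pd.DataFrame, response: str = "duration") -> dict:
    """Mixed-model summary of courtship latency or duration.

    Fixed effects: male treatment, female treatment and their interaction;
    random effects: line intercept plus a line x male-treatment variance
    component (LRT against intercept-only). Latency uses all pairs with
    censored values included; duration uses mated pairs only. Fitting is
    delegated to statsmodels MixedLM.
    """
    import statsmodels.formula.api as smf

    if response == "latency":
        df = apply_latency_censoring(obs).copy()
        df["y"] = df["latency_s"]
    elif response == "duration":
        df = duration_table(obs).copy()
        df["y"] = df["duration_s"]
    else:
        raise ValueError(f"unknown response {response!r}")
    cells = df.groupby(["male_trt", "female_trt"]).size()
    if len(cells) < 4:
        raise DataError(f"empty treatment cells for response {response!r}: "
                        f"found {len(cells)} of 4 male x female combinations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm(
            "y ~ C(male_trt, Treatment('control')) * C(female_trt, Treatment('control'))",
            df, groups=df["line"], re_formula="1",
            vc_formula={"line_x_male_trt": "0 + C(male_trt)"},
        ).fit(reml=False)
        reduced = smf.mixedlm(
            "y ~ C(male_trt, Treatment('control')) * C(female_trt, Treatment('control'))",
            df, groups=df["line"],
        ).fit(reml=False)
    fixed = pd.DataFrame({
        "term": full.fe_params.index,
        "estimate": full.fe_params.values,
        "se": full.bse_fe.values,
        "statistic": full.tvalues[full.fe_params.index].values,
        "p": full.pvalues[full.fe_params.index].values,
    })
    lrt = max(0.0, 2 * (full.llf - reduced.llf))
    return {
        "response": response,
        "fixed_effects": fixed,
        "lrt_line_x_treatment": {"statistic": float(lrt), "df": 1,
                                 "p": float(stats.chi2.sf(lrt, 1))},
        "n_obs": int(len(df)),
        "converged": bool(full.converged),
    }


def line_behavior_summaries(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-line mating-behavior summaries over control-female pairings.

    Columns: latency/duration means for the all-control pair and the
    acclimated-male pair, and behavioral plasticity.
    """
    obs = apply_latency_censoring(obs)
    cf = obs[obs["female_trt"] == "control"]
    rows = []
    for line, sub in cf.groupby("line", sort=True):
        lat = sub.groupby("male_trt")["latency_s"].mean()
        dur = sub[sub["mated"].astype(bool)].groupby("male_trt")["duration_s"].mean()
        rows.append({
            "line": line,
            "latency_control": float(lat.get("control", np.nan)),
            "latency_acclimated_male": float(lat.get("acclimated", np.nan)),
            "duration_control": float(dur.get("control", np.nan)),
            "duration_acclimated_male": float(dur.get("acclimated", np.nan)),
            "plasticity": float(dur.get("control", np.nan) -
                                dur.get("acclimated", np.nan)),
        })
    return pd.DataFrame(rows)


#: line-level behavior summaries regressed on each physiology predictor
BEHAVIOR_COLUMNS = ("latency_control", "latency_acclimated_male",
                    "duration_control", "duration_acclimated_male",
                    "plasticity")


def plasticity_regressions(line_summaries: pd.DataFrame,
                           predictors: tuple[str, ...] = ("basal_mean", "capacity"),
                           behaviors: tuple[str, ...] = BEHAVIOR_COLUMNS,
                           ) -> pd.DataFrame:
    """OLS of each line-level behavior summary on each physiology predictor.

    ``line_summaries`` must carry the behavior columns plus the predictors
    (male basal cold tolerance and RCH capacity). Returns one row per
    (behavior, predictor) with slope, F, df, p and R^2.
    """
    rows = []
    for predictor in predictors:
        for behavior in behaviors:
            sub = line_summaries[[predictor, behavior]].dropna()
            if len(sub) < 3:
                raise DataError(
                    f"need >= 3 complete lines for {behavior} ~ {predictor}")
            x = sub[predictor].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise DataError(f"constant predictor {predictor!r}")
            fit = stats.linregress(x, sub[behavior].to_numpy(dtype=float))
            df_resid = len(sub) - 2
            # two-sided slope t-test is equivalent to the regression F-test
            f_stat = np.inf if fit.stderr == 0 else (fit.slope / fit.stderr) ** 2
            rows.append({
                "behavior": behavior,
                "predictor": predictor,
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "F": float(f_stat),
                "df1": 1,
                "df2": df_resid,
                "p": float(fit.pvalue),
                "r2": float(fit.rvalue ** 2),
                "n_lines": int(len(sub)),
            })
    return pd.DataFrame(rows)
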