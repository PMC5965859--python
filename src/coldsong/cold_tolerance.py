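"""Cold-shock survival summaries and rapid cold-hardening (RCH) capacity.

The unit of analysis is the replicate vial: each vial of 10 flies yields a
survival proportion after either the basal treatment (1 h at -6 degC) or the
acclimated treatment (2 h at 4 degC, then 1 h at -6 degC), with survival
scored after 24 h recovery at 25 degC. RCH capacity for a genotype is the
unweighted mean vial proportion under acclimation minus the mean under the
basal treatment; positive capacity means acclimation improved survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Ordered (temperature degC, duration min) steps of each treatment, plus the
#: shared recovery step. Read-only protocol constants.
TREATMENT_PROTOCOL = {
    "basal": ((-6.0, 60.0),),
    "acclimated": ((4.0, 120.0), (-6.0, 60.0)),
    "recovery": ((25.0, 24 * 60.0),),
}

REQUIRED_COLUMNS = ("line", "sex", "treatment", "replicate",
                    "n_tested", "n_survived")


class DataError(ValueError):
    """Invalid or inconsistent input records."""


@dataclass(frozen=True)
class RCHCapacityResult:
    line: str
    sex: str | None
    basal_mean: float
    acclimated_mean: float

    @property
    def capacity(self) -> float:
        return self.acclimated_mean - self.basal_mean


def validate_survival_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"survival table missing columns: {missing}")
    if (records["n_tested"] <= 0).any():
        raise DataError("n_tested must be positive in every vial")
    bad = (records["n_survived"] < 0) | (records["n_survived"] > records["n_tested"])
    if bad.any():
        raise DataError("n_survived must lie in [0, n_tested]")
    return records


def survival_proportion(n_survived: int, n_tested: int) -> float:
    """Per-vial survival proportion ``n_survived / n_tested``."""
    if n_tested <= 0:
        raise DataError("n_tested must be positive")
    if not 0 <= n_survived <= n_tested:
        raise DataError("n_survived must lie in [0, n_tested]")
    return n_survived / n_tested


def _with_proportions(records: pd.DataFrame) -> pd.DataFrame:
    records = validate_survival_table(records).copy()
    records["proportion"] = records["n_survived"] / records["n_tested"]
    return records


def rch_capacity(records: pd.DataFrame, line: str,
                 sex_mode: str = "pooled") -> RCHCapacityResult | list[RCHCapacityResult]:
    """RCH capacity for one line: mean acclimated minus mean basal proportion.

    ``sex_mode='pooled'`` averages vial proportions across sexes;
    ``'by_sex'`` returns one result per sex. Means are unweighted averages of
    vial proportions within each treatment arm.
    """
    df = _with_proportions(records)
    df = df[df["line"] == line]
    if df.empty:
        raise DataError(f"no records for line {line!r}")

    def _one(sub: pd.DataFrame, sex: str | None) -> RCHCapacityResult:
        arms = sub.groupby("treatment")["proportion"].mean()
        for arm in ("basal", "acclimated"):
            if arm not in arms.index:
                raise DataError(f"line {line!r}: missing {arm} treatment arm")
        return RCHCapacityResult(line, sex, float(arms["basal"]),
                                 float(arms["acclimated"]))

    if sex_mode == "pooled":
        return _one(df, None)
    if sex_mode == "by_sex":
        return [_one(g, sex) for sex, g in df.groupby("sex", sort=True)]
    raise ValueError(f"unknown sex_mode {sex_mode!r}")


def rch_capacity_table(records: pd.DataFrame,
                       sex_mode: str = "pooled") -> pd.DataFrame:
    """Per-line summary table (line, sex, basal_mean, acclimated_mean, capacity,
    capacity_se).

    The standard error of capacity comes from the vial-to-vial variance of
    proportions in each arm (independent arms).
    """
    df = _with_proportions(records)
    rows = []
    group_cols = ["line"] if sex_mode == "pooled" else ["line", "sex"]
    for key, sub in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        arms = sub.groupby("treatment")["proportion"]
        means = arms.mean()
        if not {"basal", "acclimated"} <= set(means.index):
            raise DataError(f"group {key}: missing a treatment arm")
        var = arms.var(ddof=1)
        n = arms.count()
        se = float(np.sqrt((var / n).sum())) if (n > 1).all() else np.nan
        rows.append({
            "line": key[0],
            "sex": key[1] if sex_mode == "by_sex" else "pooled",
            "basal_mean": float(means["basal"]),
            "acclimated_mean": float(means["acclimated"]),
            "capacity": float(means["acclimated"] - means["basal"]),
            "capacity_se": se,
        })
    return pd.DataFrame(rows)


def survival_model_summary(records: pd.DataFrame) -> dict:
    """Mixed-model summary of vial survival proportions.

    Fixed effects: acclimation treatment, sex and their interaction; random
    effects: line intercept plus a line x treatment variance component. The
    fit is delegated to statsmodels MixedLM (ML, so the likelihood-ratio test
    of the line x treatment component against the intercept-only random
    structure is valid). Returns a dict with a tidy ``fixed_effects`` frame
    (term, estimate, se, statistic, p) and the LRT statistic/p for the
    line x treatment component (chi-square, 1 df; conservative for a
    boundary test).

    The treatment effect is coded acclimated minus basal, the sex effect
    male minus female (pandas categorical order).
    """
    import statsmodels.formula.api as smf

    df = _with_proportions(records)
    if df["line"].nunique() < 2:
        raise DataError("need >= 2 lines for the mixed model")
    if df["treatment"].nunique() < 2:
        raise DataError("both treatments must be present")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = smf.mixedlm(
                "proportion ~ C(treatment, Treatment('basal')) * C(sex)",
                df, groups=df["line"], re_formula="1",
                vc_formula={"line_x_treatment": "0 + C(treatment)"},
            ).fit(reml=False)
            reduced = smf.mixedlm(
                "proportion ~ C(treatment, Treatment('basal')) * C(sex)",
                df, groups=df["line"],
            ).fit(reml=False)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise DataError(f"rank-deficient design: {err}") from err
    fixed = pd.DataFrame({
        "term": full.fe_params.index,
        "estimate": full.fe_params.values,
        "se": full.bse_fe.values,
        "statistic": full.tvalues[full.fe_params.index].values,
        "p": full.pvalues[full.fe_params.index].values,
    })
    lrt = max(0.0, 2 * (full.llf - reduced.llf))
    return {
        "fixed_effects": fixed,
        "variance_components": {name: float(v) for name, v in
                                zip(full.model.exog_vc.names, full.vcomp)},
        "line_variance": float(full.cov_re.iloc[0, 0]),
        "lrt_line_x_treatment": {"statistic": float(lrt), "df": 1,
                                 "p": float(stats.chi2.sf(lrt, 1))},
        "converged": bool(full.converged),
    }
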