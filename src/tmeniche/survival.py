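"""Survival association of community scores: Kaplan-Meier and Cox models.

Patients stratified into high/low community-score groups are compared with
a one-tailed log-rank test in the direction "high score = worse survival";
the signed log-rank Z is computed from the standard observed-minus-expected
decomposition (its square equals the usual chi-square statistic, checked in
the tests against lifelines).  Proportional-hazards fits use lifelines'
partial-likelihood maximization with the Efron tie correction, reporting
univariate and covariate-adjusted hazard ratios with one-sided Wald tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter

__all__ = ["km_curves", "km_logrank", "logrank_z", "cox_ph"]


def km_curves(df: pd.DataFrame, stratum_col: str = "stratum") -> dict[str, pd.DataFrame]:
    """Product-limit survival tables per stratum.

    ``df`` needs ``time``, ``event`` and the stratum column.  Each returned
    table has time, n_risk, n_event and the KM survival estimate.
    """
    out = {}
    for stratum, sub in df.groupby(stratum_col):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        tbl = kmf.event_table.copy()
        surv = kmf.survival_function_["KM_estimate"]
        out[str(stratum)] = pd.DataFrame(
            {
                "time": tbl.index.to_numpy(),
                "n_risk": tbl["at_risk"].to_numpy(),
                "n_event": tbl["observed"].to_numpy(),
                "survival": surv.reindex(tbl.index).to_numpy(),
            }
        )
    return out


def logrank_z(time, event, high_mask) -> float:
    """Signed log-rank Z for the high stratum (positive = more events).

    Standard O-E decomposition over distinct event times with the usual
    hypergeometric variance; Z**2 is the two-sided log-rank chi-square.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    high = np.asarray(high_mask, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & high).sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & high).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e / np.sqrt(var))


def km_logrank(df: pd.DataFrame, stratum_col: str = "stratum") -> dict:
    """KM curves plus the one-tailed log-rank p (high stratum worse).

    Requires exactly the strata {"high", "low"} with at least one event
    each; returns the curves, the signed Z and the one-tailed p-value.
    """
    strata = set(df[stratum_col].unique())
    if len(strata) < 2:
        raise ValueError("km_logrank needs two strata")
    for s in strata:
        if df.loc[df[stratum_col] == s, "event"].sum() < 1:
            raise ValueError(f"stratum {s!r} has no events")
    z = logrank_z(df["time"], df["event"], df[stratum_col] == "high")
    return {
        "curves": km_curves(df, stratum_col),
        "z": z,
        "p_one_tailed": float(stats.norm.sf(z)),
        "p_two_sided": float(stats.chi2.sf(z**2, df=1)),
    }


def cox_ph(
    df: pd.DataFrame,
    score_col: str,
    covariates: list[str] | None = None,
    strata: str | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit of survival on a community score.

    Fits ``Surv(time, event) ~ score [+ covariates]`` (optionally with a
    stratified baseline) and reports per-term hazard ratios with two-sided
    and one-sided (score-increases-hazard) Wald p-values.  Zero-variance
    covariates are rejected; non-convergence propagates with lifelines'
    diagnostics.
    """
    covariates = list(covariates or [])
    cols = ["time", "event", score_col] + covariates
    use = df[cols + ([strata] if strata else [])].copy()
    for c in [score_col] + covariates:
        if use[c].std(ddof=0) == 0:
            raise ValueError(f"covariate {c!r} has zero variance")
    cph = CoxPHFitter()
    cph.fit(use, duration_col="time", event_col="event", strata=strata)
    summ = cph.summary
    out = pd.DataFrame(
        {
            "term": summ.index,
            "coef": summ["coef"].to_numpy(),
            "hr": summ["exp(coef)"].to_numpy(),
            "se": summ["se(coef)"].to_numpy(),
            "p_two_sided": summ["p"].to_numpy(),
        }
    )
    out["p_one_sided"] = stats.norm.sf(out["coef"] / out["se"])
    return out.reset_index(drop=True)
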