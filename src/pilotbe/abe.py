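"""Average bioequivalence on ln(Cmax) and the GMR-centrality decision.

The crossover ANOVA is the fixed-effects linear model with sequence,
subject (nested within sequence), period and treatment.  Because subject
dummies absorb the sequence contrast, the fitted design matrix contains
intercept + period + treatment + subject indicators; treatment and
period estimates and the residual degrees of freedom (n - 2 for complete
balanced data) are identical to the nested parameterization.

Decisions:

* average bioequivalence (TOST): the 90% CI of the geometric LSM ratio
  exp(muT - muR) must lie within [80.00, 125.00]%;
* centrality: the GMR point estimate must lie within [90.00, 111.11]%.

The intra-subject CV is recovered from the ANOVA mean square error as
ISCV% = 100*sqrt(exp(s^2) - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .nca import nca_table
from .popsim import TrialDataset

__all__ = [
    "ABE_LIMITS",
    "CENTRALITY_LIMITS",
    "ABEResult",
    "fit_crossover_anova",
    "gmr_ci",
    "abe_decision",
    "centrality_decision",
    "iscv_from_mse",
    "analyze_abe",
]

ABE_LIMITS = (80.00, 125.00)  # % of the reference
CENTRALITY_LIMITS = (90.00, 111.11)  # % of the reference


@dataclass(frozen=True)
class ABEResult:
    gmr: float  # %
    ci_lower: float  # %
    ci_upper: float  # %
    mse: float  # log-scale residual variance
    iscv: float  # %
    df: int
    decision_abe: bool
    decision_centrality: bool


def _complete_crossover(table: pd.DataFrame) -> pd.DataFrame:
    """Drop subjects without both periods/treatments; error if < 3 remain."""
    ok = (
        table.groupby("subject_id")
        .filter(lambda g: len(g) == 2 and set(g["treatment"]) == {"test", "reference"})
    )
    dropped = table["subject_id"].nunique() - ok["subject_id"].nunique()
    if dropped:
        warnings.warn(f"excluded {dropped} subject(s) without both periods", stacklevel=3)
    if ok["subject_id"].nunique() < 3:
        raise ValueError("fewer than 3 complete subjects; ANOVA not estimable")
    return ok


def _fit_balanced(table: pd.DataFrame) -> tuple[float, float, float, int] | None:
    """Closed-form paired-contrast fit for balanced complete data.

    For each subject take d = y(period 1) - y(period 2); then
    lsm_diff = (mean d over test-first subjects - mean d over
    reference-first subjects) / 2 and the ANOVA MSE is half the pooled
    variance of d.  The grouping uses the observed treatment order, not
    the sequence label.  Returns None when the two groups are unequal.
    """
    first = (
        table[table["period"] == 1].set_index("subject_id")["treatment"] == "test"
    )
    wide = table.pivot_table(index="subject_id", columns="period", values="y")
    if wide.shape[1] != 2 or wide.isna().any().any():
        return None
    d = wide[1] - wide[2]
    d_tr, d_rt = d[first.reindex(d.index)], d[~first.reindex(d.index)]
    n1, n2 = len(d_tr), len(d_rt)
    if n1 != n2 or n1 < 2:
        return None
    lsm_diff = (d_tr.mean() - d_rt.mean()) / 2.0
    df = n1 + n2 - 2
    pooled = ((d_tr - d_tr.mean()) ** 2).sum() + ((d_rt - d_rt.mean()) ** 2).sum()
    s2_d = pooled / df
    mse = s2_d / 2.0
    se_diff = np.sqrt(s2_d / 4.0 * (1.0 / n1 + 1.0 / n2))
    return float(lsm_diff), float(se_diff), float(mse), int(df)


def fit_crossover_anova(
    nca_tab: pd.DataFrame, response: str = "cmax"
) -> tuple[float, float, float, int]:
    """Fit the crossover ANOVA on the ln-transformed response.

    Parameters
    ----------
    nca_tab
        One row per subject x period with columns subject_id, sequence,
        period, treatment and the response column.

    Returns
    -------
    (lsm_diff, se_diff, mse, df)
        Test-minus-reference LSM difference on the log scale, its
        standard error, the residual mean square and residual df.
    """
    table = nca_tab.copy()
    if (table[response] <= 0).any():
        raise ValueError(f"{response} must be positive for the ln transform")
    table["y"] = np.log(table[response].to_numpy(dtype=float))
    table = _complete_crossover(table)

    closed = _fit_balanced(table)
    if closed is not None:
        return closed

    fit = smf.ols(
        "y ~ C(period) + C(treatment, Treatment('reference')) + C(subject_id)",
        data=table,
    ).fit()
    term = "C(treatment, Treatment('reference'))[T.test]"
    return (
        float(fit.params[term]),
        float(fit.bse[term]),
        float(fit.mse_resid),
        int(fit.df_resid),
    )


def gmr_ci(
    lsm_diff: float, se_diff: float, df: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Point estimate and two-sided 100*(1-2*alpha)% CI of the GMR, in %."""
    if df < 1:
        raise ValueError("df must be >= 1")
    gmr = float(np.exp(lsm_diff) * 100.0)
    if se_diff == 0.0:
        return gmr, gmr, gmr
    tq = stats.t.ppf(1.0 - alpha, df)
    lo = float(np.exp(lsm_diff - tq * se_diff) * 100.0)
    hi = float(np.exp(lsm_diff + tq * se_diff) * 100.0)
    return gmr, lo, hi


def abe_decision(ci_lower: float, ci_upper: float) -> bool:
    """True iff the CI lies within the regulatory 80.00-125.00% interval."""
    return ci_lower >= ABE_LIMITS[0] and ci_upper <= ABE_LIMITS[1]


def centrality_decision(gmr: float) -> bool:
    """True iff the GMR point estimate lies within 90.00-111.11%."""
    if gmr <= 0:
        raise ValueError("gmr must be > 0")
    return CENTRALITY_LIMITS[0] <= gmr <= CENTRALITY_LIMITS[1]


def iscv_from_mse(mse: float) -> float:
    """Intra-subject CV%, 100*sqrt(exp(s^2) - 1)."""
    if mse < 0:
        raise ValueError("mse must be >= 0")
    return float(100.0 * np.sqrt(np.expm1(mse)))


def analyze_abe(
    trial: TrialDataset | pd.DataFrame,
    alpha: float = 0.05,
    response: str = "cmax",
) -> ABEResult:
    """Full average-bioequivalence analysis of one trial.

    Accepts a raw trial (NCA is computed internally) or a precomputed NCA
    table.
    """
    if isinstance(trial, TrialDataset):
        tab = nca_table(trial)
    elif "cmax" in trial.columns:
        tab = trial
    else:
        tab = nca_table(trial)
    lsm_diff, se_diff, mse, df = fit_crossover_anova(tab, response=response)
    gmr, lo, hi = gmr_ci(lsm_diff, se_diff, df, alpha=alpha)
    return ABEResult(
        gmr=gmr,
        ci_lower=lo,
        ci_upper=hi,
        mse=mse,
        iscv=iscv_from_mse(mse),
        df=df,
        decision_abe=abe_decision(lo, hi),
        decision_centrality=centrality_decision(gmr),
    )
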