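"""Non-compartmental summaries of concentration-time profiles.

Cmax / tmax are read directly off the observed samples; the area under
the curve runs from pre-dose to the last sampling time using the
linear-up / log-down trapezoidal rule (a pure linear rule is available
behind a switch).  No extrapolation to infinity is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .popsim import TrialDataset

__all__ = ["NCAResult", "cmax_tmax", "auc_last", "nca_table"]


@dataclass(frozen=True)
class NCAResult:
    subject_id: int
    period: int
    treatment: str
    cmax: float  # ug/L
    tmax: float  # h
    auc_last: float  # ug*h/L


def cmax_tmax(times: Sequence[float], concentrations: Sequence[float]) -> tuple[float, float]:
    """Maximum observed concentration and its (earliest) time."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.any(c > 0):
        raise ValueError("all-zero profile has no quantifiable peak")
    idx = int(np.argmax(c))  # argmax returns the first maximum: earliest-time tie-break
    return float(c[idx]), float(t[idx])


def auc_last(
    times: Sequence[float],
    concentrations: Sequence[float],
    method: str = "linlog",
) -> float:
    """AUC from pre-dose to the last sampling time (ug*h/L).

    ``linlog`` uses the linear trapezoid on rising or zero-bounded
    segments and the logarithmic trapezoid ``(C1-C2)*dt/ln(C1/C2)`` on
    strictly declining positive segments; ``linear`` uses the linear
    trapezoid everywhere.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if method not in ("linlog", "linear"):
        raise ValueError("method must be 'linlog' or 'linear'")

    c1, c2 = c[:-1], c[1:]
    dt = np.diff(t)
    linear = (c1 + c2) / 2.0 * dt
    if method == "linear":
        return float(linear.sum())
    down = (c1 > c2) & (c2 > 0)
    seg = linear.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = (c1 - c2) * dt / np.log(c1 / c2)
    seg[down] = log_seg[down]
    return float(seg.sum())


def nca_table(trial: TrialDataset | pd.DataFrame, auc_method: str = "linlog") -> pd.DataFrame:
    """Per subject x period NCA summary of a crossover trial.

    Returns one row per profile with columns subject_id, sequence,
    period, treatment, cmax, tmax, auc_last.
    """
    data = trial.data if isinstance(trial, TrialDataset) else trial
    rows = []
    for (subj, period), grp in data.groupby(["subject_id", "period"], sort=True):
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy()
        c = grp["conc_ug_L"].to_numpy()
        cmax, tmax = cmax_tmax(t, c)
        rows.append(
            {
                "subject_id": subj,
                "sequence": grp["sequence"].iloc[0],
                "period": period,
                "treatment": grp["treatment"].iloc[0],
                "cmax": cmax,
                "tmax": tmax,
                "auc_last": auc_last(t, c, method=auc_method),
            }
        )
    return pd.DataFrame(rows)
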