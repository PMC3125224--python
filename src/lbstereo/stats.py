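"""Group statistics layer: gated two-group tests, correlation, report tables.

Group comparisons follow the two-stage convention common in small-sample
morphometry: an unpaired two-sided t-test when both groups are compatible
with a Gaussian (Shapiro-Wilk gate at alpha = 0.10 per group), otherwise an
exact two-sided Mann-Whitney U test (mid-ranks for ties). Means, SEM and
t-based 95% confidence intervals are always reported. Note that at n = 5 per
group the normality gate has very little power; this mirrors the practical
weakness of any "Gaussian approximation present" judgement on 5 animals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "RegressionResult", "compare_groups",
           "pearson_regression", "report_tables", "SHAPIRO_ALPHA"]

log = logging.getLogger(__name__)

SHAPIRO_ALPHA = 0.10


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    n_a: int
    n_b: int
    test_used: Literal["t", "U"]
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def _summary(x: np.ndarray):
    n = len(x)
    mean = float(np.mean(x))
    sem = float(np.std(x, ddof=1) / np.sqrt(n))
    tq = sps.t.ppf(0.975, n - 1)
    return mean, sem, (mean - tq * sem, mean + tq * sem)


def _gaussian_gate(x: np.ndarray) -> bool:
    if np.ptp(x) == 0.0:
        return False  # degenerate sample, Shapiro undefined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue >= SHAPIRO_ALPHA


def compare_groups(x: Sequence[float], y: Sequence[float], alpha: float = 0.05,
                   variable: str = "") -> GroupComparison:
    """Two-group comparison with the Gaussian gate.

    Both groups need n >= 2 finite values. Two identical constant groups get
    the conventional p = 1 (logged); the significance threshold ``alpha`` is
    carried by the caller, not applied here.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("group values must be finite")
    mean_a, sem_a, ci_a = _summary(x)
    mean_b, sem_b, ci_b = _summary(y)
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        log.info("compare_groups(%s): both groups constant and equal; p = 1", variable)
        test, p = "t", 1.0
    elif _gaussian_gate(x) and _gaussian_gate(y):
        test = "t"
        p = float(sps.ttest_ind(x, y, equal_var=True).pvalue)
    else:
        test = "U"
        method = "exact" if max(len(x), len(y)) <= 8 else "auto"
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    return GroupComparison(
        variable=variable,
        mean_a=mean_a, mean_b=mean_b,
        sem_a=sem_a, sem_b=sem_b,
        ci_a=ci_a, ci_b=ci_b,
        n_a=len(x), n_b=len(y),
        test_used=test, p_value=p,
    )


def pearson_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Pearson correlation followed by least-squares linear regression.

    ``r = cov(x, y) / (s_x s_y)``; the two-sided p-value comes from
    ``t = r sqrt((n - 2) / (1 - r^2))`` with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(x),
    )


_REPORT_VARIABLES = [
    "V_lung", "N_AE2_lung", "vbar_AE2", "N_Lb_AE2", "V_Lb_AE2", "V_Lb_lung",
    "vbar_Lb", "S_lumen_AE2", "S_cell_AE2", "S_Lb_AE2",
]


def report_tables(per_lung: pd.DataFrame, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Figure-style tables from per-lung absolute estimates.

    ``per_lung`` needs columns ``group`` (control/IR), ``lung`` and the
    estimate columns. Returns a dict of DataFrames: one long table with every
    individual value plus group summary rows, a comparison table (one row per
    variable with the gated test), the membrane-balance table, and the
    regression of S(Lb, AE2) on S(lumen, AE2).
    """
    from .stereology import membrane_balance

    groups = list(dict.fromkeys(per_lung["group"]))
    if len(groups) != 2:
        raise ValueError("report_tables expects exactly two groups")
    ga, gb = groups
    variables = [v for v in _REPORT_VARIABLES if v in per_lung.columns]

    rows = []
    for var in variables:
        for _, rec in per_lung.iterrows():
            rows.append({"variable": var, "group": rec["group"], "lung": rec["lung"],
                         "kind": "lung", "value": rec[var]})
        for g in groups:
            vals = per_lung.loc[per_lung["group"] == g, var].to_numpy(dtype=float)
            mean, sem, _ = _summary(vals)
            rows.append({"variable": var, "group": g, "lung": "", "kind": "mean",
                         "value": mean})
            rows.append({"variable": var, "group": g, "lung": "", "kind": "sem",
                         "value": sem})
    individual = pd.DataFrame(rows)

    comp_rows = []
    for var in variables:
        a = per_lung.loc[per_lung["group"] == ga, var].to_numpy(dtype=float)
        b = per_lung.loc[per_lung["group"] == gb, var].to_numpy(dtype=float)
        c = compare_groups(a, b, alpha=alpha, variable=var)
        comp_rows.append({
            "variable": var,
            f"mean_{ga}": c.mean_a, f"sem_{ga}": c.sem_a,
            f"ci_lo_{ga}": c.ci_a[0], f"ci_hi_{ga}": c.ci_a[1],
            f"mean_{gb}": c.mean_b, f"sem_{gb}": c.sem_b,
            f"ci_lo_{gb}": c.ci_b[0], f"ci_hi_{gb}": c.ci_b[1],
            "test": c.test_used, "p_value": c.p_value,
            "significant": c.p_value < alpha,
        })
    comparisons = pd.DataFrame(comp_rows)

    means = per_lung.groupby("group", sort=False)[["S_lumen_AE2", "S_Lb_AE2"]].mean()
    mb = membrane_balance(means.loc[ga].to_dict(), means.loc[gb].to_dict())
    balance = pd.DataFrame(
        [
            {"group": ga, "S_lumen_AE2": mb.S_lumen_control, "S_Lb_AE2": mb.S_Lb_control,
             "sum": mb.sum_control},
            {"group": gb, "S_lumen_AE2": mb.S_lumen_ir, "S_Lb_AE2": mb.S_Lb_ir,
             "sum": mb.sum_ir},
            {"group": f"shift ({ga}->{gb})", "S_lumen_AE2": mb.delta_S_lumen,
             "S_Lb_AE2": mb.delta_S_Lb, "sum": np.nan},
        ]
    )

    reg = pearson_regression(per_lung["S_lumen_AE2"], per_lung["S_Lb_AE2"])
    regression = pd.DataFrame(
        [{"x": "S_lumen_AE2", "y": "S_Lb_AE2", "slope": reg.slope,
          "intercept": reg.intercept, "r": reg.r, "p_value": reg.p_value, "n": reg.n}]
    )
    return {
        "individual": individual,
        "comparisons": comparisons,
        "membrane_balance": balance,
        "regression": regression,
    }
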