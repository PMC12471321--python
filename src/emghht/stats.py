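"""One-way repeated-measures ANOVA with LSD post hoc comparisons.

For n subjects measured under k conditions (trials averaged within
subject x condition first), the classical within-subject decomposition
is

    SS_total = SS_condition + SS_subject + SS_error,

with df_condition = k - 1 and df_error = (k - 1)(n - 1);
F = MS_condition / MS_error is referred to an F distribution
(sphericity assumed; no correction applied).  Post hoc pairwise
comparisons use Fisher's least significant difference:

    t = (mean_a - mean_b) / sqrt(2 * MS_error / n),  df = df_error,

two-sided, with no multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "RMAnovaResult",
    "PairwiseResult",
    "rm_anova",
    "lsd_pairwise",
    "condition_stats_table",
]

#: SS_error below this fraction of SS_total is treated as exactly zero
#: (perfectly additive data), which makes F infinite.
_DEGENERATE_RTOL = 1e-10


@dataclass(frozen=True)
class RMAnovaResult:
    """Repeated-measures ANOVA summary for one feature."""

    F: float
    df_condition: int
    df_error: int
    p: float
    grand_mean: float
    condition_means: np.ndarray
    ms_error: float
    partial_eta_sq: float
    degenerate: bool = False


@dataclass(frozen=True)
class PairwiseResult:
    """One LSD pairwise comparison (unadjusted)."""

    pair: tuple[int, int]
    mean_difference: float
    t: float
    p: float
    degenerate: bool = False


def _validate_matrix(table: np.ndarray) -> np.ndarray:
    arr = np.asarray(table, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected an n_subjects x k_conditions matrix")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 conditions, got {n}x{k}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("incomplete design: matrix contains missing/non-finite cells")
    return arr


def rm_anova(table: np.ndarray) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on an n x k subject-by-condition matrix."""
    arr = _validate_matrix(table)
    n, k = arr.shape
    grand = arr.mean()
    subj_means = arr.mean(axis=1)
    cond_means = arr.mean(axis=0)
    ss_total = float(((arr - grand) ** 2).sum())
    ss_subject = float(k * ((subj_means - grand) ** 2).sum())
    ss_condition = float(n * ((cond_means - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subject - ss_condition, 0.0)
    df_c, df_e = k - 1, (k - 1) * (n - 1)
    ms_c = ss_condition / df_c
    ms_e = ss_error / df_e
    degenerate = ss_error <= _DEGENERATE_RTOL * max(ss_total, 1e-300)
    if degenerate:
        if ss_condition <= _DEGENERATE_RTOL * max(ss_total, 1e-300):
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
    else:
        F = ms_c / ms_e
        p = float(sst.f.sf(F, df_c, df_e))
    eta = ss_condition / (ss_condition + ss_error) if (ss_condition + ss_error) > 0 else 0.0
    return RMAnovaResult(
        F=F, df_condition=df_c, df_error=df_e, p=p, grand_mean=float(grand),
        condition_means=cond_means, ms_error=ms_e, partial_eta_sq=float(eta),
        degenerate=degenerate,
    )


def lsd_pairwise(table: np.ndarray, anova: RMAnovaResult) -> list[PairwiseResult]:
    """Fisher LSD comparisons for every condition pair.

    Uses the pooled MS_error and its degrees of freedom from the ANOVA
    on the same matrix; p values are two-sided and unadjusted.
    """
    arr = _validate_matrix(table)
    n, k = arr.shape
    if len(anova.condition_means) != k:
        raise ValueError("ANOVA result does not match the table's condition count")
    out: list[PairwiseResult] = []
    se = np.sqrt(2.0 * anova.ms_error / n)
    for a, b in combinations(range(k), 2):
        diff = float(anova.condition_means[a] - anova.condition_means[b])
        if anova.degenerate or se == 0.0:
            t = float("inf") * np.sign(diff) if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
            out.append(PairwiseResult(pair=(a, b), mean_difference=diff, t=t, p=p,
                                      degenerate=True))
            continue
        t = diff / se
        p = float(2.0 * sst.t.sf(abs(t), anova.df_error))
        out.append(PairwiseResult(pair=(a, b), mean_difference=diff, t=t, p=p))
    return out


def condition_stats_table(
    features: pd.DataFrame,
    value_col: str,
    by: tuple[str, ...] = ("muscle", "window"),
    subject_col: str = "subject",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """ANOVA + LSD over a tidy feature table, one row per feature group.

    Trials are averaged within subject x condition before testing.
    Groups with incomplete subject x condition coverage are skipped.
    """
    rows = []
    conditions = sorted(features[condition_col].unique())
    for keys, grp in features.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        cell = grp.pivot_table(index=subject_col, columns=condition_col,
                               values=value_col, aggfunc="mean")
        cell = cell.reindex(columns=conditions)
        cell = cell.dropna()
        if len(cell) < 2:
            continue
        res = rm_anova(cell.to_numpy())
        row = dict(zip(by, keys))
        row.update(feature=value_col, F=res.F, df1=res.df_condition, df2=res.df_error,
                   p=res.p, partial_eta_sq=res.partial_eta_sq)
        for pw in lsd_pairwise(cell.to_numpy(), res):
            label = f"p_{conditions[pw.pair[0]]}_vs_{conditions[pw.pair[1]]}"
            row[label] = pw.p
        for c, m in zip(conditions, res.condition_means):
            row[f"mean_{c}"] = m
        rows.append(row)
    return pd.DataFrame(rows)
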