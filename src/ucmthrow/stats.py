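"""Study-level statistics: one-way repeated-measures ANOVA with the
Greenhouse-Geisser sphericity correction.

The study design has one within-subject factor (target distance, 3 levels)
and one dependent variable per analysis (mean release angle, speed or
height per participant per distance).  Sphericity is not tested before
correcting: the correction is always applied and the corrected p-value
reported, matching the study's reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AnovaResult", "rm_anova_gg", "condition_means", "gg_epsilon"]


@dataclass
class AnovaResult:
    """One-way within-subjects ANOVA with Greenhouse-Geisser correction."""

    F: float
    df1: float  # uncorrected k - 1
    df2: float  # uncorrected (k - 1)(s - 1)
    epsilon: float  # GG sphericity estimate, in (1/(k-1), 1]
    df1_gg: float
    df2_gg: float
    p_gg: float
    partial_eta_sq: float

    def __post_init__(self):
        assert self.F >= 0 and 0 < self.epsilon <= 1


def _as_matrix(table) -> np.ndarray:
    X = table.to_numpy(float) if isinstance(table, pd.DataFrame) else np.asarray(table, float)
    if X.ndim != 2:
        raise ValueError("table must be participants x conditions")
    s, k = X.shape
    if s < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    if not np.all(np.isfinite(X)):
        raise ValueError("table has missing cells")
    return X


def gg_epsilon(table) -> float:
    """Greenhouse-Geisser sphericity estimate from the doubly-centred
    covariance matrix of the condition scores.

    epsilon_hat = (sum of eigenvalues)^2 / ((k-1) * sum of squared
    eigenvalues) = tr(S)^2 / ((k-1) * sum S_ij^2), clipped to its
    theoretical range [1/(k-1), 1].
    """
    X = _as_matrix(table)
    k = X.shape[1]
    S = np.cov(X, rowvar=False)
    centred = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    denom = (k - 1) * np.sum(centred**2)
    if denom <= 0:  # no between-condition covariance structure at all
        return 1.0
    eps = np.trace(centred) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(table) -> AnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``table`` is a participants x conditions matrix (or DataFrame) of one
    dependent variable.  F = MS_condition / MS_(condition x subject);
    corrected degrees of freedom are epsilon * (k-1) and
    epsilon * (k-1)(s-1); partial eta^2 = SS_cond / (SS_cond + SS_error).
    """
    X = _as_matrix(table)
    s, k = X.shape
    grand = X.mean()
    cond_means_ = X.mean(axis=0)
    subj_means = X.mean(axis=1)
    ss_cond = s * np.sum((cond_means_ - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1.0
    df2 = (k - 1.0) * (s - 1.0)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else 0.0
    eps = gg_epsilon(X)
    df1_gg = eps * df1
    df2_gg = eps * df2
    p_gg = float(sps.f.sf(F, df1_gg, df2_gg)) if F > 0 else 1.0
    peta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return AnovaResult(
        F=float(max(F, 0.0)),
        df1=df1,
        df2=df2,
        epsilon=eps,
        df1_gg=float(df1_gg),
        df2_gg=float(df2_gg),
        p_gg=p_gg,
        partial_eta_sq=float(peta),
    )


def condition_means(
    release_table: pd.DataFrame,
    value: str,
    participant: str = "participant",
    condition: str = "distance",
) -> pd.DataFrame:
    """Participant x condition table of per-cell trial means.

    Each cell is the arithmetic mean of that participant's trials at that
    condition; raises if any cell is empty.
    """
    pivot = release_table.pivot_table(
        index=participant, columns=condition, values=value, aggfunc="mean"
    )
    if pivot.isna().any().any():
        raise ValueError("missing participant x condition cells")
    return pivot
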