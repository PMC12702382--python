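"""Group-comparison statistics and propensity-score matching.

Covers the statistical toolkit used across the cohort analyses: Welch's
heteroscedasticity-robust ANOVA (chosen when Levene's test rejects equal
variances), Tukey HSD post-hoc pairwise comparisons, simple linear
regression for brain-measure vs clinical-variable associations, and 1:1
greedy propensity-score matching to build covariate-balanced groups from
an oversized control pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "StatReport",
    "welch_anova",
    "levene",
    "tukey_hsd",
    "linear_regression",
    "psm_match",
    "MatchResult",
    "validate_cohort",
    "GROUPS",
]

GROUPS = ("FT", "PT", "PP")

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "gestational_age_weeks",
    "scan_age_weeks",
    "sex",
    "birth_weight_kg",
    "radiology_score",
]


@dataclass
class StatReport:
    """Result of one statistical test."""

    test: str
    statistic: float
    df: Tuple[float, ...]
    p: float
    extra: dict = field(default_factory=dict)


def _check_groups(groups: Sequence[np.ndarray], min_per_group: int = 2):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < min_per_group:
            raise ValueError(f"group {i} has fewer than {min_per_group} values")
        if np.var(g, ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance")
    return arrays


def welch_anova(groups: Sequence[np.ndarray]) -> StatReport:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    Group means are weighted by n_i / s_i^2; the denominator degrees of
    freedom follow the Welch-Satterthwaite approximation.  With two
    groups, F equals the square of Welch's t.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    n = np.array([g.size for g in arrays], dtype=float)
    m = np.array([g.mean() for g in arrays])
    v = np.array([g.var(ddof=1) for g in arrays])
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = 3.0 * ((1 - w / W) ** 2 / (n - 1)).sum() / (k**2 - 1)
    F = num / (1 + 2 * (k - 2) / 3 * lam)
    df2 = 1.0 / lam
    p = float(sps.f.sf(F, k - 1, df2))
    return StatReport("welch_anova", float(F), (k - 1, float(df2)), p)


def levene(groups: Sequence[np.ndarray], center: str = "mean") -> StatReport:
    """Levene's test for equality of variances (classical mean-centered
    variant by default; center="median" gives Brown-Forsythe)."""
    arrays = _check_groups(groups)
    stat, p = sps.levene(*arrays, center=center)
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    return StatReport("levene", float(stat), (k - 1, float(n_total - k)), float(p))


def tukey_hsd(groups: Sequence[np.ndarray]) -> List[StatReport]:
    """Tukey's HSD pairwise comparisons (Tukey-Kramer for unequal n).

    Each pair gets a studentized-range statistic
    q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) with the pooled
    within-group variance, and a p-value from the studentized range
    distribution with k groups and N - k error df.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    n = np.array([g.size for g in arrays], dtype=float)
    m = np.array([g.mean() for g in arrays])
    v = np.array([g.var(ddof=1) for g in arrays])
    df_err = n.sum() - k
    msw = ((n - 1) * v).sum() / df_err
    reports = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
            q = abs(m[i] - m[j]) / se
            p = float(sps.studentized_range.sf(q, k, df_err))
            reports.append(
                StatReport(
                    "tukey_hsd",
                    float(q),
                    (float(k), float(df_err)),
                    min(p, 1.0),
                    extra={"pair": (i, j), "mean_diff": float(m[i] - m[j])},
                )
            )
    return reports


def linear_regression(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float, float, float]:
    """Ordinary least squares of y on x.

    Returns (slope, intercept, Pearson r, two-sided p for zero slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must be equal-length samples, n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.pvalue),
    )


@dataclass
class MatchResult:
    """Pairs and covariate balance from 1:1 propensity matching."""

    pairs: List[Tuple[object, object]]  # (treated_id, control_id)
    propensity: pd.Series  # indexed by subject_id
    balance: pd.DataFrame  # SMD before/after per covariate


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the pooled-SD convention."""
    sd = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    if sd == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sd)


def psm_match(
    treated: pd.DataFrame,
    pool: pd.DataFrame,
    covariates: Sequence[str],
    id_column: str = "subject_id",
) -> MatchResult:
    """1:1 greedy nearest-neighbor propensity-score matching.

    A logistic regression of treated-vs-pool membership on the covariates
    yields each subject's propensity score; treated subjects are then
    processed in descending propensity order, each taking the unused pool
    subject with the nearest score (no caliper, without replacement).
    Categorical "sex" is encoded 0/1 automatically.  Returns the matched
    pairs and a standardized-mean-difference balance report.
    """
    if len(pool) < len(treated):
        raise ValueError("pool must be at least as large as treated")

    def design(df: pd.DataFrame) -> np.ndarray:
        cols = []
        for c in covariates:
            col = df[c]
            if col.dtype == object or str(col.dtype) == "category":
                col = (col == sorted(col.unique())[-1]).astype(float)
            cols.append(col.to_numpy(dtype=float))
        return np.column_stack(cols)

    x = np.vstack([design(treated), design(pool)])
    ylab = np.r_[np.ones(len(treated)), np.zeros(len(pool))]
    try:
        fit = sm.Logit(ylab, sm.add_constant(x)).fit(disp=0)
        if not np.isfinite(fit.params).all():
            raise ValueError("non-finite coefficients")
    except Exception as exc:  # perfect separation and friends
        raise ValueError(
            "propensity logistic regression failed (possibly perfect "
            "separation); reduce or rescale covariates"
        ) from exc
    ps = fit.predict(sm.add_constant(x))
    ps_t = ps[: len(treated)]
    ps_p = ps[len(treated):]

    order = np.argsort(-ps_t, kind="stable")
    available = np.ones(len(pool), dtype=bool)
    pool_ids = pool[id_column].to_numpy()
    treated_ids = treated[id_column].to_numpy()
    pairs = []
    chosen_pool_rows = []
    for ti in order:
        dist = np.abs(ps_p - ps_t[ti])
        dist[~available] = np.inf
        ci = int(np.argmin(dist))  # ties -> lowest pool row: deterministic
        available[ci] = False
        pairs.append((treated_ids[ti], pool_ids[ci]))
        chosen_pool_rows.append(ci)

    xt = design(treated)
    xp = design(pool)
    xm = xp[chosen_pool_rows]
    balance = pd.DataFrame(
        {
            "covariate": list(covariates),
            "smd_before": [_smd(xt[:, i], xp[:, i]) for i in range(len(covariates))],
            "smd_after": [_smd(xt[:, i], xm[:, i]) for i in range(len(covariates))],
        }
    )
    propensity = pd.Series(
        ps, index=np.r_[treated_ids, pool_ids], name="propensity"
    )
    return MatchResult(pairs=pairs, propensity=propensity, balance=balance)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort manifest against the group-definition rules.

    FT: GA >= 37 and scan PMA >= 37 (GA exactly 37 is assigned FT);
    PT: GA <= 37 and PMA >= 37; PP: GA <= 37 and PMA <= 37.  Included
    subjects must have radiology score <= 4.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    ga = table["gestational_age_weeks"].to_numpy(float)
    pma = table["scan_age_weeks"].to_numpy(float)
    grp = table["group"].to_numpy()
    ok = np.where(
        grp == "FT",
        (ga >= 37) & (pma >= 37),
        np.where(
            grp == "PT",
            (ga <= 37) & (pma >= 37),
            (ga <= 37) & (pma <= 37),
        ),
    )
    if not ok.all():
        bad = table.loc[~ok, "subject_id"].tolist()
        raise ValueError(f"group assignment inconsistent for subjects {bad}")
    if (table["radiology_score"] > 4).any():
        raise ValueError("cohort contains radiology score > 4 subjects")
    return table
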