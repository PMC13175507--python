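"""Group comparisons, correlations, proportion tests, and t-statistic maps.

The statistical layer mirrors standard practice for small-cohort EEG/behavior
studies: Kruskal-Wallis omnibus tests with hypothesis-driven rank-sum
post-hocs (40 Hz vs Light and 40 Hz vs Random only) under Benjamini-Hochberg
FDR control; Spearman rank correlations between band power (or connectivity)
and behavior with explicit comparison families; Pearson chi-squared tests on
2x2 proportion tables with Cramer's V as the effect size; and per-channel
unpaired t statistics for topographic difference maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_POSTHOC_PAIRS = (("40Hz", "Light"), ("40Hz", "Random"))


@dataclass
class GroupComparison:
    measure: str
    h_statistic: float
    df: int
    p_value: float
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class ProportionTest:
    table: np.ndarray
    chi2: float
    df: int
    p_value: float
    cramers_v: float


def fdr_bh(p_values, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted q values, rejection mask)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must be in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return qvals, reject


def ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney).

    Exact enumeration for small tie-free samples (both n < 10), otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (min(len(x), len(y)) < 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_posthoc(values_by_group: dict[str, np.ndarray],
                    pairs: tuple[tuple[str, str], ...] = DEFAULT_POSTHOC_PAIRS,
                    q_level: float = 0.05,
                    measure: str = "measure") -> GroupComparison:
    """Kruskal-Wallis omnibus plus FDR-corrected rank-sum post-hocs.

    Post-hoc tests run only for the declared hypothesis-driven pairs, and
    Benjamini-Hochberg correction is applied over exactly that family.
    """
    groups = {g: np.asarray(v, float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 3 for v in groups.values()):
        raise ValueError("need at least 3 subjects per group")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):   # all tied: no evidence of any difference
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups.values())
    rows = []
    for g1, g2 in pairs:
        stat, pr = ranksum(groups[g1], groups[g2])
        rows.append({"group_1": g1, "group_2": g2, "statistic": stat, "p": pr})
    posthoc = pd.DataFrame(rows)
    if len(posthoc):
        q, rej = fdr_bh(posthoc["p"], q_level)
        posthoc["q"] = q
        posthoc["significant"] = rej
    return GroupComparison(measure=measure, h_statistic=float(h),
                           df=len(groups) - 1, p_value=float(p),
                           posthoc=posthoc)


def spearman_behavior(features: pd.DataFrame, behavior: pd.Series,
                      family: int | None = None,
                      q_level: float = 0.05) -> pd.DataFrame:
    """Spearman rho between each feature column and a behavior scalar.

    FDR correction runs within the declared comparison family; ``family``
    records the family size when it differs from the number of columns
    actually tested (constant features are flagged and excluded from the
    family rather than silently reported as rho = 0).
    """
    if len(features) != len(behavior):
        raise ValueError("features and behavior must cover the same subjects")
    if len(features) < 5:
        raise ValueError("need at least 5 subjects")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(float)
        y = np.asarray(behavior, float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 5 or np.all(x[ok] == x[ok][0]):
            rows.append({"feature": col, "rho": np.nan, "p": np.nan,
                         "n": int(ok.sum()), "constant": True})
            continue
        rho, p = sps.spearmanr(x[ok], y[ok])
        rows.append({"feature": col, "rho": float(rho), "p": float(p),
                     "n": int(ok.sum()), "constant": False})
    out = pd.DataFrame(rows)
    tested = ~out["constant"]
    out["q"] = np.nan
    out["significant"] = False
    if tested.any():
        q, rej = fdr_bh(out.loc[tested, "p"], q_level)
        out.loc[tested, "q"] = q
        out.loc[tested, "significant"] = rej
    out["family_size"] = family if family is not None else int(tested.sum())
    return out


def proportion_test(counts) -> ProportionTest:
    """Pearson chi-squared (no continuity correction) with Cramer's V.

    ``counts`` is an r x c contingency table;
    V = sqrt(chi2 / (n * (min(r, c) - 1))).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("counts must be a non-negative 2-D table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    n = table.sum()
    k = min(table.shape) - 1
    v = float(np.sqrt(chi2 / (n * k))) if k > 0 else 0.0
    return ProportionTest(table=table, chi2=float(chi2), df=int(df),
                          p_value=float(p), cramers_v=v)


def two_by_two_counts(above_1: int, total_1: int,
                      above_2: int, total_2: int) -> np.ndarray:
    """Group x (above / below threshold) table for proportion tests."""
    return np.array([[above_1, total_1 - above_1],
                     [above_2, total_2 - above_2]], dtype=float)


def tstat_map(group1: np.ndarray, group2: np.ndarray,
              ch_names: list[str]) -> pd.DataFrame:
    """Unpaired two-sided t statistic per channel, sign = group1 - group2.

    Inputs are (n_subjects, n_channels) arrays; channels with zero pooled
    variance yield NaN and are flagged rather than silently zeroed.  Values
    are intended for external topographic rendering.
    """
    g1 = np.atleast_2d(np.asarray(group1, float))
    g2 = np.atleast_2d(np.asarray(group2, float))
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(g1, g2, axis=0)
    return pd.DataFrame({"channel": ch_names, "t": t, "p": p,
                         "degenerate": ~np.isfinite(t)})
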