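"""Cohort comparison of extracted hemodynamic features.

For each scalar feature, group differences are tested with a one-covariate
ANCOVA (value ~ group + age, homogeneous slopes) so reported markers are
age-independent; effect strength is the partial eta-squared
SS_group / (SS_group + SS_residual). When the group factor is significant at
alpha = 0.05, a Tukey-Kramer post hoc on the covariate-adjusted group means
(using the ANCOVA residual mean square) is run, Cohen's d on the raw values
quantifies pairwise effect sizes, and Benjamini-Hochberg correction is
applied across the pairwise p-values of that feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    adjusted_mean_diff: float
    tukey_p: float
    bh_p: float
    cohens_d: float


@dataclass
class AncovaResult:
    feature: str
    f_stat: float
    p_value: float
    partial_eta_sq: float
    df_group: int
    df_resid: int
    mse: float
    gate_passed: bool
    posthoc: list[PairwiseResult] = field(default_factory=list)


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"group", "age", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    df = df.dropna(subset=["group", "age", "value"])
    if not np.all(np.isfinite(df["age"])) or \
            not np.all(np.isfinite(df["value"])):
        raise ValueError("ages and values must be finite")
    counts = df.groupby("group").size()
    if len(counts) < 2 or (counts < 3).any():
        raise ValueError("need >= 2 groups with >= 3 subjects each")
    return df


def _design(df: pd.DataFrame):
    groups = sorted(df["group"].unique())
    n = len(df)
    dummies = np.zeros((n, len(groups)))
    for gi, g in enumerate(groups):
        dummies[:, gi] = (df["group"] == g).to_numpy()
    age_c = df["age"].to_numpy(dtype=float)
    age_c = age_c - age_c.mean()
    return groups, dummies, age_c


def _rss(design: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rank = np.linalg.matrix_rank(design)
    return float(resid @ resid), rank


def ancova(table: pd.DataFrame, feature: str | None = None,
           alpha: float = 0.05, posthoc: bool = True) -> AncovaResult:
    """Age-adjusted group comparison of one feature.

    ``table`` has columns (group, age, value); if it has a ``feature``
    column the requested feature is selected first. The F-test compares
    value ~ group + age against value ~ age; post hoc runs only when
    p < alpha.
    """
    df = table
    if feature is not None and "feature" in df.columns:
        df = df[df["feature"] == feature]
    df = _validate_table(df)
    y = df["value"].to_numpy(dtype=float)
    groups, dummies, age_c = _design(df)

    full = np.column_stack([dummies, age_c])
    reduced = np.column_stack([np.ones(len(y)), age_c])
    rss_full, rank_full = _rss(full, y)
    rss_red, _ = _rss(reduced, y)
    df_group = len(groups) - 1
    df_resid = len(y) - rank_full
    if df_resid <= 0 or rank_full < len(groups) + 1:
        raise ValueError("singular ANCOVA design (collinear group/age)")
    ss_group = rss_red - rss_full
    mse = rss_full / df_resid
    f_stat = (ss_group / df_group) / mse
    p = float(sps.f.sf(f_stat, df_group, df_resid))
    eta = ss_group / (ss_group + rss_full) if (ss_group + rss_full) > 0 else 0.0

    result = AncovaResult(feature=feature or "value", f_stat=float(f_stat),
                          p_value=p, partial_eta_sq=float(eta),
                          df_group=df_group, df_resid=df_resid,
                          mse=float(mse), gate_passed=p < alpha)
    if result.gate_passed and posthoc:
        result.posthoc = tukey_cohen(df, mse=mse, df_resid=df_resid)
    return result


def tukey_cohen(table: pd.DataFrame, mse: float | None = None,
                df_resid: int | None = None) -> list[PairwiseResult]:
    """Tukey-Kramer pairwise tests on covariate-adjusted means + Cohen's d.

    Adjusted group means are the group coefficients of the ANCOVA fit with
    the age covariate centered (i.e. means at the cohort mean age). Cohen's d
    uses raw values with the pooled standard deviation; BH correction is
    applied across the pairwise Tukey p-values.
    """
    df = _validate_table(table)
    y = df["value"].to_numpy(dtype=float)
    groups, dummies, age_c = _design(df)
    if len(groups) < 2:
        raise ValueError("post hoc needs at least 2 groups")
    full = np.column_stack([dummies, age_c])
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    adj_means = beta[:len(groups)]
    if mse is None or df_resid is None:
        resid = y - full @ beta
        df_resid = len(y) - np.linalg.matrix_rank(full)
        mse = float(resid @ resid) / df_resid
    sizes = {g: int((df["group"] == g).sum()) for g in groups}
    k = len(groups)

    rows, pvals = [], []
    for ia in range(k):
        for ib in range(ia + 1, k):
            ga, gb = groups[ia], groups[ib]
            diff = adj_means[ia] - adj_means[ib]
            se = np.sqrt(mse / 2.0 * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
            q = abs(diff) / se
            p_t = float(sps.studentized_range.sf(q, k, df_resid))
            va = df.loc[df["group"] == ga, "value"].to_numpy()
            vb = df.loc[df["group"] == gb, "value"].to_numpy()
            sp2 = (((len(va) - 1) * va.var(ddof=1)
                    + (len(vb) - 1) * vb.var(ddof=1))
                   / (len(va) + len(vb) - 2))
            d = float((va.mean() - vb.mean()) / np.sqrt(sp2)) \
                if sp2 > 0 else 0.0
            rows.append(PairwiseResult(ga, gb, float(diff), p_t, np.nan, d))
            pvals.append(p_t)
    for row, p_adj in zip(rows, bh_adjust(pvals)):
        row.bh_p = float(p_adj)
    return rows


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving, capped at 1, with monotonicity enforced over the
    sorted sequence.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out
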