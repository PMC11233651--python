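"""Nonparametric group comparisons: Mann-Whitney U, FDR, rank-biserial r.

The comparison plan tests the percentage of whispered trials in the three
conditions that require whispering, and the remaining four parameters in the
Normal and Reduced feedback conditions — 11 two-sided tests, corrected
jointly with the Benjamini-Hochberg false discovery rate procedure.

The rank-biserial correlation is the difference between the proportions of
favorable and unfavorable cross-group pairs: r = 0.38 means favorable
evidence outweighs unfavorable by 69% to 31%. The sign convention here is
positive when controls exceed the PD group, so whispering ability and
rhythm consistency carry positive r and error rate / reaction time carry
negative r when the PD group is impaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import config


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    condition: str
    n_pd: int
    n_ctrl: int
    u_stat: float
    p_raw: float
    p_fdr: float
    r_rank_biserial: float
    mean_pd: float
    sd_pd: float
    mean_ctrl: float
    sd_ctrl: float


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is reported for sample ``a``.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, and the tie-corrected normal
    approximation otherwise. Two identical constant samples carry no
    evidence: U = n_a*n_b/2, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rank_biserial(
    a: Sequence[float], b: Sequence[float], direction: str = "b_greater"
) -> float:
    """Rank-biserial correlation by direct pair counting; ties contribute 0.

    With ``direction="b_greater"`` (default) a pair is favorable when the
    value from ``b`` exceeds the value from ``a``; r is (favorable -
    unfavorable) / (n_a * n_b) and lies in [-1, 1]. Swapping the samples
    (or the direction) flips the sign.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = b[None, :] - a[:, None]
    favorable = np.count_nonzero(diff > 0)
    unfavorable = np.count_nonzero(diff < 0)
    r = (favorable - unfavorable) / (a.size * b.size)
    if direction == "b_greater":
        return float(r)
    if direction == "a_greater":
        return float(-r)
    raise ValueError(f"unknown direction: {direction!r}")


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    table: pd.DataFrame,
    plan: Sequence[tuple[str, str]] = config.DEFAULT_COMPARISON_PLAN,
    alpha: float = config.ALPHA,
) -> pd.DataFrame:
    """Run the planned PD-vs-control comparisons on a cohort feature table.

    Each (parameter, condition) test compares the two groups' values with a
    two-sided Mann-Whitney test and a rank-biserial effect size; FDR
    adjustment spans all executed tests jointly. Participants missing a
    feature are dropped from that test only; a plan entry whose column is
    absent from the table is skipped. Returns one row per executed test
    with a ``significant`` flag at ``p_fdr < alpha``.
    """
    groups = set(table["group"])
    if not {"PD", "control"} <= groups:
        raise ValueError("table must contain both 'PD' and 'control' groups")
    results = []
    for param, cond in plan:
        col = config.feature_column(param, cond)
        if col not in table.columns:
            continue
        sub = table[["group", col]].dropna()
        a = sub.loc[sub["group"] == "PD", col].to_numpy()
        b = sub.loc[sub["group"] == "control", col].to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        u, p = mann_whitney_u(a, b)
        r = rank_biserial(a, b)
        results.append(
            ComparisonResult(
                parameter=param,
                condition=cond,
                n_pd=a.size,
                n_ctrl=b.size,
                u_stat=u,
                p_raw=p,
                p_fdr=np.nan,
                r_rank_biserial=r,
                mean_pd=float(np.mean(a)),
                sd_pd=float(np.std(a, ddof=1)) if a.size > 1 else 0.0,
                mean_ctrl=float(np.mean(b)),
                sd_ctrl=float(np.std(b, ddof=1)) if b.size > 1 else 0.0,
            )
        )
    if not results:
        raise ValueError("no executable tests in the plan")
    df = pd.DataFrame([vars(r) for r in results])
    df["p_fdr"] = fdr_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_fdr"] < alpha
    return df
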