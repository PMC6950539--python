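"""Nonparametric univariate statistics for the quantified panel.

Mann-Whitney U compares metabolite concentrations between two groups (exact
null distribution for small tie-free samples, tie-corrected normal
approximation otherwise); Spearman rank correlation relates two variables
(exact permutation p for n <= 9).  Significance follows the conventional
p < 0.05 with no multiplicity correction by default; a Benjamini-Hochberg
mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "mann_whitney", "spearman", "screen_metabolites"]

#: combined sample size at or below which the exact U distribution is used
EXACT_N_MAX = 16


@dataclass(frozen=True)
class TestResult:
    metabolite: str
    statistic: float
    p_value: float
    group_ns: tuple[int, int]
    method: str  # exact | normal_approx

    def __post_init__(self):
        if not 0 <= self.p_value <= 1 + 1e-12:
            raise ValueError("p-value outside [0, 1]")


def mann_whitney(x, y, alternative: str = "two-sided",
                 metabolite: str = "") -> TestResult:
    """Two-sample Mann-Whitney U test.

    Uses the exact permutation distribution when the combined sample size is
    <= 16 and the data carry no ties; otherwise the tie-corrected normal
    approximation (with continuity correction).  The path taken is recorded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = len(pooled) <= EXACT_N_MAX and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative=alternative,
        method="exact" if exact else "asymptotic",
    )
    return TestResult(
        metabolite=metabolite,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_ns=(len(x), len(y)),
        method="exact" if exact else "normal_approx",
    )


#: sample size at or below which the Spearman p-value is exact
SPEARMAN_EXACT_N_MAX = 9


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    For n <= 9 the two-sided p-value is exact (enumeration over all rank
    permutations); above that the t-approximation applies.  Constant input
    yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p_approx = stats.spearmanr(x, y)
    n = len(x)
    if n > SPEARMAN_EXACT_N_MAX:
        return float(rho), float(p_approx)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    rhos = (pc @ rxc) / np.sqrt((pc ** 2).sum(axis=1) * (rxc ** 2).sum())
    p_exact = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return float(rho), p_exact


def screen_metabolites(
    qt: pd.DataFrame,
    manifest: pd.DataFrame,
    group_field: str,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Mann-Whitney screen of every panel metabolite across a 2-group split.

    ``group_field`` must yield exactly two nonempty groups on the samples
    present in ``qt`` (missing values are dropped).  Returns one row per
    metabolite with U, p, the method used, and a significance flag at
    ``alpha``; optional Benjamini-Hochberg correction.
    """
    groups = manifest.set_index("sample_id")[group_field].reindex(qt.index)
    groups = groups[groups.notna()
                    & ~groups.isin(["missing", "not_applicable"])]
    levels = sorted(groups.unique(), key=str)
    if len(levels) != 2:
        raise ValueError(
            f"{group_field!r} yields {len(levels)} groups; need exactly 2"
        )
    ids_a = groups.index[groups == levels[0]]
    ids_b = groups.index[groups == levels[1]]
    rows = []
    for m in qt.columns:
        r = mann_whitney(qt.loc[ids_a, m], qt.loc[ids_b, m], metabolite=m)
        rows.append({
            "metabolite": m, "U": r.statistic, "p": r.p_value,
            "method": r.method, "n_a": r.group_ns[0], "n_b": r.group_ns[1],
        })
    out = pd.DataFrame(rows).set_index("metabolite")
    if correction == "bh":
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    elif correction is None:
        out["significant"] = out["p"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out.attrs["groups"] = {levels[0]: len(ids_a), levels[1]: len(ids_b)}
    return out
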