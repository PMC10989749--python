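"""Per-sample alpha diversity (Shannon, Gini-Simpson, bias-corrected
Chao1) and its association with discrete or numeric metadata."""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MetadataTable
from .profiling import TaxonomicProfile

__all__ = [
    "shannon",
    "simpson",
    "chao1",
    "alpha_diversity",
    "alpha_group_test",
    "alpha_numeric_regression",
    "AlphaResult",
]


@dataclass
class AlphaResult:
    index_name: str
    values: pd.Series  # sample -> index value
    tests: list[dict]  # one dict per metadata variable tested


def _check_relative(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    s = p.sum()
    if s == 0:
        return p
    if not math.isclose(s, 1.0, abs_tol=1e-6):
        raise ValueError(f"relative abundances must sum to 1, got {s}")
    return p


def shannon(p) -> float | None:
    """Shannon entropy H = -sum p_i ln p_i (natural log); None if empty."""
    p = _check_relative(p)
    if p.sum() == 0:
        return None
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def simpson(p) -> float | None:
    """Gini-Simpson index D = 1 - sum p_i^2; None if empty."""
    p = _check_relative(p)
    if p.sum() == 0:
        return None
    return float(1.0 - (p**2).sum())


def chao1(counts) -> float | None:
    """Bias-corrected Chao1: S_obs + F1(F1-1)/(2(F2+1)).

    Requires integer sampling counts — relative abundances are rejected
    because the estimator reasons about singletons and doubletons.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(c, np.rint(c), atol=1e-9):
        raise TypeError("chao1 requires integer counts, not relative abundances")
    c = np.rint(c).astype(int)
    s_obs = int((c > 0).sum())
    if s_obs == 0:
        return None
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def alpha_diversity(profiles: list[TaxonomicProfile]) -> pd.DataFrame:
    """Sample x {shannon, simpson, chao1} table.

    Shannon/Simpson use copy-number-corrected relative abundances;
    Chao1 uses raw classified-read counts (tie splits rounded to the
    nearest integer), since its estimator assumes sampling counts.
    """
    rows = {}
    for prof in profiles:
        if prof.empty:
            rows[prof.sample_id] = [np.nan, np.nan, np.nan]
            continue
        p = np.array(list(prof.normalized.values()))
        c = np.rint(np.array(list(prof.counts.values())))
        rows[prof.sample_id] = [shannon(p), simpson(p), chao1(c)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["shannon", "simpson", "chao1"]
    )


# ---------------------------------------------------------------------------
# statistics


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating every split of the pooled
    values (handles ties through mid-ranks)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2.0
    dev = abs(ranks[:n1].sum() - mu) - 1e-9
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev:
            hits += 1
    return hits / total


def _drop_missing(values: pd.Series, variable: pd.Series) -> tuple[pd.Series, pd.Series, int]:
    common = values.index.intersection(variable.index)
    v, g = values.loc[common], variable.loc[common]
    keep = v.notna() & g.notna()
    return v[keep], g[keep], int((~keep).sum())


def alpha_group_test(values: pd.Series, variable: pd.Series) -> tuple[float, float, str]:
    """Rank-sum test of an alpha index across discrete groups.

    Two groups: two-sided Mann-Whitney/Wilcoxon rank-sum (exact
    enumeration when both n <= 8, else normal approximation with tie and
    continuity correction). More groups: Kruskal-Wallis with tie
    correction. Returns (statistic, p, method).
    """
    v, g, _ = _drop_missing(values, variable)
    levels = sorted(g.unique())
    if len(levels) < 2:
        raise ValueError(f"need >=2 non-empty groups, got {levels}")
    groups = [v[g == lev].to_numpy() for lev in levels]
    for lev, arr in zip(levels, groups):
        if len(arr) == 0:
            raise ValueError(f"group {lev!r} is empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # pure-tie degenerate case
        stat = float(len(groups[0]) * len(groups[1]) / 2.0) if len(levels) == 2 else 0.0
        return stat, 1.0, "degenerate"
    if len(levels) == 2:
        x, y = groups
        u = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic)
        if len(x) <= 8 and len(y) <= 8:
            return u, _exact_ranksum_p(x, y), "mann-whitney-exact"
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", use_continuity=True, method="asymptotic"
            ).pvalue
        )
        return u, p, "mann-whitney"
    h, p = stats.kruskal(*groups)
    return float(h), float(p), "kruskal-wallis"


def alpha_numeric_regression(
    values: pd.Series, variable: pd.Series
) -> tuple[float, float, float, float]:
    """OLS of an alpha index on a numeric variable.

    Returns (slope, intercept, r2, p) with p the two-sided t-test on the
    slope. Constant predictors are rejected; a constant response gives a
    flat fit (slope 0, r2 0, p 1).
    """
    v, x, _ = _drop_missing(values, variable)
    if len(v) < 3:
        raise ValueError("need at least 3 paired non-missing points")
    x = x.astype(float).to_numpy()
    y = v.astype(float).to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


def alpha_associations(
    alpha: pd.DataFrame, metadata: MetadataTable
) -> pd.DataFrame:
    """Test every alpha index against every metadata variable.

    Returns a tidy frame (index, variable, method, statistic, p, extra)
    with samples missing either value dropped per test.
    """
    rows = []
    for index_name in alpha.columns:
        values = alpha[index_name].dropna()
        for var in metadata.variables():
            col = metadata.column(var)
            try:
                if metadata.kinds[var] == "discrete":
                    stat, p, method = alpha_group_test(values, col)
                    rows.append(
                        dict(index=index_name, variable=var, method=method,
                             statistic=stat, p=p, extra="")
                    )
                else:
                    slope, intercept, r2, p = alpha_numeric_regression(values, col)
                    rows.append(
                        dict(index=index_name, variable=var, method="ols",
                             statistic=slope, p=p, extra=f"intercept={intercept:.6g};r2={r2:.6g}")
                    )
            except ValueError:
                continue
    return pd.DataFrame(rows, columns=["index", "variable", "method", "statistic", "p", "extra"])
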