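"""Biomarker selection: rank-sum screen with FDR control, Random-Forest
importance ranking (out-of-bag mean decrease in accuracy), and a
Spearman screen against numeric variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .diversity_alpha import alpha_group_test
from .io_formats import AbundanceTable

__all__ = [
    "BiomarkerReport",
    "feature_tests",
    "ranksum_screen",
    "rf_rank",
    "numeric_biomarkers",
]

PREVALENCE_MIN = 0.10  # features non-zero in fewer samples are not screened


@dataclass
class BiomarkerReport:
    """Screened features ranked by OOB permutation importance."""

    entries: list[dict] = field(default_factory=list)
    # each entry: feature, screen_p, screen_q, importance, direction
    model_error: float = float("nan")  # out-of-bag error rate

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["feature", "screen_p", "screen_q", "importance", "direction"]
        )


def _align(t: AbundanceTable, variable: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    g = variable.reindex(t.data.index)
    keep = g.notna()
    return t.data.loc[keep.to_numpy()], g[keep]


def _prevalence_filter(x: pd.DataFrame, threshold: float) -> pd.DataFrame:
    prev = (x.to_numpy() > 0).mean(axis=0)
    return x.loc[:, prev >= threshold]


def feature_tests(t: AbundanceTable, variable: pd.Series) -> pd.DataFrame:
    """Per-feature rank-sum test across groups (after the 10% prevalence
    filter) with Benjamini-Hochberg q-values over tested features."""
    x, g = _align(t, variable)
    x = _prevalence_filter(x, PREVALENCE_MIN)
    levels = sorted(g.unique())
    if len(levels) < 2:
        raise ValueError("need >=2 groups")
    groups = [x.loc[(g == lev).to_numpy()] for lev in levels]
    sizes = [len(gr) for gr in groups]
    ps = np.ones(x.shape[1])
    if len(levels) == 2 and min(sizes) > 8:
        a, b = groups[0].to_numpy(), groups[1].to_numpy()
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", use_continuity=True,
                method="asymptotic", axis=0,
            )
        ps = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)  # all-tie columns
    else:
        for j, feat in enumerate(x.columns):
            _, p, _ = alpha_group_test(x[feat], g)
            ps[j] = p
    qs = stats.false_discovery_control(ps, method="bh") if len(ps) else ps
    medians = {lev: gr.median(axis=0) for lev, gr in zip(levels, groups)}
    direction = [
        max(levels, key=lambda lev: medians[lev][feat]) for feat in x.columns
    ]
    return pd.DataFrame(
        {"feature": x.columns, "p": ps, "q": qs, "direction": direction}
    ).reset_index(drop=True)


def ranksum_screen(
    t: AbundanceTable, variable: pd.Series, q_threshold: float = 0.05
) -> list[tuple[str, float, float]]:
    """Keep features whose rank-sum q-value clears the threshold."""
    res = feature_tests(t, variable)
    kept = res[res["q"] <= q_threshold].sort_values(["p", "feature"])
    return [(r.feature, float(r.p), float(r.q)) for r in kept.itertuples()]


def _oob_permutation_importance(
    model: BaggingClassifier, x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Breiman-style mean decrease in OOB accuracy, averaged over trees."""
    n, p = x.shape
    drops = np.zeros(p)
    used = np.zeros(p)
    # sub-estimators of a bagging ensemble predict encoded class indices
    y = np.searchsorted(model.classes_, y)
    votes = np.zeros((n, len(model.classes_)))
    for est, samples in zip(model.estimators_, model.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[samples] = False
        if not oob.any():
            continue
        xo, yo = x[oob], y[oob]
        pred = est.predict(xo)
        votes[np.flatnonzero(oob), pred.astype(int)] += 1
        base = (pred == yo).mean()
        for j in range(p):
            xp = xo.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            drops[j] += base - (est.predict(xp) == yo).mean()
            used[j] += 1
    importances = np.divide(drops, used, out=np.zeros_like(drops), where=used > 0)
    voted = votes.sum(axis=1) > 0
    if voted.any():  # ensemble OOB error: aggregate votes per held-out sample
        oob_error = float((votes[voted].argmax(axis=1) != y[voted]).mean())
    else:
        oob_error = float("nan")
    return importances, oob_error


def rf_rank(
    t: AbundanceTable,
    variable: pd.Series,
    trees: int = 500,
    seed: int = 0,
    screened: list[tuple[str, float, float]] | None = None,
) -> BiomarkerReport:
    """Rank (screened) features with a bagged-tree ensemble.

    Importance is out-of-bag permutation importance (mean decrease in
    accuracy over trees); model_error is the ensemble's OOB error rate.
    """
    x, g = _align(t, variable)
    stats_by_feature: dict[str, tuple[float, float]] = {}
    if screened is not None:
        feats = [f for f, _, _ in screened]
        stats_by_feature = {f: (p, q) for f, p, q in screened}
        x = x[feats]
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features to rank")
    labels = sorted(g.unique())
    if len(labels) < 2:
        raise ValueError("labels are single-class")
    y = g.to_numpy()
    xm = x.to_numpy(dtype=float)

    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt"),
        n_estimators=trees,
        oob_score=False,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(xm, y)
    rng = np.random.default_rng(seed)
    importances, oob_error = _oob_permutation_importance(model, xm, y, rng)

    medians = {lev: x.loc[(g == lev).to_numpy()].median(axis=0) for lev in labels}
    entries = []
    for j in np.argsort(-importances):
        feat = x.columns[j]
        p, q = stats_by_feature.get(feat, (float("nan"), float("nan")))
        entries.append(
            dict(
                feature=feat,
                screen_p=p,
                screen_q=q,
                importance=float(importances[j]),
                direction=max(labels, key=lambda lev: medians[lev][feat]),
            )
        )
    return BiomarkerReport(entries, model_error=float(oob_error))


def numeric_biomarkers(
    t: AbundanceTable, variable: pd.Series, q_threshold: float = 0.05
) -> list[tuple[str, float, float, float]]:
    """Features Spearman-correlated with a numeric variable.

    Returns (feature, rho, p, q) for q <= threshold, sorted by |rho|
    descending; p from the t-approximation on mid-ranked data.
    """
    g = variable.reindex(t.data.index).astype(float)
    keep = g.notna()
    x = t.data.loc[keep.to_numpy()]
    v = g[keep].to_numpy()
    if np.ptp(v) == 0:
        raise ValueError("numeric variable is constant")
    n = len(v)
    rv = stats.rankdata(v)
    feats, rhos, ps = [], [], []
    for feat in x.columns:
        col = x[feat].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            continue
        rf_ = stats.rankdata(col)
        rho = float(np.corrcoef(rf_, rv)[0, 1])
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2 * stats.t.sf(abs(tstat), df=n - 2))
        feats.append(feat)
        rhos.append(rho)
        ps.append(p)
    if not feats:
        return []
    qs = stats.false_discovery_control(np.array(ps), method="bh")
    out = [
        (f, r, p, float(q))
        for f, r, p, q in zip(feats, rhos, ps, qs)
        if q <= q_threshold
    ]
    out.sort(key=lambda e: (-abs(e[1]), e[0]))
    return out
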