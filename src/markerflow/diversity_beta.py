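"""Phylogeny-aware and hierarchy-aware beta diversity.

Pairwise sample distances are computed by a bottom-up mass-matching
recursion on the reference tree: matched abundance at a node is
credited to similarity, unmatched mass climbs toward the root with
exponential branch-length attenuation, and whatever reaches past the
root unmatched is lost. The same recursion on the pathway hierarchy
(fixed 0.5 attenuation per level) gives the functional distance.
Ordination (PCoA/PCA) and permutation statistics (PERMANOVA, ANOSIM,
Mantel-style distance regression) complete the module.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .function_prediction import FunctionalProfile
from .io_formats import AbundanceTable, DistanceMatrix, ReferencePack
from .profiling import TaxonomicProfile

__all__ = [
    "OrdinationResult",
    "metastorms_distance",
    "hierarchical_metastorms",
    "distance_matrix",
    "pcoa",
    "pca",
    "permanova",
    "anosim",
    "distance_numeric_regression",
]


# ---------------------------------------------------------------------------
# tree-matching distances


def _tree_match_similarity(tree, mass_a: dict, mass_b: dict) -> float:
    """Bottom-up matched mass with exp(-branch length) attenuation."""
    credit = 0.0
    store: dict[int, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_tip():
            ra = mass_a.get(node.name, 0.0)
            rb = mass_b.get(node.name, 0.0)
        else:
            ra = rb = 0.0
            for child in node.children:
                ca, cb = store.pop(id(child))
                ra += ca
                rb += cb
        m = min(ra, rb)
        credit += m
        if node.parent is not None:
            att = math.exp(-(node.length or 0.0))
            store[id(node)] = ((ra - m) * att, (rb - m) * att)
    return credit


def metastorms_distance(
    a: TaxonomicProfile, b: TaxonomicProfile, pack: ReferencePack, weighted: bool = True
) -> float:
    """Phylogeny-aware distance between two taxonomic profiles, in [0,1].

    weighted uses copy-number-corrected relative abundances; unweighted
    replaces each sample's abundances by 1/n over its present leaves.
    Two empty samples are at distance 0 (degenerate); one empty is 1.
    """
    if a.empty and b.empty:
        return 0.0
    if a.empty or b.empty:
        return 1.0
    if weighted:
        ma, mb = a.normalized, b.normalized
    else:
        pa = [leaf for leaf, v in a.normalized.items() if v > 0]
        pb = [leaf for leaf, v in b.normalized.items() if v > 0]
        ma = {leaf: 1.0 / len(pa) for leaf in pa}
        mb = {leaf: 1.0 / len(pb) for leaf in pb}
    s = _tree_match_similarity(pack.tree, ma, mb)
    return float(min(1.0, max(0.0, 1.0 - s)))


class _DictTree:
    """Light rooted tree over nested labels for the hierarchy recursion."""

    __slots__ = ("name", "children", "length", "parent", "_tips")

    def __init__(self, name, length=None):
        self.name = name
        self.length = length
        self.children = []
        self.parent = None

    def add(self, child: "_DictTree") -> "_DictTree":
        child.parent = self
        self.children.append(child)
        return child

    def is_tip(self) -> bool:
        return not self.children

    def postorder(self):
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)


_HIER_ATT = 0.5  # per-level attenuation on the pathway hierarchy


def _hierarchy_tree(pack: ReferencePack) -> tuple[_DictTree, dict[str, list[str]]]:
    """Root -> L1 -> L2 -> L3 -> KO tree; every edge attenuates by 0.5.

    Returns the tree and a map KO -> list of its leaf node names (one
    per hierarchy path; mass splits equally across them).
    """
    length = -math.log(_HIER_ATT)  # so exp(-length) == 0.5
    root = _DictTree("root", 0.0)
    index: dict[tuple, _DictTree] = {}

    def level_node(path: tuple) -> _DictTree:
        if path in index:
            return index[path]
        parent = root if len(path) == 1 else level_node(path[:-1])
        node = index.setdefault(path, parent.add(_DictTree("/".join(path), length)))
        return node

    leaf_names: dict[str, list[str]] = {}
    kos = sorted(set(pack.hierarchy) | set(pack.ko_ids))
    for ko in kos:
        paths = pack.hierarchy.get(ko) or (("Unannotated",) * 3,)
        names = []
        for path in paths:
            parent = level_node(tuple(path))
            name = f"{'/'.join(path)}/{ko}"
            parent.add(_DictTree(name, length))
            names.append(name)
        leaf_names[ko] = names
    return root, leaf_names


def _hierarchy_cache(pack: ReferencePack):
    cached = getattr(pack, "_hierarchy_tree", None)
    if cached is None:
        cached = _hierarchy_tree(pack)
        pack._hierarchy_tree = cached
    return cached


def hierarchical_metastorms(
    a: FunctionalProfile, b: FunctionalProfile, pack: ReferencePack
) -> float:
    """Functional distance: the same matching recursion on the 4-level
    pathway hierarchy with a fixed 0.5 attenuation per edge."""
    if a.empty and b.empty:
        return 0.0
    if a.empty or b.empty:
        return 1.0
    tree, leaf_names = _hierarchy_cache(pack)

    def spread(fp: FunctionalProfile) -> dict[str, float]:
        mass: dict[str, float] = {}
        for ko, ab in fp.ko_abundance.items():
            names = leaf_names.get(ko)
            if names is None:  # KO unknown to the pack hierarchy
                continue
            share = ab / len(names)
            for name in names:
                mass[name] = mass.get(name, 0.0) + share
        return mass

    s = _tree_match_similarity(tree, spread(a), spread(b))
    return float(min(1.0, max(0.0, 1.0 - s)))


def distance_matrix(
    profiles: list, pack: ReferencePack, metric: str = "metastorms-weighted", threads: int = 1
) -> DistanceMatrix:
    """All-pairs distance matrix; result independent of thread count.

    metric: metastorms-weighted | metastorms-unweighted | hierarchical
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 samples")
    if metric == "metastorms-weighted":
        fn = lambda a, b: metastorms_distance(a, b, pack, weighted=True)
    elif metric == "metastorms-unweighted":
        fn = lambda a, b: metastorms_distance(a, b, pack, weighted=False)
    elif metric == "hierarchical":
        fn = lambda a, b: hierarchical_metastorms(a, b, pack)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n = len(profiles)
    d = np.zeros((n, n))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def work(pair):
        i, j = pair
        return i, j, fn(profiles[i], profiles[j])

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(work, pairs))
    else:
        results = [work(p) for p in pairs]
    for i, j, val in results:  # fixed pair order keeps output thread-invariant
        d[i, j] = d[j, i] = val
    ids = [getattr(p, "sample_id", str(k)) for k, p in enumerate(profiles)]
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    explained: np.ndarray  # fraction of (positive) variance per axis
    flags: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


def pcoa(d: DistanceMatrix, axes: int = 2) -> OrdinationResult:
    """Classical scaling: Gower-center -0.5 J D^2 J, keep positive eigenpairs."""
    n = len(d.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for ordination")
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * max(evals.max(), 0.0))
    flags = []
    n_pos = int(pos.sum())
    if n_pos == 0:
        return OrdinationResult(list(d.sample_ids), np.zeros((n, axes)),
                                np.zeros(axes), ["degenerate: no positive eigenvalues"])
    if n_pos < axes:
        flags.append(f"only {n_pos} positive eigenvalues for {axes} requested axes")
    k = min(axes, n_pos)
    lam = evals[:k]
    coords = _fix_signs(evecs[:, :k] * np.sqrt(lam))
    explained = lam / evals[pos].sum()
    return OrdinationResult(list(d.sample_ids), coords, explained, flags)


def pca(t: AbundanceTable, axes: int = 2) -> OrdinationResult:
    """PCA by SVD of the column-mean-centered table (no variance scaling)."""
    x = t.data.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for ordination")
    xc = x - x.mean(axis=0, keepdims=True)
    if np.allclose(xc, 0):
        return OrdinationResult(list(t.sample_ids), np.zeros((n, axes)),
                                np.zeros(axes), ["degenerate: constant table"])
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    keep = s > 1e-12 * s.max()
    u, s = u[:, keep], s[keep]
    k = min(axes, len(s))
    flags = [] if len(s) >= axes else [f"only {len(s)} non-trivial components"]
    coords = _fix_signs(u[:, :k] * s[:k])
    explained = (s[:k] ** 2) / (s**2).sum()
    return OrdinationResult(list(t.sample_ids), coords, explained, flags)


# ---------------------------------------------------------------------------
# permutation statistics


def _groups_from(variable: pd.Series, sample_ids: list[str]):
    g = variable.reindex(sample_ids)
    keep = g.notna()
    ids = [s for s, k in zip(sample_ids, keep) if k]
    labels = g[keep].to_numpy()
    return ids, labels


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(codes)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 1e-300:
        return math.inf
    return ((ss_total - ss_within) / df_between) / (ss_within / df_within)


def permanova(
    d: DistanceMatrix, variable: pd.Series, permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F partitions the sum of squared distances between and within
    groups; p is the add-one permutation tail probability.
    """
    ids, labels = _groups_from(variable, d.sample_ids)
    levels = np.unique(labels)
    codes = np.searchsorted(levels, labels)
    if len(levels) < 2:
        raise ValueError("need >=2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [str(levels[i]) for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    sub = d.submatrix(ids)
    d2 = sub.values**2
    f_obs = _pseudo_f(d2, codes, len(levels))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(levels)) >= f_obs:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return float(f_obs), float(p)


def _anosim_r(ranks: np.ndarray, iu: tuple, same_group: np.ndarray) -> float:
    m = len(ranks)
    mean_within = ranks[same_group].mean()
    mean_between = ranks[~same_group].mean()
    return (mean_between - mean_within) / (m / 2.0)


def anosim(
    d: DistanceMatrix, variable: pd.Series, permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """ANOSIM R (rank-based group separation) with permutation p.

    R = (mean between-group rank - mean within-group rank) / (M/2),
    M = N(N-1)/2; mid-ranks on ties.
    """
    ids, labels = _groups_from(variable, d.sample_ids)
    levels = np.unique(labels)
    codes = np.searchsorted(levels, labels)
    if len(levels) < 2:
        raise ValueError("need >=2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [str(levels[i]) for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    sub = d.submatrix(ids)
    n = len(ids)
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(sub.values[iu])
    same = codes[iu[0]] == codes[iu[1]]
    if same.all() or not same.any():
        raise ValueError("need both within- and between-group pairs")
    r_obs = _anosim_r(ranks, iu, same)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(codes)
        same_p = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, iu, same_p) >= r_obs:
            hits += 1
    return float(r_obs), float((hits + 1) / (permutations + 1))


def distance_numeric_regression(
    d: DistanceMatrix, variable: pd.Series, permutations: int = 999, seed: int = 0
) -> tuple[float, float, float]:
    """Mantel-style OLS of pairwise distance on |x_i - x_j|.

    Returns (slope, r2, p); p permutes the sample labels of x and counts
    permuted r2 >= observed with the add-one convention.
    """
    g = variable.reindex(d.sample_ids).astype(float)
    keep = g.notna()
    ids = [s for s, k in zip(d.sample_ids, keep) if k]
    x = g[keep].to_numpy()
    if len(ids) < 3:
        raise ValueError("need at least 3 samples (>=3 pairs)")
    if np.ptp(x) == 0:
        raise ValueError("numeric variable is constant")
    sub = d.submatrix(ids)
    n = len(ids)
    iu = np.triu_indices(n, 1)
    y = sub.values[iu]

    def fit(xv: np.ndarray) -> tuple[float, float]:
        dx = np.abs(xv[iu[0]] - xv[iu[1]])
        if np.ptp(dx) == 0 or np.ptp(y) == 0:
            return 0.0, 0.0
        res = stats.linregress(dx, y)
        return float(res.slope), float(res.rvalue**2)

    slope, r2_obs = fit(x)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if fit(rng.permutation(x))[1] >= r2_obs:
            hits += 1
    return slope, r2_obs, float((hits + 1) / (permutations + 1))
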