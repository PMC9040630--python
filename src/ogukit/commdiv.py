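"""Community-ecology statistics on feature tables.

Distances: Bray-Curtis and Jaccard (tree-free), unweighted and weighted
UniFrac (tree-aware).  UniFrac is evaluated by a single postorder pass that
accumulates, per branch, the fraction of each sample's counts descending
through it; this is linear in tree size per sample pair.  Ordination is
classical PCoA, and group separation is tested with PERMANOVA.  A
within-versus-between environment distance-ratio statistic quantifies how
tightly a set of focal sites cluster against the remaining sites.

Distance matrices are scikit-bio ``DistanceMatrix`` objects (symmetric,
zero-diagonal, id-labelled).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .tables import FeatureTable

__all__ = [
    "bray_curtis",
    "jaccard",
    "unweighted_unifrac",
    "weighted_unifrac",
    "beta_matrix",
    "PcoaResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "pseudo_f",
    "relative_distance_ratio",
    "METRICS",
]

METRICS = (
    "braycurtis",
    "jaccard",
    "unweighted-unifrac",
    "weighted-unifrac",
    "weighted-unifrac-normalized",
)


def _as_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"vectors differ in length: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("count vectors must be nonnegative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("both count vectors are all-zero")
    return x, y


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    x, y = _as_arrays(x, y)
    return float(np.abs(x - y).sum() / (x + y).sum())


def jaccard(x, y) -> float:
    """Jaccard distance on presence/absence: 1 - |A∩B| / |A∪B|."""
    x, y = _as_arrays(x, y)
    px, py = x > 0, y > 0
    union = (px | py).sum()
    return float(1.0 - (px & py).sum() / union)


def _branch_fractions(
    tree: TreeNode, features: Sequence[str], x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-branch lengths and fraction of each sample descending through it.

    Returns ``(lengths, px, py)`` over all non-root branches, where ``px[b]``
    is the share of sample x's total count held by tips below branch ``b``.
    """
    counts = {f: i for i, f in enumerate(features)}
    present = set()
    for f, cx, cy in zip(features, x, y):
        if cx > 0 or cy > 0:
            present.add(f)
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(present - tip_names)
    if missing:
        raise ValueError(f"feature(s) not found as tree tips: {missing}")
    xs = x.sum()
    ys = y.sum()
    lengths, px, py = [], [], []
    subtree_x: dict[int, float] = {}
    subtree_y: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_tip():
            i = counts.get(node.name)
            sx = x[i] if i is not None else 0.0
            sy = y[i] if i is not None else 0.0
        else:
            sx = sum(subtree_x[id(c)] for c in node.children)
            sy = sum(subtree_y[id(c)] for c in node.children)
        subtree_x[id(node)] = sx
        subtree_y[id(node)] = sy
        if node.parent is not None:  # root carries no branch
            lengths.append(node.length or 0.0)
            px.append(sx / xs if xs > 0 else 0.0)
            py.append(sy / ys if ys > 0 else 0.0)
    return np.array(lengths), np.array(px), np.array(py)


def unweighted_unifrac(tree: TreeNode, x, y, features: Sequence[str]) -> float:
    """Unweighted UniFrac: unique branch length / total observed branch length.

    A branch is *observed* if any tip below it is present in either sample
    and *unique* if those tips are present in exactly one of the two.
    """
    x, y = _as_arrays(x, y)
    lengths, px, py = _branch_fractions(tree, features, x, y)
    in_x, in_y = px > 0, py > 0
    total = lengths[in_x | in_y].sum()
    if total == 0:
        return 0.0
    unique = lengths[in_x ^ in_y].sum()
    return float(unique / total)


def weighted_unifrac(
    tree: TreeNode, x, y, features: Sequence[str], normalized: bool = False
) -> float:
    """Weighted UniFrac: sum over branches of length * |p_x - p_y|.

    ``p_s`` is the fraction of sample ``s``'s total count descending through
    the branch.  The normalized variant divides by
    ``sum(length * (p_x + p_y))``, bounding the value to [0, 1].
    """
    x, y = _as_arrays(x, y)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("weighted UniFrac requires both samples nonempty")
    lengths, px, py = _branch_fractions(tree, features, x, y)
    num = float((lengths * np.abs(px - py)).sum())
    if not normalized:
        return num
    denom = float((lengths * (px + py)).sum())
    return num / denom if denom > 0 else 0.0


def beta_matrix(
    table: FeatureTable, metric: str, tree: TreeNode | None = None
) -> DistanceMatrix:
    """All pairwise sample distances for a table under one metric.

    ``metric`` is one of ``braycurtis``, ``jaccard``, ``unweighted-unifrac``,
    ``weighted-unifrac`` or ``weighted-unifrac-normalized``; the UniFrac
    metrics require ``tree``.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    samples = table.sample_ids
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    needs_tree = "unifrac" in metric
    if needs_tree and tree is None:
        raise ValueError(f"metric {metric!r} requires a tree")
    features = table.feature_ids
    mat = table.data.to_numpy(dtype=float)
    n = len(samples)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        x, y = mat[:, i], mat[:, j]
        try:
            if metric == "braycurtis":
                d = bray_curtis(x, y)
            elif metric == "jaccard":
                d = jaccard(x, y)
            elif metric == "unweighted-unifrac":
                d = unweighted_unifrac(tree, x, y, features)
            elif metric == "weighted-unifrac":
                d = weighted_unifrac(tree, x, y, features, normalized=False)
            else:
                d = weighted_unifrac(tree, x, y, features, normalized=True)
        except ValueError as exc:
            raise ValueError(
                f"metric {metric!r} failed for samples ({samples[i]!r}, {samples[j]!r}): {exc}"
            ) from exc
        dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=samples)


@dataclass
class PcoaResult:
    """Classical-scaling ordination of a distance matrix.

    ``coordinates`` holds samples x axes for the positive eigenvalues only;
    ``eigenvalues`` includes negative ones (a diagnostic for non-Euclidean
    distance matrices); ``proportion_explained`` is each positive eigenvalue
    over the sum of positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis (classical multidimensional scaling).

    The squared distance matrix is double-centered (Gower transform
    ``-1/2 J D² J``) and eigendecomposed; axes are ordered by decreasing
    eigenvalue and scaled by sqrt(eigenvalue).  No correction is applied for
    negative eigenvalues; they are reported as-is and excluded from the axes.
    """
    d = dm.data
    n = d.shape[0]
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals).max()) if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(pos.sum())]
    coordinates = pd.DataFrame(coords, index=list(dm.ids), columns=axes)
    pos_sum = evals[pos].sum()
    proportion = evals[pos] / pos_sum if pos_sum > 0 else evals[pos]
    return PcoaResult(coordinates=coordinates, eigenvalues=evals, proportion_explained=proportion)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value outside (0, 1]")


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        n_g = idx.size
        ss += d2[np.ix_(idx, idx)].sum() / (2 * n_g)
    return ss


def pseudo_f(dm: DistanceMatrix, grouping: Mapping[str, str] | Sequence[str]) -> float:
    """PERMANOVA pseudo-F for one grouping factor, without a permutation test."""
    labels = _labels_for(dm, grouping)
    groups = np.unique(labels)
    a, n = groups.size, labels.size
    if a < 2:
        raise ValueError("need at least 2 groups")
    if a >= n:
        raise ValueError("each group must leave residual degrees of freedom")
    d2 = dm.data**2
    ss_total = d2.sum() / (2 * n)
    ss_within = _ss_within(d2, labels, groups)
    ss_between = ss_total - ss_within
    return float((ss_between / (a - 1)) / (ss_within / (n - a)))


def _labels_for(dm: DistanceMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, Mapping):
        missing = [s for s in dm.ids if s not in grouping]
        if missing:
            raise ValueError(f"grouping missing samples: {missing}")
        return np.asarray([grouping[s] for s in dm.ids])
    labels = np.asarray(list(grouping))
    if labels.size != len(dm.ids):
        raise ValueError("grouping length does not match distance matrix")
    return labels


def permanova(
    dm: DistanceMatrix,
    grouping: Mapping[str, str] | Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
    *,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate analysis of variance.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)), with sums of squares
    computed from squared distances (SS_total = sum_{i<j} d²/N; SS_within
    summed per group with its own 1/n_g).  The p-value counts permuted
    statistics >= the observed one with the +1 correction, so it never
    returns 0 and is never below 1/(n_permutations + 1).  With
    ``exhaustive=True`` all distinct label permutations are enumerated
    instead (only sensible for very small N).
    """
    labels = _labels_for(dm, grouping)
    groups = np.unique(labels)
    a, n = groups.size, labels.size
    if a < 2:
        raise ValueError("need at least 2 groups")
    if a >= n:
        raise ValueError("a group spans all samples; no residual variation")
    d2 = dm.data**2
    ss_total = d2.sum() / (2 * n)

    def f_of(lab: np.ndarray) -> float:
        ss_w = _ss_within(d2, lab, groups)
        return ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = f_of(labels)
    if exhaustive:
        perms = [np.asarray(p) for p in set(itertools.permutations(labels))]
        hits = sum(1 for p in perms if f_of(p) >= f_obs - 1e-12)
        return PermanovaResult(
            pseudo_F=f_obs, p_value=hits / len(perms), n_permutations=len(perms)
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if f_of(rng.permutation(labels)) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(pseudo_F=f_obs, p_value=p, n_permutations=n_permutations)


def relative_distance_ratio(
    dm: DistanceMatrix,
    site_of_sample: Mapping[str, str],
    focal_sites: set[str] | Sequence[str],
) -> pd.Series:
    """Within- versus between-environment distance ratio, per focal sample.

    For each sample in a focal site, own-site samples are excluded; the
    numerator is its mean distance to samples of the *other* focal sites and
    the denominator its mean distance to samples of non-focal sites.  The
    returned per-sample ratios form the reported distribution; values below
    1 mean the focal sites cluster together against the background.
    """
    focal = set(focal_sites)
    if len(focal) < 2:
        raise ValueError("need at least 2 focal sites")
    ids = list(dm.ids)
    missing = [s for s in ids if s not in site_of_sample]
    if missing:
        raise ValueError(f"samples missing site metadata: {missing}")
    site = {s: site_of_sample[s] for s in ids}
    ratios = {}
    for s in ids:
        if site[s] not in focal:
            continue
        in_group = [t for t in ids if t != s and site[t] in focal and site[t] != site[s]]
        out_group = [t for t in ids if site[t] not in focal]
        if not in_group:
            raise ValueError(f"sample {s!r}: no samples in other focal sites")
        if not out_group:
            raise ValueError(f"sample {s!r}: no samples in non-focal sites")
        num = float(np.mean([dm[s, t] for t in in_group]))
        den = float(np.mean([dm[s, t] for t in out_group]))
        if den == 0:
            raise ValueError(f"sample {s!r}: zero mean distance to non-focal sites")
        ratios[s] = num / den
    return pd.Series(ratios, name="relative_distance_ratio")
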