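"""Nonparametric comparison, correlation and congener clustering.

Concentration data here are heavily left-censored (zeros from
nondetect substitution), so every routine is tie-aware: Kruskal-Wallis
uses the tie-corrected H, Spearman uses average ranks, and congeners
with zero variance (never detected) are excluded from correlation and
clustering rather than imputed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import ConcentrationTable, DegenerateInputError, ValidationError

# Largest pooled n for which the exact permutation null is enumerated.
PERMUTATION_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest collectible

    statistic: float
    p_value: float
    df: int | None = None
    groups: tuple[str, ...] = ()


def normality_test(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk test of normality."""
    x = np.asarray(values, float)
    if len(x) < 3:
        raise DegenerateInputError(f"need n >= 3, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant vector: normality test undefined")
    stat, p = sps.shapiro(x)
    return TestResult(statistic=float(stat), p_value=float(p))


def _h_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H (0 when all pooled values tie)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    if tie_term == 0.0:
        return 0.0
    return h / tie_term


def kruskal_wallis(groups: Mapping[str, Sequence[float]],
                   method: str = "chi2") -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    ``method="chi2"`` uses the chi-square null with g-1 df (via scipy);
    ``method="permutation"`` enumerates every assignment of the pooled
    values to the group sizes (pooled n <= 12) and returns the exact
    p-value P(H_perm >= H_obs). All pooled values identical returns
    (H=0, p=1) by convention rather than dividing by a zero tie term.
    """
    labels = tuple(groups)
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(groups[lab], float) for lab in labels]
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("empty group")
    pooled = np.concatenate(arrays)
    if len(pooled) < 3:
        raise ValidationError("pooled n must be >= 3")
    df = len(labels) - 1
    if np.ptp(pooled) == 0:
        return TestResult(statistic=0.0, p_value=1.0, df=df, groups=labels)

    if method == "chi2":
        stat, p = sps.kruskal(*arrays)
        return TestResult(statistic=float(stat), p_value=float(p), df=df,
                          groups=labels)
    if method == "permutation":
        n = len(pooled)
        if n > PERMUTATION_LIMIT:
            raise ValidationError(
                f"exact permutation limited to pooled n <= {PERMUTATION_LIMIT}")
        h_obs = _h_statistic(arrays)
        sizes = [len(a) for a in arrays]
        count = 0
        total = 0
        for assignment in _partitions(n, sizes):
            perm_groups = [pooled[list(idx)] for idx in assignment]
            total += 1
            if _h_statistic(perm_groups) >= h_obs - 1e-12:
                count += 1
        return TestResult(statistic=float(h_obs), p_value=count / total, df=df,
                          groups=labels)
    raise ValidationError(f"unknown method {method!r}")


def _partitions(n: int, sizes: Sequence[int]):
    """All ways to split indices 0..n-1 into ordered blocks of the given sizes."""
    indices = tuple(range(n))

    def rec(remaining: tuple[int, ...], sizes_left: Sequence[int]):
        if len(sizes_left) == 1:
            yield (remaining,)
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            chosen = set(combo)
            rest = tuple(i for i in remaining if i not in chosen)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo,) + tail

    yield from rec(indices, sizes)


@dataclass
class CorrelationMatrix:
    """Spearman correlation of congener concentration vectors.

    Congeners that are constant across samples (typically never
    detected) are listed in ``excluded`` and dropped from the matrix,
    since rank correlation is undefined for constant vectors.
    """

    labels: tuple[str, ...]
    rho: np.ndarray
    p: np.ndarray
    excluded: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "rho": self.rho.tolist(),
            "p": self.p.tolist(),
            "excluded": list(self.excluded),
        }


def spearman_matrix(table: ConcentrationTable,
                    species: str | None = None) -> CorrelationMatrix:
    """Pairwise Spearman correlation over per-sample concentration vectors.

    Pooled over all samples by default; pass ``species`` to restrict.
    Average ranks handle the massive zero ties from censoring.
    """
    wide = table.to_wide()
    if species is not None:
        meta = table.sample_meta()
        wide = wide.loc[meta["species"] == species]
    if len(wide) < 3:
        raise DegenerateInputError("need at least 3 samples")
    variances = wide.var(axis=0)
    excluded = tuple(c for c in wide.columns if variances[c] == 0)
    included = [c for c in wide.columns if variances[c] > 0]
    if len(included) < 2:
        raise DegenerateInputError("fewer than 2 non-constant congeners")
    x = wide[included].to_numpy(float)
    rho, p = sps.spearmanr(x)
    rho = np.atleast_2d(np.asarray(rho, float))
    p = np.atleast_2d(np.asarray(p, float))
    if rho.shape == (1, 1):  # scipy collapses the 2-variable case to scalars
        r = float(rho[0, 0])
        pv = float(p[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, pv], [pv, 0.0]])
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(labels=tuple(included), rho=rho, p=p,
                             excluded=excluded)


@dataclass
class ClusterAssignment:
    """Flat congener clusters cut from an agglomerative tree.

    ``linkage_tree`` is the scipy merge history: rows of
    (left, right, height, size). Cluster ids are 1..k, numbered by
    first appearance in label order so the labeling is canonical.
    """

    labels: tuple[str, ...]
    cluster_ids: tuple[int, ...]
    k: int
    linkage_tree: np.ndarray

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for lab, cid in zip(self.labels, self.cluster_ids):
            out.setdefault(cid, []).append(lab)
        return out

    def as_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "cluster_ids": list(self.cluster_ids),
            "k": self.k,
            "linkage_tree": self.linkage_tree.tolist(),
        }


def cluster_congeners(matrix: CorrelationMatrix, k: int = 3,
                      linkage: str = "average") -> ClusterAssignment:
    """Agglomerative clustering of congeners on d(i,j) = 1 - |rho(i,j)|.

    Correlation-magnitude distance groups congeners that co-vary across
    samples, the standard reading for shared pollution sources.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if linkage not in ("average", "ward", "complete"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    n = len(matrix.labels)
    if k > n:
        raise ValidationError(f"k={k} exceeds {n} congeners")
    d = 1.0 - np.abs(matrix.rho)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # enforce exact symmetry
    condensed = squareform(d, checks=False)
    tree = hierarchy.linkage(condensed, method=linkage)
    raw = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    ids = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        ids.append(relabel[r])
    return ClusterAssignment(labels=matrix.labels, cluster_ids=tuple(ids),
                             k=int(max(ids)), linkage_tree=tree)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (reported alongside, not used
    for the survey-mirroring report which keeps per-test alpha=0.05)."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
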