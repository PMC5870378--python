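"""Compositional dissimilarity, NMDS ordination, ANOSIM and clustering.

Community fingerprints are compared through Bray-Curtis dissimilarity

    d_hi = Σ_j |x_hj − x_ij| / Σ_j (x_hj + x_ij),

often reported on the percent-similarity scale 100 × (1 − d).  On top of
the distance matrix this module provides:

* :func:`nmds_embed` — nonmetric multidimensional scaling minimizing
  Kruskal stress-1, √(Σ(d − ď)² / Σd²), where d are configuration
  distances and ď their monotone (isotonic) regression onto the rank order
  of the observed dissimilarities; multiple random starts guard against
  local minima.
* :func:`anosim_test` — rank-based analysis of similarities with
  R = (r̄_between − r̄_within) / (n(n−1)/4), permutation p-values, exact
  enumeration when feasible, and pairwise group contrasts.
* :func:`upgma_cluster` — group-average hierarchical clustering with
  Newick export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .profiles import CommunityMatrix

__all__ = [
    "DistanceMatrix",
    "NMDSResult",
    "ANOSIMResult",
    "Dendrogram",
    "bray_curtis",
    "monotone_regression",
    "nmds_embed",
    "anosim_test",
    "upgma_cluster",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarity matrix with sample labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix has nonzero diagonal")
        object.__setattr__(self, "d", d)

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def similarity_percent(self) -> np.ndarray:
        """The matrix on the percent-similarity scale, 100 × (1 − d)."""
        return 100.0 * (1.0 - self.d)

    def subset(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(s) for s in keep]
        return DistanceMatrix(tuple(keep), self.d[np.ix_(idx, idx)])


def bray_curtis(matrix: CommunityMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between all sample pairs of a matrix."""
    x = matrix.abundance.to_numpy(dtype=float)
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if zero_rows.size >= 2:
        bad = [matrix.samples[i] for i in zero_rows]
        raise ValueError(f"Bray-Curtis undefined between empty samples: {bad}")
    d = squareform(pdist(x, metric="braycurtis"), checks=False)
    return DistanceMatrix(tuple(matrix.samples), d)


# ---------------------------------------------------------------------------
# isotonic regression (pool-adjacent-violators)
# ---------------------------------------------------------------------------


def _pava(y: np.ndarray) -> np.ndarray:
    """Least-squares monotone non-decreasing fit, equal weights."""
    means: list[float] = []
    counts: list[int] = []
    for v in y:
        means.append(float(v))
        counts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, c2 = means.pop(), counts.pop()
            m1, c1 = means.pop(), counts.pop()
            c = c1 + c2
            means.append((m1 * c1 + m2 * c2) / c)
            counts.append(c)
    return np.repeat(means, counts)


def monotone_regression(d: Sequence[float], target: Sequence[float]) -> np.ndarray:
    """Monotone regression of ``target`` onto the rank order of ``d``.

    Returns the least-squares non-decreasing fit (pool-adjacent-violators)
    of ``target`` taken in order of increasing ``d``.  Tied ``d`` values are
    free to appear in whichever order fits best (Kruskal's primary
    approach), achieved by sorting targets ascending within each tied block.
    """
    d = np.asarray(d, dtype=float)
    y = np.asarray(target, dtype=float)
    if d.shape != y.shape:
        raise ValueError("d and target must have the same length")
    order = np.lexsort((y, d))
    fitted = _pava(y[order])
    out = np.empty_like(fitted)
    out[order] = fitted
    return out


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NMDSResult:
    coordinates: np.ndarray  # samples × k, centered, principal axes
    stress: float  # Kruskal stress-1
    n_starts: int
    best_start_index: int
    seed: int | None
    converged: bool
    disparities: np.ndarray  # condensed ď, aligned with observed pairs
    labels: tuple[str, ...] = ()


def _pcoa_init(d: np.ndarray, k: int) -> np.ndarray:
    """Classical-scaling (principal coordinates) starting configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    if not np.any(coords):  # fully degenerate input
        coords = np.zeros((n, k))
        coords[:, 0] = np.arange(n)
    return coords


def _kruskal_stress(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float((dist**2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((dist - disp) ** 2).sum()) / denom)


def nmds_embed(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 100,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> NMDSResult:
    """Nonmetric MDS by multi-start majorization with isotonic disparities.

    The first start is initialized from classical scaling (principal
    coordinates) of the dissimilarities — the usual guard against the
    degenerate tied-distance solutions pure nonmetric fitting can reach —
    and every further start draws a random configuration.  Each start
    alternates (i) Euclidean configuration distances, (ii) monotone
    regression of those distances on the observed dissimilarity ranks,
    (iii) a Guttman-transform update, until the stress change drops below
    ``tol`` or ``max_iter`` is hit.  The minimum-stress configuration over
    all starts is returned, centered at the origin and rotated to its
    principal axes.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("NMDS needs at least 3 samples")
    if k >= n:
        raise ValueError("embedding dimension must be below the sample count")
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    delta = dist.condensed
    rng = np.random.default_rng(seed)

    best: tuple[float, int, np.ndarray, np.ndarray, bool] | None = None
    for start in range(n_starts):
        x = _pcoa_init(dist.d, k) if start == 0 else rng.normal(size=(n, k))
        prev_stress = np.inf
        converged = False
        for _ in range(max_iter):
            cd = pdist(x)
            disp = monotone_regression(delta, cd)
            stress = _kruskal_stress(cd, disp)
            if prev_stress - stress < tol:
                converged = True
                break
            prev_stress = stress
            # Guttman transform with weights 1 and targets ď
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(cd > 0, disp / cd, 0.0)
            b = -squareform(ratio, checks=False)
            np.fill_diagonal(b, -b.sum(axis=1))
            x = b @ x / n
        cd = pdist(x)
        disp = monotone_regression(delta, cd)
        stress = _kruskal_stress(cd, disp)
        if best is None or stress < best[0]:
            best = (stress, start, x, disp, converged)

    stress, start_idx, x, disp, converged = best
    x = x - x.mean(axis=0)
    # rotate to principal axes
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    return NMDSResult(
        coordinates=x,
        stress=stress,
        n_starts=n_starts,
        best_start_index=start_idx,
        seed=seed,
        converged=converged,
        disparities=disp,
        labels=dist.labels,
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ANOSIMResult:
    R: float
    p_value: float
    n_permutations: int
    method: str  # "exact" or "sampled"
    pairwise: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )


def _anosim_r(rank_c: np.ndarray, within_c: np.ndarray, n: int) -> float:
    rw = rank_c[within_c].mean()
    rb = rank_c[~within_c].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def _multiset_permutations(counts: dict[int, int], n: int):
    """Yield every distinct arrangement of a label multiset."""
    if n == 0:
        yield ()
        return
    for v in sorted(counts):
        if counts[v] == 0:
            continue
        counts[v] -= 1
        for rest in _multiset_permutations(counts, n - 1):
            yield (v, *rest)
        counts[v] += 1


def _n_labelings(sizes: Sequence[int]) -> int:
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def anosim_test(
    dist: DistanceMatrix,
    labels: Mapping[str, str],
    n_permutations: int = 999,
    seed: int | None = None,
    pairwise: bool = True,
) -> ANOSIMResult:
    """ANOSIM: do between-group dissimilarities exceed within-group ones?

    All off-diagonal dissimilarities are ranked (average ranks on ties) and
    R contrasts the mean between- and within-group rank, scaled to [−1, 1].
    Significance comes from permuting sample labels: exact enumeration of
    all distinct labelings when their number does not exceed
    ``n_permutations``, otherwise ``n_permutations`` random relabelings with
    p = (1 + #{R* ≥ R}) / (1 + m).  With ``pairwise=True`` each group pair
    is additionally tested on its sub-matrix.
    """
    group_of = [labels.get(s) for s in dist.labels]
    missing = [s for s, g in zip(dist.labels, group_of) if g is None]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    groups = sorted(set(group_of))
    sizes = [group_of.count(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if min(sizes) < 2:
        small = [g for g, s in zip(groups, sizes) if s < 2]
        raise ValueError(f"groups of size 1 are not testable: {small}")

    n = len(dist.labels)
    g = np.array([groups.index(x) for x in group_of])
    rank_c = rankdata(dist.condensed)
    iu, ju = np.triu_indices(n, k=1)

    def r_for(gvec: np.ndarray) -> float:
        return _anosim_r(rank_c, gvec[iu] == gvec[ju], n)

    r_obs = r_for(g)
    n_exact = _n_labelings(sizes)
    if n_exact <= n_permutations:
        counts = {v: int((g == v).sum()) for v in np.unique(g)}
        count = sum(
            r_for(np.array(perm)) >= r_obs - 1e-12
            for perm in _multiset_permutations(counts, n)
        )
        p = count / n_exact
        method, m_used = "exact", n_exact
    else:
        rng = np.random.default_rng(seed)
        count = sum(
            r_for(rng.permutation(g)) >= r_obs - 1e-12
            for _ in range(n_permutations)
        )
        p = (1 + count) / (1 + n_permutations)
        method, m_used = "sampled", n_permutations

    pair_results: dict[tuple[str, str], tuple[float, float]] = {}
    if pairwise and len(groups) > 2:
        child_seed = np.random.default_rng(seed).integers(2**31)
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                keep = [
                    s for s, grp in zip(dist.labels, group_of)
                    if grp in (groups[a], groups[b])
                ]
                sub = anosim_test(
                    dist.subset(keep), labels, n_permutations,
                    seed=int(child_seed) + a * len(groups) + b, pairwise=False,
                )
                pair_results[(groups[a], groups[b])] = (sub.R, sub.p_value)

    return ANOSIMResult(r_obs, float(p), m_used, method, pair_results)


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dendrogram:
    """Group-average (UPGMA) dendrogram over a distance matrix."""

    labels: tuple[str, ...]
    merges: np.ndarray  # scipy linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def similarity_levels(self) -> np.ndarray:
        """Merge heights on the percent-similarity scale, 100 × (1 − h)."""
        return 100.0 * (1.0 - self.heights)

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distances (ultrametric heights)."""
        return cophenet(self.merges)

    def to_newick(self) -> str:
        """Newick string; branch lengths are height/2 differences, so leaf
        depths equal half the merge height (ultrametric tree)."""
        n = len(self.labels)

        def node_height(i: int) -> float:
            return 0.0 if i < n else float(self.merges[i - n, 2])

        def render(i: int) -> str:
            if i < n:
                return self.labels[i]
            a, b, h, _ = self.merges[i - n]
            parts = []
            for child in (int(a), int(b)):
                bl = (h - node_height(child)) / 2.0
                parts.append(f"{render(child)}:{bl:.6g}")
            return "(" + ",".join(parts) + ")"

        return render(2 * n - 2) + ";"


def upgma_cluster(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA (average-linkage) agglomeration of a distance matrix.

    Merge heights are the mean inter-cluster dissimilarities and are
    non-decreasing; ties are broken deterministically by input order.
    """
    if len(dist.labels) < 2:
        raise ValueError("clustering needs at least 2 samples")
    z = linkage(dist.condensed, method="average")
    return Dendrogram(tuple(dist.labels), z)
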