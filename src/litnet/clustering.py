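"""Clustering of disease profiles with bootstrap support values.

Disease columns of a gene × disease profile matrix are clustered by
complete-linkage agglomeration on correlation distance
d(i, j) = 1 − Pearson(col_i, col_j).  Cluster confidence comes from
multiscale bootstrap resampling of the genes (rows): for each scale r the
rows are resampled with replacement to size round(r·n), the tree is
rebuilt, and the proportion BP_r of replicates containing each reference
cluster (exact leaf-set equality) is recorded.  The approximately unbiased
(AU) value extrapolates these proportions across scales through the probit
fit

    Phi^{-1}(1 − BP_r) ≈ v·sqrt(r) + c/sqrt(r),    AU = 1 − Phi(v − c)

estimated by weighted least squares.  Scales where a cluster appeared in
none or all replicates carry no information about (v, c) and are dropped;
if fewer than three informative scales remain, AU saturates at 100 (mean
BP ≥ 0.5) or 0 — the standard treatment in multiscale-bootstrap software.
BP is reported at r = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .association import ProfileMatrix
from .errors import ValidationError

DEFAULT_SCALES: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


def profile_distance(matrix: ProfileMatrix) -> pd.DataFrame:
    """Correlation distance 1 − r between disease columns.

    Symmetric with zero diagonal, range [0, 2].  A constant column has no
    defined correlation and is rejected by name.
    """
    frame = matrix.frame
    if frame.shape[1] < 2:
        raise ValidationError("need at least 2 disease columns")
    stds = frame.std(axis=0, ddof=0)
    constant = [str(c) for c in frame.columns[stds == 0.0]]
    if constant:
        raise ValidationError(f"constant column(s): {constant}")
    corr = np.corrcoef(frame.to_numpy(dtype=float), rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=frame.columns, columns=frame.columns)


def _guarded_distance(X: np.ndarray, columns: Sequence[str]) -> pd.DataFrame:
    """Correlation distance tolerating constant columns (bootstrap use).

    Correlations involving a zero-variance column are set to 0 (distance 1):
    a profile that degenerated in a resample supports no particular
    grouping.
    """
    stds = X.std(axis=0)
    safe = stds > 0.0
    corr = np.zeros((X.shape[1], X.shape[1]))
    if safe.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            sub = np.corrcoef(X[:, safe], rowvar=False)
        sub = np.atleast_2d(np.nan_to_num(sub, nan=0.0))
        corr[np.ix_(safe, safe)] = sub
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=columns, columns=columns)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over leaf ids.

    Nodes are numbered 0..n-1 for leaves (in input order) and n+i for the
    i-th merge; ``merges[i] = (left, right, height)``.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def members(self, node: int) -> frozenset[str]:
        n = len(self.leaves)
        if node < n:
            return frozenset({self.leaves[node]})
        left, right, _ = self.merges[node - n]
        return self.members(left) | self.members(right)

    def clusters(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes, in merge order (root last)."""
        return [self.members(len(self.leaves) + i) for i in range(len(self.merges))]

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(
        self, support: "ClusterSupport | None" = None
    ) -> str:
        """Newick with branch lengths = height differences.

        Internal nodes are labelled "AU/BP" (integer percent) when support
        is given.
        """
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        for i, (_, _, h) in enumerate(self.merges):
            height[n + i] = h

        def label(node: int) -> str:
            if support is None:
                return ""
            rec = support.records.get(self.members(node))
            if rec is None:
                return ""
            return f"{rec.au:.0f}/{rec.bp:.0f}"

        def render(node: int, parent_height: float) -> str:
            branch = max(parent_height - height[node], 0.0)
            if node < n:
                return f"{self.leaves[node]}:{branch:.6g}"
            left, right, h = self.merges[node - n]
            inner = f"({render(left, h)},{render(right, h)})"
            return f"{inner}{label(node)}:{branch:.6g}"

        root = n + len(self.merges) - 1
        left, right, h = self.merges[-1]
        return f"({render(left, h)},{render(right, h)}){label(root)};"


def hcluster(
    distances: pd.DataFrame, linkage: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering with deterministic tie-breaking.

    Complete linkage is the supported setting (single/average exist behind
    the flag).  Ties in merge distance are broken by the lexicographically
    smallest member id of the candidate pair, so the tree is a pure
    function of the distance matrix.
    """
    if linkage not in {"complete", "single", "average"}:
        raise ValidationError(f"unknown linkage {linkage!r}")
    D = distances.to_numpy(dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    ids = [str(c) for c in distances.columns]
    n = len(ids)
    if n < 2:
        raise ValidationError("need at least 2 items")

    # Active clusters: node index -> (smallest member id, size).
    active: dict[int, tuple[str, int]] = {i: (ids[i], 1) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(active) > 1:
        best_key = None
        best_pair = None
        for (i, j), d in dist.items():
            key = (d, *sorted((active[i][0], active[j][0])))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (i, j)
        i, j = best_pair
        d_merge = dist[(i, j)]
        size_i, size_j = active[i][1], active[j][1]
        new = next_node
        next_node += 1
        merges.append((i, j, d_merge))
        # Lance-Williams updates against every other active cluster.
        for k in active:
            if k in (i, j):
                continue
            d_ik = dist[tuple(sorted((i, k)))]
            d_jk = dist[tuple(sorted((j, k)))]
            if linkage == "complete":
                d_new = max(d_ik, d_jk)
            elif linkage == "single":
                d_new = min(d_ik, d_jk)
            else:  # average
                d_new = (size_i * d_ik + size_j * d_jk) / (size_i + size_j)
            dist[(k, new)] = d_new
        dist = {
            (a, b): v
            for (a, b), v in dist.items()
            if i not in (a, b) and j not in (a, b)
        }
        active[new] = (min(active[i][0], active[j][0]), size_i + size_j)
        del active[i], active[j]
    return Dendrogram(leaves=tuple(ids), merges=tuple(merges))


@dataclass(frozen=True)
class ClusterRecord:
    """Support values for one reference cluster."""

    bp: float                       # bootstrap probability at r = 1, percent
    au: float                       # approximately unbiased value, percent
    bp_per_scale: dict[float, float]  # raw proportions in [0, 1]
    v: float                        # probit-fit signed distance
    c: float                        # probit-fit curvature
    never_observed: bool = False


@dataclass(frozen=True)
class ClusterSupport:
    records: dict[frozenset[str], ClusterRecord]
    B: int
    scales: tuple[float, ...]


def _fit_au(
    bp_per_scale: Mapping[float, float], B: int
) -> tuple[float, float, float]:
    """(AU%, v, c) from per-scale bootstrap proportions.

    Degenerate scales (BP of 0 or 1) are dropped; with < 3 informative
    scales AU saturates by majority of the mean BP.  Remaining proportions
    are clipped to [1/(2B), 1 − 1/(2B)] before the probit transform as a
    numerical guard.
    """
    scales = sorted(bp_per_scale)
    bp_all = np.array([bp_per_scale[r] for r in scales])
    usable = (bp_all > 0.0) & (bp_all < 1.0)
    if usable.sum() < 3:
        return (100.0 if bp_all.mean() >= 0.5 else 0.0), math.nan, math.nan
    r = np.array(scales)[usable]
    bp = np.clip(bp_all[usable], 1.0 / (2 * B), 1.0 - 1.0 / (2 * B))
    z = norm.ppf(1.0 - bp)
    weights = B * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    sw = np.sqrt(weights)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = 100.0 * (1.0 - norm.cdf(v - c))
    return au, v, c


def bootstrap_support(
    matrix: ProfileMatrix,
    B: int = 100,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int | None = None,
    linkage: str = "complete",
) -> tuple[Dendrogram, ClusterSupport]:
    """Reference dendrogram plus multiscale-bootstrap cluster support.

    Rows (genes) are the resampling unit.  Identical seed gives identical
    support values.  Returns the dendrogram of the full matrix and, for
    each of its internal clusters, BP (at r = 1), AU, the per-scale
    proportions and the probit-fit coefficients.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    scales = tuple(scales)
    if not scales:
        raise ValidationError("need at least one scale")
    rng = np.random.default_rng(seed)
    reference = hcluster(profile_distance(matrix), linkage=linkage)
    ref_clusters = reference.clusters()
    X = matrix.frame.to_numpy(dtype=float)
    columns = [str(c) for c in matrix.frame.columns]
    n = X.shape[0]

    counts: dict[float, dict[frozenset[str], int]] = {
        r: {c: 0 for c in ref_clusters} for r in scales
    }
    for r in scales:
        n_r = max(2, round(r * n))
        for _ in range(B):
            rows = rng.integers(0, n, size=n_r)
            dist = _guarded_distance(X[rows], columns)
            observed = set(hcluster(dist, linkage=linkage).clusters())
            for cluster in ref_clusters:
                if cluster in observed:
                    counts[r][cluster] += 1

    r_for_bp = min(scales, key=lambda r: abs(r - 1.0))
    records: dict[frozenset[str], ClusterRecord] = {}
    for cluster in ref_clusters:
        bp_per_scale = {r: counts[r][cluster] / B for r in scales}
        au, v, c = _fit_au(bp_per_scale, B)
        records[cluster] = ClusterRecord(
            bp=100.0 * bp_per_scale[r_for_bp],
            au=au,
            bp_per_scale=bp_per_scale,
            v=v,
            c=c,
            never_observed=all(p == 0.0 for p in bp_per_scale.values()),
        )
    return reference, ClusterSupport(records=records, B=B, scales=scales)
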