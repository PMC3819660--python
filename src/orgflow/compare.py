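"""Organ-comparison statistics and correlation-based clustering.

Pairwise sample/organ comparisons use the Pearson correlation of the
transcripts expressed in *both* members of a pair (the common set),
tested either with the exact t statistic ``t = r*sqrt(n-2)/sqrt(1-r^2)``
or, for very large n, the Fisher z transform ``z = atanh(r)*sqrt(n-3)``.
A one-sample Wilcoxon signed-rank test compares a small sample's
location against a fixed value (exact null distribution up to n = 25).

Expression profiles are clustered agglomeratively: rows are scaled by
their maximum (maxtf), similarity is the Pearson correlation, distance
is 1 - r, and merging follows UPGMA (average linkage) with a
deterministic lowest-index-first tie-break.  Trees export to Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counts import ValidationError

__all__ = [
    "CorrelationReport",
    "correlate_common",
    "wilcoxon_rank",
    "ClusterTree",
    "cluster_expression",
]


@dataclass
class CorrelationReport:
    """Pearson correlation on the common non-zero set, with its test."""

    pair: tuple[str, str]
    n: int
    r: float
    test: str          # "t" or "z"
    statistic: float
    p: float


def correlate_common(x: pd.Series, y: pd.Series, test: str = "t",
                     pair: tuple[str, str] | None = None
                     ) -> CorrelationReport:
    """Correlate two expression vectors over genes non-zero in both.

    ``test="t"`` uses the exact t distribution with n-2 df; ``test="z"``
    the Fisher transform against the standard normal (preferable for very
    large n).  Both are two-sided.
    """
    if test not in ("t", "z"):
        raise ValueError("test must be 't' or 'z'")
    x, y = x.align(y, join="inner")
    mask = (x != 0) & (y != 0) & x.notna() & y.notna()
    xv = x[mask].to_numpy(dtype=float)
    yv = y[mask].to_numpy(dtype=float)
    n = len(xv)
    if n < 3:
        raise ValidationError(f"only {n} common non-zero genes; need >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValidationError("undefined correlation: zero variance")
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = min(1.0, max(-1.0, r))
    if test == "t":
        if abs(r) == 1.0:
            stat, p = np.inf * np.sign(r), 0.0
        else:
            stat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
            p = 2.0 * sps.t.sf(abs(stat), df=n - 2)
    else:
        if n < 4:
            raise ValidationError("z-test requires n >= 4")
        if abs(r) == 1.0:
            stat, p = np.inf * np.sign(r), 0.0
        else:
            stat = np.arctanh(r) * np.sqrt(n - 3)
            p = 2.0 * sps.norm.sf(abs(stat))
    name = pair if pair is not None else (str(x.name), str(y.name))
    return CorrelationReport(pair=name, n=n, r=r, test=test,
                             statistic=float(stat), p=float(p))


def wilcoxon_rank(values, mu0: float, alternative: str = "two-sided"
                  ) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of location against ``mu0``.

    Uses the exact permutation null for n <= 25 non-zero differences and
    the normal approximation with continuity correction above.  Returns
    ``(W+, p)`` where W+ is the positive-rank sum.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    n = len(d)
    if n < 5:
        raise ValidationError(
            f"only {n} non-zero differences; need >= 5"
        )
    if n <= 25:
        res = sps.wilcoxon(d, alternative=alternative, method="exact")
    else:
        res = sps.wilcoxon(d, alternative=alternative, method="approx",
                           correction=True)
    # scipy reports the positive-rank sum when given the differences
    return float(res.statistic), float(res.pvalue)


@dataclass
class ClusterTree:
    """Binary agglomerative merge tree over labelled leaves.

    ``merges`` follows the scipy linkage convention: row ``i`` merges
    clusters ``(a, b)`` (indices < n_leaves are leaves) at ``height``
    into new cluster ``n_leaves + i`` of size ``size``.
    """

    leaves: list[str]
    merges: np.ndarray       # (n-1, 4): a, b, height, size
    scaling: str

    def to_newick(self) -> str:
        """Ultrametric Newick with branch lengths from merge heights."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.leaves[i] for i in range(n)}
        for i, (a, b, h, _size) in enumerate(self.merges):
            a, b = int(a), int(b)
            ba = h / 2.0 - height[a]
            bb = h / 2.0 - height[b]
            node[n + i] = f"({node[a]}:{ba:.6g},{node[b]}:{bb:.6g})"
            height[n + i] = h / 2.0
        return node[n + len(self.merges) - 1] + ";"


def _upgma(dist: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration with lowest-index-first tie-break.

    O(n^3); fine at the scale of organ panels and gene modules.  Returns
    a scipy-style linkage matrix.
    """
    n = dist.shape[0]
    d = dist.astype(float).copy()
    active = list(range(n))            # current cluster ids, in creation order
    sizes = {i: 1 for i in range(n)}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                val = d[ai, bi]
                if best is None or val < best[0]:
                    best = (val, ai, bi)
        _, ai, bi = best
        a, b = active[ai], active[bi]
        h = d[ai, bi]
        sa, sb = sizes[a], sizes[b]
        # average-linkage update of distances to the merged cluster
        new_row = (sa * d[ai, :] + sb * d[bi, :]) / (sa + sb)
        keep = [i for i in range(len(active)) if i not in (ai, bi)]
        d = np.vstack([d[keep][:, keep],
                       new_row[keep][None, :]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        active = [active[i] for i in keep] + [next_id]
        sizes[next_id] = sa + sb
        merges[step] = (min(a, b), max(a, b), h, sa + sb)
        next_id += 1
    return merges


def cluster_expression(matrix: pd.DataFrame, axis: str = "genes",
                       scaling: str = "maxtf") -> ClusterTree:
    """Agglomerative clustering of genes (rows) or samples (columns).

    Each profile is scaled by its maximum, pairwise similarity is the
    Pearson correlation and distance is ``1 - r``; merging is UPGMA.
    Constant profiles have no defined correlation and raise an error
    naming the offending row.
    """
    if axis not in ("genes", "samples"):
        raise ValueError("axis must be 'genes' or 'samples'")
    data = matrix if axis == "genes" else matrix.T
    if data.shape[0] < 2:
        raise ValidationError("need at least 2 profiles to cluster")
    vals = data.to_numpy(dtype=float)
    labels = [str(i) for i in data.index]
    const = np.ptp(vals, axis=1) == 0
    if const.any():
        bad = [labels[i] for i in np.flatnonzero(const)]
        raise ValidationError(f"constant profile(s), correlation undefined: {bad}")
    if scaling == "maxtf":
        row_max = np.abs(vals).max(axis=1)
        if np.any(row_max == 0):
            bad = [labels[i] for i in np.flatnonzero(row_max == 0)]
            raise ValidationError(f"all-zero profile(s): {bad}")
        vals = vals / row_max[:, None]
    elif scaling != "none":
        raise ValueError("scaling must be 'maxtf' or 'none'")
    r = np.corrcoef(vals)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist[dist < 0] = 0.0   # guard tiny negative round-off
    merges = _upgma(dist)
    return ClusterTree(leaves=labels, merges=merges, scaling=scaling)
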