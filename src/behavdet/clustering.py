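"""Hierarchical clustering of determinants on Spearman dissimilarity.

The dissimilarity between two questionnaire items is ``D = 1 - |rho|`` with
``rho`` the Spearman rank correlation (midranks for the heavy ties of Likert
data).  Taking the absolute value means strongly *anti*-correlated items are
treated as similar; with harmonized scales (1 = favorable everywhere) strong
negative correlations are rare, but the convention is deliberate and
documented.

Agglomeration uses average linkage (UPGMA): at each step the two clusters
with the smallest mean pairwise dissimilarity between their members are
merged.  The merge loop is written out explicitly (Lance-Williams update)
so that tie-breaking is deterministic: among tied candidate pairs the one
whose combined member-id tuple sorts first wins.

The number of clusters is chosen by cutting the dendrogram at every
k = 2..p-1 and computing, from the original dissimilarity matrix,

* compactness — the maximum D between two items in the same cluster, and
* separation  — the minimum D between items of different clusters,

then picking the k whose difference (compactness - separation) is smallest,
i.e. compactness as far below separation as possible; ties go to the
smaller k (parsimony).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

from ._plotutils import save_figure
from .io import ResponseMatrix

__all__ = [
    "DissimilarityMatrix",
    "DendrogramModel",
    "ClusterSolution",
    "ConstantItemError",
    "spearman_dissimilarity",
    "average_linkage",
    "cophenetic_correlation",
    "compactness_separation_curve",
    "optimal_k",
    "profile_clusters",
    "cluster_determinants",
    "plot_dendrogram",
]


class ConstantItemError(ValueError):
    """Spearman correlation is undefined for a constant item."""


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric item-by-item dissimilarity with entries in [0, 1]."""

    items: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        p = len(self.items)
        if v.shape != (p, p):
            raise ValueError("dissimilarity matrix shape does not match items")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")

    @property
    def p(self) -> int:
        return len(self.items)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def _extract_frame(data, items: Optional[Sequence[str]]) -> pd.DataFrame:
    if isinstance(data, ResponseMatrix):
        df = data.data
    else:
        df = pd.DataFrame(data)
    if items is not None:
        df = df[list(items)]
    return df


def spearman_dissimilarity(data, items: Optional[Sequence[str]] = None) -> DissimilarityMatrix:
    """``D = 1 - |rho|`` over the given item columns (midrank Spearman).

    Raises :class:`ConstantItemError` naming the first constant column, for
    which the correlation is undefined.
    """
    df = _extract_frame(data, items)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 items")
    if df.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    for col in df.columns:
        if df[col].nunique() < 2:
            raise ConstantItemError(f"item {col!r} is constant; rho undefined")
    rho = stats.spearmanr(df.to_numpy(dtype=float)).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if rho.shape == (1, 1):  # spearmanr collapses the p == 2 case to a scalar
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    D = 1.0 - np.abs(rho)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    return DissimilarityMatrix(items=tuple(df.columns), values=D)


@dataclass
class DendrogramModel:
    """The UPGMA merge sequence and its implied cophenetic distances.

    ``linkage`` follows the scipy convention: row ``t`` merges nodes
    ``linkage[t, 0]`` and ``linkage[t, 1]`` (leaves are 0..p-1, the merge
    creates node ``p + t``) at height ``linkage[t, 2]`` into a cluster of
    ``linkage[t, 3]`` leaves.  The cophenetic distance of an item pair is
    the height of their lowest common merge.
    """

    items: tuple
    linkage: np.ndarray
    cophenetic: np.ndarray  # condensed, same pair order as DissimilarityMatrix

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            warnings.warn(
                "non-monotone merge heights in average-linkage dendrogram",
                RuntimeWarning,
            )

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cut(self, k: int) -> Dict[str, int]:
        """Partition into k clusters using the first p-k merges.

        Cluster ids are 1..k in order of each cluster's first item, so
        cutting at k and k+1 yields nested partitions by construction.
        """
        p = self.p
        if not (1 <= k <= p):
            raise ValueError(f"k must lie in 1..{p}")
        parent = list(range(p))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        node_repr = {i: i for i in range(p)}  # tree node -> leaf representative
        for t in range(p - k):
            a = node_repr[int(self.linkage[t, 0])]
            b = node_repr[int(self.linkage[t, 1])]
            ra, rb = find(a), find(b)
            parent[rb] = ra
            node_repr[p + t] = ra
        roots: Dict[int, int] = {}
        labels = {}
        for i in range(p):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots) + 1
            labels[self.items[i]] = roots[r]
        return labels


def average_linkage(D: DissimilarityMatrix) -> DendrogramModel:
    """UPGMA agglomeration with a deterministic lexicographic tie-break."""
    p = D.p
    if p < 2:
        raise ValueError("need at least 2 items to cluster")
    dist = D.values.astype(float).copy()
    items = list(D.items)
    # active cluster state, keyed by scipy node id
    members: Dict[int, List[int]] = {i: [i] for i in range(p)}
    key: Dict[int, tuple] = {i: (items[i],) for i in range(p)}
    active = list(range(p))
    # current inter-cluster average distances, indexed by node id
    d: Dict[int, Dict[int, float]] = {
        i: {j: float(dist[i, j]) for j in range(p) if j != i} for i in range(p)
    }
    Z = np.zeros((p - 1, 4))
    coph = np.zeros((p, p))
    for t in range(p - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dij = d[a][b]
                tie_key = tuple(sorted(key[a] + key[b]))
                cand = (dij, tie_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        h, _, a, b = best
        ma, mb = members[a], members[b]
        for i in ma:
            for j in mb:
                coph[i, j] = coph[j, i] = h
        new = p + t
        Z[t] = [a, b, h, len(ma) + len(mb)]
        na, nb = len(ma), len(mb)
        d[new] = {}
        for c in active:
            if c in (a, b):
                continue
            val = (na * d[a][c] + nb * d[b][c]) / (na + nb)
            d[new][c] = val
            d[c][new] = val
        members[new] = ma + mb
        key[new] = tuple(sorted(key[a] + key[b]))
        active = [c for c in active if c not in (a, b)] + [new]
        del d[a], d[b]
    return DendrogramModel(
        items=D.items, linkage=Z, cophenetic=squareform(coph, checks=False)
    )


def cophenetic_correlation(D: DissimilarityMatrix, dendrogram: DendrogramModel) -> float:
    """Pearson correlation between raw and tree-implied pairwise distances."""
    if D.p < 3:
        raise ValueError("cophenetic correlation needs at least 3 items")
    raw = D.condensed()
    coph = dendrogram.cophenetic
    if np.std(raw) == 0 or np.std(coph) == 0:
        return 1.0 if np.allclose(raw, coph) else 0.0
    return float(stats.pearsonr(raw, coph).statistic)


def _compact_sep(D: np.ndarray, labels: np.ndarray):
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within = D[iu][same[iu]]
    between = D[iu][~same[iu]]
    compact = float(within.max()) if within.size else 0.0
    sep = float(between.min()) if between.size else 0.0
    return compact, sep


def compactness_separation_curve(
    D: DissimilarityMatrix, dendrogram: DendrogramModel
) -> pd.DataFrame:
    """Compactness and separation, from the original D, for k = 2..p-1."""
    rows = []
    item_index = {it: i for i, it in enumerate(D.items)}
    for k in range(2, D.p):
        assignment = dendrogram.cut(k)
        labels = np.array([assignment[it] for it in D.items])
        compact, sep = _compact_sep(D.values, labels)
        rows.append({"k": k, "compactness": compact, "separation": sep})
    return pd.DataFrame(rows)


def optimal_k(curve: pd.DataFrame) -> int:
    """k with the smallest (compactness - separation); ties to smaller k."""
    if curve.empty:
        raise ValueError("curve is empty")
    diff = curve["compactness"].to_numpy() - curve["separation"].to_numpy()
    best = int(np.argmin(diff))  # argmin takes the first minimum: smallest k
    return int(curve["k"].iloc[best])


def profile_clusters(data, assignment: Dict[str, int]) -> pd.DataFrame:
    """Per-cluster score profiles.

    For each cluster: the member items; ``mean_clus`` and ``sd_clus``, the
    mean and sample SD over respondents of the per-respondent mean of the
    member items; and ``rho_clus``, the mean pairwise Spearman correlation
    among members (omitted for singletons).
    """
    df = _extract_frame(data, None)
    clusters: Dict[int, List[str]] = {}
    for item, cid in assignment.items():
        if item not in df.columns:
            raise KeyError(f"item {item!r} not present in data")
        clusters.setdefault(cid, []).append(item)
    rows = []
    for cid in sorted(clusters):
        items = clusters[cid]
        if not items:
            raise ValueError(f"cluster {cid} is empty")
        scores = df[items].mean(axis=1)
        if len(items) > 1:
            rho = stats.spearmanr(df[items].to_numpy(dtype=float)).statistic
            rho = np.atleast_2d(np.asarray(rho))
            if rho.shape == (1, 1):
                rho_clus = float(rho[0, 0])
            else:
                iu = np.triu_indices(len(items), k=1)
                rho_clus = float(rho[iu].mean())
        else:
            rho_clus = np.nan
        rows.append(
            {
                "cluster": cid,
                "n_items": len(items),
                "members": ";".join(items),
                "mean_clus": float(scores.mean()),
                "sd_clus": float(scores.std(ddof=1)),
                "rho_clus": rho_clus,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ClusterSolution:
    """A complete clustering of the selected determinants."""

    k: int
    assignment: Dict[str, int]
    compactness: float
    separation: float
    ccc: float
    profiles: pd.DataFrame
    dissimilarity: DissimilarityMatrix
    dendrogram: DendrogramModel
    curve: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "assignment": self.assignment,
            "compactness": self.compactness,
            "separation": self.separation,
            "ccc": self.ccc,
            "profiles": self.profiles.to_dict(orient="records"),
        }


def cluster_determinants(
    data,
    items: Sequence[str],
    k: Optional[int] = None,
) -> ClusterSolution:
    """Full clustering stage: dissimilarity, UPGMA, CCC, k choice, profiles.

    ``k=None`` applies the compactness/separation rule; an explicit k
    overrides it.
    """
    D = spearman_dissimilarity(data, items)
    dend = average_linkage(D)
    ccc = cophenetic_correlation(D, dend)
    curve = compactness_separation_curve(D, dend)
    chosen = optimal_k(curve) if k is None else int(k)
    assignment = dend.cut(chosen)
    labels = np.array([assignment[it] for it in D.items])
    compact, sep = _compact_sep(D.values, labels)
    profiles = profile_clusters(data, assignment)
    return ClusterSolution(
        k=chosen,
        assignment=assignment,
        compactness=compact,
        separation=sep,
        ccc=ccc,
        profiles=profiles,
        dissimilarity=D,
        dendrogram=dend,
        curve=curve,
    )


def plot_dendrogram(
    dendrogram: DendrogramModel,
    path: Union[str, Path],
    k: Optional[int] = None,
) -> Path:
    """Render the dendrogram; if k is given, box the k clusters."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    fig, ax = plt.subplots(figsize=(max(4.0, 0.45 * dendrogram.p), 4))
    dd = scipy_dendrogram(
        dendrogram.linkage,
        labels=list(dendrogram.items),
        ax=ax,
        color_threshold=0.0,
        above_threshold_color="#444444",
    )
    ax.set_ylabel("D")
    if k is not None:
        assignment = dendrogram.cut(k)
        leaves = dd["ivl"]
        # contiguous leaf runs belong to the same cluster after a valid cut
        start = 0
        for i in range(1, len(leaves) + 1):
            if i == len(leaves) or assignment[leaves[i]] != assignment[leaves[start]]:
                x0 = start * 10.0
                ax.add_patch(
                    Rectangle(
                        (x0 + 1, 0),
                        (i - start) * 10.0 - 2,
                        ax.get_ylim()[1] * 0.98,
                        fill=False,
                        edgecolor="#7a8fa6",
                        lw=0.9,
                    )
                )
                start = i
    fig.tight_layout()
    save_figure(fig, path)
    plt.close(fig)
    return Path(path)
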