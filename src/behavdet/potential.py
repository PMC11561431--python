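"""Effect sizes and the Potential for Change Index (PCI).

For each determinant (item) and each determinant cluster, the association
with dichotomized intention is expressed as Cohen's d: the standardized
difference between the mean score of the neutral/negative-intention group
and the positive-intention group.  With scales harmonized so that 1 is the
favorable pole, d is positive when positive-intention respondents score
more favorably (lower).

The PCI combines room for improvement with association strength:

    PCI = |1 - mean| * d**2

where ``mean`` is the full-sample mean score (scale 1..5).  PCI is 0 when
the mean already sits at the favorable pole or when the determinant is
unrelated to intention; d is squared to penalize weak associations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._plotutils import save_figure

__all__ = [
    "cohens_d",
    "mean_ci",
    "compute_pci",
    "change_potential_table",
    "plot_ciber",
]


def cohens_d(scores, positive) -> Tuple[float, Tuple[float, float]]:
    """Cohen's d between the intention groups, with a 95% CI.

    ``d = (mean_neutral_negative - mean_positive) / s_pooled`` with the
    pooled sample SD; the CI uses the large-sample normal approximation
    ``SE(d) = sqrt(1/n1 + 1/n2 + d^2 / (2 (n1 + n2)))``.

    Raises ``ValueError`` if either group has fewer than 2 members or the
    pooled SD is zero.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if scores.shape != positive.shape:
        raise ValueError("scores and group indicator must align")
    pos = scores[positive]
    neg = scores[~positive]
    n1, n2 = len(neg), len(pos)
    if n1 < 2 or n2 < 2:
        raise ValueError("both intention groups need at least 2 members")
    s1, s2 = neg.var(ddof=1), pos.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    d = (neg.mean() - pos.mean()) / pooled
    se = np.sqrt(1.0 / n1 + 1.0 / n2 + d**2 / (2.0 * (n1 + n2)))
    z = stats.norm.ppf(0.975)
    return float(d), (float(d - z * se), float(d + z * se))


def mean_ci(scores, confidence: float = 0.95) -> Tuple[float, Tuple[float, float]]:
    """Sample mean with a t-based confidence interval."""
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 2:
        raise ValueError("mean_ci needs at least 2 observations")
    m = float(scores.mean())
    sem = scores.std(ddof=1) / np.sqrt(n)
    half = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1) * sem)
    return m, (m - half, m + half)


def compute_pci(mean: float, d: float) -> float:
    """``PCI = |1 - mean| * d**2`` for a mean on the 1..5 scale."""
    if not (1.0 <= mean <= 5.0):
        raise ValueError(f"mean must lie on the 1..5 scale, got {mean}")
    return float(abs(1.0 - mean) * d**2)


def _record(entity: str, level: str, cluster, scores: np.ndarray, positive: np.ndarray) -> dict:
    mean, _ = mean_ci(scores)
    sd = float(np.asarray(scores, float).std(ddof=1))
    mp, (mp_lo, mp_hi) = mean_ci(scores[positive])
    mn, (mn_lo, mn_hi) = mean_ci(scores[~positive])
    d, (d_lo, d_hi) = cohens_d(scores, positive)
    return {
        "entity": entity,
        "level": level,
        "cluster": cluster,
        "mean": mean,
        "sd": sd,
        "mean_pos": mp,
        "mean_pos_lo": mp_lo,
        "mean_pos_hi": mp_hi,
        "mean_neg": mn,
        "mean_neg_lo": mn_lo,
        "mean_neg_hi": mn_hi,
        "d": d,
        "d_lo": d_lo,
        "d_hi": d_hi,
        "pci": compute_pci(mean, d),
    }


def change_potential_table(
    data,
    positive,
    assignment: Dict[str, int],
) -> pd.DataFrame:
    """Determinant-selection table: one record per item and per cluster.

    The cluster score of a respondent is the mean of the member items.
    Within each cluster, item records are sorted by PCI descending with the
    cluster record last, mirroring the conventional presentation.
    """
    from .io import ResponseMatrix

    df = data.data if isinstance(data, ResponseMatrix) else pd.DataFrame(data)
    positive = np.asarray(positive, dtype=bool)
    clusters: Dict[int, list] = {}
    for item, cid in assignment.items():
        clusters.setdefault(cid, []).append(item)
    blocks = []
    for cid in sorted(clusters):
        items = clusters[cid]
        item_rows = [
            _record(it, "item", cid, df[it].to_numpy(float), positive)
            for it in items
        ]
        item_rows.sort(key=lambda r: (-r["pci"], r["entity"]))
        cluster_scores = df[items].mean(axis=1).to_numpy(float)
        item_rows.append(
            _record(f"C{cid}", "cluster", cid, cluster_scores, positive)
        )
        blocks.extend(item_rows)
    return pd.DataFrame(blocks)


def plot_ciber(
    data,
    positive,
    entities: Dict[str, Sequence[str]],
    path: Union[str, Path],
    order: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> Path:
    """CIBER-style two-panel plot.

    Left panel: per entity, jittered respondent scores colored by intention
    group (green = positive, purple = neutral/negative) with the 95% CIs of
    the two group means drawn as diamonds.  Right panel: the 95% CI of
    Cohen's d.  ``entities`` maps an entity name to the item columns whose
    per-respondent mean is its score (a single column for item-level plots).
    The jitter stream is seeded, so output is reproducible.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .io import ResponseMatrix

    df = data.data if isinstance(data, ResponseMatrix) else pd.DataFrame(data)
    positive = np.asarray(positive, dtype=bool)
    if not entities:
        raise ValueError("entities must be nonempty")
    names = list(order) if order is not None else list(entities)
    rng = np.random.default_rng(seed)

    fig, (ax_l, ax_r) = plt.subplots(
        1, 2, figsize=(9, max(2.5, 0.5 * len(names))),
        gridspec_kw={"width_ratios": [3, 1]}, sharey=True,
    )
    ypos = {name: len(names) - i for i, name in enumerate(names)}
    sub = min(1.0, 400 / len(df))  # thin the dot cloud for large samples
    for name in names:
        cols = list(entities[name])
        scores = df[cols].mean(axis=1).to_numpy(float)
        y = ypos[name]
        keep = rng.random(len(scores)) < sub
        jitter = rng.uniform(-0.22, 0.22, size=keep.sum())
        colors = np.where(positive[keep], "#2d8a4e", "#6b3fa0")
        ax_l.scatter(scores[keep] + rng.uniform(-0.08, 0.08, keep.sum()),
                     np.full(keep.sum(), y) + jitter,
                     s=4, c=colors, alpha=0.25, linewidths=0)
        _, (p_lo, p_hi) = mean_ci(scores[positive])
        _, (n_lo, n_hi) = mean_ci(scores[~positive])
        ax_l.plot([p_lo, p_hi], [y + 0.12] * 2, color="#2d8a4e", lw=3)
        ax_l.plot([n_lo, n_hi], [y - 0.12] * 2, color="#6b3fa0", lw=3)
        d, (d_lo, d_hi) = cohens_d(scores, positive)
        ax_r.plot([d_lo, d_hi], [y, y], color="#333333", lw=2)
        ax_r.plot([d], [y], "D", color="#333333", ms=4)
    ax_l.set_yticks([ypos[n] for n in names])
    ax_l.set_yticklabels(names, fontsize=7)
    ax_l.set_xlim(0.5, 5.5)
    ax_l.set_xlabel("score (1 = favorable)")
    ax_r.axvline(0, color="grey", lw=0.5)
    ax_r.set_xlabel("Cohen's d (95% CI)")
    fig.tight_layout()
    save_figure(fig, path)
    plt.close(fig)
    return Path(path)
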