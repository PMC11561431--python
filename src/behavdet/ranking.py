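"""Random-forest screening of intention determinants.

Fits a bootstrap ensemble of classification trees to the dichotomized
intention outcome and ranks predictors by permutation importance measured
as the increase in the probability of misclassification (pmc) on
out-of-bag respondents — the classic Breiman importance, reported in error-
rate units.  Model quality is summarized by out-of-bag pmc, sensitivity,
specificity and AUC.

The ensemble is built tree-by-tree from :class:`sklearn.tree.
DecisionTreeClassifier` so that each tree's out-of-bag index set is
available for the importance computation and for honest out-of-bag
performance estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from ._plotutils import save_figure
from .io import ResponseMatrix

__all__ = [
    "RankingConfig",
    "ForestFit",
    "ImportanceRanking",
    "SingleClassError",
    "fit_forest",
    "permutation_importance",
    "select_determinants",
    "plot_vir",
]


class SingleClassError(ValueError):
    """The outcome contains a single class; a classifier cannot be fit."""


@dataclass(frozen=True)
class RankingConfig:
    """Forest hyperparameters and the determinant-selection cut.

    ``predictors_per_split="auto"`` uses floor(sqrt(p)), the convention of
    the classical random-forest implementations.  ``top_k`` is the number of
    top-ranked predictors selected as determinants (default 20).
    """

    n_trees: int = 1000
    predictors_per_split: Union[int, str] = "auto"
    top_k: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 100:
            raise ValueError("n_trees must be >= 100")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.predictors_per_split != "auto" and int(self.predictors_per_split) < 1:
            raise ValueError("predictors_per_split must be 'auto' or >= 1")


@dataclass
class ForestFit:
    """A fitted bootstrap tree ensemble with out-of-bag bookkeeping."""

    trees: List[DecisionTreeClassifier]
    oob_indices: List[np.ndarray]
    X: np.ndarray
    y: np.ndarray                # boolean, True = positive intention
    feature_names: List[str]
    config: RankingConfig
    oob_prob: np.ndarray = field(init=False)
    metrics: dict = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.y)
        votes_pos = np.zeros(n)
        votes_tot = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_indices):
            if oob.size == 0:
                continue
            pred = tree.predict(self.X[oob])
            votes_pos[oob] += pred
            votes_tot[oob] += 1
        covered = votes_tot > 0
        prob = np.full(n, np.nan)
        prob[covered] = votes_pos[covered] / votes_tot[covered]
        self.oob_prob = prob
        # majority vote; exact ties go to the neutral/negative class
        pred_pos = prob[covered] > 0.5
        y_cov = self.y[covered]
        tp = int(np.sum(pred_pos & y_cov))
        tn = int(np.sum(~pred_pos & ~y_cov))
        fp = int(np.sum(pred_pos & ~y_cov))
        fn = int(np.sum(~pred_pos & y_cov))
        n_cov = tp + tn + fp + fn
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        pmc = (fp + fn) / n_cov
        auc = float(roc_auc_score(y_cov, prob[covered]))
        self.metrics = {
            "pmc": float(pmc),
            "sens": float(sens),
            "spec": float(spec),
            "auc": auc,
            "prevalence": float(np.mean(y_cov)),
            "n_oob_covered": int(n_cov),
        }


@dataclass
class ImportanceRanking:
    """Ordered (item, delta-pmc) list with the forest's quality metrics."""

    entries: pd.DataFrame        # columns: item, importance, rank
    metrics: dict

    def __post_init__(self) -> None:
        e = self.entries
        if not (e["importance"].values[:-1] >= e["importance"].values[1:] - 1e-15).all():
            raise ValueError("entries must be sorted by importance descending")

    @property
    def items(self) -> List[str]:
        return list(self.entries["item"])

    def elbow(self) -> int:
        """Rank before the largest relative importance drop (advisory only)."""
        imp = self.entries["importance"].to_numpy()
        pos = np.clip(imp, 1e-12, None)
        drops = (pos[:-1] - pos[1:]) / pos[:-1]
        return int(np.argmax(drops) + 1)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.entries.to_csv(path, index=False)


def _as_design(matrix, outcome):
    """Accept a ResponseMatrix, or an (X DataFrame, y boolean) pair."""
    if isinstance(matrix, ResponseMatrix):
        Xdf = matrix.predictor_frame()
        y = matrix.positive.to_numpy() if outcome is None else np.asarray(outcome, bool)
    else:
        Xdf = pd.DataFrame(matrix)
        if outcome is None:
            raise ValueError("outcome is required when matrix is a plain table")
        y = np.asarray(outcome, dtype=bool)
    if Xdf.shape[1] == 0:
        raise ValueError("no predictors available")
    if Xdf.isna().any().any():
        raise ValueError("predictor matrix contains missing values")
    return Xdf, y


def fit_forest(
    matrix,
    outcome=None,
    config: Optional[RankingConfig] = None,
) -> ForestFit:
    """Fit the bootstrap tree ensemble.

    Parameters
    ----------
    matrix
        A :class:`ResponseMatrix` (its predictor frame and dichotomized
        outcome are used) or a plain respondent-by-predictor table.
    outcome
        Boolean positive-intention indicator per respondent; required when
        ``matrix`` is a plain table.
    config
        Hyperparameters; defaults to :class:`RankingConfig()`.
    """
    config = config or RankingConfig()
    Xdf, y = _as_design(matrix, outcome)
    if len(np.unique(y)) < 2:
        raise SingleClassError("outcome has a single class")
    X = Xdf.to_numpy(dtype=float)
    n, p = X.shape
    max_features = (
        max(1, int(np.sqrt(p)))
        if config.predictors_per_split == "auto"
        else int(config.predictors_per_split)
    )
    rng = np.random.default_rng(config.seed)
    all_rows = np.arange(n)
    trees, oobs = [], []
    for _ in range(config.n_trees):
        boot = rng.integers(0, n, n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[boot] = True
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        oobs.append(all_rows[~in_bag])
    return ForestFit(
        trees=trees,
        oob_indices=oobs,
        X=X,
        y=y,
        feature_names=list(Xdf.columns),
        config=config,
    )


def permutation_importance(
    fit: ForestFit,
    seed: Optional[int] = None,
) -> ImportanceRanking:
    """Breiman out-of-bag permutation importance in pmc units.

    For each tree, the error rate on its out-of-bag respondents is compared
    with the error rate after permuting one predictor's out-of-bag values;
    the importance of the predictor is the mean increase over trees.  Ties
    in the resulting ranking break by item id ascending.
    """
    rng = np.random.default_rng(fit.config.seed if seed is None else seed)
    p = fit.X.shape[1]
    delta = np.zeros(p)
    n_used = 0
    for tree, oob in zip(fit.trees, fit.oob_indices):
        if oob.size < 2:
            continue
        Xo = fit.X[oob]
        yo = fit.y[oob]
        e0 = np.mean(tree.predict(Xo) != yo)
        Xp = Xo.copy()
        for j in range(p):
            original = Xp[:, j].copy()
            Xp[:, j] = original[rng.permutation(oob.size)]
            delta[j] += np.mean(tree.predict(Xp) != yo) - e0
            Xp[:, j] = original
        n_used += 1
    if n_used == 0:
        raise ValueError("no tree had out-of-bag rows")
    delta /= n_used
    entries = pd.DataFrame({"item": fit.feature_names, "importance": delta})
    entries = entries.sort_values(
        by=["importance", "item"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    entries["rank"] = np.arange(1, p + 1)
    return ImportanceRanking(entries=entries, metrics=dict(fit.metrics))


def select_determinants(ranking: ImportanceRanking, top_k: int) -> List[str]:
    """The top-k ranked items, order preserved."""
    p = len(ranking.entries)
    if not (1 <= top_k <= p):
        raise ValueError(f"top_k must lie in 1..{p}, got {top_k}")
    return ranking.items[:top_k]


def plot_vir(
    ranking: ImportanceRanking,
    path: Union[str, Path],
    top_k: Optional[int] = None,
) -> Path:
    """Dot chart of the variable importance ranking (most important on top)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = ranking.entries
    if entries.empty:
        raise ValueError("ranking is empty")
    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.25 * len(entries))))
    ypos = np.arange(len(entries))[::-1]
    ax.plot(entries["importance"], ypos, "o", color="#1f5fa8", ms=4)
    ax.set_yticks(ypos)
    ax.set_yticklabels(entries["item"], fontsize=7)
    ax.set_xlabel("Increase in pmc")
    ax.set_xlim(left=min(0.0, float(entries["importance"].min())))
    ax.axvline(0.0, color="grey", lw=0.5)
    if top_k is not None and 0 < top_k < len(entries):
        ax.axhline(ypos[top_k - 1] - 0.5, color="orange", lw=0.8, ls="--")
    ax.set_title("Variable importance ranking")
    fig.tight_layout()
    save_figure(fig, path)
    plt.close(fig)
    return Path(path)
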