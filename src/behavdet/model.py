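"""Model-style front end for the determinant analysis.

`DeterminantAnalysis` wraps a harmonized response matrix; `fit()` runs the
four analysis stages — descriptives, random-forest importance screening,
Spearman-dissimilarity clustering, and change-potential scoring — and
returns a `DeterminantAnalysisResults` carrying the estimates with a
statsmodels-flavoured `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import clustering, io, potential, ranking

__all__ = ["DeterminantAnalysis", "DeterminantAnalysisResults"]


class DeterminantAnalysis:
    """Determinant analysis of a dichotomized behavioral intention.

    Parameters
    ----------
    responses
        A harmonized :class:`behavdet.io.ResponseMatrix`.

    Examples
    --------
    >>> from behavdet import synthetic
    >>> ds = synthetic.generate(synthetic.strong_signal_design(seed=7))
    >>> res = DeterminantAnalysis(ds.responses).fit(top_k=9, n_trees=200)
    >>> res.solution_.k >= 2
    True
    """

    def __init__(self, responses: io.ResponseMatrix):
        self.responses = responses

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, codebook: io.Codebook) -> "DeterminantAnalysis":
        return cls(io.ResponseMatrix(data=data, codebook=codebook))

    @classmethod
    def from_csv(
        cls,
        path: Union[str, Path],
        codebook: io.Codebook,
        sep: str = ",",
    ) -> "DeterminantAnalysis":
        return cls(io.read_responses(path, codebook, sep=sep))

    def fit(
        self,
        top_k: int = 20,
        n_trees: int = 1000,
        predictors_per_split: Union[int, str] = "auto",
        n_clusters: Optional[int] = None,
        seed: int = 0,
    ) -> "DeterminantAnalysisResults":
        """Run the full four-stage analysis.

        Parameters
        ----------
        top_k
            Number of top-ranked predictors selected as determinants.
        n_trees
            Trees in the bootstrap ensemble (>= 100).
        n_clusters
            Fixed number of determinant clusters; None applies the
            compactness/separation rule.
        seed
            Drives the bootstrap, the permutation streams and plot jitter.
        """
        matrix = self.responses
        descriptives = io.describe(matrix)
        config = ranking.RankingConfig(
            n_trees=n_trees,
            predictors_per_split=predictors_per_split,
            top_k=top_k,
            seed=seed,
        )
        forest = ranking.fit_forest(matrix, config=config)
        vir = ranking.permutation_importance(forest)
        determinants = ranking.select_determinants(vir, top_k)
        # clustering runs on original likert items only (one-hot demographic
        # indicators, if selected, are not clusterable questionnaire items)
        likert = [d for d in determinants if d in matrix.data.columns]
        solution = clustering.cluster_determinants(matrix, likert, k=n_clusters)
        table = potential.change_potential_table(
            matrix, matrix.positive, solution.assignment
        )
        return DeterminantAnalysisResults(
            model=self,
            descriptives_=descriptives,
            ranking_=vir,
            determinants_=determinants,
            solution_=solution,
            change_potential_=table,
            seed=seed,
        )


@dataclass
class DeterminantAnalysisResults:
    """Fitted determinant analysis: rankings, clusters, change potential."""

    model: DeterminantAnalysis
    descriptives_: pd.DataFrame
    ranking_: ranking.ImportanceRanking
    determinants_: list
    solution_: clustering.ClusterSolution
    change_potential_: pd.DataFrame
    seed: int

    @property
    def metrics_(self) -> dict:
        return self.ranking_.metrics

    def summary(self) -> str:
        m = self.metrics_
        matrix = self.model.responses
        lines = [
            "      Determinant analysis of behavioral intention",
            "=" * 60,
            f"No. respondents:      {matrix.n_respondents:>6}"
            f"    Positive intention: {matrix.positive.mean():6.1%}",
            f"Forest (OOB):  pmc {m['pmc']:.3f}  sens {m['sens']:.3f}  "
            f"spec {m['spec']:.3f}  AUC {m['auc']:.3f}",
            f"Determinants selected: {len(self.determinants_):>4}"
            f"    Clusters (k): {self.solution_.k}   CCC {self.solution_.ccc:.3f}",
            "-" * 60,
            "Top determinants (increase in pmc):",
        ]
        for _, row in self.ranking_.entries.head(len(self.determinants_)).iterrows():
            lines.append(f"  {row['rank']:>3}. {row['item']:<28} {row['importance']:+.4f}")
        lines.append("-" * 60)
        lines.append("Change potential (cluster level):")
        lines.append(f"  {'cluster':<9}{'mean':>7}{'sd':>7}{'d':>7}{'PCI':>7}")
        ctab = self.change_potential_
        for _, row in ctab[ctab["level"] == "cluster"].iterrows():
            lines.append(
                f"  {row['entity']:<9}{row['mean']:>7.2f}{row['sd']:>7.2f}"
                f"{row['d']:>7.2f}{row['pci']:>7.2f}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)

    # -- plots --------------------------------------------------------

    def plot_vir(self, path: Union[str, Path]) -> Path:
        return ranking.plot_vir(self.ranking_, path, top_k=len(self.determinants_))

    def plot_dendrogram(self, path: Union[str, Path]) -> Path:
        return clustering.plot_dendrogram(
            self.solution_.dendrogram, path, k=self.solution_.k
        )

    def plot_ciber_items(self, path: Union[str, Path]) -> Path:
        matrix = self.model.responses
        likert = [d for d in self.determinants_ if d in matrix.data.columns]
        entities = {item: [item] for item in likert}
        return potential.plot_ciber(
            matrix, matrix.positive, entities, path, order=likert, seed=self.seed
        )

    def plot_ciber_clusters(self, path: Union[str, Path]) -> Path:
        matrix = self.model.responses
        members: dict = {}
        for item, cid in self.solution_.assignment.items():
            members.setdefault(f"C{cid}", []).append(item)
        order = sorted(members, key=lambda c: int(c[1:]))
        return potential.plot_ciber(
            matrix, matrix.positive, members, path, order=order, seed=self.seed
        )
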