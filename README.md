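# behavdet

Determinant analysis for health-behavior questionnaires: find out *which*
beliefs and attitudes drive a behavioral intention, *how* they group
together, and *where* an intervention has the most room to move the
population.

The package implements the pipeline used in determinant studies of
participation in (digital, self-led) contact tracing: a cross-sectional
5-point Likert questionnaire is screened with a random forest for
predictors of a dichotomized intention outcome, the selected determinants
are grouped by hierarchical clustering on rank-correlation dissimilarity,
and candidate behavior-change targets are prioritized with Cohen's *d* and
the Potential for Change Index, visualized in CIBER-style plots.  A
synthetic questionnaire generator with planted block structure makes every
stage testable against known ground truth.

## The method

Given a respondent × item table (harmonized so 1 is always the most
favorable answer) and an intention item dichotomized into *positive*
("very willing"/"willing") versus *neutral/negative*:

1. **Descriptives** — per-item mean/SD (sample convention) and level
   proportions; complete-case only, dropped respondents are counted.
2. **Importance screening** — a bootstrap ensemble of classification trees
   predicts the dichotomized intention from all items.  Each predictor's
   importance is the mean increase in out-of-bag misclassification
   probability (Δpmc) when its out-of-bag values are permuted; model
   quality is reported as out-of-bag pmc, sensitivity, specificity and
   AUC.  The top-*k* predictors (default 20) are the determinants.
3. **Clustering** — pairwise dissimilarity `D = 1 − |ρ|` (Spearman, midrank
   ties) over the determinants; average-linkage (UPGMA) agglomeration;
   goodness of fit via the cophenetic correlation coefficient.  The number
   of clusters minimizes `compactness(k) − separation(k)`, where
   compactness is the largest within-cluster `D` and separation the
   smallest between-cluster `D` over cuts `k = 2..p−1`.
4. **Change potential** — per determinant and per cluster (cluster score =
   per-respondent mean of member items): Cohen's
   `d = (mean_neutral/negative − mean_positive) / s_pooled` with a
   normal-approximation 95% CI, t-based CIs for group means, and

   `PCI = |1 − mean| · d²`

   — room for improvement times squared association strength.  PCI is 0
   when the mean is already at the favorable pole or `d = 0`.

## Worked example

```python
import behavdet as bd
from behavdet import synthetic

# study-shaped synthetic data: 3000 respondents, 20 signal items in 9
# correlated blocks plus 40 noise items, 76% positive intention
ds = synthetic.generate(synthetic.paper_like_design(seed=1, n_respondents=3000))
res = bd.DeterminantAnalysis(ds.responses).fit(top_k=20, n_trees=300, seed=1)
print(res.summary())
```

```
      Determinant analysis of behavioral intention
============================================================
No. respondents:        3000    Positive intention:  76.0%
Forest (OOB):  pmc 0.196  sens 0.987  spec 0.225  AUC 0.856
Determinants selected:   20    Clusters (k): 9   CCC 0.999
------------------------------------------------------------
Top determinants (increase in pmc):
    1. q08                          +0.0117
    2. q05                          +0.0081
    3. q04                          +0.0067
...
Change potential (cluster level):
  cluster     mean     sd      d    PCI
  C1          2.40   1.11   0.64   0.58
  C2          2.40   0.95   0.70   0.69
...
```

Reading the output: the forest separates positive from neutral/negative
intention well (out-of-bag AUC 0.86, above the conventional "good" mark of
0.8); the twenty planted signal items occupy the top twenty importance
ranks; the compactness/separation rule recovers the nine planted blocks
(CCC 0.999 means the dendrogram reproduces the observed dissimilarities
almost exactly).  Cluster C2 combines moderate room for improvement
(mean 2.40 on the 1–5 scale) with the strongest intention association
(d = 0.70), giving it the highest change potential (PCI = 0.69).

`res.plot_vir(...)`, `res.plot_dendrogram(...)`, `res.plot_ciber_items(...)`
and `res.plot_ciber_clusters(...)` write the corresponding figures.

The same analysis is available from the shell:

```sh
behavdet simulate --seed 1 --out data.csv --truth truth.json
behavdet rank --data data.csv --codebook data.codebook.json \
    --top-k 20 --trees 1000 --seed 1 --out vir.csv --metrics metrics.json
behavdet cluster --data data.csv --codebook data.codebook.json \
    --items vir.csv --out clusters.json --curve curve.csv
behavdet potential --data data.csv --codebook data.codebook.json \
    --clusters clusters.json --out change_potential.csv
```

or as one cached, manifest-tracked run: `behavdet run --config config.yaml`.

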