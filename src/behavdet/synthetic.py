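"""Synthetic Likert questionnaire generator with planted structure.

Generates respondent-by-item tables in which items form correlated blocks
(one latent Gaussian factor per block, discretized to a 5-point scale by
fixed thresholds) and a dichotomous behavioral-intention outcome is driven
by a linear combination of the block factors.  Because the block membership,
factor loadings and intention effects are known, every downstream stage —
importance screening, clustering, effect sizes — can be tested against
ground truth.

Model
-----
For respondent ``r`` and an item in block ``k`` with loading ``lambda_k``::

    z = lambda_k * f_k + sqrt(1 - lambda_k**2) * eps + shift
    score = 1 + #{thresholds below z}          (an integer 1..5)

with ``f_k ~ N(0,1)`` independent across blocks and ``eps ~ N(0,1)``.
Noise items use ``z = eps + shift``.  The intention latent is

    L = -(sum_k effect_k * f_k) + eps_L

so that respondents with *favorable* item scores (low, since 1 is the
favorable pole) have *high* L; intention is positive when L exceeds the
empirical cut that yields the target positive rate.  A negative ``shift``
produces the right-skewed score distributions typical of acceptability
questionnaires.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import Codebook, ResponseMatrix

__all__ = [
    "SyntheticDesign",
    "SyntheticDataset",
    "DesignError",
    "generate",
    "threshold_for_rate",
    "effect_for_target_d",
    "paper_like_design",
    "strong_signal_design",
    "block_design",
]


class DesignError(ValueError):
    """A design field violates its constraints; the message names the field."""


def _rng_for(seed: int, stage: str) -> np.random.Generator:
    """Named child stream: same seed + stage name -> same stream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the planted-structure generator.

    Parameters
    ----------
    n_respondents
        Sample size.
    items_per_cluster
        Number of items in each correlated block (each >= 2 unless the block
        is an intentional singleton; >= 1 enforced, length defines the true K).
    n_noise_items
        Pure-noise filler items with no block membership and no intention
        effect.
    loading
        Factor loading in (0, 1), scalar or per cluster; the latent
        within-block correlation is ``loading**2``.
    effect
        Contribution of each block factor to the intention latent, scalar or
        per cluster; 0 means the block is unrelated to intention.
    target_positive_rate
        Desired share of positive-intention respondents, in (0, 1).
    thresholds
        Four ascending cut points on the latent scale mapping z to 1..5.
    latent_shift
        Added to every item latent before discretization; negative values
        skew scores toward the favorable (low) end.
    seed
        Master seed; identical (seed, design) gives a bit-identical dataset.
    """

    n_respondents: int = 3000
    items_per_cluster: Tuple[int, ...] = (2, 3, 2, 1, 4, 2, 2, 1, 3)
    n_noise_items: int = 40
    loading: Union[float, Tuple[float, ...]] = 0.8
    effect: Union[float, Tuple[float, ...]] = (
        0.5, 0.9, 0.55, 1.0, 0.6, 0.7, 0.45, 0.55, 0.8
    )
    target_positive_rate: float = 0.76
    thresholds: Tuple[float, float, float, float] = (-1.2, -0.4, 0.4, 1.2)
    latent_shift: float = -0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 2:
            raise DesignError("n_respondents must be >= 2")
        if len(self.items_per_cluster) < 1:
            raise DesignError("items_per_cluster must be nonempty")
        if any(int(m) < 1 for m in self.items_per_cluster):
            raise DesignError("items_per_cluster entries must be >= 1")
        if self.n_noise_items < 0:
            raise DesignError("n_noise_items must be >= 0")
        for lam in self.loadings:
            if not (0.0 < lam < 1.0):
                raise DesignError("loading must lie in (0, 1)")
        if not (0.0 < self.target_positive_rate < 1.0):
            raise DesignError("target_positive_rate must lie in (0, 1)")
        t = self.thresholds
        if len(t) != 4 or any(t[i] >= t[i + 1] for i in range(3)):
            raise DesignError("thresholds must be 4 strictly ascending values")
        if len(self.effects) != self.n_clusters:
            raise DesignError("effect must be scalar or one value per cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.items_per_cluster)

    @property
    def loadings(self) -> Tuple[float, ...]:
        if np.ndim(self.loading) == 0:
            return (float(self.loading),) * self.n_clusters
        if len(self.loading) != self.n_clusters:
            raise DesignError("loading must be scalar or one value per cluster")
        return tuple(float(v) for v in self.loading)

    @property
    def effects(self) -> Tuple[float, ...]:
        if np.ndim(self.effect) == 0:
            return (float(self.effect),) * self.n_clusters
        return tuple(float(v) for v in self.effect)

    @property
    def n_items(self) -> int:
        return int(sum(self.items_per_cluster)) + self.n_noise_items


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    responses: ResponseMatrix
    true_assignment: Dict[str, str]  # item -> "c1".."cK" or "noise"
    true_effects: Dict[str, float]   # cluster -> intention effect
    realized_positive_rate: float
    design: SyntheticDesign

    @property
    def signal_items(self) -> list:
        return [i for i, c in self.true_assignment.items() if c != "noise"]

    @property
    def noise_items(self) -> list:
        return [i for i, c in self.true_assignment.items() if c == "noise"]


def threshold_for_rate(latent_scores, rate: float) -> float:
    """Cut point such that the given fraction of scores lies strictly above it.

    The cut is the midpoint between the two bracketing order statistics, so
    for continuous scores the realized fraction matches ``rate`` to within
    1/n.  A constant vector has no such cut and raises ``ValueError``.
    """
    s = np.sort(np.asarray(latent_scores, dtype=float))
    n = s.size
    if n == 0:
        raise ValueError("latent_scores must be nonempty")
    if not (0.0 < rate < 1.0):
        raise ValueError("rate must lie in (0, 1)")
    if s[0] == s[-1]:
        raise ValueError("degenerate latent_scores: all values equal")
    m = int(round(n * rate))
    m = min(max(m, 1), n - 1)
    return 0.5 * (s[n - m - 1] + s[n - m])


def _discretize(z: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    return 1 + np.digitize(z, np.asarray(thresholds, dtype=float))


def generate(design: SyntheticDesign) -> SyntheticDataset:
    """Draw one dataset from the planted-structure model.

    Deterministic: the same (seed, design) yields a bit-identical dataset.
    """
    n = design.n_respondents
    K = design.n_clusters
    rng_items = _rng_for(design.seed, "items")
    rng_intent = _rng_for(design.seed, "intention")

    factors = rng_items.standard_normal((n, K))
    columns: dict = {}
    assignment: Dict[str, str] = {}
    idx = 0
    for k, (m, lam) in enumerate(zip(design.items_per_cluster, design.loadings)):
        for _ in range(int(m)):
            idx += 1
            name = f"q{idx:02d}"
            z = (
                lam * factors[:, k]
                + np.sqrt(1.0 - lam**2) * rng_items.standard_normal(n)
                + design.latent_shift
            )
            columns[name] = _discretize(z, design.thresholds)
            assignment[name] = f"c{k + 1}"
    for _ in range(design.n_noise_items):
        idx += 1
        name = f"q{idx:02d}"
        z = rng_items.standard_normal(n) + design.latent_shift
        columns[name] = _discretize(z, design.thresholds)
        assignment[name] = "noise"

    effects = np.asarray(design.effects)
    latent = -(factors @ effects) + rng_intent.standard_normal(n)
    cut = threshold_for_rate(latent, design.target_positive_rate)
    positive = latent > cut
    columns["intention"] = _intention_levels(latent, positive)

    df = pd.DataFrame(columns, index=pd.RangeIndex(1, n + 1, name="respondent_id"))
    codebook = _synthetic_codebook(list(assignment))
    matrix = ResponseMatrix(data=df, codebook=codebook)
    return SyntheticDataset(
        responses=matrix,
        true_assignment=assignment,
        true_effects={f"c{k + 1}": float(e) for k, e in enumerate(effects)},
        realized_positive_rate=float(positive.mean()),
        design=design,
    )


def _intention_levels(latent: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Spread the dichotomous intention back over 5 ordered levels.

    Positive respondents split at their median latent into "very willing"
    (1) and "willing" (2); the rest split into neutral/unwilling/very
    unwilling (3/4/5) by latent terciles, so that dichotomizing the 5-level
    variable reproduces the planted positive set exactly.
    """
    raw = np.empty(latent.size, dtype=int)
    pos_latent = latent[positive]
    if pos_latent.size:
        med = np.median(pos_latent)
        raw[positive] = np.where(latent[positive] > med, 1, 2)
    neg = ~positive
    neg_latent = latent[neg]
    if neg_latent.size:
        t1, t2 = np.quantile(neg_latent, [2 / 3, 1 / 3])
        neg_raw = np.full(neg_latent.size, 4)
        neg_raw[neg_latent > t1] = 3
        neg_raw[neg_latent <= t2] = 5
        raw[neg] = neg_raw
    return raw


def _synthetic_codebook(item_names: list) -> Codebook:
    records = [
        {
            "id": name,
            "label": f"synthetic item {name}",
            "role": "predictor",
            "scale": "likert5",
            "reverse_coded": False,
        }
        for name in item_names
    ]
    records.append(
        {
            "id": "intention",
            "label": "intention to participate",
            "role": "outcome",
            "scale": "likert5",
            "reverse_coded": False,
        }
    )
    return Codebook.from_records(records)


def effect_for_target_d(
    target_d: float,
    loading: float = 0.8,
    thresholds: Sequence[float] = (-1.2, -0.4, 0.4, 1.2),
    latent_shift: float = -0.55,
    positive_rate: float = 0.76,
    n_calibration: int = 400_000,
    seed: int = 20_240_101,
) -> float:
    """Intention effect that yields a given Cohen's d on a single item.

    Uses a large common-random-numbers Monte-Carlo estimate of the
    effect -> d mapping (which is smooth and increasing) and solves for the
    root with Brent's method.  Deterministic for fixed arguments.
    """
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n_calibration)
    eps_item = rng.standard_normal(n_calibration)
    eps_l = rng.standard_normal(n_calibration)
    score = _discretize(
        loading * f + np.sqrt(1 - loading**2) * eps_item + latent_shift,
        thresholds,
    ).astype(float)

    def d_of(effect: float) -> float:
        latent = -effect * f + eps_l
        cut = np.quantile(latent, 1.0 - positive_rate)
        pos = latent > cut
        a, b = score[~pos], score[pos]
        sp = np.sqrt(
            ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
            / (a.size + b.size - 2)
        )
        return float((a.mean() - b.mean()) / sp)

    return float(brentq(lambda e: d_of(e) - target_d, 1e-3, 8.0, xtol=1e-4))


# ---------------------------------------------------------------------------
# Stock designs used throughout the test-bench
# ---------------------------------------------------------------------------

def paper_like_design(seed: int = 0, n_respondents: int = 3000) -> SyntheticDesign:
    """Design emulating the study's structure: ~3000 respondents, 20 signal
    items in 9 blocks (two of them singletons), 40 noise fillers, 76%
    positive intention."""
    return SyntheticDesign(n_respondents=n_respondents, seed=seed)


def strong_signal_design(seed: int = 0, n_respondents: int = 2000) -> SyntheticDesign:
    """Three well-separated signal blocks with strong intention effects and
    noise fillers; the regime where the forest screen should be clearly
    'good' (out-of-bag AUC at or above 0.8)."""
    return SyntheticDesign(
        n_respondents=n_respondents,
        items_per_cluster=(3, 3, 3),
        n_noise_items=8,
        loading=0.8,
        effect=(1.0, 1.1, 1.2),
        seed=seed,
    )


def block_design(
    n_clusters: int,
    items_per_cluster: Optional[Sequence[int]] = None,
    n_respondents: int = 1000,
    loading: float = 0.85,
    seed: int = 0,
) -> SyntheticDesign:
    """K well-separated blocks (no noise items) for cluster-recovery checks."""
    if items_per_cluster is None:
        items_per_cluster = (3,) * n_clusters
    return SyntheticDesign(
        n_respondents=n_respondents,
        items_per_cluster=tuple(int(m) for m in items_per_cluster),
        n_noise_items=0,
        loading=loading,
        effect=0.6,
        seed=seed,
    )
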