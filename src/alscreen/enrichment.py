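"""Ranking-enrichment metrics for labeled active/decoy score lists.

Lower scores rank better throughout (docking convention).  ``roc_auc`` is
the Mann–Whitney probability that a random active outscores a random decoy
(ties count one half); ``rie`` is the Robust Initial Enhancement, an
exponentially rank-weighted early-enrichment ratio whose null expectation
under random ranking is 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class LabeledScores:
    """Scores (kcal/mol, lower better) with active/decoy labels."""

    scores: np.ndarray
    is_active: np.ndarray
    ids: np.ndarray | None = None

    @classmethod
    def from_arrays(cls, scores: Sequence[float], labels: Sequence, ids: Sequence[str] | None = None):
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(
            [l if isinstance(l, (bool, np.bool_, int, np.integer)) else str(l).lower() == "active" for l in labels],
            dtype=bool,
        )
        if scores.shape != labels.shape:
            raise ValueError("scores and labels must have equal length")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if labels.all() or not labels.any():
            raise ValueError("need at least one active and one decoy")
        idarr = None if ids is None else np.asarray(ids, dtype=str)
        return cls(scores=scores, is_active=labels, ids=idarr)


def roc_auc(data: LabeledScores) -> float:
    """Probability a random active scores better (lower) than a random decoy."""
    ranks = rankdata(data.scores, method="average")  # low score → low rank
    n_act = int(data.is_active.sum())
    n_dec = len(ranks) - n_act
    r_act = ranks[data.is_active].sum()
    # pairs in which the active ranks worse than a decoy (ties already half)
    u_worse = r_act - n_act * (n_act + 1) / 2
    return float(1 - u_worse / (n_act * n_dec))


def _ranks_best_first(data: LabeledScores) -> np.ndarray:
    """1-based ranks from best score, ties broken by id (or input order)."""
    tiebreak = data.ids if data.ids is not None else np.arange(len(data.scores))
    order = np.lexsort((tiebreak, data.scores))
    ranks = np.empty(len(order), dtype=float)
    ranks[order] = np.arange(1, len(order) + 1)
    return ranks


def rie(data: LabeledScores, alpha: float = 20.0) -> float:
    """Robust Initial Enhancement at exponential weight ``alpha``.

    RIE = [(1/n)·Σ_actives e^(−α·r_i/N)] / [(1/N)·(1−e^(−α)) / (e^(α/N)−1)],
    with ranks r_i from best = 1.  Random rankings give 1 in expectation;
    the metric is invariant to strictly monotone score transforms.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    ranks = _ranks_best_first(data)
    n = int(data.is_active.sum())
    big_n = len(ranks)
    numerator = np.exp(-alpha * ranks[data.is_active] / big_n).sum() / n
    denominator = (1 - np.exp(-alpha)) / (big_n * (np.exp(alpha / big_n) - 1))
    return float(numerator / denominator)


def rie_max(n_actives: int, n_total: int, alpha: float = 20.0) -> float:
    """The analytic RIE maximum: all actives at ranks 1..n."""
    r = np.arange(1, n_actives + 1)
    numerator = np.exp(-alpha * r / n_total).sum() / n_actives
    denominator = (1 - np.exp(-alpha)) / (n_total * (np.exp(alpha / n_total) - 1))
    return float(numerator / denominator)
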