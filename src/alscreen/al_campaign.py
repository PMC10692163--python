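"""Two-tier active-learning campaign orchestration and hit-recall estimation.

The screening campaign alternates oracle scoring with surrogate retraining:
a random seed round, exploratory rounds that pick diverse molecules from the
top fraction of surrogate predictions, and a final greedy round.  The default
schedule expresses the reference protocol — three rounds of 1/2654 of the
library (the first random, the next two diverse from the top ~3.77% of
predictions) and a final greedy round of 3/2654 — as library fractions, so a
desk-scale library runs the same campaign shape as a billion-scale one.

The rescoring campaign drives the slower tier-2 oracle over tier-1 hits:
a Tanimoto<0.4 leader seed set, an iterative surrogate-guided selection
loop, an acid-count-filtered diversity stage and a final relaxed-pool stage.

Hit recall is estimated by bootstrap: the initial uniform random round
calibrates the library-wide hit rate below a score threshold, and percentile
resampling gives a 95% CI for the total number of hits and hence for the
fraction of them the campaign found.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from rdkit import DataStructs

from .chem_core import MoleculeRecord, diverse_subset, ensure_fingerprint, leadlike_filter
from .surrogate import (
    InsufficientDataError,
    SurrogateConfig,
    SurrogateModel,
    train_surrogate,
)
from .synth_library import OracleParams, score_tier1_batch, score_tier2_batch

logger = logging.getLogger(__name__)

#: library fractions of the reference schedule: per-round acquisition
#: 1/2654 (three rounds) + 3/2654 (final), and prediction pool top 100M of
#: 2.654B ≈ 0.0377.
ROUND_FRACTION = 1 / 2654
POOL_FRACTION = 0.0377
DEFAULT_SIMILARITY_THRESHOLD = 0.4


class ScheduleError(ValueError):
    """Raised for schedules that cannot be executed (e.g. over budget)."""


@dataclass(frozen=True)
class RoundSpec:
    """One acquisition round of the screening campaign."""

    acquire_size: int
    pool: str | float = "whole_library"  # or a top fraction of predictions
    selection: str = "random"  # random | greedy | diverse
    threshold: float | None = None  # Tanimoto ceiling for diverse selection
    exclude_scored: bool = True

    def __post_init__(self) -> None:
        if self.acquire_size < 1:
            raise ScheduleError("acquire_size must be >= 1")
        if isinstance(self.pool, float) and not 0 < self.pool <= 1:
            raise ScheduleError("pool fraction must be in (0, 1]")
        if self.selection not in ("random", "greedy", "diverse"):
            raise ScheduleError(f"unknown selection mode: {self.selection!r}")
        if self.selection == "diverse" and self.threshold is None:
            raise ScheduleError("diverse selection requires a similarity threshold")


def default_schedule(library_size: int) -> list[RoundSpec]:
    """The reference four-round schedule rescaled to ``library_size``."""
    per_round = max(1, round(library_size * ROUND_FRACTION))
    final = max(1, round(3 * library_size * ROUND_FRACTION))
    diverse = dict(pool=POOL_FRACTION, selection="diverse", threshold=DEFAULT_SIMILARITY_THRESHOLD)
    return [
        RoundSpec(acquire_size=per_round, pool="whole_library", selection="random"),
        RoundSpec(acquire_size=per_round, **diverse),
        RoundSpec(acquire_size=per_round, **diverse),
        RoundSpec(acquire_size=final, pool=POOL_FRACTION, selection="greedy"),
    ]


@dataclass
class CampaignState:
    """The evolving scored set of a screening campaign."""

    library: Sequence[MoleculeRecord]
    hit_threshold: float
    ledger: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "score", "round"])
    )
    models: list[SurrogateModel | None] = field(default_factory=list)
    round_logs: list[dict] = field(default_factory=list)

    @property
    def scored_ids(self) -> set[str]:
        return set(self.ledger["id"])

    def hits(self, threshold: float | None = None) -> pd.DataFrame:
        thr = self.hit_threshold if threshold is None else threshold
        return self.ledger[self.ledger["score"] < thr]

    def initial_sample_scores(self) -> np.ndarray:
        """Scores of the first (random) round — the recall calibration sample."""
        return self.ledger.loc[self.ledger["round"] == 0, "score"].to_numpy()


def _as_scorer(oracle) -> Callable[[Sequence[MoleculeRecord]], np.ndarray]:
    if isinstance(oracle, OracleParams):
        return lambda records: score_tier1_batch(records, oracle)
    return oracle


def _deterministic_order(indices: np.ndarray, keys: np.ndarray, ids: list[str]) -> np.ndarray:
    """Sort indices by (key, id): score-primary, lexicographic-id tie-break."""
    sub_ids = np.array([ids[i] for i in indices])
    order = np.lexsort((sub_ids, keys[indices]))
    return indices[order]


def select_batch(
    spec: RoundSpec,
    library: Sequence[MoleculeRecord],
    model: SurrogateModel | None,
    scored_ids: set[str],
    seed: int,
    predictions: np.ndarray | None = None,
) -> list[int]:
    """Select the indices of the next acquisition batch.

    ``predictions`` may carry precomputed surrogate predictions over the
    whole library (one per record); otherwise the model is asked.  Returns
    library indices; if the pool is smaller than ``acquire_size`` a shortfall
    warning is issued and the whole pool is returned.
    """
    ids = [r.id for r in library]
    candidates = np.arange(len(library))
    if spec.exclude_scored and scored_ids:
        mask = np.array([i not in scored_ids for i in ids])
        candidates = candidates[mask]
    if len(candidates) == 0:
        raise ScheduleError("selection pool is empty after exclusions")

    needs_model = spec.selection != "random" or spec.pool != "whole_library"
    if needs_model:
        if predictions is None:
            if model is None:
                raise ScheduleError("round requires a surrogate model")
            predictions = model.predict(library)
        if isinstance(spec.pool, float):
            n_pool = max(1, int(round(spec.pool * len(library))))
            order = _deterministic_order(candidates, predictions, ids)
            candidates = order[:n_pool]

    if len(candidates) < spec.acquire_size:
        warnings.warn(
            f"pool ({len(candidates)}) smaller than acquire_size ({spec.acquire_size}); "
            "returning whole pool"
        )

    if spec.selection == "random":
        rng = np.random.default_rng(seed)
        k = min(spec.acquire_size, len(candidates))
        return sorted(rng.choice(candidates, size=k, replace=False).tolist())
    order = _deterministic_order(candidates, predictions, ids)
    if spec.selection == "greedy":
        return order[: spec.acquire_size].tolist()
    # diverse: leader filter over the prediction-sorted pool
    kept: list[int] = []
    kept_bvs = []
    for i in order:
        bv = ensure_fingerprint(library[i]).to_bitvect()
        if kept_bvs and max(DataStructs.BulkTanimotoSimilarity(bv, kept_bvs)) >= spec.threshold:
            continue
        kept.append(int(i))
        kept_bvs.append(bv)
        if len(kept) >= spec.acquire_size:
            break
    if len(kept) < spec.acquire_size:
        warnings.warn(
            f"diverse selection kept {len(kept)} < acquire_size {spec.acquire_size}"
        )
    return kept


def run_screening_campaign(
    library: Sequence[MoleculeRecord],
    oracle_tier1,
    schedule: Sequence[RoundSpec] | None = None,
    seed: int = 0,
    *,
    hit_threshold: float = -9.0,
    surrogate_config: SurrogateConfig | None = None,
) -> CampaignState:
    """Execute the active-learning screening campaign.

    Each round scores its batch with the tier-1 oracle, appends to the
    ledger, retrains the surrogate on everything scored so far and logs the
    round (pool size, selection mode, cumulative hits below
    ``hit_threshold``).  ``oracle_tier1`` is either an :class:`OracleParams`
    or a callable mapping records to scores.
    """
    schedule = list(schedule) if schedule is not None else default_schedule(len(library))
    if not schedule:
        raise ScheduleError("schedule must contain at least one round")
    total = sum(s.acquire_size for s in schedule)
    if total > len(library):
        raise ScheduleError(f"schedule budget {total} exceeds library size {len(library)}")
    scorer = _as_scorer(oracle_tier1)
    surrogate_config = surrogate_config or SurrogateConfig(seed=seed)
    state = CampaignState(library=library, hit_threshold=hit_threshold)
    model: SurrogateModel | None = None
    rows: list[pd.DataFrame] = []
    ids = [r.id for r in library]
    for round_idx, spec in enumerate(schedule):
        predictions = model.predict(library) if model is not None else None
        batch_idx = select_batch(
            spec, library, model, state.scored_ids, seed=seed + round_idx, predictions=predictions
        )
        batch = [library[i] for i in batch_idx]
        scores = np.asarray(scorer(batch), dtype=float)
        rows.append(pd.DataFrame({"id": [ids[i] for i in batch_idx], "score": scores, "round": round_idx}))
        state.ledger = pd.concat(rows, ignore_index=True)
        try:
            model = train_surrogate(
                list(state.ledger["id"].map({r.id: r for r in library})),
                state.ledger["score"].to_numpy(),
                replace(surrogate_config, seed=surrogate_config.seed + round_idx),
            )
        except InsufficientDataError:
            model = None
        state.models.append(model)
        state.round_logs.append(
            {
                "round": round_idx,
                "selection": spec.selection,
                "pool": spec.pool,
                "acquired": len(batch_idx),
                "hits_below_threshold": int((state.ledger["score"] < hit_threshold).sum()),
                "surrogate_r2": model.validation_r2 if model is not None else math.nan,
            }
        )
    if state.ledger["id"].duplicated().any():
        raise AssertionError("ledger contains duplicate ids")
    return state


# --------------------------------------------------------------------------
# tier-2 rescoring campaign
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RescoreConfig:
    """Stage counts and thresholds of the tier-2 rescoring campaign.

    Defaults carry the reference protocol's absolute counts; use
    :meth:`scaled` to express them at a desk-scale library fraction (counts
    floor at 1).  The stage-A seed-set size is emergent (the Tanimoto<0.4
    leader filter decides it), so only loop/stage counts rescale.
    """

    tier1_threshold: float = -9.0
    relaxed_threshold: float = -4.0
    sim_threshold: float = DEFAULT_SIMILARITY_THRESHOLD
    loop_batch: int = 200
    loop_pool: int = 1500
    loop_total: int = 1700
    stage_c_pool: int = 4000
    stage_c_keep: int = 800
    max_acid_groups: int = 2  # strict: keep molecules with < 2 acid matches
    stage_d_count: int = 522

    def scaled(self, fraction: float) -> "RescoreConfig":
        s = lambda n: max(1, round(n * fraction))
        return replace(
            self,
            loop_batch=s(self.loop_batch),
            loop_pool=s(self.loop_pool),
            loop_total=s(self.loop_total),
            stage_c_pool=s(self.stage_c_pool),
            stage_c_keep=s(self.stage_c_keep),
            stage_d_count=s(self.stage_d_count),
        )


def _train_or_none(records, scores, config: SurrogateConfig):
    try:
        return train_surrogate(records, scores, config)
    except InsufficientDataError:
        logger.warning("too few tier-2 scores to train surrogate; ranking by tier-1 score")
        return None


def maxmin_select(
    candidates: Sequence[MoleculeRecord],
    k: int,
    anchors: Sequence[MoleculeRecord] = (),
) -> list[MoleculeRecord]:
    """Minimal-similarity (MaxMin) selection of ``k`` records.

    Iteratively picks the candidate whose maximum Tanimoto similarity to the
    already-selected set (plus optional ``anchors``, e.g. previously scored
    molecules) is smallest; ties break toward the earlier candidate, so
    callers passing prediction-sorted lists prefer better-predicted
    molecules.  Unlike the leader filter this always reaches ``k`` when
    enough candidates exist.
    """
    if k <= 0 or not candidates:
        return []
    cand_bvs = [ensure_fingerprint(r).to_bitvect() for r in candidates]
    maxsim = np.zeros(len(candidates))
    if anchors:
        anchor_bvs = [ensure_fingerprint(r).to_bitvect() for r in anchors]
        for i, bv in enumerate(cand_bvs):
            maxsim[i] = max(DataStructs.BulkTanimotoSimilarity(bv, anchor_bvs))
    taken = np.zeros(len(candidates), dtype=bool)
    selected: list[int] = []
    for _ in range(min(k, len(candidates))):
        open_idx = np.nonzero(~taken)[0]
        pick = open_idx[int(np.argmin(maxsim[open_idx]))]
        taken[pick] = True
        selected.append(int(pick))
        sims = np.asarray(DataStructs.BulkTanimotoSimilarity(cand_bvs[pick], cand_bvs))
        np.maximum(maxsim, sims, out=maxsim)
    return [candidates[i] for i in selected]


def run_rescoring_campaign(
    state: CampaignState,
    oracle_tier2,
    config: RescoreConfig | None = None,
    seed: int = 0,
    *,
    surrogate_config: SurrogateConfig | None = None,
) -> pd.DataFrame:
    """Drive the tier-2 oracle over tier-1 hits in four stages.

    Stage A seeds with a Tanimoto<``sim_threshold`` leader subset of tier-1
    hits (best tier-1 first) — its size is emergent.  Stage B repeats: train
    a tier-2 surrogate, take the top ``loop_pool`` predictions of the
    eligible pool, pick ``loop_batch`` by minimal similarity to everything
    scored or selected (MaxMin), and score — until ``loop_total`` tier-2
    scores are collected.  Stage C takes the ``stage_c_pool``
    best-predicted, keeps molecules with fewer than two carboxylic-acid
    groups, diversity-selects ``stage_c_keep`` (MaxMin) and scores them.
    Stage D relaxes eligibility to tier-1 < ``relaxed_threshold``, filters
    on lead-like properties and diversity-selects ``stage_d_count``.
    Returns the tier-2 ledger (id, smiles, score, stage).
    """
    config = config or RescoreConfig()
    scorer = (
        (lambda records: score_tier2_batch(records, oracle_tier2))
        if isinstance(oracle_tier2, OracleParams)
        else oracle_tier2
    )
    surrogate_config = surrogate_config or SurrogateConfig(seed=seed)
    by_id = {r.id: r for r in state.library}
    tier1 = state.ledger.set_index("id")["score"]

    def eligible(threshold: float) -> list[MoleculeRecord]:
        sub = tier1[tier1 < threshold].sort_values(kind="stable")
        # deterministic tie-break: score then id
        sub = sub.reset_index().sort_values(["score", "id"], kind="stable")
        return [by_id[i] for i in sub["id"]]

    ledger_rows: list[dict] = []
    scored: list[MoleculeRecord] = []
    scored_scores: list[float] = []

    def score_stage(records: list[MoleculeRecord], stage: str) -> None:
        if not records:
            return
        values = np.asarray(scorer(records), dtype=float)
        for rec, val in zip(records, values):
            ledger_rows.append({"id": rec.id, "smiles": rec.smiles, "score": float(val), "stage": stage})
        scored.extend(records)
        scored_scores.extend(values.tolist())

    pool_a = eligible(config.tier1_threshold)
    if not pool_a:
        warnings.warn("no tier-1 hits below threshold; rescoring stages skipped")
        return pd.DataFrame(columns=["id", "smiles", "score", "stage"])

    # stage A: diverse seed set among tier-1 hits
    seeds = diverse_subset(pool_a, config.sim_threshold)
    score_stage(seeds, "A")

    # stage B: iterative surrogate-guided selection loop
    while len(scored) < config.loop_total:
        remaining = [r for r in pool_a if r.id not in {s.id for s in scored}]
        if not remaining:
            warnings.warn("stage B pool exhausted before reaching loop_total")
            break
        model = _train_or_none(scored, scored_scores, surrogate_config)
        if model is not None:
            preds = model.predict(remaining)
            order = np.lexsort(([r.id for r in remaining], preds))
            remaining = [remaining[i] for i in order]
        top = remaining[: config.loop_pool]
        batch = maxmin_select(
            top, min(config.loop_batch, config.loop_total - len(scored)), anchors=scored
        )
        if not batch:
            warnings.warn("stage B selection empty; stopping loop")
            break
        score_stage(batch, "B")

    # stage C: best-predicted, acid-filtered, diversity-selected
    model = _train_or_none(scored, scored_scores, surrogate_config)
    remaining = [r for r in pool_a if r.id not in {s.id for s in scored}]
    if remaining:
        if model is not None:
            preds = model.predict(remaining)
            order = np.lexsort(([r.id for r in remaining], preds))
            remaining = [remaining[i] for i in order]
        top = remaining[: config.stage_c_pool]
        low_acid = [r for r in top if r.n_acid < config.max_acid_groups]
        if not low_acid:
            raise ValueError("acid-group filter eliminated the whole stage-C pool")
        batch = maxmin_select(low_acid, config.stage_c_keep)
        score_stage(batch, "C")
    else:
        warnings.warn("stage C pool empty; skipped")

    # stage D: relaxed eligibility, property + diversity selection
    model = _train_or_none(scored, scored_scores, surrogate_config)
    pool_d = [
        r for r in eligible(config.relaxed_threshold) if r.id not in {s.id for s in scored}
    ]
    pool_d = [r for r in pool_d if leadlike_filter(r).passed]
    if pool_d:
        if model is not None:
            preds = model.predict(pool_d)
            order = np.lexsort(([r.id for r in pool_d], preds))
            pool_d = [pool_d[i] for i in order]
        batch = maxmin_select(pool_d, config.stage_d_count)
        score_stage(batch, "D")
    else:
        warnings.warn("stage D pool empty; skipped")

    ledger = pd.DataFrame(ledger_rows)
    if not ledger.empty and ledger["id"].duplicated().any():
        raise AssertionError("tier-2 ledger contains duplicate ids")
    return ledger


# --------------------------------------------------------------------------
# bootstrap recall estimation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RecallEstimate:
    """Bootstrap estimate of campaign hit recall below a score threshold."""

    threshold: float
    found: int
    sample_hits: int
    sample_size: int
    estimated_total: float
    total_ci: tuple[float, float]
    recall: float
    recall_ci: tuple[float, float]


def estimate_recall_bootstrap(
    initial_sample_scores: Sequence[float],
    library_size: int,
    threshold: float,
    found: int,
    B: int = 1000,
    seed: int = 0,
) -> RecallEstimate:
    """Estimate total hits and recall from the initial uniform random round.

    With *k* of *n* sampled scores below the threshold, the total-hit point
    estimate is ``(k/n)·library_size``; a percentile 95% CI comes from *B*
    bootstrap resamples of the sample.  Recall is ``found`` divided by the
    estimated total, its CI mapping the total CI endpoints (upper total →
    lower recall) and clamped to [0, 1] in the report.
    """
    scores = np.asarray(initial_sample_scores, dtype=float)
    n = len(scores)
    if n == 0:
        raise ValueError("empty calibration sample")
    if B < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    if found < 0:
        raise ValueError("found must be non-negative")
    k = int((scores < threshold).sum())
    if k == 0:
        raise ValueError("no hits in calibration sample; recall unidentifiable")
    rng = np.random.default_rng(seed)
    # a resample-with-replacement hit count is exactly Binomial(n, k/n), so
    # the bootstrap draws counts directly instead of materialising resamples
    resample_hits = rng.binomial(n, k / n, size=B)
    totals = resample_hits / n * library_size
    t_lo, t_hi = np.percentile(totals, [2.5, 97.5])
    t_hat = k / n * library_size
    recall = found / t_hat
    r_lo = found / t_hi if t_hi > 0 else 1.0
    r_hi = found / t_lo if t_lo > 0 else 1.0
    clamp = lambda x: float(min(1.0, max(0.0, x)))
    return RecallEstimate(
        threshold=threshold,
        found=found,
        sample_hits=k,
        sample_size=n,
        estimated_total=t_hat,
        total_ci=(float(t_lo), float(t_hi)),
        recall=clamp(recall),
        recall_ci=(clamp(r_lo), clamp(r_hi)),
    )
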