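import warnings

import numpy as np
import pytest

from alscreen.al_campaign import (
    RecallEstimate,
    RescoreConfig,
    RoundSpec,
    ScheduleError,
    default_schedule,
    estimate_recall_bootstrap,
    run_rescoring_campaign,
    run_screening_campaign,
    select_batch,
)
from alscreen.chem_core import count_substructure, diverse_subset, ensure_fingerprint, tanimoto
from alscreen.synth_library import OracleParams, score_tier1_batch, score_tier2_batch


class TestRoundSpec:
    def test_validation(self):
        with pytest.raises(ScheduleError):
            RoundSpec(acquire_size=0)
        with pytest.raises(ScheduleError):
            RoundSpec(acquire_size=1, pool=1.5)
        with pytest.raises(ScheduleError):
            RoundSpec(acquire_size=1, selection="diverse")  # missing threshold
        with pytest.raises(ScheduleError):
            RoundSpec(acquire_size=1, selection="best")

    def test_default_schedule_shape(self):
        sched = default_schedule(2_654_000_000)
        assert [s.acquire_size for s in sched] == [1_000_000] * 3 + [3_000_000]
        assert [s.selection for s in sched] == ["random", "diverse", "diverse", "greedy"]
        assert sched[1].pool == sched[3].pool == pytest.approx(0.0377)


class TestSelectBatch:
    def test_greedy_takes_best_predicted(self, small_library):
        _, records = small_library
        library = records[:10]
        predictions = np.array([5.0, -1.0, 3.0, -7.0, 0.0, 2.0, -3.0, 9.0, 1.0, 4.0])
        spec = RoundSpec(acquire_size=3, selection="greedy")
        chosen = select_batch(spec, library, None, set(), seed=0, predictions=predictions)
        assert chosen == [3, 6, 1]  # most negative predictions first

    def test_diverse_degenerate_pool_warns_and_returns_one(self, small_library):
        _, records = small_library
        clones = [records[0]] * 8
        spec = RoundSpec(acquire_size=5, selection="diverse", threshold=0.4)
        with pytest.warns(UserWarning, match="kept 1"):
            chosen = select_batch(spec, clones, None, set(), seed=0, predictions=np.zeros(8))
        assert len(chosen) == 1

    def test_diverse_matches_brute_force_leader(self, small_library):
        _, records = small_library
        library = records[:50]
        rng = np.random.default_rng(5)
        predictions = rng.normal(size=50)
        spec = RoundSpec(acquire_size=50, selection="diverse", threshold=0.4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chosen = select_batch(spec, library, None, set(), seed=0, predictions=predictions)
        order = np.lexsort(([r.id for r in library], predictions))
        expected = diverse_subset([library[i] for i in order], 0.4)
        assert [library[i].id for i in chosen] == [r.id for r in expected]

    def test_exclude_scored_removes_ledger_ids(self, small_library):
        _, records = small_library
        library = records[:10]
        scored = {library[0].id, library[1].id}
        spec = RoundSpec(acquire_size=10, selection="random", exclude_scored=True)
        with pytest.warns(UserWarning, match="shortfall|whole pool"):
            chosen = select_batch(spec, library, None, scored, seed=0)
        assert len(chosen) == 8
        assert all(library[i].id not in scored for i in chosen)


class TestScreeningCampaign:
    @pytest.fixture(scope="class")
    def campaign(self, small_library, small_params):
        _, records = small_library
        schedule = [
            RoundSpec(acquire_size=100),
            RoundSpec(acquire_size=60, pool=0.1, selection="diverse", threshold=0.4),
            RoundSpec(acquire_size=120, pool=0.1, selection="greedy"),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return run_screening_campaign(
                records, small_params, schedule, seed=3, hit_threshold=-7.5
            )

    def test_ledger_accounting(self, campaign):
        acquired = sum(log["acquired"] for log in campaign.round_logs)
        assert len(campaign.ledger) == acquired
        assert not campaign.ledger["id"].duplicated().any()
        library_ids = {r.id for r in campaign.library}
        assert set(campaign.ledger["id"]) <= library_ids

    def test_hit_count_monotone_across_rounds(self, campaign):
        counts = [log["hits_below_threshold"] for log in campaign.round_logs]
        assert counts == sorted(counts)

    def test_scores_match_oracle(self, campaign, small_library, small_params):
        _, records = small_library
        by_id = {r.id: r for r in records}
        sub = campaign.ledger.head(20)
        expected = score_tier1_batch([by_id[i] for i in sub["id"]], small_params)
        np.testing.assert_allclose(sub["score"].to_numpy(), expected)

    def test_exhaustive_screen_has_full_recall(self, small_library, small_params):
        _, records = small_library
        schedule = [RoundSpec(acquire_size=len(records))]
        state = run_screening_campaign(records, small_params, schedule, seed=0)
        truth = score_tier1_batch(records, small_params)
        for thr in (-8.0, -7.0):
            assert (state.ledger["score"] < thr).sum() == (truth < thr).sum()
        est = estimate_recall_bootstrap(
            state.initial_sample_scores(), len(records), -7.0,
            int((state.ledger["score"] < -7.0).sum()), B=500, seed=1,
        )
        assert est.recall_ci[0] <= 1.0 <= est.recall_ci[1] or est.recall == 1.0

    def test_over_budget_schedule_rejected_before_scoring(self, small_library, small_params):
        _, records = small_library
        with pytest.raises(ScheduleError, match="budget"):
            run_screening_campaign(
                records, small_params, [RoundSpec(acquire_size=len(records) + 1)], seed=0
            )


class TestRescoringCampaign:
    @pytest.fixture(scope="class")
    def scored_state(self, small_library, small_params):
        _, records = small_library
        state = run_screening_campaign(
            records, small_params, [RoundSpec(acquire_size=len(records))], seed=0,
            hit_threshold=-7.0,
        )
        return state

    @pytest.fixture(scope="class")
    def desk_config(self):
        return RescoreConfig(
            tier1_threshold=-6.8,
            relaxed_threshold=-6.0,
            loop_batch=15,
            loop_pool=80,
            loop_total=60,
            stage_c_pool=120,
            stage_c_keep=40,
            stage_d_count=40,
        )

    @pytest.fixture(scope="class")
    def tier2_ledger(self, scored_state, small_params, desk_config):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return run_rescoring_campaign(scored_state, small_params, desk_config, seed=2)

    def test_stage_c_respects_acid_filter(self, tier2_ledger):
        stage_c = tier2_ledger[tier2_ledger["stage"] == "C"]
        assert len(stage_c) > 0
        for smiles in stage_c["smiles"]:
            assert count_substructure(smiles, "carboxylic_acid") < 2

    def test_stage_counts_match_config_when_pools_suffice(self, tier2_ledger, desk_config):
        sizes = tier2_ledger.groupby("stage").size()
        assert sizes.get("C", 0) == desk_config.stage_c_keep
        assert sizes.get("D", 0) == desk_config.stage_d_count
        # loop stops once loop_total tier-2 scores are collected
        n_ab = sizes.get("A", 0) + sizes.get("B", 0)
        assert n_ab >= desk_config.loop_total

    def test_seed_set_is_diverse_at_threshold(self, tier2_ledger, scored_state, desk_config):
        stage_a = tier2_ledger[tier2_ledger["stage"] == "A"]
        by_id = {r.id: r for r in scored_state.library}
        fps = [ensure_fingerprint(by_id[i]) for i in stage_a["id"]]
        for i in range(len(fps)):
            for j in range(i + 1, len(fps)):
                assert tanimoto(fps[i], fps[j]) < desk_config.sim_threshold

    def test_no_duplicate_ids_and_scores_match_oracle(self, tier2_ledger, scored_state, small_params):
        assert not tier2_ledger["id"].duplicated().any()
        by_id = {r.id: r for r in scored_state.library}
        sub = tier2_ledger.head(15)
        expected = score_tier2_batch([by_id[i] for i in sub["id"]], small_params)
        np.testing.assert_allclose(sub["score"].to_numpy(), expected)

    def test_enriches_tier2_scores_over_random_selection(
        self, scored_state, small_params, desk_config
    ):
        """Surrogate-guided rescoring collects better (more negative) tier-2
        scores than random draws of equal size from the widest pool the
        campaign may touch (the relaxed tier-1 eligibility)."""
        tier1 = scored_state.ledger.set_index("id")["score"]
        eligible = tier1[tier1 < desk_config.relaxed_threshold].index.to_list()
        by_id = {r.id: r for r in scored_state.library}
        means_al, means_rand = [], []
        for seed in range(5):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ledger = run_rescoring_campaign(
                    scored_state, small_params, desk_config, seed=seed
                )
            means_al.append(ledger["score"].mean())
            rng = np.random.default_rng(100 + seed)
            ids = rng.choice(eligible, size=min(len(ledger), len(eligible)), replace=False)
            means_rand.append(
                score_tier2_batch([by_id[i] for i in ids], small_params).mean()
            )
        assert np.mean(means_al) < np.mean(means_rand)

    def test_empty_hit_pool_skips_with_warning(self, scored_state, small_params, desk_config):
        import dataclasses

        config = dataclasses.replace(desk_config, tier1_threshold=-99.0, relaxed_threshold=-99.0)
        with pytest.warns(UserWarning, match="skipped"):
            ledger = run_rescoring_campaign(scored_state, small_params, config, seed=0)
        assert ledger.empty

    def test_scaled_counts_floor_at_one(self):
        scaled = RescoreConfig().scaled(1e-5)
        assert scaled.loop_batch == 1
        assert scaled.stage_d_count == 1
        bigger = RescoreConfig().scaled(0.1)
        assert bigger.loop_total == 170


class TestMaxMinSelect:
    def test_reaches_target_count_and_starts_with_first_candidate(self, small_library):
        from alscreen.al_campaign import maxmin_select

        _, records = small_library
        picked = maxmin_select(records[:100], 30)
        assert len(picked) == 30
        assert picked[0].id == records[0].id  # no anchors: best-ranked first
        assert len({r.id for r in picked}) == 30

    def test_anchors_push_selection_away_from_scored_set(self, small_library):
        from alscreen.al_campaign import maxmin_select
        from alscreen.chem_core import ensure_fingerprint, tanimoto

        _, records = small_library
        anchors = records[:20]
        candidates = records[:60]  # first 20 identical to anchors
        picked = maxmin_select(candidates, 10, anchors=anchors)
        anchor_fps = [ensure_fingerprint(a) for a in anchors]
        picked_max = [
            max(tanimoto(ensure_fingerprint(p), fa) for fa in anchor_fps) for p in picked
        ]
        unpicked = [c for c in candidates if c.id not in {p.id for p in picked}][:10]
        unpicked_max = [
            max(tanimoto(ensure_fingerprint(u), fa) for fa in anchor_fps) for u in unpicked
        ]
        assert np.mean(picked_max) < np.mean(unpicked_max)


class TestBootstrapRecall:
    def test_all_hits_sample_gives_degenerate_recall_one(self):
        scores = np.full(500, -12.0)
        est = estimate_recall_bootstrap(scores, 500, -9.0, found=500, B=200, seed=0)
        assert est.recall == 1.0
        assert est.recall_ci == (1.0, 1.0)

    def test_synthetic_calibration_with_known_truth(self, rng):
        """Library of 10,000 with exactly 100 true hits; the CI from a
        1,000-sample calibration brackets the true recall 0.5."""
        library = np.concatenate([np.full(100, -10.0), np.full(9900, -5.0)])
        rng.shuffle(library)
        sample = rng.choice(library, size=1000, replace=False)
        k = int((sample < -9.0).sum())
        est = estimate_recall_bootstrap(sample, 10_000, -9.0, found=50, B=1000, seed=3)
        assert est.sample_hits == k
        assert est.estimated_total == pytest.approx(k / 1000 * 10_000)
        assert est.recall == pytest.approx(min(1.0, 50 / (k / 1000 * 10_000)))
        assert est.recall_ci[0] <= 0.5 <= est.recall_ci[1]

    def test_deterministic_under_seed(self, rng):
        scores = rng.normal(-6, 1, size=2000)
        a = estimate_recall_bootstrap(scores, 100_000, -8.0, found=30, B=1000, seed=9)
        b = estimate_recall_bootstrap(scores, 100_000, -8.0, found=30, B=1000, seed=9)
        assert a == b

    def test_no_hits_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_recall_bootstrap(np.full(100, -5.0), 1000, -9.0, found=0, B=200, seed=0)

    def test_ci_orders_and_clamps(self, rng):
        scores = rng.normal(-6, 1, size=1000)
        est = estimate_recall_bootstrap(scores, 50_000, -8.0, found=100, B=500, seed=4)
        assert est.total_ci[0] <= est.estimated_total <= est.total_ci[1]
        assert 0.0 <= est.recall_ci[0] <= est.recall <= est.recall_ci[1] <= 1.0

    def test_coverage_over_simulated_campaigns(self):
        """The 95% recall CI covers the true recall in ≥90% of 60 simulated
        screens with known ground truth."""
        n_lib, n_sample, B = 40_000, 2000, 400
        master = np.random.default_rng(2024)
        covered = 0
        n_sim = 60
        for _ in range(n_sim):
            lib = master.normal(-5.7, 0.887, size=n_lib)
            threshold = -7.5
            total_hits = int((lib < threshold).sum())
            sample = master.choice(lib, size=n_sample, replace=False)
            if (sample < threshold).sum() == 0:
                n_sim -= 1
                continue
            found = master.integers(1, total_hits + 1)
            true_recall = found / total_hits
            est = estimate_recall_bootstrap(
                sample, n_lib, threshold, int(found), B=B,
                seed=int(master.integers(2**31)),
            )
            if est.recall_ci[0] <= true_recall <= est.recall_ci[1]:
                covered += 1
        assert n_sim >= 50
        assert covered / n_sim >= 0.90
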