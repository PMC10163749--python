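"""Linkage engine: prior, winner selection, pre-filter, whole-file runs."""

import math
from dataclasses import replace
from datetime import date

import pytest

import bayeslink as bl
from bayeslink.comparison import NEG_INF
from bayeslink.engine import (
    build_comparable,
    prefilter_candidates,
    score_candidate,
    select_winner,
)


class TestPriorLogOdds:
    def test_local_population_estimate(self):
        assert bl.prior_log_odds(852_523) == pytest.approx(-13.7, abs=0.05)

    def test_even_odds_at_two(self):
        assert bl.prior_log_odds(2) == 0.0

    def test_closed_form(self):
        assert bl.prior_log_odds(round(math.e) + 1) != 0  # guard the rounding
        assert bl.prior_log_odds(int(math.e) + 1) == -math.log(int(math.e))
        assert bl.prior_log_odds(1000) == -math.log(999)

    def test_invalid_population(self):
        with pytest.raises(ValueError):
            bl.prior_log_odds(1)


class TestSelectWinner:
    def test_clear_leader_declared(self):
        winner, leader, runner, leader_id = select_winner(
            [("a", 10.0), ("b", 2.0)], theta=5.0, delta=0.0)
        assert winner == "a" and leader == 10.0 and runner == 2.0

    def test_below_consideration_threshold(self):
        winner, *_ = select_winner([("a", 4.9)], theta=5.0, delta=0.0)
        assert winner is None

    def test_duplicate_candidates_with_leader_advantage(self):
        # identical copies can never satisfy delta > 0
        winner, *_ = select_winner([("copy1", 12.0), ("copy2", 12.0)],
                                   theta=5.0, delta=1.0)
        assert winner is None

    def test_tie_at_delta_zero_first_wins(self):
        winner, *_ = select_winner([("copy1", 12.0), ("copy2", 12.0)],
                                   theta=5.0, delta=0.0)
        assert winner == "copy1"

    def test_single_candidate_has_infinite_advantage(self):
        winner, *_ = select_winner([("only", 8.0)], theta=5.0, delta=3.0)
        assert winner == "only"

    def test_ruled_out_runner_up(self):
        winner, *_ = select_winner([("a", 8.0), ("b", NEG_INF)],
                                   theta=5.0, delta=3.0)
        assert winner == "a"

    def test_all_ruled_out(self):
        winner, leader, *_ = select_winner([("a", NEG_INF)], theta=0.0, delta=0.0)
        assert winner is None and leader == NEG_INF

    def test_empty(self):
        assert select_winner([], 5.0, 0.0) == (None, None, None, None)


class TestScoreCandidate:
    def test_self_beats_everyone_else(self, model, config, population):
        sample = [build_comparable(r, config, model, proband_side=False)
                  for r in population[:10]]
        proband = build_comparable(population[0], config, model, proband_side=True)
        scores = [score_candidate(proband, c, config) for c in sample]
        assert scores[0] == max(scores)
        assert scores[0] > max(scores[1:])

    def test_matching_gender_never_hurts(self, model, config):
        base = bl.PersonRecord(local_id="p", forenames=[bl.DatedValue("Anna")],
                               dob=date(1980, 1, 1), gender="F")
        with_gender = bl.PersonRecord(local_id="c1",
                                      forenames=[bl.DatedValue("Anna")],
                                      dob=date(1980, 1, 1), gender="F")
        without_gender = bl.PersonRecord(local_id="c2",
                                         forenames=[bl.DatedValue("Anna")],
                                         dob=date(1980, 1, 1), gender=None)
        proband = build_comparable(base, config, model, proband_side=True)
        s_with = score_candidate(proband,
                                 build_comparable(with_gender, config, model,
                                                  proband_side=False), config)
        s_without = score_candidate(proband,
                                    build_comparable(without_gender, config, model,
                                                     proband_side=False), config)
        assert s_with >= s_without

    def test_complete_dob_mismatch_is_absorbing(self, model, config):
        a = bl.PersonRecord(local_id="p", dob=date(1980, 1, 1),
                            forenames=[bl.DatedValue("Anna")], gender="F")
        b = bl.PersonRecord(local_id="c", dob=date(1990, 2, 2),
                            forenames=[bl.DatedValue("Anna")], gender="F")
        proband = build_comparable(a, config, model, proband_side=True)
        candidate = build_comparable(b, config, model, proband_side=False)
        assert score_candidate(proband, candidate, config) == NEG_INF


class TestPrefilter:
    def test_equivalent_to_full_scan(self, model, config, population):
        """With p_en_dob = 0, ruled-out (−∞) candidates can never win, so
        shortlisting by DOB reproduces the full-scan decisions exactly."""
        probands, sample, _ = bl.derive_sample_with_errors(
            population[:120], overlap_fraction=0.5, profile=bl.ErrorProfile(),
            model=model, seed=31)
        filtered = bl.link_datasets(probands, sample, config, model=model)
        sample_comparables = [build_comparable(r, config, model,
                                               proband_side=False)
                              for r in sample]
        for record, result in zip(probands, filtered):
            proband = build_comparable(record, config, model, proband_side=True)
            scored = [(c.local_id, score_candidate(proband, c, config))
                      for c in sample_comparables]
            winner, leader, runner, leader_id = select_winner(
                scored, config.theta, config.delta)
            assert result.match_local_id == winner
            if result.leader_local_id is not None and leader != NEG_INF:
                assert result.leader_local_id == leader_id
                assert result.leader_log_odds == leader

    def test_proband_without_dob_compared_to_all(self, model, config, population):
        record = bl.PersonRecord(local_id="nodob",
                                 forenames=[bl.DatedValue("Anna")], gender="F")
        proband = build_comparable(record, config, model, proband_side=True)
        sample = [build_comparable(r, config, model, proband_side=False)
                  for r in population[:30]]
        assert len(prefilter_candidates(proband, sample, config)) == 30

    def test_candidates_without_dob_always_kept(self, model, config):
        proband = build_comparable(
            bl.PersonRecord(local_id="p", dob=date(1980, 1, 1)),
            config, model, proband_side=True)
        sample = [build_comparable(bl.PersonRecord(local_id="nodob"),
                                   config, model, proband_side=False),
                  build_comparable(bl.PersonRecord(local_id="far",
                                                   dob=date(1931, 7, 12)),
                                   config, model, proband_side=False)]
        kept = {c.local_id for c in prefilter_candidates(proband, sample, config)}
        assert kept == {"nodob"}

    def test_exact_only_when_partial_errors_also_zero(self, model, config):
        proband = build_comparable(
            bl.PersonRecord(local_id="p", dob=date(1980, 1, 1)),
            config, model, proband_side=True)
        sample = [build_comparable(bl.PersonRecord(local_id="exact",
                                                   dob=date(1980, 1, 1)),
                                   config, model, proband_side=False),
                  build_comparable(bl.PersonRecord(local_id="partial",
                                                   dob=date(1980, 1, 2)),
                                   config, model, proband_side=False)]
        strict = replace(config, p_ep_dob=0.0)
        kept = {c.local_id for c in prefilter_candidates(proband, sample, strict)}
        assert kept == {"exact"}
        kept = {c.local_id for c in prefilter_candidates(proband, sample, config)}
        assert kept == {"exact", "partial"}


class TestLinkDatasets:
    def test_error_free_self_linkage_matches_everyone(self, model, config,
                                                      population):
        results = bl.link_datasets(population[:100], population[:100], config,
                                   model=model)
        for record, result in zip(population[:100], results):
            assert result.match_local_id == record.local_id

    def test_empty_sample(self, model, config, population):
        results = bl.link_datasets(population[:5], [], config, model=model)
        assert all(r.match_local_id is None and r.basis == "none"
                   for r in results)

    def test_results_follow_proband_order(self, model, config, population):
        results = bl.link_datasets(population[:20], population[:10], config,
                                   model=model)
        assert [r.proband_local_id for r in results] == \
            [p.local_id for p in population[:20]]

    def test_sample_permutation_changes_no_decision(self, model, config,
                                                    population):
        probands = population[:60]
        sample = population[:60]
        forward = bl.link_datasets(probands, sample, config, model=model)
        backward = bl.link_datasets(probands, list(reversed(sample)), config,
                                    model=model)
        for f, b in zip(forward, backward):
            assert f.match_local_id == b.match_local_id

    def test_threshold_monotonicity(self, model, config, population, linked_world):
        """Raising either threshold can only shrink the declared-match set."""
        _, _, _, results = linked_world
        grid = [(0.0, 0.0), (5.0, 0.0), (5.0, 3.0), (10.0, 3.0), (15.0, 15.0)]
        previous = None
        for theta, delta in grid:
            declared = {r.proband_local_id for r in results
                        if bl.decide_match(r, theta, delta) is not None}
            if previous is not None:
                assert declared <= previous
            previous = declared

    def test_duplicate_local_ids_processed_with_warning(self, model, config,
                                                        population, caplog):
        import logging
        twice = [population[0], population[0]]
        with caplog.at_level(logging.WARNING, logger="bayeslink.engine"):
            results = bl.link_datasets(twice, population[:5], config, model=model)
        assert len(results) == 2
        assert any("duplicate" in r.message for r in caplog.records)


class TestPerfectIdentifiers:
    def test_shared_perfect_id_short_circuits(self, model, config):
        proband = bl.PersonRecord(local_id="p", gender="F",
                                  forenames=[bl.DatedValue("Anna")],
                                  dob=date(1980, 1, 1),
                                  perfect_ids={"nhs_number": "943-476-5919"})
        impostor = bl.PersonRecord(local_id="wrong-name", gender="M",
                                   forenames=[bl.DatedValue("Bob")],
                                   dob=date(1955, 5, 5),
                                   perfect_ids={"nhs_number": "943-476-5919"})
        lookalike = bl.PersonRecord(local_id="lookalike", gender="F",
                                    forenames=[bl.DatedValue("Anna")],
                                    dob=date(1980, 1, 1))
        results = bl.link_datasets([proband], [lookalike, impostor], config,
                                   model=model)
        assert results[0].match_local_id == "wrong-name"
        assert results[0].basis == "perfect-id"

    def test_translation_map_bridges_field_names(self, model, config):
        proband = bl.PersonRecord(local_id="p", dob=date(1980, 1, 1),
                                  perfect_ids={"nhsnum": "123"})
        candidate = bl.PersonRecord(local_id="c", dob=date(1999, 9, 9),
                                    perfect_ids={"nhs_number": "123"})
        results = bl.link_datasets(
            [proband], [candidate], config, model=model,
            perfect_id_translation={"nhsnum": "nhs_number"})
        assert results[0].match_local_id == "c"

    def test_no_perfect_ids_falls_through_to_bayesian(self, model, config,
                                                      population):
        results = bl.link_datasets(population[:3], population[:3], config,
                                   model=model)
        assert all(r.basis == "bayesian" for r in results)
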