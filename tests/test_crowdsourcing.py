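"""HIT batching, cost model, response round trip, vote aggregation,
worker scoring, and the simulated-worker model."""

from __future__ import annotations

import io
from collections import defaultdict

import numpy as np
import pytest

from conftest import make_annotation
from crowdkb.crowdsourcing import (AggregationConfig, CostPlan,
                                   WorkerResponse, aggregate_votes,
                                   estimate_cost, ingest_responses,
                                   partition_into_hits, render_hits,
                                   render_option, score_workers,
                                   simulate_workers, write_question_batch,
                                   write_responses)
from crowdkb.extraction import CandidateTriple, Mention


class TestPartitionIntoHits:
    def _anns(self, n):
        return [make_annotation(2, 1, doc_id=f"D{i}") for i in range(n)]

    def test_671_sentences_make_27_hits(self):
        hits = partition_into_hits(self._anns(671), per_hit=25)
        assert len(hits) == 27
        sizes = [len(h.questions) for h in hits]
        assert sizes == [25] * 26 + [21]

    def test_exactly_one_full_hit(self):
        hits = partition_into_hits(self._anns(25), per_hit=25)
        assert len(hits) == 1 and len(hits[0].questions) == 25

    def test_101_sentences_at_10_per_hit(self):
        hits = partition_into_hits(self._anns(101), per_hit=10)
        assert [len(h.questions) for h in hits] == [10] * 10 + [1]

    def test_zero_per_hit_is_an_error(self):
        with pytest.raises(ValueError):
            partition_into_hits(self._anns(5), per_hit=0)

    def test_order_preserved(self):
        hits = partition_into_hits(self._anns(30), per_hit=25)
        keys = [q.sentence_key for h in hits for q in h.questions]
        assert keys == [f"D{i}:0" for i in range(30)]


class TestRenderAndIngest:
    def test_option_template(self):
        ann = make_annotation(2, 1)
        (t,) = [CandidateTriple(ann.sentence.key, ann.entities[0],
                                ann.predicates[0], ann.entities[1])]
        assert render_option(t) == "entity00 — predic00 — entity01"

    def test_zero_option_question_omitted_from_batch(self):
        anns = [make_annotation(2, 1), make_annotation(1, 1),
                make_annotation(3, 2)]
        hits = partition_into_hits(anns, per_hit=25)
        rows = render_hits(hits)
        assert len(hits[0].questions) == 3       # kept in the HIT
        assert len(rows) == 2                    # omitted at render time

    def test_round_trip_recovers_identical_responses(self):
        """simulate -> write CSV -> ingest yields the same in-memory
        responses, and every selection maps to an enumerated triple."""
        anns = [make_annotation(3, 2, doc_id=f"D{i}") for i in range(60)]
        hits = partition_into_hits(anns, per_hit=25)
        gold = {a.sentence.key: set() for a in anns}
        resp = simulate_workers(hits, gold, sensitivity=0.5, specificity=0.5,
                                n_workers_per_hit=3, rng_seed=4)
        buf = io.StringIO()
        write_responses(resp, buf)
        buf.seek(0)
        back = ingest_responses(buf, hits)
        assert len(back) == len(resp)
        for a, b in zip(resp, back):
            assert (a.worker_id, a.hit_id, a.selections) == \
                   (b.worker_id, b.hit_id, b.selections)
            assert b.time_spent == pytest.approx(a.time_spent, abs=0.1)

    def test_malformed_rows_rejected_others_retained(self):
        anns = [make_annotation(3, 2, doc_id=f"D{i}") for i in range(3)]
        hits = partition_into_hits(anns, per_hit=25)
        csv_text = (
            "hit_id,worker_id,time_spent_seconds,selections\n"
            "hit0000,w1,100.0,0:0|1\n"
            "hit0000,w2,100.0,0:99\n"       # option index out of range
            "nosuchhit,w3,100.0,0:0\n"      # unknown HIT
            "hit0000,w4,100.0,1:0\n")
        out = ingest_responses(io.StringIO(csv_text), hits)
        assert [r.worker_id for r in out] == ["w1", "w4"]
        with pytest.raises(ValueError):
            ingest_responses(io.StringIO(csv_text), hits, strict=True)

    def test_simulated_batch_bookkeeping(self):
        anns = [make_annotation(3, 2, doc_id=f"D{i}") for i in range(671)]
        hits = partition_into_hits(anns, per_hit=25)
        resp = simulate_workers(hits, {}, n_workers_per_hit=5, rng_seed=0)
        assert len(resp) == 135
        per_hit = defaultdict(int)
        for r in resp:
            per_hit[r.hit_id] += 1
        assert set(per_hit.values()) == {5}


class TestCostModel:
    def test_pilot_estimate(self):
        # 1 HIT, 400 assignments at $0.15; >= 10 assignments/HIT so the
        # 20% fee surcharge applies: $60.00 reward + $24.00 fees = $84.00
        rep = estimate_cost(CostPlan(1, 400, 0.15))
        assert (rep.total_reward, rep.total_fees, rep.total_cost) == \
               (60.0, 24.0, 84.0)

    def test_pilot_actual_with_193_approved_assignments(self):
        rep = estimate_cost(CostPlan(1, 400, 0.15), n_assignments_actual=193)
        assert rep.total_reward == 28.95
        assert rep.total_fees == 11.58
        assert rep.total_cost == 40.53

    def test_final_study_total(self):
        # 27 HITs x 5 assignments at $0.50; under the surcharge threshold
        rep = estimate_cost(CostPlan(27, 5, 0.5))
        assert rep.total_fees == 13.5
        assert rep.total_cost == 81.0

    def test_zero_assignments_cost_nothing(self):
        assert estimate_cost(CostPlan(0, 5, 0.5)).total_cost == 0.0

    def test_negative_reward_is_an_error(self):
        with pytest.raises(ValueError):
            CostPlan(1, 5, -0.1)

    def test_cost_linear_in_assignments(self):
        plan = CostPlan(1, 5, 0.5)
        c1 = estimate_cost(plan, 10).total_cost
        c2 = estimate_cost(plan, 20).total_cost
        c3 = estimate_cost(plan, 30).total_cost
        assert c2 - c1 == pytest.approx(c3 - c2)


def _one_hit_setup(n_sent=4):
    anns = [make_annotation(3, 2, doc_id=f"D{i}") for i in range(n_sent)]
    hits = partition_into_hits(anns, per_hit=25)
    return anns, hits


def _response(hits, worker, time_spent, chosen):
    return WorkerResponse(worker, hits[0].hit_id, time_spent,
                          {qi: frozenset(opts)
                           for qi, opts in chosen.items()})


class TestAggregateVotes:
    def test_unanimous_selection_validates_at_five(self):
        anns, hits = _one_hit_setup()
        t = hits[0].questions[0].options[0]
        resp = [_response(hits, f"w{i}", 100, {0: {0}}) for i in range(5)]
        validated, counts = aggregate_votes(
            resp, hits, AggregationConfig(min_votes=5))
        assert t.key in validated
        assert counts[t.key] == 5

    def test_time_filter_discounts_fast_workers(self):
        anns, hits = _one_hit_setup()
        t = hits[0].questions[0].options[0]
        resp = [_response(hits, f"w{i}", 400, {0: {0}}) for i in range(3)]
        resp.append(_response(hits, "w3", 10, {0: {0}}))   # below min_time
        resp.append(_response(hits, "w4", 400, {}))
        validated, counts = aggregate_votes(
            resp, hits, AggregationConfig(min_votes=4, min_time=300))
        assert counts[t.key] == 3
        assert t.key not in validated

    def test_repeated_submissions_by_one_worker_count_once(self):
        anns, hits = _one_hit_setup()
        t = hits[0].questions[0].options[0]
        resp = [_response(hits, "same", 100, {0: {0}}) for _ in range(4)]
        _, counts = aggregate_votes(resp, hits, AggregationConfig(min_votes=1))
        assert counts[t.key] == 1

    def test_exact_equality_mode(self):
        anns, hits = _one_hit_setup()
        resp = [_response(hits, f"w{i}", 100, {0: {0}}) for i in range(4)]
        v_exact, _ = aggregate_votes(
            resp, hits, AggregationConfig(min_votes=5, exact=True))
        assert not v_exact
        v_ge, _ = aggregate_votes(resp, hits, AggregationConfig(min_votes=4))
        assert len(v_ge) == 1

    def test_randomized_fixture_matches_brute_force_recount(self):
        """Validated set equals an independent recount over every
        (triple, worker) pair on a ~200-triple simulated batch."""
        anns = [make_annotation(4, 3, doc_id=f"D{i}") for i in range(12)]
        hits = partition_into_hits(anns, per_hit=5)
        gold = {a.sentence.key: set() for a in anns}
        resp = simulate_workers(hits, gold, sensitivity=0.5, specificity=0.6,
                                n_workers_per_hit=5, rng_seed=21)
        cfg = AggregationConfig(min_votes=3, min_time=400)
        validated, counts = aggregate_votes(resp, hits, cfg)

        voters = defaultdict(set)
        hit_by_id = {h.hit_id: h for h in hits}
        for r in resp:
            if r.time_spent < cfg.min_time:
                continue
            for qi, chosen in r.selections.items():
                for oi in chosen:
                    key = hit_by_id[r.hit_id].questions[qi].options[oi].key
                    voters[key].add(r.worker_id)
        assert validated == {k for k, v in voters.items() if len(v) >= 3}
        assert counts == {k: len(v) for k, v in voters.items()}

    def test_monotone_in_min_votes_and_min_time(self, small_scenario):
        """Raising either threshold never grows the validated set (the
        row/column ordering of a votes-by-time table)."""
        b = small_scenario
        table = {}
        for k in (3, 4, 5):
            for mt in (0, 300, 750):
                v, _ = aggregate_votes(
                    b.responses, b.hits,
                    AggregationConfig(min_votes=k, min_time=mt))
                table[(k, mt)] = v
        for k in (3, 4, 5):
            assert table[(k, 750)] <= table[(k, 300)] <= table[(k, 0)]
        for mt in (0, 300, 750):
            assert table[(5, mt)] <= table[(4, mt)] <= table[(3, mt)]


class TestScoreWorkers:
    def test_exact_gold_selection_scores_one(self):
        anns, hits = _one_hit_setup(2)
        q0 = hits[0].questions[0]
        gold = {q0.sentence_key: {q0.options[0].key, q0.options[1].key}}
        resp = [_response(hits, "w0", 100, {0: {0, 1}})]
        sent_f, overall, n = score_workers(resp, hits, gold)
        assert sent_f[q0.sentence_key] == 1.0
        assert overall == 1.0 and n == 1

    def test_empty_selection_on_nonempty_gold_scores_zero(self):
        anns, hits = _one_hit_setup(2)
        q0 = hits[0].questions[0]
        gold = {q0.sentence_key: {q0.options[0].key}}
        resp = [_response(hits, "w0", 100, {})]
        sent_f, overall, _ = score_workers(resp, hits, gold)
        assert sent_f[q0.sentence_key] == 0.0

    def test_two_worker_two_sentence_hand_computation(self):
        anns, hits = _one_hit_setup(2)
        q0, q1 = hits[0].questions
        gold = {q0.sentence_key: {q0.options[0].key, q0.options[1].key},
                q1.sentence_key: {q1.options[0].key}}
        # w0 on q0: picks {0,2} -> P=1/2, R=1/2, F=1/2; on q1: {0} -> F=1
        # w1 on q0: picks {0,1} -> F=1;               on q1: {0,1} -> F=2/3
        resp = [_response(hits, "w0", 500, {0: {0, 2}, 1: {0}}),
                _response(hits, "w1", 500, {0: {0, 1}, 1: {0, 1}})]
        sent_f, overall, n = score_workers(resp, hits, gold)
        assert sent_f[q0.sentence_key] == pytest.approx((0.5 + 1.0) / 2)
        assert sent_f[q1.sentence_key] == pytest.approx((1.0 + 2 / 3) / 2)
        assert overall == pytest.approx((0.75 + 5 / 6) / 2)
        assert n == 2

    def test_min_time_excludes_workers_from_count(self):
        anns, hits = _one_hit_setup(1)
        q0 = hits[0].questions[0]
        gold = {q0.sentence_key: {q0.options[0].key}}
        resp = [_response(hits, "slow", 500, {0: {0}}),
                _response(hits, "fast", 10, {0: {1}})]
        _, overall, n = score_workers(resp, hits, gold, min_time=300)
        assert n == 1 and overall == 1.0


class TestSimulateWorkers:
    def _gold_setup(self):
        anns = [make_annotation(3, 2, doc_id=f"D{i}") for i in range(6)]
        hits = partition_into_hits(anns, per_hit=25)
        gold = {}
        for q in hits[0].questions:
            gold[q.sentence_key] = {q.options[0].key}
        return hits, gold

    def test_perfect_workers_select_exactly_gold(self):
        hits, gold = self._gold_setup()
        resp = simulate_workers(hits, gold, sensitivity=1.0, specificity=1.0,
                                n_workers_per_hit=2, rng_seed=0)
        for r in resp:
            chosen = {hits[0].questions[qi].options[oi].key
                      for qi, sel in r.selections.items() for oi in sel}
            assert chosen == set().union(*gold.values())

    def test_zero_sensitivity_never_selects_gold(self):
        hits, gold = self._gold_setup()
        resp = simulate_workers(hits, gold, sensitivity=0.0, specificity=0.5,
                                n_workers_per_hit=3, rng_seed=1)
        gold_all = set().union(*gold.values())
        for r in resp:
            chosen = {hits[0].questions[qi].options[oi].key
                      for qi, sel in r.selections.items() for oi in sel}
            assert not (chosen & gold_all)

    def test_deterministic_under_seed(self):
        hits, gold = self._gold_setup()
        a = simulate_workers(hits, gold, rng_seed=9)
        b = simulate_workers(hits, gold, rng_seed=9)
        assert [(r.worker_id, r.time_spent, r.selections) for r in a] == \
               [(r.worker_id, r.time_spent, r.selections) for r in b]

    def test_aggregate_beats_single_worker_monte_carlo(self):
        """Wisdom of the crowd: at sensitivity = specificity = 0.8 with 5
        workers and majority vote 3, the mean F of the aggregated triple
        set against gold exceeds the mean single-worker F over 100 seeds."""
        hits, gold = self._gold_setup()
        gold_all = set().union(*gold.values())

        def set_f(sel):
            if not sel and not gold_all:
                return 1.0
            tp = len(sel & gold_all)
            if tp == 0:
                return 0.0
            p, r = tp / len(sel), tp / len(gold_all)
            return 2 * p * r / (p + r)

        agg_f, single_f = [], []
        for seed in range(100):
            resp = simulate_workers(hits, gold, sensitivity=0.8,
                                    specificity=0.8, n_workers_per_hit=5,
                                    rng_seed=seed)
            validated, _ = aggregate_votes(resp, hits,
                                           AggregationConfig(min_votes=3))
            agg_f.append(set_f(validated))
            for r in resp:
                chosen = {hits[0].questions[qi].options[oi].key
                          for qi, sel in r.selections.items() for oi in sel}
                single_f.append(set_f(chosen))
        assert np.mean(agg_f) > np.mean(single_f)

    def test_aggregate_f_nondecreasing_in_worker_count(self):
        """More workers never hurt the aggregated set in expectation for
        accuracy above one half (one-sided Monte-Carlo check)."""
        hits, gold = self._gold_setup()
        gold_all = set().union(*gold.values())

        def mean_f(n_workers, k):
            fs = []
            for seed in range(40):
                resp = simulate_workers(hits, gold, sensitivity=0.8,
                                        specificity=0.8,
                                        n_workers_per_hit=n_workers,
                                        rng_seed=1000 + seed)
                v, _ = aggregate_votes(resp, hits,
                                       AggregationConfig(min_votes=k))
                tp = len(v & gold_all)
                p = tp / len(v) if v else 0.0
                r = tp / len(gold_all)
                fs.append(2 * p * r / (p + r) if p + r else 0.0)
            return float(np.mean(fs))

        # majority vote at each panel size
        f3, f5, f9 = mean_f(3, 2), mean_f(5, 3), mean_f(9, 5)
        assert f3 <= f5 + 0.02 and f5 <= f9 + 0.02
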