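"""The crowdsourcing feedback loop.

Candidate triples are rendered as multiple-choice options — one question
per sentence, "entity1 — relation — entity2" per option — batched into
HITs of up to 25 sentences, each completed by a fixed number of workers.
Responses come back as an MTurk-style batch CSV; aggregation validates a
triple when at least ``min_votes`` distinct qualifying workers selected
it, where a worker qualifies if the assignment took at least ``min_time``
seconds.  A seeded simulated-worker model (per-worker sensitivity /
specificity, lognormal time-spent) stands in for the live platform.

The cost model reproduces the platform fee structure: a 20% base fee on
the reward plus a 20% surcharge for HITs with 10 or more assignments.
"""

from __future__ import annotations

import csv
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .extraction import CandidateTriple, SentenceAnnotation, \
    enumerate_candidate_triples

__all__ = [
    "HIT",
    "Question",
    "WorkerResponse",
    "AggregationConfig",
    "CostPlan",
    "CostReport",
    "partition_into_hits",
    "render_hits",
    "write_question_batch",
    "estimate_cost",
    "ingest_responses",
    "write_responses",
    "aggregate_votes",
    "score_workers",
    "simulate_workers",
]

TripleKey = tuple[str, str, str, str]   # (sentence_key, subj, pred, obj)


@dataclass(frozen=True)
class Question:
    sentence_key: str
    sentence_text: str
    options: tuple[CandidateTriple, ...]


@dataclass(frozen=True)
class HIT:
    hit_id: str
    questions: tuple[Question, ...]
    assignments_planned: int = 5


@dataclass
class WorkerResponse:
    worker_id: str
    hit_id: str
    time_spent: float                       # seconds, whole assignment
    selections: dict[int, frozenset[int]]   # question index -> option indices

    def __post_init__(self) -> None:
        if self.time_spent < 0:
            raise ValueError("time_spent must be >= 0")


@dataclass(frozen=True)
class AggregationConfig:
    """``min_votes`` distinct workers, counting only assignments with
    ``time_spent >= min_time``; ``exact`` switches ≥k to =k."""

    min_votes: int = 3
    min_time: float = 0.0
    exact: bool = False

    def __post_init__(self) -> None:
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")
        if self.min_time < 0:
            raise ValueError("min_time must be >= 0")


@dataclass(frozen=True)
class CostPlan:
    n_hits: int
    assignments_per_hit: int
    reward_per_assignment: float
    fee_rate_base: float = 0.20
    fee_surcharge_rate: float = 0.20
    surcharge_threshold: int = 10

    def __post_init__(self) -> None:
        if self.reward_per_assignment < 0:
            raise ValueError("reward must be >= 0")
        if self.n_hits < 0 or self.assignments_per_hit < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class CostReport:
    n_assignments: int
    total_reward: float
    total_fees: float
    total_cost: float


def partition_into_hits(annotations: Sequence[SentenceAnnotation],
                        per_hit: int = 25,
                        assignments_per_hit: int = 5,
                        max_options: int | None = None) -> list[HIT]:
    """Order-preserving partition of sentences into HITs of ``per_hit``
    questions; all HITs full except possibly the last (ceil(n/per_hit)
    HITs in total).  Zero-option questions are kept here and omitted at
    render time."""
    if per_hit < 1:
        raise ValueError("per_hit must be >= 1")
    questions = []
    for ann in annotations:
        opts = enumerate_candidate_triples(ann)
        if max_options is not None:
            opts = opts[:max_options]
        questions.append(Question(ann.sentence.key, ann.sentence.text,
                                  tuple(opts)))
    hits = []
    for h in range(math.ceil(len(questions) / per_hit)):
        chunk = tuple(questions[h * per_hit:(h + 1) * per_hit])
        hits.append(HIT(f"hit{h:04d}", chunk, assignments_per_hit))
    return hits


def render_option(triple: CandidateTriple) -> str:
    s, p, o = triple.surfaces
    return f"{s} — {p} — {o}"


def render_hits(hits: Sequence[HIT], max_options: int = 18) -> list[dict]:
    """Question batch rows: hit_id, sentence_id, sentence_text,
    option_1..option_N (empty-padded).  Zero-option questions are
    omitted (a multiple-choice question needs at least one option)."""
    rows = []
    for hit in hits:
        for q in hit.questions:
            if not q.options:
                continue
            row = {"hit_id": hit.hit_id, "sentence_id": q.sentence_key,
                   "sentence_text": q.sentence_text}
            for i in range(max_options):
                row[f"option_{i + 1}"] = (render_option(q.options[i])
                                          if i < len(q.options) else "")
            rows.append(row)
    return rows


def write_question_batch(hits: Sequence[HIT], fh: TextIO,
                         max_options: int = 18) -> None:
    rows = render_hits(hits, max_options)
    if not rows:
        return
    w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
    w.writeheader()
    w.writerows(rows)


# -- cost model ---------------------------------------------------------------

def estimate_cost(plan: CostPlan,
                  n_assignments_actual: int | None = None) -> CostReport:
    """Total reward + platform fees for a batch of HITs.

    The per-assignment fee is ``reward × fee_rate_base``, plus
    ``reward × fee_surcharge_rate`` when a HIT has at least
    ``surcharge_threshold`` assignments.  ``n_assignments_actual``
    replaces the planned count (approved assignments)."""
    if n_assignments_actual is not None and n_assignments_actual < 0:
        raise ValueError("actual assignment count must be >= 0")
    n = (plan.n_hits * plan.assignments_per_hit
         if n_assignments_actual is None else n_assignments_actual)
    fee_rate = plan.fee_rate_base
    if plan.assignments_per_hit >= plan.surcharge_threshold:
        fee_rate += plan.fee_surcharge_rate
    reward = n * plan.reward_per_assignment
    fees = n * plan.reward_per_assignment * fee_rate
    return CostReport(n, round(reward, 2), round(fees, 2),
                      round(reward + fees, 2))


# -- response ingestion -------------------------------------------------------

class ResponseValidationError(ValueError):
    def __init__(self, message: str, rows: list[int]):
        super().__init__(f"{message} (rows: {rows})")
        self.rows = rows


def write_responses(responses: Sequence[WorkerResponse], fh: TextIO) -> None:
    """Results batch CSV: one row per assignment; selections are
    per-question pipe-separated option indices, questions separated by
    semicolons as ``qidx:opt|opt``."""
    w = csv.writer(fh)
    w.writerow(["hit_id", "worker_id", "time_spent_seconds", "selections"])
    for r in responses:
        parts = [f"{qi}:{'|'.join(map(str, sorted(sel)))}"
                 for qi, sel in sorted(r.selections.items()) if sel]
        w.writerow([r.hit_id, r.worker_id, f"{r.time_spent:.1f}",
                    ";".join(parts)])


def ingest_responses(fh: TextIO, hits: Sequence[HIT],
                     strict: bool = False) -> list[WorkerResponse]:
    """Parse a results batch CSV against the HIT definitions.

    Rows referencing an unknown hit_id, question, or an option index
    beyond the question's option count are rejected with row-level
    diagnostics; valid rows are retained (``strict=True`` raises
    instead)."""
    by_id = {h.hit_id: h for h in hits}
    out: list[WorkerResponse] = []
    bad: list[int] = []
    reader = csv.DictReader(fh)
    for rowno, row in enumerate(reader, start=2):
        hit = by_id.get(row.get("hit_id", ""))
        if hit is None:
            bad.append(rowno)
            continue
        try:
            time_spent = float(row["time_spent_seconds"])
            selections: dict[int, frozenset[int]] = {}
            sel_field = row.get("selections", "") or ""
            for part in filter(None, sel_field.split(";")):
                qs, opts = part.split(":")
                qi = int(qs)
                if not 0 <= qi < len(hit.questions):
                    raise ValueError("bad question index")
                chosen = frozenset(int(x) for x in filter(None, opts.split("|")))
                if any(not 0 <= oi < len(hit.questions[qi].options)
                       for oi in chosen):
                    raise ValueError("bad option index")
                selections[qi] = chosen
            out.append(WorkerResponse(row["worker_id"], hit.hit_id,
                                      time_spent, selections))
        except (KeyError, ValueError):
            bad.append(rowno)
    if bad and strict:
        raise ResponseValidationError("malformed response rows", bad)
    return out


# -- aggregation and scoring --------------------------------------------------

def _selected_triples(resp: WorkerResponse, hit: HIT
                      ) -> Iterable[CandidateTriple]:
    for qi, chosen in resp.selections.items():
        q = hit.questions[qi]
        for oi in chosen:
            yield q.options[oi]


def aggregate_votes(responses: Sequence[WorkerResponse],
                    hits: Sequence[HIT],
                    cfg: AggregationConfig = AggregationConfig(),
                    ) -> tuple[set[TripleKey], dict[TripleKey, int]]:
    """Validated triple set plus the full per-triple vote histogram.

    A vote is one distinct worker selecting the triple in a qualifying
    assignment (``time_spent >= min_time``); repeated submissions by the
    same worker on the same HIT count once.  Validated means vote count
    ≥ ``min_votes`` (or == when ``cfg.exact``)."""
    by_id = {h.hit_id: h for h in hits}
    voters: dict[TripleKey, set[str]] = defaultdict(set)
    for resp in responses:
        if resp.time_spent < cfg.min_time:
            continue
        hit = by_id[resp.hit_id]
        for t in _selected_triples(resp, hit):
            voters[t.key].add(resp.worker_id)
    counts = {k: len(v) for k, v in voters.items()}
    if cfg.exact:
        validated = {k for k, c in counts.items() if c == cfg.min_votes}
    else:
        validated = {k for k, c in counts.items() if c >= cfg.min_votes}
    return validated, counts


def _set_f1(selected: set, gold: set) -> float:
    if not gold and not selected:
        return 1.0
    tp = len(selected & gold)
    if tp == 0:
        return 0.0
    prec = tp / len(selected)
    rec = tp / len(gold)
    return 2 * prec * rec / (prec + rec)


def score_workers(responses: Sequence[WorkerResponse],
                  hits: Sequence[HIT],
                  gold: Mapping[str, set[TripleKey]],
                  min_time: float = 0.0,
                  ) -> tuple[dict[str, float], float, int]:
    """Worker performance against a gold standard.

    Each qualifying assignment's per-sentence selections are scored as set
    retrieval (F1 against the gold triple set of that sentence); sentence
    F averages over qualifying responses; the overall F is the mean of the
    per-sentence values.  Returns (per-sentence F, overall mean F, number
    of qualifying workers)."""
    by_id = {h.hit_id: h for h in hits}
    per_sentence: dict[str, list[float]] = defaultdict(list)
    workers: set[str] = set()
    for resp in responses:
        if resp.time_spent < min_time:
            continue
        workers.add(resp.worker_id)
        hit = by_id[resp.hit_id]
        for qi, q in enumerate(hit.questions):
            if q.sentence_key not in gold:
                continue
            chosen = {q.options[oi].key
                      for oi in resp.selections.get(qi, frozenset())}
            per_sentence[q.sentence_key].append(
                _set_f1(chosen, gold[q.sentence_key]))
    sent_f = {k: float(np.mean(v)) for k, v in per_sentence.items()}
    overall = float(np.mean(list(sent_f.values()))) if sent_f else 0.0
    return sent_f, overall, len(workers)


# -- simulated workers --------------------------------------------------------

def simulate_workers(hits: Sequence[HIT],
                     gold: Mapping[str, set[TripleKey]],
                     sensitivity: float = 0.8,
                     specificity: float = 0.8,
                     n_workers_per_hit: int = 5,
                     time_log_mean: float = math.log(600.0),
                     time_log_sigma: float = 0.5,
                     rng_seed: int = 0,
                     ) -> list[WorkerResponse]:
    """MTurk stand-in: each worker selects each gold option with
    probability ``sensitivity`` and each non-gold option with probability
    ``1 - specificity``, independently; assignment time is lognormal.
    Deterministic under ``rng_seed``; worker ids are unique per (HIT,
    slot)."""
    if not 0 <= sensitivity <= 1 or not 0 <= specificity <= 1:
        raise ValueError("sensitivity/specificity must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    out: list[WorkerResponse] = []
    for hit in hits:
        for w in range(n_workers_per_hit):
            selections: dict[int, frozenset[int]] = {}
            for qi, q in enumerate(hit.questions):
                g = gold.get(q.sentence_key, set())
                chosen = []
                for oi, opt in enumerate(q.options):
                    p = sensitivity if opt.key in g else 1.0 - specificity
                    if rng.random() < p:
                        chosen.append(oi)
                if chosen:
                    selections[qi] = frozenset(chosen)
            t = float(rng.lognormal(time_log_mean, time_log_sigma))
            out.append(WorkerResponse(f"{hit.hit_id}-w{w:02d}", hit.hit_id,
                                      t, selections))
    return out
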