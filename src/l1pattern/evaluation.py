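"""Scoring predictions against truth annotations and the (m, t, delta)
parameter sweep.

Predictions and truths are strand-annotated intervals.  A prediction counts
as a true positive when it can be assigned one-to-one to a same-strand
truth interval with positive overlap; the assignment is greedy by
descending overlap, which maximizes matched pairs on the disjoint-ish
intervals this tool produces.  An optional reciprocal-overlap fraction
tightens the criterion.  The F1-maximizing grid point selects default
detection parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

from .pattern_chaining import PatternMatch, chain_seeds, detect, infer_element_bounds, resolve_overlaps
from .probe_design import ProbeSet
from .seed_mapping import DetectionParams, map_probeset

__all__ = [
    "Interval",
    "EvaluationResult",
    "SweepRecord",
    "match_predictions",
    "precision_recall_f1",
    "f1_score",
    "parameter_sweep",
    "matches_to_intervals",
    "sweep_table",
]


class Interval(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str = "."


def matches_to_intervals(matches: Sequence[PatternMatch]) -> list[Interval]:
    return [Interval(m.chrom, m.element_start, m.element_end, m.strand) for m in matches]


@dataclass(frozen=True)
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class SweepRecord:
    m: int
    t: int
    delta: int
    result: EvaluationResult


def _check(intervals: Sequence[Interval], label: str) -> None:
    for iv in intervals:
        if iv.start > iv.end:
            raise ValueError(f"malformed {label} interval {iv}: start > end")


def match_predictions(
    predictions: Sequence[Interval],
    truth: Sequence[Interval],
    min_reciprocal_overlap: float = 0.0,
) -> tuple[int, int, int]:
    """One-to-one greedy assignment of predictions to truth intervals.

    Returns (tp, fp, fn).  A pair is eligible when on the same chromosome
    and strand with positive overlap (and, if requested, overlap covering
    at least ``min_reciprocal_overlap`` of both intervals).  Pairs are
    assigned in order of descending overlap.
    """
    _check(predictions, "prediction")
    _check(truth, "truth")
    pairs: list[tuple[int, int, int]] = []  # (overlap, pred idx, truth idx)
    for pi, p in enumerate(predictions):
        for ti, tr in enumerate(truth):
            if p.chrom != tr.chrom or p.strand != tr.strand:
                continue
            ov = min(p.end, tr.end) - max(p.start, tr.start)
            if ov <= 0:
                continue
            if min_reciprocal_overlap > 0:
                if ov < min_reciprocal_overlap * (p.end - p.start) or ov < min_reciprocal_overlap * (tr.end - tr.start):
                    continue
            pairs.append((ov, pi, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        tp += 1
    return tp, len(predictions) - tp, len(truth) - tp


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def precision_recall_f1(tp: int, fp: int, fn: int) -> EvaluationResult:
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvaluationResult(tp, fp, fn, precision, recall, f1_score(precision, recall))


def evaluate_matches(
    matches: Sequence[PatternMatch],
    truth: Sequence[Interval],
    min_reciprocal_overlap: float = 0.0,
) -> EvaluationResult:
    tp, fp, fn = match_predictions(
        matches_to_intervals(matches), truth, min_reciprocal_overlap
    )
    return precision_recall_f1(tp, fp, fn)


def parameter_sweep(
    genome: dict[str, str],
    probeset: ProbeSet,
    truth: Sequence[Interval],
    ms: Sequence[int],
    ts: Sequence[int],
    deltas: Sequence[int],
) -> tuple[list[SweepRecord], SweepRecord]:
    """Run detection over the full (m, t, delta) grid and score each point.

    Returns all records plus the F1-argmax (ties -> smaller m, then t, then
    delta).  Seed mapping is shared per delta and chaining per (delta, t);
    m only filters chains by length, so the sweep costs far less than
    independent detection runs.
    """
    ms, ts, deltas = list(ms), list(ts), list(deltas)
    if not ms or not ts or not deltas:
        raise ValueError("empty parameter grid")
    m_floor = max(2, min(ms))
    records: list[SweepRecord] = []
    from dataclasses import replace as _replace

    for delta in sorted(set(deltas)):
        base = DetectionParams(m=m_floor, t=max(ts), delta=delta)
        base.validate_for(probeset)
        index = map_probeset(genome, probeset, base)
        for t in sorted(set(ts)):
            chains = chain_seeds(index, probeset, DetectionParams(m=m_floor, t=t, delta=delta))
            bounded = []
            for chain in chains:
                s, e = infer_element_bounds(chain, probeset, index.chrom_lengths.get(chain.chrom))
                bounded.append(_replace(chain, element_start=s, element_end=e))
            for m in sorted(set(ms)):
                DetectionParams(m=m, t=t, delta=delta).validate_for(probeset)
                kept = resolve_overlaps([c for c in bounded if c.n_seeds >= m])
                records.append(
                    SweepRecord(m, t, delta, evaluate_matches(kept, truth))
                )
    best = min(records, key=lambda r: (-r.result.f1, r.m, r.t, r.delta))
    return records, best


def sweep_table(records: Sequence[SweepRecord]) -> pd.DataFrame:
    """Sweep records as a table (delta, t, m, precision, recall, f1)."""
    return pd.DataFrame(
        [
            {
                "delta": r.delta,
                "t": r.t,
                "m": r.m,
                "precision": r.result.precision,
                "recall": r.result.recall,
                "f1": r.result.f1,
            }
            for r in records
        ]
    )
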