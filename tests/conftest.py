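"""Shared fixtures and independent oracle implementations."""

from __future__ import annotations

import numpy as np
import pytest

from serialsv.alignment import AlnRecord
from serialsv.segmentation import SegmentMatrix


def make_record(qs, qe, ts, te, strand="+", qlen=None, tlen=None,
                qname="query", tname="ref", matches=None, block=None):
    span = max(qe - qs, te - ts)
    return AlnRecord(
        query_name=qname, query_len=qlen if qlen is not None else max(qe, 100_000),
        query_start=qs, query_end=qe, strand=strand,
        target_name=tname, target_len=tlen if tlen is not None else max(te, 100_000),
        target_start=ts, target_end=te,
        matches=matches if matches is not None else min(qe - qs, te - ts),
        block_len=block if block is not None else span,
    )


def make_matrix(rows, col_lengths=None, row_lengths=None) -> SegmentMatrix:
    ent = np.asarray(rows, dtype=np.int8)
    n, m = ent.shape
    return SegmentMatrix(
        ent,
        col_lengths if col_lengths is not None else np.full(m, 1000),
        row_lengths if row_lengths is not None else np.full(n, 1000),
    )


def score_reference(entries: np.ndarray, gap_cap: int = 20) -> float:
    """Straightforward re-implementation of the greedy segment score."""
    entries = np.asarray(entries)
    n, m = entries.shape
    steps = min(n, m)
    offset = 0
    total = 0.0
    for i in range(steps):
        cands = [j + 1 for j in range(m)
                 if entries[i, j] == 1 and abs(offset + 1 - (j + 1)) <= gap_cap]
        if not cands:
            offset += 1
            continue
        dist = min(abs(offset + 1 - j) for j in cands)
        total += 1.0 / (1.0 + dist)
        offset = min(j for j in cands if abs(offset + 1 - j) == dist)
    denom = m + n - offset
    return total / denom if denom > 0 else 0.0


def brute_force_best_score(matrix: SegmentMatrix, max_depth: int = 3,
                           max_dups: int = 2, gap_cap: int = 20) -> float:
    """Exhaustive enumeration of all op sequences to max_depth (no beam, no
    deduplication) — the independent reference for the breadth-first search."""
    from serialsv.engine import apply_sv, enumerate_candidate_svs, score_matrix

    best = score_matrix(matrix, gap_cap)

    def recurse(m: SegmentMatrix, depth: int) -> None:
        nonlocal best
        if depth == max_depth:
            return
        for op in enumerate_candidate_svs(m):
            if op.kind == "DUP" and np.any(
                    m.dup_counts[op.col_i : op.col_j] >= max_dups):
                continue
            child = apply_sv(m, op, validate=False)
            best = max(best, score_matrix(child, gap_cap))
            recurse(child, depth + 1)

    recurse(matrix, 0)
    return best


def random_repeat_matrix(rng: np.random.Generator, max_cols: int = 6,
                         max_rows: int = 5) -> SegmentMatrix:
    """Random small matrix guaranteed to carry at least one repeat pair."""
    m = int(rng.integers(2, max_cols + 1))
    n = int(rng.integers(2, max_rows + 1))
    ent = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        for j in range(m):
            if rng.random() < 0.4:
                ent[i, j] = 1 if rng.random() < 0.7 else -1
    # force a repeat pair in a random row
    row = int(rng.integers(0, n))
    cols = rng.choice(m, size=2, replace=False)
    sign = 1 if rng.random() < 0.5 else -1
    ent[row, cols[0]] = sign
    ent[row, cols[1]] = sign if rng.random() < 0.5 else -sign
    return make_matrix(ent)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
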