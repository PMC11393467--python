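"""NAHR trajectory enumeration, simulation, scoring and breadth-first search.

Rearrangements mediated by non-allelic homologous recombination leave a
signature in the segmented dotplot: a repeat pair appears as two nonzero cells
in the same row. Deletions and duplications arise between equally oriented
copies, inversions between oppositely oriented ones. Candidate events are
simulated directly on the matrix by deleting, duplicating or inverting
reference columns, and each mutated matrix is scored against the query
ordering with a greedy, gap-penalized segment alignment score (1.0 = the
mutated reference reproduces the query structure exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment import InputError
from .segmentation import SegmentMatrix

KINDS = ("DEL", "DUP", "INV")


@dataclass(frozen=True, order=True)
class SVOp:
    """One candidate NAHR event anchored on a repeat pair.

    ``col_i`` / ``col_j`` are the anchoring reference columns (i < j);
    ``anchor_row`` records one query row in which the repeat pair was seen.
    DEL removes columns [col_i, col_j) (one repeat copy survives), DUP inserts
    a copy of [col_i, col_j) before col_j, INV reverses and negates columns
    [col_i, col_j] inclusive.
    """

    kind: str
    col_i: int
    col_j: int
    anchor_row: int = field(compare=False, default=0)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InputError(f"unknown SV kind {self.kind!r}")
        if not 0 <= self.col_i < self.col_j:
            raise InputError("need col_i < col_j")


@dataclass(frozen=True)
class SearchConfig:
    """Search and reporting parameters.

    max_depth: longest event series explored (3 by default).
    max_dups: per-column duplication budget (2 by default).
    beam_width: nodes retained per layer (None = unbounded).
    report_window: trajectories within this fraction of the best score are reported.
    success_threshold: minimum score for a trajectory to count as a successful
        sequence reconstruction (0.98 default; 0.95 is the cross-species preset).
    gap_cap: maximum segment offset considered by the scoring recurrence.
    """

    max_depth: int = 3
    max_dups: int = 2
    beam_width: int | None = None
    report_window: float = 0.05
    success_threshold: float = 0.98
    gap_cap: int = 20

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise InputError("max_depth must be >= 1")
        if not 0 < self.success_threshold <= 1:
            raise InputError("success_threshold must be in (0, 1]")


@dataclass
class Trajectory:
    """An ordered series of NAHR events and the matrix state it produces."""

    ops: tuple[SVOp, ...]
    final_matrix: SegmentMatrix
    score: float
    depth: int

    def op_string(self) -> str:
        return "+".join(op.kind.lower() for op in self.ops) if self.ops else "ref"


STATUSES = ("REF", "SV1", "SSV", "UNEXPLAINED", "UNASSEMBLED")


@dataclass
class LocusCall:
    """Classification of one locus: reference-like, simple SV, serial SV,
    unexplained, or not contiguously assembled."""

    status: str
    trajectories: list[Trajectory]
    best_score: float

    @property
    def best(self) -> Trajectory | None:
        return self.trajectories[0] if self.trajectories else None


def _enumerate_fast(ent: np.ndarray) -> list[tuple[str, int, int, int]]:
    """(kind, col_i, col_j, anchor_row) tuples, deduplicated and sorted."""
    out: dict[tuple[str, int, int], int] = {}
    for row in range(ent.shape[0]):
        cols = np.flatnonzero(ent[row])
        if len(cols) < 2:
            continue
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                i, j = int(cols[a]), int(cols[b])
                kinds = ("DEL", "DUP") if ent[row, i] == ent[row, j] else ("INV",)
                for kind in kinds:
                    out.setdefault((kind, i, j), row)
    return [(k, i, j, r) for (k, i, j), r in sorted(out.items())]


def enumerate_candidate_svs(matrix: SegmentMatrix) -> list[SVOp]:
    """All NAHR events licensed by repeat pairs in the matrix.

    For every row and pair of nonzero columns i<j: equal signs license DEL and
    DUP, opposite signs license INV. Identical (kind, col_i, col_j) triples
    found in several rows are deduplicated (first row kept); output is sorted.
    """
    return [SVOp(k, i, j, anchor_row=r) for k, i, j, r in _enumerate_fast(matrix.entries)]


def _check_op(matrix: SegmentMatrix, op: SVOp) -> None:
    if op.col_j >= matrix.n_cols:
        raise InputError(f"{op} out of bounds for {matrix.n_cols} columns")
    a = matrix.entries[op.anchor_row, op.col_i]
    b = matrix.entries[op.anchor_row, op.col_j]
    if a == 0 or b == 0:
        raise InputError(f"{op}: anchor cells must be nonzero")
    if op.kind == "INV":
        if a == b:
            raise InputError(f"{op}: INV needs oppositely oriented anchors")
    elif a != b:
        raise InputError(f"{op}: DEL/DUP need equally oriented anchors")


def _apply_fast(ent: np.ndarray, lens: np.ndarray, dups: np.ndarray,
                kind: str, i: int, j: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = ent.shape[1]
    if kind == "DEL":
        keep = np.concatenate((np.arange(0, i), np.arange(j, m)))
        return ent[:, keep], lens[keep], dups[keep]
    if kind == "DUP":
        order = np.concatenate((np.arange(0, j), np.arange(i, j), np.arange(j, m)))
        new_dups = dups[order].copy()
        new_dups[i:j] += 1                 # original block
        new_dups[j : j + (j - i)] += 1     # inserted copy
        return ent[:, order], lens[order], new_dups
    # INV: reverse [i, j] inclusive, negate entries in those columns
    order = np.concatenate((np.arange(0, i), np.arange(j, i - 1, -1),
                            np.arange(j + 1, m)))
    new_ent = ent[:, order].copy()
    new_ent[:, i : j + 1] *= -1
    return new_ent, lens[order], dups[order]


def apply_sv(matrix: SegmentMatrix, op: SVOp, *, validate: bool = True) -> SegmentMatrix:
    """Simulate one NAHR event by mutating reference columns.

    Column bp lengths and duplication counters travel with their columns;
    DUP increments the counter on both copies of the duplicated block.
    """
    if validate:
        _check_op(matrix, op)
    ent, lens, dups = _apply_fast(matrix.entries, matrix.col_lengths,
                                  matrix.dup_counts, op.kind, op.col_i, op.col_j)
    return SegmentMatrix(ent, lens, matrix.row_lengths, dups)


def score_matrix(matrix: SegmentMatrix, gap_cap: int = 20, *,
                 weighted: bool = False) -> float:
    """Greedy gap-penalized segment alignment score in [0, 1].

    Forward-aligning cells (+1) are matches; everything else is a mismatch.
    Walking query segments in order, each row is scored by its closest match
    relative to the running reference offset: ``1 / (1 + |offset + 1 - j|)``
    with 1-based reference index ``j``, offset starting at 0 and following the
    matched column (advancing by one on unmatched rows). The sum is normalized
    by ``n_cols + n_rows - offset_end`` so that a full main diagonal of a
    square matrix — a perfect alignment — scores exactly 1.0. Candidate
    matches farther than ``gap_cap`` columns from the expected position are
    ignored, keeping the scan linear.

    With ``weighted=True`` rows and columns contribute proportionally to their
    bp segment lengths instead of counting each segment once.
    """
    n, m = matrix.n_rows, matrix.n_cols
    if n == 0 or m == 0:
        return 0.0
    if not weighted:
        return _score_entries(matrix.entries, gap_cap)
    ent = matrix.entries
    steps = min(n, m)
    offset = 0  # 1-based index of the last matched reference column
    total = 0.0
    for i in range(steps):
        js = np.flatnonzero(ent[i] == 1) + 1  # 1-based
        if len(js):
            dist = np.abs(offset + 1 - js)
            in_cap = dist <= gap_cap
            js, dist = js[in_cap], dist[in_cap]
        if len(js) == 0:
            offset += 1
            continue
        best = int(np.argmin(dist))  # ties: smaller j (np.argmin is first)
        total += float(matrix.row_lengths[i]) / (1.0 + float(dist[best]))
        offset = int(js[best])
    matched_bp = float(matrix.x_bounds[min(offset, m)])
    denom = float(matrix.col_lengths.sum() + matrix.row_lengths.sum()) - matched_bp
    return float(total / denom) if denom > 0 else 0.0


def _score_kernel(ent, gap_cap):
    """Unweighted greedy segment score on a raw entry array.

    Scans each query row for its closest forward match (ties resolve to the
    smaller column); written with plain loops so it can be JIT-compiled.
    """
    n, m = ent.shape
    steps = n if n < m else m
    offset = 0
    total = 0.0
    for i in range(steps):
        best_d = 1 << 30
        best_j = -1
        for j in range(m):
            if ent[i, j] == 1:
                d = offset - j  # = offset + 1 - (j + 1), 1-based columns
                if d < 0:
                    d = -d
                if d < best_d:
                    best_d = d
                    best_j = j + 1
        if best_j < 0 or best_d > gap_cap:
            offset += 1
        else:
            total += 1.0 / (1.0 + best_d)
            offset = best_j
    denom = m + n - offset
    if denom <= 0:
        return 0.0
    return total / denom


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _score_entries = njit(cache=False)(_score_kernel)
except ImportError:  # pragma: no cover
    _score_entries = _score_kernel


def search_ssv(matrix: SegmentMatrix, config: SearchConfig | None = None) -> list[Trajectory]:
    """Breadth-first exploration of NAHR event series up to ``max_depth``.

    Each node holds a mutated matrix; children are all candidate events of
    that state (DUPs are skipped once any column of the duplicated block has
    exhausted ``max_dups``). Matrix states already reached at a shallower or
    equal depth are not re-expanded. Returns every explored trajectory whose
    score is within ``report_window`` of the best, best first, with
    deterministic ordering (score desc, depth asc, lexicographic ops).
    """
    import hashlib

    config = config or SearchConfig()
    ent0 = np.ascontiguousarray(matrix.entries, dtype=np.int8)
    lens0 = np.ascontiguousarray(matrix.col_lengths, dtype=np.int64)
    dups0 = np.ascontiguousarray(matrix.dup_counts, dtype=np.int64)

    def digest(ent, lens, dups):
        h = hashlib.blake2b(digest_size=16)
        h.update(ent.shape[1].to_bytes(4, "little"))
        h.update(ent.tobytes())
        h.update(lens.tobytes())
        h.update(dups.tobytes())
        return h.digest()

    root_score = _score_entries(ent0, config.gap_cap)
    # per-layer nodes carry only (score, op tuples); matrices are replayed
    # from the root on expansion and for reporting, keeping memory flat
    explored: list[tuple[float, int, tuple]] = [(root_score, 0, ())]
    seen = {digest(ent0, lens0, dups0)}
    layer: list[tuple] = [()] if root_score < 1.0 - 1e-12 else []
    for depth in range(1, config.max_depth + 1):
        nxt: list[tuple[float, tuple]] = []
        for node_ops in layer:
            ent, lens, dups = ent0, lens0, dups0
            for kind, i, j, _ in node_ops:
                ent, lens, dups = _apply_fast(ent, lens, dups, kind, i, j)
            for op in _enumerate_fast(ent):
                kind, i, j, _ = op
                if kind == "DUP" and dups[i:j].max() >= config.max_dups:
                    continue
                cent, clens, cdups = _apply_fast(ent, lens, dups, kind, i, j)
                key = digest(cent, clens, cdups)
                if key in seen:
                    continue
                seen.add(key)
                nxt.append((_score_entries(cent, config.gap_cap), node_ops + (op,)))
        nxt.sort(key=lambda t: (-t[0], t[1]))
        if config.beam_width is not None:
            nxt = nxt[: config.beam_width]
        explored.extend((s, depth, ops) for s, ops in nxt)
        layer = [ops for _, ops in nxt]
        if not layer:
            break
        # a perfect reconstruction cannot be improved on; deeper series can
        # only restate it, so stop expanding further layers
        if nxt[0][0] >= 1.0 - 1e-12:
            break
    best = max(s for s, _, _ in explored)
    cut = (1.0 - config.report_window) * best
    kept = [(s, d, ops) for s, d, ops in explored if s >= cut - 1e-12]
    kept.sort(key=lambda t: (-t[0], t[1], t[2]))
    report = []
    for s, d, ops in kept:
        ent, lens, dups = ent0, lens0, dups0
        for kind, i, j, _ in ops:
            ent, lens, dups = _apply_fast(ent, lens, dups, kind, i, j)
        final = SegmentMatrix(ent, lens, matrix.row_lengths, dups)
        svops = tuple(SVOp(kind, i, j, anchor_row=r) for kind, i, j, r in ops)
        report.append(Trajectory(svops, final, s, d))
    return report


def classify_locus(trajectories: Sequence[Trajectory],
                   config: SearchConfig | None = None, *,
                   contiguous: bool = True) -> LocusCall:
    """Classify a locus from its reported trajectories.

    UNASSEMBLED if the query is not contiguously assembled; otherwise REF /
    SV1 / SSV according to the depth of the best successful trajectory
    (score >= success_threshold), or UNEXPLAINED if none succeeds.
    """
    config = config or SearchConfig()
    trajectories = list(trajectories)
    best_score = max((t.score for t in trajectories), default=0.0)
    if not contiguous:
        return LocusCall("UNASSEMBLED", trajectories, best_score)
    successful = [t for t in trajectories if t.score >= config.success_threshold]
    if not successful:
        return LocusCall("UNEXPLAINED", trajectories, best_score)
    best = min(successful, key=lambda t: (-t.score, t.depth, t.ops))
    if best.depth == 0:
        status = "REF"
    elif best.depth == 1:
        status = "SV1"
    else:
        status = "SSV"
    return LocusCall(status, trajectories, best_score)
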