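"""Alignment noise-reduction and dotplot condensation.

A set of pairwise alignments is compressed into a *segmented dotplot*: a small
matrix whose columns are reference segments, rows are query segments, and
entries are +1 (forward alignment), -1 (reverse) or 0 (no alignment). The
segmentation is exact — the union of nonzero cells traversed diagonally
reproduces the denoised alignments without information loss — and small, which
is what makes the exhaustive rearrangement search downstream tractable.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .alignment import AlnRecord, InputError


class ConsistencyError(RuntimeError):
    """An alignment could not be resolved exactly onto the grid."""


@dataclass(frozen=True)
class NoiseParams:
    """Minimum alignment length ``min_len`` and coordinate ``rounding``, in bp."""

    min_len: int
    rounding: int

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.rounding < 1:
            raise InputError("noise parameters must be >= 1 bp")

    def doubled(self) -> "NoiseParams":
        return NoiseParams(self.min_len * 2, self.rounding * 2)


def select_noise_params(seq_length: int) -> NoiseParams:
    """Stepwise default filtering/rounding resolution as a function of length.

    <50 kbp: 100 bp; 50–500 kbp: 1 kbp; 500 kbp–5 Mbp: 10 kbp; >=5 Mbp: 20 kbp.
    """
    if seq_length < 1:
        raise InputError("seq_length must be positive")
    if seq_length < 50_000:
        v = 100
    elif seq_length < 500_000:
        v = 1_000
    elif seq_length < 5_000_000:
        v = 10_000
    else:
        v = 20_000
    return NoiseParams(v, v)


def _round_to(x: int, r: int) -> int:
    """Round to the nearest multiple of r; exact halves round up."""
    return ((2 * x + r) // (2 * r)) * r


def denoise_alignments(records: Sequence[AlnRecord], params: NoiseParams) -> list[AlnRecord]:
    """Filter short alignments, snap breakpoints to the rounding lattice and
    force slopes to exactly +-1.

    Steps: (1) drop records spanning fewer than ``min_len`` bases; (2) round
    all four coordinates to the nearest multiple of ``rounding``; (3) trim
    each record until the query and target spans agree, taking the trim from
    the interior side: endpoints that touch a sequence boundary stay pinned
    to the (lattice-snapped) axis end, so that the same bp position — in
    particular a sequence end — always maps to the same lattice point; with
    nothing pinned the record is trimmed at its end; (4) drop records that
    degenerate to zero span.
    """
    out = []
    for rec in records:
        if min(rec.query_span, rec.target_span) < params.min_len:
            continue
        # axis lengths snap to the same lattice so that rounded coordinates
        # stay in bounds and no sub-lattice remainder segment survives
        qlen = max(params.rounding, _round_to(rec.query_len, params.rounding))
        tlen = max(params.rounding, _round_to(rec.target_len, params.rounding))
        qs = _round_to(rec.query_start, params.rounding)
        qe = _round_to(rec.query_end, params.rounding)
        ts = _round_to(rec.target_start, params.rounding)
        te = _round_to(rec.target_end, params.rounding)
        span = min(qe - qs, te - ts, qlen, tlen)
        if span <= 0:
            continue
        if rec.query_end == rec.query_len:
            qe, qs = qlen, qlen - span
        elif rec.query_start == 0:
            qs, qe = 0, span
        else:
            qe = qs + span
        if rec.strand == "+":
            if rec.target_end == rec.target_len:
                te, ts = tlen, tlen - span
            elif rec.target_start == 0:
                ts, te = 0, span
            else:
                te = ts + span
        else:
            # '-' strand: the query end corresponds to the target start
            if rec.target_start == 0:
                ts, te = 0, span
            elif rec.target_end == rec.target_len:
                te, ts = tlen, tlen - span
            else:
                ts = te - span
        out.append(replace(rec, query_len=qlen, query_start=qs, query_end=qe,
                           target_len=tlen, target_start=ts, target_end=te,
                           matches=min(rec.matches, span), block_len=span))
    return out


@dataclass
class Grid:
    """Sorted gridline positions on the reference (x) and query (y) axes."""

    x_cuts: list[int]
    y_cuts: list[int]

    @property
    def n_cols(self) -> int:
        return len(self.x_cuts) - 1

    @property
    def n_rows(self) -> int:
        return len(self.y_cuts) - 1

    @property
    def span(self) -> int:
        return self.n_rows + self.n_cols


def _axis_bounds(records: Sequence[AlnRecord], ref_len: int | None,
                 query_len: int | None) -> tuple[int, int]:
    if ref_len is None:
        ref_len = max((r.target_len for r in records), default=1)
    if query_len is None:
        query_len = max((r.query_len for r in records), default=1)
    return ref_len, query_len


def build_grid(records: Sequence[AlnRecord], ref_len: int | None = None,
               query_len: int | None = None) -> Grid:
    """Compute the gridline fixpoint for a set of denoised alignments.

    Gridlines start at every alignment start/end point; every interior
    crossing of a gridline with an alignment spawns a perpendicular gridline
    at the crossing point, repeated to a fixpoint. Records must be denoised
    (slope exactly +-1), which guarantees termination on the rounding lattice.
    """
    ref_len, query_len = _axis_bounds(records, ref_len, query_len)
    segs = []  # (xs, xe, ys, ye, strand)
    for r in records:
        if r.query_span != r.target_span:
            raise ConsistencyError(f"record not slope-normalized: {r!r}")
        segs.append((r.target_start, r.target_end, r.query_start, r.query_end, r.strand))
    x_cuts = {0, ref_len}
    y_cuts = {0, query_len}
    for xs, xe, ys, ye, _ in segs:
        x_cuts.update((xs, xe))
        y_cuts.update((ys, ye))
    changed = True
    while changed:
        changed = False
        for xs, xe, ys, ye, strand in segs:
            for c in [c for c in x_cuts if xs < c < xe]:
                y = ys + (c - xs) if strand == "+" else ye - (c - xs)
                if y not in y_cuts:
                    y_cuts.add(y)
                    changed = True
            for c in [c for c in y_cuts if ys < c < ye]:
                x = xs + (c - ys) if strand == "+" else xs + (ye - c)
                if x not in x_cuts:
                    x_cuts.add(x)
                    changed = True
    return Grid(sorted(x_cuts), sorted(y_cuts))


@dataclass
class SegmentMatrix:
    """The segmented dotplot: query-segment rows x reference-segment columns.

    ``entries[i, j]`` is +1/-1/0 for forward/reverse/no alignment of query
    segment i onto reference segment j. Column bp lengths (and per-column
    duplication counters used by the search heuristics) travel with columns
    when the matrix is mutated.
    """

    entries: np.ndarray  # int8, shape (n_rows, n_cols)
    col_lengths: np.ndarray  # int64, bp
    row_lengths: np.ndarray  # int64, bp
    dup_counts: np.ndarray = field(default=None)  # int64 per column

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int8)
        self.col_lengths = np.asarray(self.col_lengths, dtype=np.int64)
        self.row_lengths = np.asarray(self.row_lengths, dtype=np.int64)
        if self.dup_counts is None:
            self.dup_counts = np.zeros(self.n_cols, dtype=np.int64)
        else:
            self.dup_counts = np.asarray(self.dup_counts, dtype=np.int64)
        if self.entries.shape != (self.n_rows, self.n_cols):
            raise InputError("entries shape does not match segment lengths")

    @property
    def n_rows(self) -> int:
        return len(self.row_lengths)

    @property
    def n_cols(self) -> int:
        return len(self.col_lengths)

    @property
    def x_bounds(self) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(self.col_lengths)))

    @property
    def y_bounds(self) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(self.row_lengths)))

    def copy(self) -> "SegmentMatrix":
        return SegmentMatrix(self.entries.copy(), self.col_lengths.copy(),
                             self.row_lengths.copy(), self.dup_counts.copy())

    def state_key(self) -> bytes:
        return (self.entries.tobytes() + b"|" + self.col_lengths.tobytes()
                + b"|" + self.dup_counts.tobytes()
                + b"|" + self.n_cols.to_bytes(4, "little"))


def matrix_from_grid(records: Sequence[AlnRecord], grid: Grid) -> SegmentMatrix:
    """Rasterize denoised alignments onto the grid.

    Every alignment decomposes exactly into diagonal cell traversals (the grid
    is a fixpoint); a cell covered by both orientations keeps the sign of the
    longer parent alignment, ties resolving to +.
    """
    n, m = grid.n_rows, grid.n_cols
    entries = np.zeros((n, m), dtype=np.int8)
    parent = np.zeros((n, m), dtype=np.int64)  # bp length of the owning record
    xc, yc = grid.x_cuts, grid.y_cuts
    for rec in records:
        j0 = bisect_left(xc, rec.target_start)
        if j0 >= len(xc) or xc[j0] != rec.target_start:
            raise ConsistencyError(f"start of {rec!r} not on grid")
        sign = 1 if rec.strand == "+" else -1
        x = rec.target_start
        j = j0
        while x < rec.target_end:
            if j >= m:
                raise ConsistencyError(f"{rec!r} exceeds grid")
            xlo, xhi = xc[j], xc[j + 1]
            if rec.strand == "+":
                ylo = rec.query_start + (xlo - rec.target_start)
                yhi = rec.query_start + (xhi - rec.target_start)
            else:
                ylo = rec.query_end - (xhi - rec.target_start)
                yhi = rec.query_end - (xlo - rec.target_start)
            i = bisect_left(yc, ylo)
            if i >= len(yc) or yc[i] != ylo or i + 1 >= len(yc) or yc[i + 1] != yhi:
                raise ConsistencyError(f"{rec!r} cell [{xlo},{xhi}) not on grid")
            plen = rec.query_span
            if entries[i, j] == 0 or (plen, sign) > (parent[i, j], entries[i, j]):
                entries[i, j] = sign
                parent[i, j] = plen
            x = xhi
            j += 1
    col_lengths = np.diff(xc)
    row_lengths = np.diff(yc)
    return SegmentMatrix(entries, col_lengths, row_lengths)


def cap_dimensions(records: Sequence[AlnRecord], params: NoiseParams, *,
                   ref_len: int | None = None, query_len: int | None = None,
                   max_span: int = 250, max_alignments: int = 150,
                   max_doublings: int = 20) -> tuple[list[AlnRecord], NoiseParams]:
    """Double ``l`` and ``r`` until the grid fits the dimension caps.

    Denoising is re-applied to the original records at every step (rounding is
    destructive). Returns the denoised records and the effective parameters.
    """
    for _ in range(max_doublings + 1):
        denoised = denoise_alignments(records, params)
        rl = None if ref_len is None else max(params.rounding,
                                              _round_to(ref_len, params.rounding))
        ql = None if query_len is None else max(params.rounding,
                                                _round_to(query_len, params.rounding))
        grid = build_grid(denoised, rl, ql)
        if grid.span <= max_span and len(denoised) <= max_alignments:
            return denoised, params
        params = params.doubled()
    raise ConsistencyError(
        f"dimension caps unreachable after {max_doublings} doublings")


def segment_records(records: Sequence[AlnRecord], params: NoiseParams | None = None, *,
                    ref_len: int | None = None, query_len: int | None = None,
                    max_span: int = 250, max_alignments: int = 150
                    ) -> tuple[SegmentMatrix, NoiseParams]:
    """Full condensation: denoise (with dimension capping), grid, matrix."""
    ref_len, query_len = _axis_bounds(records, ref_len, query_len)
    if params is None:
        params = select_noise_params(max(ref_len, query_len))
    denoised, params = cap_dimensions(records, params, ref_len=ref_len,
                                      query_len=query_len, max_span=max_span,
                                      max_alignments=max_alignments)
    rl = max(params.rounding, _round_to(ref_len, params.rounding))
    ql = max(params.rounding, _round_to(query_len, params.rounding))
    grid = build_grid(denoised, rl, ql)
    return matrix_from_grid(denoised, grid), params


def reconstruct_records(matrix: SegmentMatrix, grid: Grid) -> set[tuple]:
    """Diagonal traversal of nonzero cells back into alignment intervals.

    Returns a set of (target_start, target_end, query_start, query_end,
    strand) tuples — used to verify that segmentation is lossless.
    """
    n, m = matrix.n_rows, matrix.n_cols
    xc, yc = grid.x_cuts, grid.y_cuts
    seen = np.zeros((n, m), dtype=bool)
    out = set()
    for i in range(n):
        for j in range(m):
            if matrix.entries[i, j] == 0 or seen[i, j]:
                continue
            sign = int(matrix.entries[i, j])
            # walk the diagonal run of same-signed cells
            cells = [(i, j)]
            seen[i, j] = True
            di = sign
            ii, jj = i + di, j + 1
            while 0 <= ii < n and jj < m and matrix.entries[ii, jj] == sign \
                    and not seen[ii, jj] \
                    and yc[ii + 1] - yc[ii] == xc[jj + 1] - xc[jj]:
                # contiguity on both axes
                prev_i, prev_j = cells[-1]
                if xc[jj] != xc[prev_j + 1]:
                    break
                if sign > 0 and yc[ii] != yc[prev_i + 1]:
                    break
                if sign < 0 and yc[ii + 1] != yc[prev_i]:
                    break
                seen[ii, jj] = True
                cells.append((ii, jj))
                ii, jj = ii + di, jj + 1
            rows = [c[0] for c in cells]
            cols = [c[1] for c in cells]
            out.add((xc[min(cols)], xc[max(cols) + 1],
                     yc[min(rows)], yc[max(rows) + 1],
                     "+" if sign > 0 else "-"))
    return out
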