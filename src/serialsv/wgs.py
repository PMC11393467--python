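"""Whole-genome ROI discovery and BED-merging procedures.

Regions of interest are derived from alignment breaks in a whole-genome
alignment: breakpoints that are not explained by small indels or contig ends
seed windows at several merge distances, which are then expanded and
size-filtered. A separate 7-step merging procedure turns raw SV calls plus
segmental-duplication annotation into a non-redundant set of candidate loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment import AlnRecord, InputError, RegionSpec


@dataclass(frozen=True)
class RoiParams:
    """Whole-genome ROI discovery parameters (bp)."""

    min_breakpoint_separation: int = 10_000
    merge_distances: tuple[int, ...] = (200_000, 1_000_000, 5_000_000)
    expand_fraction: float = 0.5
    min_window: int = 50_000

    def __post_init__(self) -> None:
        if self.min_breakpoint_separation <= 0 or self.min_window <= 0 \
                or self.expand_fraction <= 0 or not self.merge_distances:
            raise InputError("ROI parameters must be positive")


@dataclass(frozen=True)
class LocusMergeParams:
    """Parameters of the 7-step locus merging procedure (bp)."""

    min_sv_len: int = 10_000
    reciprocal_overlap: float = 0.5
    elongate_fraction: float = 0.25
    proximity_merge: int = 100_000
    min_region: int = 40_000


# ---------------------------------------------------------------------------
# BED helpers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ (0-based half-open) into a chrom/start/end frame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise InputError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def _merge_close(intervals: list[tuple[int, int]], dist: int) -> list[tuple[int, int]]:
    """Union of intervals, joining any pair separated by < dist."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - out[-1][1] < dist:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _subtract(intervals: list[tuple[int, int]],
              masks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Subtract mask intervals; split parts are each carried forward."""
    out = []
    masks = sorted(masks)
    for s, e in intervals:
        cur = s
        for ms, me in masks:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# ROI discovery
# ---------------------------------------------------------------------------

def _contained(r: AlnRecord, other: AlnRecord) -> bool:
    """r entirely inside other on both axes (and not identical)."""
    if r is other or r.target_name != other.target_name \
            or r.query_name != other.query_name:
        return False
    inside_t = other.target_start <= r.target_start and r.target_end <= other.target_end
    inside_q = other.query_start <= r.query_start and r.query_end <= other.query_end
    strictly_smaller = (r.target_span < other.target_span
                        or r.query_span < other.query_span)
    return inside_t and inside_q and strictly_smaller


def discover_rois(wga_records: Sequence[AlnRecord],
                  params: RoiParams | None = None,
                  ref_label: str = "ref") -> list[RegionSpec]:
    """Derive candidate SV windows from breaks in a whole-genome alignment.

    Alignments contained in another on both axes are dropped; alignment
    endpoints become breakpoints, excluding contig termini and any pair of
    breakpoints closer than ``min_breakpoint_separation`` on BOTH axes (small
    indels). Surviving breakpoints seed reference windows of +-d/2 at each
    merge distance d (overlapping windows union), which are expanded by
    ``expand_fraction`` per side and filtered to ``min_window``. Windows from
    different merge distances may overlap; all are returned.
    """
    params = params or RoiParams()
    records = [r for r in wga_records
               if not any(_contained(r, o) for o in wga_records)]
    # breakpoints as (ref_contig, ref_pos, query_pos) pairs
    bps = []
    for r in records:
        ends = [(r.target_start, r.query_start), (r.target_end, r.query_end)] \
            if r.strand == "+" else \
            [(r.target_start, r.query_end), (r.target_end, r.query_start)]
        for t, q in ends:
            if t in (0, r.target_len) or q in (0, r.query_len):
                continue  # contig terminus, not SV evidence
            bps.append((r.target_name, t, q))
    sep = params.min_breakpoint_separation
    drop = set()
    for i in range(len(bps)):
        for j in range(i + 1, len(bps)):
            if bps[i][0] == bps[j][0] \
                    and abs(bps[i][1] - bps[j][1]) < sep \
                    and abs(bps[i][2] - bps[j][2]) < sep:
                drop.update((i, j))
    kept = [bp for i, bp in enumerate(bps) if i not in drop]
    contig_len = {r.target_name: r.target_len for r in records}
    rois: list[RegionSpec] = []
    for dist in params.merge_distances:
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, t, _ in kept:
            by_contig.setdefault(contig, []).append((t - dist // 2, t + dist // 2))
        for contig, ivals in sorted(by_contig.items()):
            for s, e in _merge_close(ivals, 1):
                pad = int(params.expand_fraction * (e - s))
                s2 = max(0, s - pad)
                e2 = min(contig_len.get(contig, e + pad), e + pad)
                if e2 - s2 >= params.min_window:
                    rois.append(RegionSpec(ref_label, contig, s2, e2))
    return rois


def reconcile_window_calls(calls: Sequence[tuple[RegionSpec, object]]
                           ) -> list[tuple[RegionSpec, object]]:
    """Resolve overlapping windows: per overlap group the smallest
    ('most zoomed-in') window's call is kept; concordant duplicates collapse
    to one entry."""
    calls = list(calls)
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = calls[i][0], calls[j][0]
            if a.contig == b.contig and a.start < b.end and b.start < a.end:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        best = min(members, key=lambda i: (calls[i][0].length, calls[i][0].start))
        out.append(calls[best])
    out.sort(key=lambda rc: (rc[0].contig, rc[0].start, rc[0].end))
    return out


# ---------------------------------------------------------------------------
# Locus-set construction (7-step merge)
# ---------------------------------------------------------------------------

def build_locus_set(sv_bed: pd.DataFrame, sd_bed: pd.DataFrame,
                    mask_bed: pd.DataFrame | None = None,
                    params: LocusMergeParams | None = None) -> pd.DataFrame:
    """Merge SV calls with repeat annotation into candidate sSV loci.

    Steps, in order: (1) keep SVs longer than ``min_sv_len``; (2) union each
    SV with every overlapping SD interval; (3) merge intervals overlapping by
    at least ``reciprocal_overlap`` of the smaller one; (4) elongate each
    region by ``elongate_fraction`` of its length per side; (5) subtract mask
    regions (centromeres / satellite arrays), keeping split parts; (6) merge
    regions closer than ``proximity_merge``; (7) keep regions longer than
    ``min_region``.
    """
    params = params or LocusMergeParams()
    out_rows = []
    chroms = sorted(set(sv_bed["chrom"]))
    for chrom in chroms:
        svs = [(int(s), int(e)) for _, s, e in
               sv_bed[sv_bed["chrom"] == chrom].itertuples(index=False)]
        sds = [(int(s), int(e)) for _, s, e in
               sd_bed[sd_bed["chrom"] == chrom].itertuples(index=False)] \
            if len(sd_bed) else []
        masks = [(int(s), int(e)) for _, s, e in
                 mask_bed[mask_bed["chrom"] == chrom].itertuples(index=False)] \
            if mask_bed is not None and len(mask_bed) else []
        # 1: length filter
        regions = [(s, e) for s, e in svs if e - s > params.min_sv_len]
        # 2: union with overlapping SDs
        unioned = []
        for s, e in regions:
            lo, hi = s, e
            for ss, se in sds:
                if ss < e and s < se:
                    lo, hi = min(lo, ss), max(hi, se)
            unioned.append((lo, hi))
        # 3: merge on >=50% overlap of the smaller interval (transitive)
        merged = sorted(unioned)
        changed = True
        while changed:
            changed = False
            nxt: list[tuple[int, int]] = []
            for s, e in sorted(merged):
                if nxt:
                    ps, pe = nxt[-1]
                    ov = min(pe, e) - max(ps, s)
                    smaller = min(pe - ps, e - s)
                    if ov >= params.reciprocal_overlap * smaller and ov > 0:
                        nxt[-1] = (min(ps, s), max(pe, e))
                        changed = True
                        continue
                nxt.append((s, e))
            merged = nxt
        # 4: elongate by 25% per side
        elongated = []
        for s, e in merged:
            pad = int(params.elongate_fraction * (e - s))
            elongated.append((max(0, s - pad), e + pad))
        # 5: subtract masks, split parts carried forward
        sub = _subtract(elongated, masks)
        # 6: proximity merge
        prox = _merge_close(sub, params.proximity_merge)
        # 7: size filter
        for s, e in prox:
            if e - s > params.min_region:
                out_rows.append((chrom, s, e))
    return pd.DataFrame(out_rows, columns=["chrom", "start", "end"])
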