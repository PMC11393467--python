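"""Chunked pairwise alignment production and post-processing.

Pairwise alignments between a reference region and its query counterpart are
produced by splitting the query into fixed-size chunks, aligning every chunk
separately (keeping multi-mappings, which carry the repeat information needed
downstream), and re-joining collinear chunk alignments. All coordinates are
0-based half-open, PAF-native. Two aligner adapters are provided: a
deterministic built-in exact-seed aligner and a subprocess wrapper around an
external PAF-emitting aligner (minimap2).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: minimap2 flags used for chunk-vs-region alignment (genotyping mode).
MINIMAP2_GENOTYPE_ARGS = ("-x", "asm20", "-P", "-c", "-s", "0", "-M", "0.2")
#: minimap2 preset used for whole-genome alignment.
MINIMAP2_WGA_ARGS = ("-x", "asm5", "-c")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class InputError(ValueError):
    """Invalid user-supplied input."""


class EnvironmentError_(RuntimeError):
    """External tool failure (missing binary, malformed output)."""


@dataclass
class AlnRecord:
    """One pairwise alignment in PAF semantics.

    Coordinates are 0-based half-open on both axes; ``strand`` is '+' when
    query and target run in the same direction. ``matches`` counts matching
    bases, ``block_len`` the alignment block length.
    """

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise InputError(f"bad query interval in {self!r}")
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise InputError(f"bad target interval in {self!r}")
        if self.strand not in "+-":
            raise InputError(f"bad strand {self.strand!r}")
        if self.matches > self.block_len:
            raise InputError("matches exceed block length")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


@dataclass(frozen=True)
class ChunkParams:
    """Chunking / chunk-merging parameters.

    chunk_length
        Length of the query chunks aligned independently (bp).
    merge_proximity_fraction
        Two collinear chunk alignments are concatenated when the end-to-start
        gap on both axes is at most this fraction of ``chunk_length``.
    """

    chunk_length: int = 1000
    merge_proximity_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.chunk_length < 100:
            raise InputError("chunk_length must be >= 100")
        if not 0 < self.merge_proximity_fraction < 1:
            raise InputError("merge_proximity_fraction must be in (0, 1)")

    @property
    def proximity_bp(self) -> int:
        return int(self.merge_proximity_fraction * self.chunk_length)


@dataclass
class RegionSpec:
    """A genomic interval on a named contig of a named assembly (0-based, half-open)."""

    assembly_label: str
    contig: str
    start: int
    end: int
    orientation_vs_ref: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"empty region {self!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # 1-based inclusive, the usual CLI convention
        return f"{self.contig}:{self.start + 1}-{self.end}"


def parse_region(text: str, assembly_label: str = "ref") -> RegionSpec:
    """Parse a 1-based inclusive ``chr:start-end`` region string."""
    try:
        contig, span = text.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        return RegionSpec(assembly_label, contig, int(lo) - 1, int(hi))
    except (ValueError, IndexError) as exc:
        raise InputError(f"cannot parse region {text!r}") from exc


# ---------------------------------------------------------------------------
# PAF I/O
# ---------------------------------------------------------------------------

def read_paf(path: str | Path) -> list[AlnRecord]:
    """Read PAF (minimap2 dialect); columns beyond 12 (tags) are ignored."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise EnvironmentError_(f"malformed PAF line {lineno}: {line!r}")
            try:
                records.append(
                    AlnRecord(
                        query_name=parts[0],
                        query_len=int(parts[1]),
                        query_start=int(parts[2]),
                        query_end=int(parts[3]),
                        strand=parts[4],
                        target_name=parts[5],
                        target_len=int(parts[6]),
                        target_start=int(parts[7]),
                        target_end=int(parts[8]),
                        matches=int(parts[9]),
                        block_len=int(parts[10]),
                    )
                )
            except (ValueError, InputError) as exc:
                raise EnvironmentError_(f"malformed PAF line {lineno}: {line!r}") from exc
    return records


def write_paf(records: Iterable[AlnRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_name, r.query_len, r.query_start, r.query_end,
                        r.strand,
                        r.target_name, r.target_len, r.target_start, r.target_end,
                        r.matches, r.block_len, 60,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Chunking
# ---------------------------------------------------------------------------

def split_query_into_chunks(seq_length: int, params: ChunkParams) -> list[tuple[int, int]]:
    """Tile ``[0, seq_length)`` into chunk intervals; the remainder is kept."""
    if seq_length < 1:
        raise InputError("seq_length must be positive")
    step = params.chunk_length
    return [(s, min(s + step, seq_length)) for s in range(0, seq_length, step)]


# ---------------------------------------------------------------------------
# Aligner adapters
# ---------------------------------------------------------------------------

class ExactSeedAligner:
    """Deterministic built-in aligner based on exact k-mer seeds.

    Seeds are exact k-mer matches grouped per diagonal and strand; a group is
    reported as a (gapless) local alignment when its seed-covered extent
    reaches ``min_seed`` bases. Divergent repeat copies still share abundant
    exact k-mers, so multi-mappings onto every sufficiently similar repeat
    copy are reported, which is what the segmented dotplot needs.
    """

    def __init__(self, k: int = 16, min_seed: int = 250, gap_split: int = 2000):
        self.k = k
        self.min_seed = min_seed
        self.gap_split = gap_split

    @staticmethod
    def _codes(seq: str) -> np.ndarray:
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        out = np.full(arr.shape, 255, dtype=np.uint8)
        for code, base in enumerate(b"ACGT"):
            out[arr == base] = code
        return out

    def _hashes(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k, n = self.k, len(codes)
        if n < k:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
        h = np.zeros(n - k + 1, dtype=np.int64)
        valid = np.ones(n - k + 1, dtype=bool)
        for i in range(k):
            c = codes[i : n - k + 1 + i]
            h = h * 4 + (c & 3)
            valid &= c != 255
        return h, valid

    def _index(self, target: str) -> dict[int, np.ndarray]:
        h, valid = self._hashes(self._codes(target))
        index: dict[int, list[int]] = {}
        for pos in np.flatnonzero(valid):
            index.setdefault(int(h[pos]), []).append(int(pos))
        return {key: np.asarray(v, dtype=np.int64) for key, v in index.items()}

    def _hits(self, index: dict[int, np.ndarray], seq: str) -> tuple[np.ndarray, np.ndarray]:
        h, valid = self._hashes(self._codes(seq))
        qs, ts = [], []
        for pos in np.flatnonzero(valid):
            tpos = index.get(int(h[pos]))
            if tpos is not None:
                qs.append(np.full(len(tpos), pos, dtype=np.int64))
                ts.append(tpos)
        if not qs:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(qs), np.concatenate(ts)

    def _diagonal_groups(self, q: np.ndarray, t: np.ndarray):
        """Yield (q_sorted, t_start) per diagonal group, split at large q gaps."""
        diag = t - q
        order = np.lexsort((q, diag))
        q, t, diag = q[order], t[order], diag[order]
        start = 0
        for i in range(1, len(q) + 1):
            boundary = (
                i == len(q)
                or diag[i] != diag[start]
                or q[i] - q[i - 1] > self.gap_split
            )
            if boundary:
                yield q[start:i], int(diag[start])
                start = i

    def map(self, query_records: Sequence[tuple[str, str]], target_name: str,
            target_seq: str) -> list[AlnRecord]:
        """Align each named query sequence to the target; return all local hits."""
        index = self._index(target_seq)
        tlen = len(target_seq)
        out: list[AlnRecord] = []
        for qname, qseq in query_records:
            qlen = len(qseq)
            for strand in "+-":
                seq = qseq if strand == "+" else revcomp(qseq)
                q, t = self._hits(index, seq)
                for qgrp, diag in self._diagonal_groups(q, t):
                    lo, hi = int(qgrp[0]), int(qgrp[-1]) + self.k
                    # union of k-length seed windows = matched bases
                    gaps = np.diff(qgrp)
                    covered = self.k + int(np.minimum(gaps, self.k).sum())
                    if covered < self.min_seed:
                        continue
                    if strand == "+":
                        q0, q1 = lo, hi
                    else:  # coordinates on the original (forward) query
                        q0, q1 = qlen - hi, qlen - lo
                    out.append(
                        AlnRecord(
                            query_name=qname, query_len=qlen,
                            query_start=q0, query_end=q1,
                            strand=strand,
                            target_name=target_name, target_len=tlen,
                            target_start=lo + diag, target_end=hi + diag,
                            matches=covered, block_len=hi - lo,
                        )
                    )
        return out


class Minimap2Aligner:
    """Adapter invoking the minimap2 binary and parsing its PAF output."""

    def __init__(self, binary: str = "minimap2", extra_args: Sequence[str] = MINIMAP2_GENOTYPE_ARGS):
        self.binary = binary
        self.extra_args = tuple(extra_args)

    def map(self, query_records: Sequence[tuple[str, str]], target_name: str,
            target_seq: str) -> list[AlnRecord]:
        if shutil.which(self.binary) is None:
            raise EnvironmentError_(f"aligner binary {self.binary!r} not found on PATH")
        with tempfile.TemporaryDirectory(prefix="serialsv_mm2_") as tmp:
            tdir = Path(tmp)
            tgt = tdir / "target.fa"
            qry = tdir / "query.fa"
            tgt.write_text(f">{target_name}\n{target_seq}\n")
            with open(qry, "w") as fh:
                for name, seq in query_records:
                    fh.write(f">{name}\n{seq}\n")
            cmd = [self.binary, *self.extra_args, str(tgt), str(qry)]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise EnvironmentError_(
                    f"{self.binary} failed ({proc.returncode}): {proc.stderr.strip()[:500]}"
                )
            paf = tdir / "out.paf"
            paf.write_text(proc.stdout)
            return read_paf(paf)


def align_chunks(query_seq: str, ref_seq: str, adapter, *,
                 params: ChunkParams | None = None,
                 query_name: str = "query", target_name: str = "ref") -> list[AlnRecord]:
    """Split the query into chunks, align each, and lift coordinates back.

    Multi-mappings are preserved; returned records carry whole-query offsets.
    """
    params = params or ChunkParams()
    chunks = split_query_into_chunks(len(query_seq), params)
    named = [(f"chunk_{s}_{e}", query_seq[s:e]) for s, e in chunks]
    raw = adapter.map(named, target_name, ref_seq)
    qlen = len(query_seq)
    lifted = []
    for r in raw:
        offset = int(r.query_name.split("_")[1])
        lifted.append(
            replace(
                r,
                query_name=query_name,
                query_len=qlen,
                query_start=r.query_start + offset,
                query_end=r.query_end + offset,
            )
        )
    lifted.sort(key=lambda r: (r.query_start, r.target_start, r.strand))
    return lifted


# ---------------------------------------------------------------------------
# Chunk merging
# ---------------------------------------------------------------------------

def _chainable(u: AlnRecord, v: AlnRecord, tol: int) -> bool:
    """Can v be appended to u? Same strand, collinear, gaps <= tol on both axes."""
    if u.strand != v.strand or u.target_name != v.target_name:
        return False
    if abs(v.query_start - u.query_end) > tol:
        return False
    if u.strand == "+":
        return abs(v.target_start - u.target_end) <= tol
    # '-' chains: target decreases as query increases
    return abs(u.target_start - v.target_end) <= tol


def _merge_pass(records: list[AlnRecord], tol: int) -> list[AlnRecord]:
    n = len(records)
    order = sorted(range(n), key=lambda i: (records[i].query_start, records[i].target_start,
                                            records[i].strand))
    records = [records[i] for i in order]
    # candidate edges u -> v (v appended after u)
    succ: dict[int, int] = {}
    pred: dict[int, int] = {}
    # For each v, competitors are all u that could chain into it; only the
    # longest competitor (ties: smaller target_start) gets to merge.
    for v in range(n):
        cands = [u for u in range(n) if u != v and _chainable(records[u], records[v], tol)]
        if not cands:
            continue
        best = max(cands, key=lambda u: (records[u].block_len, -records[u].target_start))
        if best in succ:  # u already claimed a (nearer) partner
            prev_v = succ[best]
            gap = abs(records[v].query_start - records[best].query_end)
            prev_gap = abs(records[prev_v].query_start - records[best].query_end)
            if (gap, records[v].target_start) >= (prev_gap, records[prev_v].target_start):
                continue
            del pred[prev_v]
        succ[best] = v
        pred[v] = best
    merged: list[AlnRecord] = []
    for i in range(n):
        if i in pred:
            continue  # interior of a chain
        chain = [i]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        if len(chain) == 1:
            merged.append(records[i])
            continue
        parts = [records[j] for j in chain]
        first, last = parts[0], parts[-1]
        if first.strand == "+":
            ts, te = first.target_start, last.target_end
        else:
            ts, te = last.target_start, first.target_end
        merged.append(
            AlnRecord(
                query_name=first.query_name, query_len=first.query_len,
                query_start=first.query_start, query_end=last.query_end,
                strand=first.strand,
                target_name=first.target_name, target_len=first.target_len,
                target_start=ts, target_end=te,
                matches=sum(p.matches for p in parts),
                block_len=sum(p.block_len for p in parts),
            )
        )
    merged.sort(key=lambda r: (r.query_start, r.target_start, r.strand))
    return merged


def merge_chunk_alignments(records: Sequence[AlnRecord],
                           params: ChunkParams | None = None) -> list[AlnRecord]:
    """Concatenate chains of collinear chunk alignments.

    Alignment pairs merge when the end of one falls within
    ``merge_proximity_fraction * chunk_length`` bp of the start of the next on
    both axes (strand-aware). When several records compete for the same merge
    partner, only the longest competitor merges. Applied to a fixpoint, so
    merging is idempotent.
    """
    params = params or ChunkParams()
    tol = params.proximity_bp
    out = list(records)
    while True:
        nxt = _merge_pass(out, tol)
        if len(nxt) == len(out):
            return nxt
        out = nxt


# ---------------------------------------------------------------------------
# Counterpart location / liftover
# ---------------------------------------------------------------------------

def _coverage(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total, lo, hi = 0, *intervals[0]
    for s, e in intervals[1:]:
        if s > hi:
            total += hi - lo
            lo, hi = s, e
        else:
            hi = max(hi, e)
    return total + hi - lo


class CounterpartNotFound(RuntimeError):
    """No alignment between the ROI and any query contig."""


def locate_counterpart(ref_fasta, roi: RegionSpec, query_fasta, adapter=None, *,
                       params: ChunkParams | None = None,
                       pad_fraction: float = 0.10,
                       min_contig_cover: float = 0.80,
                       query_label: str = "query") -> tuple[RegionSpec, bool]:
    """Locate the region in the query assembly homologous to ``roi``.

    ``ref_fasta`` / ``query_fasta`` are mappings of contig name to sequence
    (e.g. ``pyfaidx.Fasta`` objects or plain dicts). Returns the counterpart
    interval on the contig with the largest aligned span, padded by
    ``pad_fraction`` per side, plus a contiguity flag that is False when no
    single contig covers at least ``min_contig_cover`` of the ROI's aligned
    span (the locus is then unassembled in this query).
    """
    adapter = adapter or ExactSeedAligner()
    params = params or ChunkParams()
    roi_seq = str(ref_fasta[roi.contig][roi.start : roi.end])
    per_contig: dict[str, list[AlnRecord]] = {}
    for contig in query_fasta.keys():
        recs = align_chunks(roi_seq, str(query_fasta[contig][:]), adapter,
                            params=params, query_name="roi", target_name=contig)
        recs = merge_chunk_alignments(recs, params)
        if recs:
            per_contig[contig] = recs
    if not per_contig:
        raise CounterpartNotFound(f"counterpart not found for {roi}")
    # NB the chunked query here is the ROI sequence; its aligned span lives on
    # the *query* axis of the records, the contig interval on the target axis.
    cover = {c: _coverage([(r.query_start, r.query_end) for r in recs])
             for c, recs in per_contig.items()}
    best = max(cover, key=lambda c: (cover[c], c))
    total = _coverage([(r.query_start, r.query_end)
                       for recs in per_contig.values() for r in recs])
    contiguous = cover[best] >= min_contig_cover * total
    recs = per_contig[best]
    lo = min(r.target_start for r in recs)
    hi = max(r.target_end for r in recs)
    pad = int(pad_fraction * (hi - lo))
    contig_len = recs[0].target_len
    lo, hi = max(0, lo - pad), min(contig_len, hi + pad)
    fwd = sum(r.block_len for r in recs if r.strand == "+")
    rev = sum(r.block_len for r in recs if r.strand == "-")
    orientation = "+" if fwd >= rev else "-"
    return RegionSpec(query_label, best, lo, hi, orientation), contiguous


def liftover_region(roi_on_a: RegionSpec, assembly_a, assembly_b, adapter=None, *,
                    params: ChunkParams | None = None,
                    label_b: str = "lifted") -> RegionSpec:
    """Lift a region from assembly A to assembly B by chunk mapping.

    The ROI is cut into chunks, mapped to B, and the spanning interval of the
    chunk hits on the majority contig is returned (no padding).
    """
    adapter = adapter or ExactSeedAligner()
    params = params or ChunkParams()
    roi_seq = str(assembly_a[roi_on_a.contig][roi_on_a.start : roi_on_a.end])
    hits: dict[str, list[AlnRecord]] = {}
    for contig in assembly_b.keys():
        recs = align_chunks(roi_seq, str(assembly_b[contig][:]), adapter,
                            params=params, query_name="roi", target_name=contig)
        if recs:
            hits[contig] = recs
    if not hits:
        raise CounterpartNotFound(f"counterpart not found for {roi_on_a}")
    cover = {c: _coverage([(r.query_start, r.query_end) for r in recs])
             for c, recs in hits.items()}
    best = max(cover, key=lambda c: (cover[c], c))
    recs = hits[best]
    lo = min(r.target_start for r in recs)
    hi = max(r.target_end for r in recs)
    fwd = sum(r.block_len for r in recs if r.strand == "+")
    rev = sum(r.block_len for r in recs if r.strand == "-")
    return RegionSpec(label_b, best, lo, hi, "+" if fwd >= rev else "-")
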