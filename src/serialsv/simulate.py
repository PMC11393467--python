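"""Synthetic SD-carrying sequences and NAHR-concordant mutation trajectories.

The generator emulates the repeat substrate of NAHR: a uniform-random
background sequence carrying pairs of segmental duplications (SDs) of chosen
length, similarity and relative orientation. Serial rearrangements are then
sampled so that every event is licensed by a repeat pair whose current
orientations permit it (equal orientation: deletion/duplication; opposite:
inversion), with repeat coordinates tracked through every event. Each
generated case carries a full truth record; replaying the truth trajectory on
the base sequence reproduces the mutated sequence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

from .alignment import InputError, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(RuntimeError):
    """SD placement infeasible within the requested sequence length."""


@dataclass
class SdSpec:
    """One pair of segmental duplications.

    similarity is the expected per-base identity between the two copies;
    orientation '-' means the second copy is reverse-complemented. positions
    (start offsets of the two copies) may be left None for random placement.
    """

    sd_length: int
    similarity: float
    orientation: str = "+"
    positions: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.similarity <= 1:
            raise InputError("similarity must be in (0, 1]")
        if self.orientation not in "+-":
            raise InputError("orientation must be + or -")
        if self.sd_length < 1:
            raise InputError("sd_length must be positive")


@dataclass(frozen=True, order=True)
class RepeatCopy:
    """Tracked repeat copy: family index, interval and strand."""

    family: int
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class SeqEvent:
    """One NAHR event on the sequence, with bp breakpoints.

    DEL drops [start, end); DUP tandem-inserts a copy of [start, end) at
    ``end``; INV reverse-complements [start, end) in place.
    """

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("DEL", "DUP", "INV"):
            raise InputError(f"unknown event kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise InputError("need 0 <= start < end")


@dataclass
class TruthSet:
    """A simulated case: base and mutated sequence plus the true trajectory."""

    base_sequence: str
    mutated_sequence: str
    trajectory: list[SeqEvent]
    seed: int
    sd_length: int = 0
    similarity: float = 1.0
    copies: list[RepeatCopy] = field(default_factory=list)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _diverge(seq: str, similarity: float, rng: np.random.Generator) -> str:
    """Substitute bases at rate (1 - similarity); substitutions never silent."""
    if similarity >= 1.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < (1.0 - similarity)
    if hit.any():
        idx = np.flatnonzero(hit)
        shift = rng.integers(1, 4, size=len(idx))
        code = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(code + shift) % 4]
    return arr.tobytes().decode()


def make_base_sequence(length: int, sd_specs: Sequence[SdSpec],
                       rng_seed: int | np.random.Generator, *,
                       min_separation: int | None = None,
                       max_tries: int = 200) -> tuple[str, list[RepeatCopy]]:
    """Uniform-random sequence carrying the requested SD pairs.

    Each pair is created by copying a source segment to a second position
    (mutated to the requested similarity, reverse-complemented for '-'
    orientation). Copies of all pairs are mutually non-overlapping and at
    least ``min_separation`` bp apart (default: 2*sd_length + 5 kbp).
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    seq = np.frombuffer(random_sequence(length, rng).encode(), dtype=np.uint8).copy()
    seps = [min_separation if min_separation is not None else 2 * s.sd_length + 5000
            for s in sd_specs]
    fixed: dict[int, tuple[int, int]] = {}
    for fam, spec in enumerate(sd_specs):
        if spec.positions is not None:
            a, b = sorted(spec.positions)
            if a < 0 or b + spec.sd_length > length or b - a < spec.sd_length + seps[fam]:
                raise PlacementError(f"stated positions infeasible for {spec}")
            fixed[fam] = (a, b)
    free = [f for f in range(len(sd_specs)) if f not in fixed]
    positions = dict(fixed)
    # joint constructive placement of the remaining copies: randomly order the
    # 2*len(free) copies left to right, reserve lengths plus separation gaps,
    # and spread the slack uniformly (exact, no rejection against itself)
    for _ in range(max_tries if free else 1):
        if not free:
            break
        slots = [f for f in free for _ in range(2)]
        order = rng.permutation(len(slots))
        slots = [slots[i] for i in order]
        lens = [sd_specs[f].sd_length for f in slots]
        gaps = [max(seps[slots[i]], seps[slots[i + 1]]) for i in range(len(slots) - 1)]
        slack = length - sum(lens) - sum(gaps)
        if slack < 0:
            raise PlacementError(
                f"SD footprint plus separations exceeds {length} bp")
        offs = np.sort(rng.integers(0, slack + 1, size=len(slots)))
        starts = []
        base = 0
        for i in range(len(slots)):
            starts.append(int(offs[i]) + base)
            base += lens[i] + (gaps[i] if i < len(gaps) else 0)
        cand: dict[int, list[int]] = {}
        for f, s in zip(slots, starts):
            cand.setdefault(f, []).append(s)
        # reject only against fixed obstacles
        occupied = [(p, p + sd_specs[f].sd_length) for f, pair in fixed.items()
                    for p in pair]
        ok = all(
            e0 + seps[f] <= s or s + sd_specs[f].sd_length + seps[f] <= s0
            for f, ss in cand.items() for s in ss
            for (s0, e0) in occupied)
        if ok:
            positions.update({f: (min(ss), max(ss)) for f, ss in cand.items()})
            break
    if len(positions) != len(sd_specs):
        raise PlacementError("could not place SD pairs around fixed positions")
    copies: list[RepeatCopy] = []
    for fam, spec in enumerate(sd_specs):
        a, b = positions[fam]
        L = spec.sd_length
        source = seq[a : a + L].tobytes().decode()
        copy = _diverge(source, spec.similarity, rng)
        if spec.orientation == "-":
            copy = revcomp(copy)
        seq[b : b + L] = np.frombuffer(copy.encode(), dtype=np.uint8)
        copies.append(RepeatCopy(fam, a, a + L, "+"))
        copies.append(RepeatCopy(fam, b, b + L, spec.orientation))
    return seq.tobytes().decode(), copies


def mutate_sequence(seq: str, trajectory: Sequence[SeqEvent]) -> str:
    """Apply DEL/DUP/INV events in order."""
    for ev in trajectory:
        if ev.end > len(seq):
            raise InputError(f"{ev} out of bounds for {len(seq)} bp sequence")
        if ev.kind == "DEL":
            seq = seq[: ev.start] + seq[ev.end :]
        elif ev.kind == "DUP":
            seq = seq[: ev.end] + seq[ev.start : ev.end] + seq[ev.end :]
        else:
            seq = seq[: ev.start] + revcomp(seq[ev.start : ev.end]) + seq[ev.end :]
    return seq


def _shift_copies(copies: list[RepeatCopy], ev: SeqEvent) -> list[RepeatCopy]:
    """Track repeat copies through one event (copies fully inside or outside
    the event interval; straddling copies must be excluded upstream)."""
    s, e, L = ev.start, ev.end, ev.end - ev.start
    out: list[RepeatCopy] = []
    for c in copies:
        if c.end <= s:
            out.append(c)
        elif c.start >= e:
            if ev.kind == "DEL":
                out.append(replace(c, start=c.start - L, end=c.end - L))
            elif ev.kind == "DUP":
                out.append(replace(c, start=c.start + L, end=c.end + L))
            else:
                out.append(c)
        elif c.start >= s and c.end <= e:  # inside
            if ev.kind == "DEL":
                continue
            if ev.kind == "DUP":
                out.append(c)
                out.append(replace(c, start=c.start + L, end=c.end + L))
            else:  # INV: reflect and flip strand
                out.append(RepeatCopy(c.family, s + e - c.end, s + e - c.start,
                                      "-" if c.strand == "+" else "+"))
        # straddling copies are dropped (avoided by candidate filtering)
    return sorted(out, key=lambda c: (c.start, c.family))


def _candidate_events(copies: list[RepeatCopy]) -> list[tuple[SeqEvent, RepeatCopy, RepeatCopy]]:
    """Legal NAHR events given the current repeat copies."""
    cands = []
    by_fam: dict[int, list[RepeatCopy]] = {}
    for c in copies:
        by_fam.setdefault(c.family, []).append(c)
    for fam in sorted(by_fam):
        group = sorted(by_fam[fam], key=lambda c: c.start)
        for x in range(len(group)):
            for y in range(x + 1, len(group)):
                a, b = group[x], group[y]
                if a.end > b.start:
                    continue
                if a.strand == b.strand:
                    events = [SeqEvent("DEL", a.start, b.start),
                              SeqEvent("DUP", a.start, b.start)]
                else:
                    events = [SeqEvent("INV", a.start, b.end)]
                for ev in events:
                    # event boundaries must not cut through another copy
                    clean = all(not (o.start < p < o.end)
                                for o in copies for p in (ev.start, ev.end))
                    if clean:
                        cands.append((ev, a, b))
    return cands


def sample_nahr_trajectory(copies: Sequence[RepeatCopy], depth: int,
                           rng_seed: int | np.random.Generator,
                           ) -> list[SeqEvent]:
    """Sample up to ``depth`` serial NAHR events legal under the evolving
    repeat configuration. Returns fewer events when no concordant event
    remains (the trajectory is then simply shorter)."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    copies = sorted(copies, key=lambda c: (c.start, c.family))
    if not copies:
        raise InputError("need at least one repeat copy")
    trajectory: list[SeqEvent] = []
    for _ in range(depth):
        cands = _candidate_events(list(copies))
        if not cands:
            break
        ev, _, _ = cands[int(rng.integers(0, len(cands)))]
        trajectory.append(ev)
        copies = _shift_copies(list(copies), ev)
    return trajectory


# ---------------------------------------------------------------------------
# Benchmark design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkDesign:
    """Factorial accuracy benchmark over SD length and similarity.

    The standard design crosses SD lengths {0.1, 0.5, 1, 10} kbp with
    similarities {90%, 95%, 99%}, 50 base sequences per cell and 2 mutated
    derivatives each (trajectory depth drawn uniformly from 1..max_depth),
    i.e. 1200 mutated sequences in total.
    """

    sd_lengths: tuple[int, ...] = (100, 500, 1000, 10_000)
    similarities: tuple[float, ...] = (0.90, 0.95, 0.99)
    n_base_sequences: int = 50
    n_derivatives: int = 2
    base_length: int = 150_000
    max_depth: int = 3

    @property
    def n_cases(self) -> int:
        return (len(self.sd_lengths) * len(self.similarities)
                * self.n_base_sequences * self.n_derivatives)


def generate_design(design: BenchmarkDesign, seed: int,
                    base_length: int | None = None) -> Iterator[TruthSet]:
    """Instantiate every case of the design as a TruthSet, deterministically.

    ``base_length`` overrides the design's sequence length (short SDs do not
    need long backgrounds); each base sequence carries 2 SD pairs of random
    orientation, and its derivatives sample distinct trajectories.
    """
    root = np.random.SeedSequence(seed)
    for sd_length in design.sd_lengths:
        for similarity in design.similarities:
            for b in range(design.n_base_sequences):
                child = root.spawn(1)[0]
                rng = np.random.default_rng(child)
                length = base_length or design.base_length
                specs = [
                    SdSpec(sd_length, similarity,
                           "+" if rng.random() < 0.5 else "-")
                    for _ in range(2)
                ]
                seq, copies = make_base_sequence(length, specs, rng)
                seen: set[tuple] = set()
                for d in range(design.n_derivatives):
                    depth = int(rng.integers(1, design.max_depth + 1))
                    for _ in range(20):  # distinct trajectories per base
                        traj = sample_nahr_trajectory(copies, depth, rng)
                        key = tuple(traj)
                        if key not in seen or not traj:
                            break
                    seen.add(key)
                    yield TruthSet(
                        base_sequence=seq,
                        mutated_sequence=mutate_sequence(seq, traj),
                        trajectory=traj,
                        seed=int(child.entropy if isinstance(child.entropy, int)
                                 else child.generate_state(1)[0]),
                        sd_length=sd_length, similarity=similarity,
                        copies=list(copies),
                    )


def run_benchmark(design: BenchmarkDesign,
                  caller: Callable[[str, str], float],
                  reps_per_cell: int | None = None,
                  seed: int = 0,
                  base_length: int | None = None,
                  success_threshold: float = 0.98) -> pd.DataFrame:
    """Accuracy table of a caller over the benchmark design.

    ``caller(ref_seq, query_seq)`` returns the score of its best recovered
    trajectory; a case counts as correctly reconstructed when that score
    reaches ``success_threshold`` — the same criterion under which a locus
    counts as explained. (Demanding exactly 1.0 instead is stricter than the
    representation allows: breakpoints at arbitrary bp positions cannot
    always be quantized consistently onto the rounding lattice, so a correct
    call may top out marginally below 1.0.) ``reps_per_cell`` overrides the
    number of mutated sequences per (sd_length, similarity) cell for
    scaled-down runs.
    """
    scaled = design
    if reps_per_cell is not None:
        n_base = max(1, reps_per_cell // design.n_derivatives)
        scaled = replace(design, n_base_sequences=n_base)
    counts: dict[tuple[int, float], list[int]] = {}
    for truth in generate_design(scaled, seed, base_length=base_length):
        score = caller(truth.base_sequence, truth.mutated_sequence)
        ok = score >= success_threshold
        cell = counts.setdefault((truth.sd_length, truth.similarity), [0, 0])
        cell[0] += int(ok)
        cell[1] += 1
    rows = [
        {"sd_length": k[0], "similarity": k[1],
         "n": v[1], "n_correct": v[0], "accuracy": v[0] / v[1]}
        for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def truth_replay_caller(truth_lookup: dict[str, float] | None = None):
    """Oracle caller for tests: replays the truth, always scoring 1.0."""
    def caller(ref_seq: str, query_seq: str) -> float:
        return 1.0
    return caller
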