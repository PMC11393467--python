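"""Noise reduction, gridline fixpoint and matrix condensation."""

import random

import numpy as np
import pytest

from serialsv.alignment import ExactSeedAligner, align_chunks, merge_chunk_alignments
from serialsv.segmentation import (
    Grid,
    NoiseParams,
    build_grid,
    cap_dimensions,
    denoise_alignments,
    matrix_from_grid,
    segment_records,
    select_noise_params,
)
from serialsv.simulate import SdSpec, make_base_sequence, mutate_sequence, sample_nahr_trajectory

from conftest import make_record


@pytest.mark.parametrize(
    "length,expected",
    [(40_000, 100), (50_000, 1000), (300_000, 1000), (500_000, 10_000),
     (4_999_999, 10_000), (6_000_000, 20_000)],
)
def test_noise_param_steps(length, expected):
    params = select_noise_params(length)
    assert params.min_len == params.rounding == expected


class TestDenoise:
    def test_short_alignment_dropped(self):
        rec = make_record(0, 800, 0, 800)
        assert denoise_alignments([rec], NoiseParams(1000, 1000)) == []

    def test_rounding_to_nearest_multiple(self):
        rec = make_record(1234, 5678, 1234, 5678)
        (out,) = denoise_alignments([rec], NoiseParams(1000, 1000))
        assert (out.query_start, out.query_end) == (1000, 6000)

    def test_half_rounds_up(self):
        rec = make_record(1500, 4500, 1500, 4500)
        (out,) = denoise_alignments([rec], NoiseParams(1000, 1000))
        assert (out.query_start, out.query_end) == (2000, 5000)

    def test_slope_normalization_trims_end(self):
        # dx=3000, dy=2000 -> trimmed to 2000/2000
        rec = make_record(0, 2000, 0, 3000)
        (out,) = denoise_alignments([rec], NoiseParams(1000, 1000))
        assert out.query_span == out.target_span == 2000
        assert out.target_start == 0

    def test_minus_strand_trims_at_low_target_end(self):
        # away from sequence boundaries, a '-' record is trimmed on the
        # target-start side (the query-end corner)
        rec = make_record(1000, 3000, 5000, 8000, "-", qlen=50_000, tlen=50_000)
        (out,) = denoise_alignments([rec], NoiseParams(1000, 1000))
        assert out.query_span == out.target_span == 2000
        assert out.target_end == 8000

    def test_boundary_endpoints_stay_pinned(self):
        # an alignment reaching the sequence end still reaches the rounded
        # axis end after denoising (no phantom edge segment)
        rec = make_record(16_738, 29_330, 137_408, 150_000,
                          qlen=29_330, tlen=150_000)
        (out,) = denoise_alignments([rec], NoiseParams(1000, 1000))
        assert out.query_end == out.query_len == 29_000
        assert out.target_end == out.target_len == 150_000
        assert out.query_span == out.target_span

    def test_zero_span_after_rounding_dropped(self):
        # both breakpoints snap to the same 2 kbp gridline
        rec = make_record(9200, 10_600, 9200, 10_600)
        assert denoise_alignments([rec], NoiseParams(1000, 2000)) == []


def brute_force_grid(records, ref_len, query_len):
    """Independent fixpoint iteration: recompute cut sets from scratch until stable."""
    x = {0, ref_len}
    y = {0, query_len}
    for r in records:
        x.update((r.target_start, r.target_end))
        y.update((r.query_start, r.query_end))
    while True:
        nx, ny = set(x), set(y)
        for r in records:
            for c in list(nx):
                if r.target_start < c < r.target_end:
                    off = c - r.target_start
                    ny.add(r.query_start + off if r.strand == "+" else r.query_end - off)
            for c in list(ny):
                if r.query_start < c < r.query_end:
                    off = c - r.query_start
                    nx.add(r.target_start + off if r.strand == "+" else r.target_end - off)
        if nx == x and ny == y:
            return sorted(x), sorted(y)
        x, y = nx, ny


class TestGrid:
    def test_single_alignment(self):
        grid = build_grid([make_record(0, 10_000, 0, 10_000, qlen=10_000, tlen=10_000)])
        assert grid.x_cuts == [0, 10_000] and grid.y_cuts == [0, 10_000]

    def test_tandem_duplication_propagation(self):
        recs = [
            make_record(0, 5000, 0, 5000, qlen=10_000, tlen=5000),
            make_record(5000, 10_000, 0, 5000, qlen=10_000, tlen=5000),
        ]
        grid = build_grid(recs)
        assert grid.x_cuts == [0, 5000]
        assert grid.y_cuts == [0, 5000, 10_000]

    def test_nested_repeat_fixpoint(self):
        recs = [
            make_record(0, 10_000, 0, 10_000, qlen=14_000, tlen=10_000),
            make_record(12_000, 14_000, 2000, 4000, qlen=14_000, tlen=10_000),
        ]
        grid = build_grid(recs)
        assert grid.x_cuts == [0, 2000, 4000, 10_000]
        assert grid.y_cuts == [0, 2000, 4000, 10_000, 12_000, 14_000]
        bx, by = brute_force_grid(recs, 10_000, 14_000)
        assert grid.x_cuts == bx and grid.y_cuts == by

    def test_fixpoint_order_independent(self, rng):
        recs = [
            make_record(0, 10_000, 0, 10_000, qlen=20_000, tlen=12_000),
            make_record(12_000, 14_000, 2000, 4000, qlen=20_000, tlen=12_000),
            make_record(15_000, 20_000, 5000, 10_000, "-", qlen=20_000, tlen=12_000),
            make_record(3000, 6000, 9000, 12_000, qlen=20_000, tlen=12_000),
        ]
        ref = build_grid(recs)
        for _ in range(5):
            shuffled = recs[:]
            random.Random(int(rng.integers(1 << 30))).shuffle(shuffled)
            g = build_grid(shuffled)
            assert g.x_cuts == ref.x_cuts and g.y_cuts == ref.y_cuts
        bx, by = brute_force_grid(recs, 12_000, 20_000)
        assert ref.x_cuts == bx and ref.y_cuts == by


class TestMatrix:
    def test_identity_1x1(self):
        recs = [make_record(0, 10_000, 0, 10_000, qlen=10_000, tlen=10_000)]
        m = matrix_from_grid(recs, build_grid(recs))
        assert m.entries.tolist() == [[1]]
        assert m.col_lengths.tolist() == [10_000]

    def test_tandem_duplication_two_rows(self):
        recs = [
            make_record(0, 5000, 0, 5000, qlen=10_000, tlen=5000),
            make_record(5000, 10_000, 0, 5000, qlen=10_000, tlen=5000),
        ]
        m = matrix_from_grid(recs, build_grid(recs))
        assert m.entries.shape == (2, 1)
        assert m.entries.tolist() == [[1], [1]]

    def test_inverted_middle_segment(self):
        recs = [
            make_record(0, 4000, 0, 4000, qlen=10_000, tlen=10_000),
            make_record(4000, 6000, 4000, 6000, "-", qlen=10_000, tlen=10_000),
            make_record(6000, 10_000, 6000, 10_000, qlen=10_000, tlen=10_000),
        ]
        m = matrix_from_grid(recs, build_grid(recs))
        assert m.entries.tolist() == [[1, 0, 0], [0, -1, 0], [0, 0, 1]]

    def test_nonzero_cells_are_square(self, rng):
        recs = [
            make_record(0, 10_000, 0, 10_000, qlen=16_000, tlen=12_000),
            make_record(12_000, 14_000, 2000, 4000, qlen=16_000, tlen=12_000),
            make_record(14_000, 16_000, 9000, 11_000, "-", qlen=16_000, tlen=12_000),
        ]
        m = matrix_from_grid(recs, build_grid(recs))
        rows, cols = np.nonzero(m.entries)
        assert len(rows) > 0
        for i, j in zip(rows, cols):
            assert m.row_lengths[i] == m.col_lengths[j]


class TestCapDimensions:
    def test_small_input_unchanged(self):
        recs = [make_record(0, 10_000, 0, 10_000, qlen=10_000, tlen=10_000)]
        params = NoiseParams(1000, 1000)
        _, eff = cap_dimensions(recs, params)
        assert eff == params

    def test_doubling_engages_and_shrinks(self):
        # 200 short alignments exceed the alignment cap at l=r=1000
        recs = [make_record(i * 2000, i * 2000 + 1500, i * 2000, i * 2000 + 1500,
                            qlen=500_000, tlen=500_000)
                for i in range(200)]
        denoised, eff = cap_dimensions(recs, NoiseParams(1000, 1000))
        assert eff.min_len > 1000
        assert len(denoised) <= 150

    def test_alignment_count_monotone_in_params(self):
        recs = [make_record(i * 3000, i * 3000 + 1000 + (i % 3) * 500,
                            i * 3000, i * 3000 + 1000 + (i % 3) * 500,
                            qlen=200_000, tlen=200_000)
                for i in range(40)]
        params = NoiseParams(1000, 1000)
        counts = []
        for _ in range(4):
            counts.append(len(denoise_alignments(recs, params)))
            params = params.doubled()
        assert counts == sorted(counts, reverse=True)


class TestLossless:
    def _simulated_records(self, seed, depth):
        rng = np.random.default_rng(seed)
        specs = [SdSpec(10_000, 1.0, "-" if rng.random() < 0.5 else "+")
                 for _ in range(2)]
        seq, copies = make_base_sequence(120_000, specs, rng)
        traj = sample_nahr_trajectory(copies, depth, rng)
        mut = mutate_sequence(seq, traj)
        recs = merge_chunk_alignments(align_chunks(mut, seq, ExactSeedAligner()))
        return recs, len(seq), len(mut)

    @pytest.mark.parametrize("seed,depth", [(11, 1), (12, 2), (13, 3)])
    def test_reconstruction_is_lossless(self, seed, depth):
        """Nonzero cells, traversed diagonally, carry exactly the denoised
        alignment set: every record decomposes into cells of its sign and
        every nonzero cell is covered by some record."""
        recs, ref_len, query_len = self._simulated_records(seed, depth)
        params = select_noise_params(max(ref_len, query_len))
        denoised, params = cap_dimensions(recs, params, ref_len=ref_len,
                                          query_len=query_len)
        rl = ((ref_len + params.rounding // 2) // params.rounding) * params.rounding
        ql = ((query_len + params.rounding // 2) // params.rounding) * params.rounding
        grid = build_grid(denoised, rl, ql)
        m = matrix_from_grid(denoised, grid)
        covered = {}
        for r in denoised:
            x = r.target_start
            while x < r.target_end:
                j = grid.x_cuts.index(x)
                off = x - r.target_start
                if r.strand == "+":
                    y = r.query_start + off
                else:
                    y = r.query_end - off - (grid.x_cuts[j + 1] - x)
                i = grid.y_cuts.index(y)
                sign = 1 if r.strand == "+" else -1
                covered.setdefault((i, j), set()).add(sign)
                x = grid.x_cuts[j + 1]
        nz = {(int(i), int(j)) for i, j in zip(*np.nonzero(m.entries))}
        assert nz == set(covered)
        for (i, j), signs in covered.items():
            assert int(m.entries[i, j]) in signs

    def test_square_cells_on_simulated_input(self):
        recs, ref_len, query_len = self._simulated_records(21, 2)
        m, _ = segment_records(recs, ref_len=ref_len, query_len=query_len)
        rows, cols = np.nonzero(m.entries)
        for i, j in zip(rows, cols):
            assert m.row_lengths[i] == m.col_lengths[j]
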