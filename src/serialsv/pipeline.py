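"""End-to-end genotyping: sequences in, locus call out.

Chains the alignment, segmentation and search stages: chunk-align the query
region against the reference region, merge and denoise the alignments,
condense them into a segmented dotplot, search for NAHR event series, and
classify the locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import alignment as aln
from .alignment import AlnRecord, ChunkParams, ExactSeedAligner, RegionSpec
from .engine import LocusCall, SearchConfig, Trajectory, classify_locus, search_ssv
from .segmentation import NoiseParams, SegmentMatrix, segment_records, select_noise_params


@dataclass
class GenotypeResult:
    """Everything the pipeline produced for one locus."""

    call: LocusCall
    matrix: SegmentMatrix | None
    noise_params: NoiseParams | None
    records: list[AlnRecord]

    @property
    def status(self) -> str:
        return self.call.status

    @property
    def best_score(self) -> float:
        return self.call.best_score

    @property
    def best_trajectory(self) -> Trajectory | None:
        return self.call.best


def genotype_sequences(ref_seq: str, query_seq: str, *,
                       adapter=None,
                       chunk_params: ChunkParams | None = None,
                       config: SearchConfig | None = None,
                       contiguous: bool = True) -> GenotypeResult:
    """Genotype a query sequence against a reference sequence."""
    adapter = adapter or ExactSeedAligner()
    chunk_params = chunk_params or ChunkParams()
    config = config or SearchConfig()
    records = aln.align_chunks(query_seq, ref_seq, adapter, params=chunk_params)
    records = aln.merge_chunk_alignments(records, chunk_params)
    noise = select_noise_params(max(len(ref_seq), len(query_seq)))
    if not records:
        return GenotypeResult(LocusCall("UNEXPLAINED" if contiguous else "UNASSEMBLED",
                                        [], 0.0), None, noise, [])
    matrix, noise = segment_records(records, noise,
                                    ref_len=len(ref_seq), query_len=len(query_seq))
    trajectories = search_ssv(matrix, config)
    call = classify_locus(trajectories, config, contiguous=contiguous)
    return GenotypeResult(call, matrix, noise, records)


def genotype_region(ref_fasta, query_fasta, roi: RegionSpec, *,
                    adapter=None,
                    chunk_params: ChunkParams | None = None,
                    config: SearchConfig | None = None,
                    pad_fraction: float = 0.0) -> tuple[GenotypeResult, RegionSpec]:
    """Genotype a reference ROI against its located counterpart in the query.

    The counterpart defaults to the unpadded homologous span: extra padding
    would appear as unaligned query flanks, which the segment score counts
    against the reconstruction.
    """
    adapter = adapter or ExactSeedAligner()
    counterpart, contiguous = aln.locate_counterpart(
        ref_fasta, roi, query_fasta, adapter, params=chunk_params,
        pad_fraction=pad_fraction)
    ref_seq = str(ref_fasta[roi.contig][roi.start : roi.end])
    query_seq = str(query_fasta[counterpart.contig][counterpart.start : counterpart.end])
    if counterpart.orientation_vs_ref == "-":
        query_seq = aln.revcomp(query_seq)
    result = genotype_sequences(ref_seq, query_seq, adapter=adapter,
                                chunk_params=chunk_params, config=config,
                                contiguous=contiguous)
    return result, counterpart


def benchmark_caller(config: SearchConfig | None = None, adapter=None, *,
                     weighted: bool = True):
    """Caller for the simulator benchmark.

    Returns the score of the best recovered trajectory. By default the final
    state is re-scored with the bp-weighted (size-scaled) segment score — the
    scale on which reconstruction success is defined — while the search
    itself ranks states by the literal segment-count recurrence.
    """
    from .engine import score_matrix

    def caller(ref_seq: str, query_seq: str) -> float:
        result = genotype_sequences(ref_seq, query_seq, adapter=adapter,
                                    config=config)
        best = result.best_trajectory
        if best is None:
            return 0.0
        if weighted:
            return score_matrix(best.final_matrix, weighted=True)
        return best.score
    return caller


def results_row(sample: str, haplotype: str, roi: RegionSpec,
                result: GenotypeResult) -> dict:
    best = result.best_trajectory
    return {
        "sample": sample,
        "haplotype": haplotype,
        "roi": str(roi),
        "status": result.status,
        "depth": best.depth if best else 0,
        "trajectory": best.op_string() if best else "",
        "score": round(result.best_score, 4),
        "noise_l": result.noise_params.min_len if result.noise_params else "",
        "noise_r": result.noise_params.rounding if result.noise_params else "",
        "matrix_rows": result.matrix.n_rows if result.matrix is not None else 0,
        "matrix_cols": result.matrix.n_cols if result.matrix is not None else 0,
    }


def results_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)
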