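"""Pairwise-alignment helpers shared by the search and phylogeny modules.

Dynamic programming itself is delegated to :class:`Bio.Align.PairwiseAligner`;
this module standardizes scoring, and converts alignments into match/column
statistics in which N never counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -3
DEFAULT_GAP_OPEN = -5
DEFAULT_GAP_EXTEND = -2


def make_aligner(
    mode: str = "local",
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    free_end_gaps: bool = False,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global" if free_end_gaps else mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if free_end_gaps:
        # free end gaps on the query side only: a truncated query aligns to
        # part of the target for free, but skipping query sequence is not free
        # (a half-matching chimera must pay for its non-matching half)
        try:
            aligner.open_end_deletion_score = 0
            aligner.extend_end_deletion_score = 0
        except AttributeError:  # older Biopython naming
            aligner.query_end_open_gap_score = 0
            aligner.query_end_extend_gap_score = 0
    return aligner


@dataclass(frozen=True)
class PairwiseHit:
    """Statistics of the best alignment of query against target."""

    score: float
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _alignment_stats(alignment, target: str, query: str) -> PairwiseHit:
    t_blocks, q_blocks = alignment.aligned
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for x, y in zip(target[ts:te], query[qs:qe]):
            columns += 1
            if x == y and x != "N":
                matches += 1
    for i in range(1, len(t_blocks)):
        columns += t_blocks[i][0] - t_blocks[i - 1][1]
        columns += q_blocks[i][0] - q_blocks[i - 1][1]
    return PairwiseHit(
        score=float(alignment.score),
        target_start=int(t_blocks[0][0]),
        target_end=int(t_blocks[-1][1]),
        query_start=int(q_blocks[0][0]),
        query_end=int(q_blocks[-1][1]),
        matches=matches,
        columns=columns,
    )


def best_alignment(
    aligner: Align.PairwiseAligner, target: str, query: str
) -> PairwiseHit | None:
    """Best-scoring alignment of query vs target, or None when score <= 0."""
    alignments = aligner.align(target, query)
    if aligner.mode == "local" and alignments.score <= 0:
        return None
    best = alignments[0]
    if len(best.aligned[0]) == 0:
        return None
    return _alignment_stats(best, target, query)


def glocal_identity(
    consensus: str,
    sequence: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> float:
    """Identity of ``sequence`` against ``consensus`` with free end gaps.

    End gaps are excluded from the column count, so a truncated copy is
    judged only over the region it actually covers.
    """
    aligner = make_aligner(
        match=match,
        mismatch=mismatch,
        gap_open=gap_open,
        gap_extend=gap_extend,
        free_end_gaps=True,
    )
    hit = best_alignment(aligner, consensus, sequence)
    if hit is None or hit.columns == 0:
        return 0.0
    return hit.identity
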