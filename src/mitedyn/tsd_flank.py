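"""Flank extraction and target-site-duplication (TSD) detection.

A TSD is the short stretch of host sequence duplicated on both sides of an
element upon insertion; detection is junction-anchored: the suffix of the
left flank is compared with the prefix of the right flank on the genome
forward strand, so the element's own strand is irrelevant.  Minimum
reportable length is 2 bp (1-bp "duplications" match 25% of junctions by
chance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import GenomeAssembly
from .te_search import InsertionSite


@dataclass
class FlankedLocus:
    """An insertion plus its left/right flanks at a stated window."""

    site: InsertionSite
    window: int
    left_flank: str
    right_flank: str
    clipped_left: bool = False
    clipped_right: bool = False


@dataclass(frozen=True)
class TSD:
    motif: str
    length: int
    mismatches: int
    adjusted_junction: bool = False


@dataclass
class PositionFrequencyMatrix:
    """Per-position A/C/G/T fractions over a set of motifs."""

    columns: list[dict[str, float]]
    depth: int
    column_depths: list[int] = field(default_factory=list)


def extract_flanks(
    site: InsertionSite, assembly: GenomeAssembly, window: int
) -> FlankedLocus:
    """Forward-strand flanks of ``window`` bp on each side of the element.

    Requests overrunning chromosome ends are clipped and flagged.
    """
    iv = site.interval
    chrom_seq = assembly.chromosomes[iv.chromosome]  # KeyError on unknown name
    left_start = iv.start - window
    left = chrom_seq[max(0, left_start) : iv.start]
    right_end = iv.end + window
    right = chrom_seq[iv.end : right_end]
    return FlankedLocus(
        site,
        window,
        left,
        right,
        clipped_left=left_start < 0,
        clipped_right=right_end > len(chrom_seq),
    )


def _best_tsd(
    left: str, right: str, max_tsd_len: int, max_mismatches: int, min_len: int
) -> TSD | None:
    limit = min(max_tsd_len, len(left), len(right))
    for L in range(limit, min_len - 1, -1):
        suffix = left[-L:]
        prefix = right[:L]
        mismatches = sum(
            1 for a, b in zip(suffix, prefix) if a != b or a == "N"
        )
        if mismatches <= max_mismatches:
            return TSD(motif=suffix, length=L, mismatches=mismatches)
    return None


def detect_tsd(
    flanked: FlankedLocus,
    max_tsd_len: int = 10,
    max_mismatches: int = 0,
    min_len: int = 2,
    junction_slide: int = 0,
) -> TSD | None:
    """Longest junction-anchored duplication of length in [min_len, max_tsd_len].

    With ``junction_slide`` > 0 the element boundaries are additionally slid
    by up to that many bases into flank or element (for copies whose exact
    ends are uncertain), and the longest hit over all shifts is reported,
    flagged ``adjusted_junction``.
    """
    best = _best_tsd(
        flanked.left_flank, flanked.right_flank, max_tsd_len, max_mismatches, min_len
    )
    if junction_slide <= 0:
        return best
    combined = flanked.left_flank + flanked.site.sequence + flanked.right_flank
    left_junction = len(flanked.left_flank)
    right_junction = left_junction + len(flanked.site.sequence)
    for dl in range(-junction_slide, junction_slide + 1):
        for dr in range(-junction_slide, junction_slide + 1):
            if dl == 0 and dr == 0:
                continue
            lj = left_junction + dl
            rj = right_junction + dr
            if not (0 < lj < rj < len(combined)):
                continue
            cand = _best_tsd(
                combined[:lj], combined[rj:], max_tsd_len, max_mismatches, min_len
            )
            if cand is not None and (best is None or cand.length > best.length):
                best = TSD(cand.motif, cand.length, cand.mismatches, True)
    return best


def tsd_logo(tsds: list[TSD]) -> PositionFrequencyMatrix:
    """Position frequency matrix over TSD motifs.

    Motifs are right-padded to the longest length; pad positions do not
    contribute, so each column's fractions sum to 1 over contributing motifs.
    """
    motifs = [t.motif for t in tsds]
    if not motifs:
        raise ValueError("tsd_logo requires at least one motif")
    width = max(len(m) for m in motifs)
    columns: list[dict[str, float]] = []
    column_depths: list[int] = []
    for pos in range(width):
        counts = {b: 0 for b in "ACGT"}
        depth = 0
        for m in motifs:
            if pos < len(m) and m[pos] in counts:
                counts[m[pos]] += 1
                depth += 1
        columns.append(
            {b: (counts[b] / depth if depth else 0.0) for b in "ACGT"}
        )
        column_depths.append(depth)
    return PositionFrequencyMatrix(columns, len(motifs), column_depths)
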