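"""Genome I/O, coordinate conventions, and sequence primitives.

Coordinates are 0-based half-open everywhere inside the package; every
serialized table is 1-based inclusive with ``start <= end`` and the strand in
its own column.  Input coordinates written in the ``start > end`` style (minus
strand encoded by reversed bounds) are accepted by
:meth:`GenomicInterval.from_1based` but never emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


class GffFormatError(ValueError):
    """Raised for unusable GFF3 input."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with explicit strand."""

    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[str, int, int, str]:
        """(chromosome, start, end, strand) with 1-based inclusive bounds."""
        return self.chromosome, self.start + 1, self.end, self.strand

    @classmethod
    def from_1based(
        cls, chromosome: str, start: int, end: int, strand: str | None = None
    ) -> "GenomicInterval":
        """Parse 1-based inclusive coordinates.

        ``start > end`` encodes the minus strand (as printed in some reports);
        an explicit ``strand`` argument wins over that encoding.
        """
        if start > end:
            start, end = end, start
            strand = strand or "-"
        return cls(chromosome, start - 1, end, strand or "+")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeAssembly:
    """Named set of chromosome sequences with species/sub-genome labels."""

    species_id: str
    chromosomes: dict[str, str]
    subgenome_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError(f"assembly {self.species_id!r} has no chromosomes")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")

    def subgenome(self, chromosome: str) -> str:
        """Sub-genome letter (A/B/D) of a chromosome, 'U' when unmapped."""
        if chromosome in self.subgenome_of:
            return self.subgenome_of[chromosome]
        head = chromosome[:1].upper()
        return head if head in "ABD" else "U"

    def chrom_length(self, chromosome: str) -> int:
        try:
            return len(self.chromosomes[chromosome])
        except KeyError:
            raise KeyError(
                f"unknown chromosome {chromosome!r} in assembly {self.species_id!r}"
            ) from None


def _clean_sequence(raw: str, name: str) -> str:
    seq = raw.upper()
    if not set(seq) <= VALID_BASES:
        n_bad = sum(1 for c in seq if c not in VALID_BASES)
        logger.warning(
            "record %s: %d non-ACGTN characters mapped to N", name, n_bad
        )
        seq = "".join(c if c in VALID_BASES else "N" for c in seq)
    return seq


def read_fasta(path: str | Path, species_id: str | None = None) -> GenomeAssembly:
    """Load a (multi-record) FASTA file into a :class:`GenomeAssembly`.

    Sequences are uppercased; IUPAC ambiguity codes and any other non-ACGTN
    characters collapse to N with a logged warning.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno} is not a FASTA header"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: empty file")
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise FastaFormatError(f"{path}: duplicate record {record.id!r}")
        seq = _clean_sequence(str(record.seq), record.id)
        if not seq:
            raise FastaFormatError(f"{path}: record {record.id!r} has no sequence")
        chromosomes[record.id] = seq
    return GenomeAssembly(species_id or path.stem, chromosomes)


def write_fasta(
    assembly: GenomeAssembly | Mapping[str, str], path: str | Path, width: int = 60
) -> None:
    chromosomes = (
        assembly.chromosomes if isinstance(assembly, GenomeAssembly) else assembly
    )
    with open(path, "w") as fh:
        for name, seq in chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_region(assembly: GenomeAssembly, interval: GenomicInterval) -> str:
    """Sequence of an in-bounds interval; minus strand is reverse-complemented."""
    length = assembly.chrom_length(interval.chromosome)
    if interval.start < 0 or interval.end > length:
        raise ValueError(
            f"interval {interval.chromosome}:{interval.start}-{interval.end} "
            f"outside chromosome of length {length}"
        )
    seq = assembly.chromosomes[interval.chromosome][interval.start : interval.end]
    return revcomp(seq) if interval.strand == "-" else seq


def extract_region_clipped(
    assembly: GenomeAssembly, interval: GenomicInterval
) -> tuple[str, bool, bool]:
    """Like :func:`extract_region` but clips at chromosome ends.

    Returns ``(sequence, clipped_left, clipped_right)`` where the clip flags
    refer to the forward-strand bounds of the request.
    """
    length = assembly.chrom_length(interval.chromosome)
    start = max(0, interval.start)
    end = min(length, interval.end)
    clipped_left = start != interval.start
    clipped_right = end != interval.end
    if end <= start:
        return "", clipped_left, clipped_right
    seq = assembly.chromosomes[interval.chromosome][start:end]
    if interval.strand == "-":
        seq = revcomp(seq)
    return seq, clipped_left, clipped_right


@dataclass
class GeneAnnotation:
    """A gene with its exon/CDS children and implied introns."""

    gene_id: str
    interval: GenomicInterval
    features: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    def features_of_type(self, feature_type: str) -> list[GenomicInterval]:
        return [iv for t, iv in self.features if t == feature_type]


def _implied_introns(
    exons: list[GenomicInterval], strand: str
) -> list[GenomicInterval]:
    introns = []
    exons = sorted(exons, key=lambda iv: iv.start)
    for a, b in zip(exons, exons[1:]):
        if b.start > a.end:
            introns.append(GenomicInterval(a.chromosome, a.end, b.start, strand))
    return introns


def read_gff(path: str | Path) -> list[GeneAnnotation]:
    """Parse gene/mRNA/exon/CDS rows of a GFF3 file.

    GFF 1-based inclusive coordinates convert to the internal convention;
    exon/CDS rows without a resolvable parent gene are skipped with a warning.
    Implied introns (gaps between exons of one gene) are added as ``intron``
    features.
    """
    import gffutils

    path = Path(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    for gene in db.features_of_type("gene"):
        interval = GenomicInterval.from_1based(
            gene.seqid, gene.start, gene.end, gene.strand if gene.strand in "+-" else "+"
        )
        features: list[tuple[str, GenomicInterval]] = []
        for child in db.children(gene, featuretype=("exon", "CDS")):
            features.append(
                (
                    child.featuretype,
                    GenomicInterval.from_1based(
                        child.seqid, child.start, child.end, interval.strand
                    ),
                )
            )
        exons = [iv for t, iv in features if t == "exon"]
        for intron in _implied_introns(exons, interval.strand):
            features.append(("intron", intron))
        genes.append(GeneAnnotation(gene.id, interval, features))
    known_parents = {g.gene_id for g in genes}
    for child in db.features_of_type(("exon", "CDS")):
        parents = list(db.parents(child, featuretype="gene"))
        if not parents:
            logger.warning(
                "GFF feature %s (%s) has no parent gene; skipped",
                child.id,
                child.featuretype,
            )
    del known_parents
    return genes


def write_gff(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Serialize annotations back to GFF3 (genes with exon/CDS children)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            chrom, start, end, strand = gene.interval.to_1based()
            fh.write(
                f"{chrom}\tmitedyn\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for ftype, iv in gene.features:
                if ftype == "intron":
                    continue  # implied, never serialized
                c, s, e, st = iv.to_1based()
                fh.write(
                    f"{c}\tmitedyn\t{ftype}\t{s}\t{e}\t.\t{st}\t.\t"
                    f"Parent={gene.gene_id}\n"
                )
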