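"""Cross-genome presence/absence of insertion loci via flank mapping.

For every detected insertion, 1000-bp flanks on either side are placed in
each counterpart genome (reciprocal best hits at >= 0.90 identity over >=
0.80 of the flank — stricter than the 80/80 family rule because flanks are
unique sequence); the relation between the mapped flanks decides the locus
state.  Loci that reciprocally classify as full sites cluster into
orthologous groups, which yield the species-membership matrix and the Venn
region counts.  Venn regions count full sites only; an empty site is "locus
conserved, element absent" and is reported separately.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .core_io import GeneAnnotation, GenomeAssembly, GenomicInterval
from .te_search import (
    AssemblyIndex,
    InsertionSite,
    SeqHit,
    TEConsensus,
    search_sequence,
)
from .tsd_flank import FlankedLocus, extract_flanks

logger = logging.getLogger(__name__)

PRESENCE_STATES = (
    "full_site",
    "empty_site",
    "absent_locus",
    "rearranged_candidate",
    "ambiguous",
)

#: informativeness order used when aggregating calls over a cluster
_STATE_PRIORITY = {s: i for i, s in enumerate(PRESENCE_STATES)}


@dataclass
class MappingParams:
    flank_window: int = 1000
    min_flank_length: int = 200
    min_identity: float = 0.90
    min_coverage: float = 0.80
    max_flank_separation: int = 50_000
    empty_gap_tolerance: int = 100  # absorbs TSD remnants and small indels
    element_min_identity: float = 0.80
    element_min_coverage: float = 0.80
    reciprocal: bool = True
    min_seeds: int = 5  # unique flanks seed densely; filters noise windows
    min_score: float = 100.0  # raw floor; a passing flank hit scores ~1000


@dataclass
class LocusMapping:
    source_site: InsertionSite
    target_species: str
    left_flank_hit: SeqHit | None = None
    right_flank_hit: SeqHit | None = None
    inter_flank_gap: int | None = None
    element_present_in_gap: bool = False
    gap_element_identity: float = 0.0
    gap_element_coverage: float = 0.0
    gap_interval: GenomicInterval | None = None
    flanks_usable: bool = True


@dataclass
class PresenceCall:
    state: str
    evidence: LocusMapping


@dataclass
class MembershipMatrix:
    """Orthologous locus clusters x species presence states."""

    species: list[str]
    clusters: list[dict]  # cluster_id, members {species: site_id}, states {...}
    warnings: list[str] = field(default_factory=list)

    def states(self, cluster_id: str) -> dict[str, str]:
        for c in self.clusters:
            if c["cluster_id"] == cluster_id:
                return c["states"]
        raise KeyError(cluster_id)


@dataclass(frozen=True)
class GeneAssociation:
    site_id: str
    gene_id: str
    relation: str  # within_CDS | within_exon_UTR | within_intron | upstream | downstream
    distance: int


def _best_reciprocal_hit(
    flank_seq: str,
    source_assembly: GenomeAssembly,
    source_interval: GenomicInterval,
    target_assembly: GenomeAssembly,
    params: MappingParams,
    target_index: AssemblyIndex | None,
    source_index: AssemblyIndex | None,
) -> SeqHit | None:
    hits = search_sequence(
        flank_seq,
        target_assembly,
        min_identity=params.min_identity,
        min_coverage=params.min_coverage,
        min_score=params.min_score,
        min_seeds=params.min_seeds,
        index=target_index,
    )
    if not hits:
        return None
    best = hits[0]
    if params.reciprocal:
        back_seq = target_assembly.chromosomes[best.interval.chromosome][
            best.interval.start : best.interval.end
        ]
        back = search_sequence(
            back_seq,
            source_assembly,
            min_identity=params.min_identity,
            min_coverage=params.min_coverage,
            min_score=params.min_score,
            min_seeds=params.min_seeds,
            index=source_index,
        )
        if not back or not back[0].interval.overlaps(source_interval):
            return None
    return best


def map_locus(
    flanked: FlankedLocus,
    source: GenomeAssembly,
    target: GenomeAssembly,
    consensus_set: list[TEConsensus] | None = None,
    params: MappingParams | None = None,
    target_index: AssemblyIndex | None = None,
    source_index: AssemblyIndex | None = None,
) -> LocusMapping:
    """Place both flanks of a locus in a counterpart genome."""
    params = params or MappingParams()
    site = flanked.site
    mapping = LocusMapping(source_site=site, target_species=target.species_id)
    if (
        len(flanked.left_flank) < params.min_flank_length
        or len(flanked.right_flank) < params.min_flank_length
    ):
        mapping.flanks_usable = False
        return mapping
    iv = site.interval
    left_iv = GenomicInterval(iv.chromosome, iv.start - len(flanked.left_flank), iv.start)
    right_iv = GenomicInterval(iv.chromosome, iv.end, iv.end + len(flanked.right_flank))
    mapping.left_flank_hit = _best_reciprocal_hit(
        flanked.left_flank, source, left_iv, target, params, target_index, source_index
    )
    mapping.right_flank_hit = _best_reciprocal_hit(
        flanked.right_flank, source, right_iv, target, params, target_index, source_index
    )
    lh, rh = mapping.left_flank_hit, mapping.right_flank_hit
    if lh is None or rh is None:
        return mapping
    if (
        lh.interval.chromosome != rh.interval.chromosome
        or lh.interval.strand != rh.interval.strand
    ):
        return mapping
    if lh.interval.strand == "+":
        gap_start, gap_end = lh.interval.end, rh.interval.start
    else:  # locus inverted in target: right flank precedes left flank
        gap_start, gap_end = rh.interval.end, lh.interval.start
    gap = gap_end - gap_start
    if abs(gap) > params.max_flank_separation:
        return mapping
    mapping.inter_flank_gap = gap
    if gap > 0 and consensus_set:
        chrom = target.chromosomes[lh.interval.chromosome]
        gap_seq = chrom[gap_start:gap_end]
        mapping.gap_interval = GenomicInterval(
            lh.interval.chromosome, gap_start, gap_end, lh.interval.strand
        )
        for cons in consensus_set:
            identity, coverage = _element_in_gap(gap_seq, cons)
            if identity * coverage > (
                mapping.gap_element_identity * mapping.gap_element_coverage
            ):
                mapping.gap_element_identity = identity
                mapping.gap_element_coverage = coverage
        mapping.element_present_in_gap = (
            mapping.gap_element_identity >= params.element_min_identity
            and mapping.gap_element_coverage >= params.element_min_coverage
        )
    return mapping


def _element_in_gap(gap_seq: str, consensus: TEConsensus) -> tuple[float, float]:
    """(identity, fraction of the gap explained) of a consensus in a gap."""
    from .align import best_alignment, make_aligner
    from .core_io import revcomp

    if not gap_seq:
        return 0.0, 0.0
    best_ident, best_cov = 0.0, 0.0
    aligner = make_aligner("local")
    for q in (consensus.sequence, revcomp(consensus.sequence)):
        hit = best_alignment(aligner, gap_seq, q)
        if hit is None:
            continue
        coverage = (hit.target_end - hit.target_start) / len(gap_seq)
        if hit.identity * coverage > best_ident * best_cov:
            best_ident, best_cov = hit.identity, coverage
    return best_ident, best_cov


def classify_presence(
    mapping: LocusMapping, params: MappingParams | None = None
) -> PresenceCall:
    """Pure rule-based presence state of a locus in a target genome.

    Rules in order: (1) both flanks mapped and the gap carries the element ->
    full_site; (2) both flanks mapped with a small gap and no element ->
    empty_site; (3) one flank mapped, or flanks inconsistent (different
    chromosomes, opposite strands, > 50 kb apart) -> rearranged_candidate;
    (4) neither flank mapped -> absent_locus; (5) otherwise ambiguous.
    """
    params = params or MappingParams()
    m = mapping
    if not m.flanks_usable:
        return PresenceCall("ambiguous", m)
    lh, rh = m.left_flank_hit, m.right_flank_hit
    both = lh is not None and rh is not None
    consistent = both and m.inter_flank_gap is not None
    if consistent and m.element_present_in_gap:
        return PresenceCall("full_site", m)
    if consistent and m.inter_flank_gap <= params.empty_gap_tolerance:
        return PresenceCall("empty_site", m)
    if (lh is None) != (rh is None) or (both and not consistent):
        return PresenceCall("rearranged_candidate", m)
    if lh is None and rh is None:
        return PresenceCall("absent_locus", m)
    return PresenceCall("ambiguous", m)


def membership_matrix(
    sites_by_species: dict[str, list[InsertionSite]],
    assemblies: dict[str, GenomeAssembly],
    consensus_set: list[TEConsensus],
    params: MappingParams | None = None,
) -> MembershipMatrix:
    """Cluster orthologous loci across species and call their states.

    Sites whose loci reciprocally classify as full sites join one cluster
    (connected components, so non-transitive triples merge with a warning).
    A species with a detected member is a full site; otherwise the cluster
    state aggregates the members' mapping calls.
    """
    params = params or MappingParams()
    species_list = list(sites_by_species)
    indexes = {sp: AssemblyIndex(assemblies[sp]) for sp in species_list}
    nodes: list[tuple[str, InsertionSite]] = [
        (sp, site) for sp in species_list for site in sites_by_species[sp]
    ]
    node_ids = {(sp, site.site_id): i for i, (sp, site) in enumerate(nodes)}
    parent = list(range(len(nodes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    calls: dict[tuple[str, str, str], PresenceCall] = {}
    for sp, site in nodes:
        flanked = extract_flanks(site, assemblies[sp], params.flank_window)
        for other in species_list:
            if other == sp:
                continue
            mapping = map_locus(
                flanked,
                assemblies[sp],
                assemblies[other],
                consensus_set,
                params,
                target_index=indexes[other],
                source_index=indexes[sp],
            )
            call = classify_presence(mapping, params)
            calls[(sp, site.site_id, other)] = call
            if call.state != "full_site" or mapping.gap_interval is None:
                continue
            for tsite in sites_by_species[other]:
                if tsite.interval.overlaps(mapping.gap_interval):
                    union(
                        node_ids[(sp, site.site_id)],
                        node_ids[(other, tsite.site_id)],
                    )
                    break

    groups: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    warnings: list[str] = []
    for members in groups.values():
        member_sites = [nodes[i] for i in members]
        by_species: dict[str, str] = {}
        multi = False
        for sp, site in sorted(
            member_sites, key=lambda t: (t[0], t[1].interval.start)
        ):
            if sp in by_species:
                multi = True
                continue
            by_species[sp] = site.site_id
        if multi:
            warnings.append(
                f"cluster with multiple members in one species: {by_species}"
            )
        states: dict[str, str] = {}
        for sp in species_list:
            if sp in by_species:
                states[sp] = "full_site"
                continue
            member_calls = [
                calls[(msp, msite.site_id, sp)].state
                for msp, msite in member_sites
                if (msp, msite.site_id, sp) in calls
            ]
            if member_calls:
                states[sp] = min(member_calls, key=lambda s: _STATE_PRIORITY[s])
            else:
                states[sp] = "ambiguous"
        lead_sp, lead_site = min(
            member_sites, key=lambda t: (t[0], t[1].interval.start)
        )
        clusters.append(
            {
                "cluster_id": lead_site.site_id,
                "members": by_species,
                "states": states,
            }
        )
    clusters.sort(key=lambda c: c["cluster_id"])
    for w in warnings:
        logger.warning(w)
    return MembershipMatrix(species_list, clusters, warnings)


def venn_counts(matrix: MembershipMatrix) -> dict[frozenset, int]:
    """Cluster counts per species subset (full sites only; a partition)."""
    counts: Counter = Counter()
    for cluster in matrix.clusters:
        subset = frozenset(
            sp for sp, state in cluster["states"].items() if state == "full_site"
        )
        if subset:
            counts[subset] += 1
    return dict(counts)


def gene_association(
    site: InsertionSite,
    annotations: list[GeneAnnotation],
    window: int = 500,
) -> list[GeneAssociation]:
    """Genes overlapping or within ``window`` bp of an insertion.

    Overlapping genes resolve to within_CDS > within_exon_UTR > within_intron
    by feature overlap; others are reported as upstream/downstream of the
    element (genome forward orientation) with their distance.
    """
    iv = site.interval
    out: list[GeneAssociation] = []
    for gene in annotations:
        giv = gene.interval
        if giv.chromosome != iv.chromosome:
            continue
        if giv.overlaps(iv):
            if any(f.overlaps(iv) for f in gene.features_of_type("CDS")):
                relation = "within_CDS"
            elif any(f.overlaps(iv) for f in gene.features_of_type("exon")):
                relation = "within_exon_UTR"
            elif any(f.overlaps(iv) for f in gene.features_of_type("intron")):
                relation = "within_intron"
            else:
                relation = "within_exon_UTR"
            out.append(GeneAssociation(site.site_id, gene.gene_id, relation, 0))
        else:
            if giv.end <= iv.start:
                distance = iv.start - giv.end
                relation = "upstream"
            else:
                distance = giv.start - iv.end
                relation = "downstream"
            if distance <= window:
                out.append(
                    GeneAssociation(site.site_id, gene.gene_id, relation, distance)
                )
    out.sort(key=lambda a: (a.distance, a.gene_id))
    return out
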