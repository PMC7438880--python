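"""End-to-end orchestration: scan -> tsd -> compare -> venn -> phylo -> walk.

A single declarative :class:`RunConfig` (YAML-loadable, unknown keys
rejected) drives the full analysis and writes one artifact per stage plus a
human-readable summary whose every number comes from those tables.  All
stages log their record counts, and the run is deterministic under a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .comparative import (
    MappingParams,
    membership_matrix,
    venn_counts,
)
from .core_io import GenomeAssembly, read_fasta, write_fasta
from .phylo import bootstrap_support, progressive_msa, tree_to_newick
from .rearrangement import chromosome_walk
from .synthetic_data import ScenarioConfig, paper_scenario, simulate_species_set
from .te_search import (
    AssemblyIndex,
    InsertionSite,
    ScanParams,
    TEConsensus,
    merge_family_scans,
    scan_genome,
)
from .tsd_flank import detect_tsd, extract_flanks, tsd_logo

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for unusable run configurations."""


@dataclass
class RunConfig:
    genomes: list[str] = field(default_factory=list)
    consensus: str = ""
    gff: str | None = None
    outdir: str = "mitedyn-out"
    seed: int = 42
    min_identity: float = 0.80
    min_coverage: float = 0.30
    tsd_window: int = 10
    tsd_max_len: int = 10
    tsd_max_mismatches: int = 0
    flank_window: int = 1000
    gene_window: int = 500
    bootstrap_replicates: int = 100
    bootstrap_collapse: float | None = 45.0
    walk_preset: str = "desk"
    max_tree_leaves: int = 80

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _tsv_header(fh, columns: list[str], params: dict) -> None:
    param_str = " ".join(f"{k}={v}" for k, v in params.items())
    fh.write(f"# mitedyn {__version__} {param_str}\n")
    fh.write("\t".join(columns) + "\n")


def write_sites_tsv(
    sites_by_species: dict[str, list[InsertionSite]], path, params: dict
) -> None:
    columns = [
        "site_id",
        "species",
        "chromosome",
        "start",
        "end",
        "strand",
        "identity",
        "coverage",
        "length_class",
        "subfamily",
        "score",
    ]
    with open(path, "w") as fh:
        _tsv_header(fh, columns, params)
        for species, sites in sites_by_species.items():
            for s in sites:
                chrom, start, end, strand = s.interval.to_1based()
                fh.write(
                    f"{s.site_id}\t{species}\t{chrom}\t{start}\t{end}\t{strand}\t"
                    f"{s.aligned_identity:.4f}\t{s.consensus_coverage:.4f}\t"
                    f"{s.length_class}\t{s.subfamily}\t{s.score:.1f}\n"
                )


def write_sites_bed(sites_by_species: dict[str, list[InsertionSite]], path) -> None:
    with open(path, "w") as fh:
        for species, sites in sites_by_species.items():
            for s in sites:
                iv = s.interval
                fh.write(
                    f"{iv.chromosome}\t{iv.start}\t{iv.end}\t"
                    f"{s.site_id}\t{int(s.score)}\t{iv.strand}\n"
                )


def write_pfm_tsv(pfm, path, params: dict) -> None:
    with open(path, "w") as fh:
        _tsv_header(fh, ["position", "A", "C", "G", "T", "depth"], params)
        for i, col in enumerate(pfm.columns, start=1):
            depth = pfm.column_depths[i - 1] if pfm.column_depths else pfm.depth
            fh.write(
                f"{i}\t{col['A']:.4f}\t{col['C']:.4f}\t{col['G']:.4f}\t"
                f"{col['T']:.4f}\t{depth}\n"
            )


def read_consensus_fasta(path) -> list[TEConsensus]:
    assembly = read_fasta(path)
    return [TEConsensus(name, seq) for name, seq in assembly.chromosomes.items()]


def _venn_label(subset: frozenset) -> str:
    return "+".join(sorted(subset))


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns a dict of in-memory results.

    Writes sites.tsv, tsd.tsv, pfm.tsv, matrix.tsv, venn.tsv, tree.nwk,
    walk-reports/*.json and summary.md under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    if not config.genomes:
        raise ConfigError("no genome FASTA files configured")
    if not config.consensus:
        raise ConfigError("no consensus FASTA configured")
    assemblies: dict[str, GenomeAssembly] = {}
    for path in config.genomes:
        asm = read_fasta(path)
        assemblies[asm.species_id] = asm
    consensuses = read_consensus_fasta(config.consensus)
    logger.info(
        "loaded %d genomes, %d consensus sequences",
        len(assemblies),
        len(consensuses),
    )

    # stage 1: scan
    scan_params = ScanParams(
        min_identity=config.min_identity, min_coverage=config.min_coverage
    )
    sites_by_species: dict[str, list[InsertionSite]] = {}
    indexes: dict[str, AssemblyIndex] = {}
    for species, asm in assemblies.items():
        indexes[species] = AssemblyIndex(asm)
        per_family = [
            scan_genome(c, asm, scan_params, index=indexes[species])
            for c in consensuses
        ]
        sites_by_species[species] = merge_family_scans(per_family, asm)
        logger.info("scan %s: %d sites", species, len(sites_by_species[species]))
    write_sites_tsv(
        sites_by_species,
        outdir / "sites.tsv",
        {"min_identity": config.min_identity, "min_coverage": config.min_coverage},
    )
    write_sites_bed(sites_by_species, outdir / "sites.bed")

    # stage 2: TSD
    tsd_rows = []
    tsds = []
    for species, sites in sites_by_species.items():
        for site in sites:
            flanked = extract_flanks(site, assemblies[species], config.tsd_window)
            tsd = detect_tsd(
                flanked,
                max_tsd_len=config.tsd_max_len,
                max_mismatches=config.tsd_max_mismatches,
            )
            tsd_rows.append((species, site, tsd))
            if tsd is not None:
                tsds.append(tsd)
    with open(outdir / "tsd.tsv", "w") as fh:
        _tsv_header(
            fh,
            ["site_id", "species", "length_class", "tsd_length", "motif", "mismatches"],
            {
                "window": config.tsd_window,
                "max_mismatches": config.tsd_max_mismatches,
            },
        )
        for species, site, tsd in tsd_rows:
            if tsd is None:
                fh.write(f"{site.site_id}\t{species}\t{site.length_class}\t0\t.\t.\n")
            else:
                fh.write(
                    f"{site.site_id}\t{species}\t{site.length_class}\t"
                    f"{tsd.length}\t{tsd.motif}\t{tsd.mismatches}\n"
                )
    logger.info("tsd: %d/%d sites with a TSD", len(tsds), len(tsd_rows))
    if tsds:
        write_pfm_tsv(
            tsd_logo(tsds), outdir / "pfm.tsv", {"n_motifs": len(tsds)}
        )

    # stage 3: comparative matrix + venn
    mapping_params = MappingParams(flank_window=config.flank_window)
    matrix = membership_matrix(
        sites_by_species, assemblies, consensuses, mapping_params
    )
    logger.info("compare: %d orthologous clusters", len(matrix.clusters))
    species_order = list(assemblies)
    with open(outdir / "matrix.tsv", "w") as fh:
        _tsv_header(
            fh, ["cluster_id"] + species_order, {"flank": config.flank_window}
        )
        for cluster in matrix.clusters:
            fh.write(
                cluster["cluster_id"]
                + "\t"
                + "\t".join(cluster["states"][sp] for sp in species_order)
                + "\n"
            )
    venn = venn_counts(matrix)
    with open(outdir / "venn.tsv", "w") as fh:
        _tsv_header(fh, ["species_subset", "clusters"], {})
        for subset, count in sorted(
            venn.items(), key=lambda kv: (-kv[1], _venn_label(kv[0]))
        ):
            fh.write(f"{_venn_label(subset)}\t{count}\n")
    logger.info("venn: %d regions, %d clusters", len(venn), sum(venn.values()))

    # stage 4: phylogeny over detected element sequences
    tree_newick = ""
    seqs = {
        f"{sp}-{s.site_id}" if not s.site_id.startswith(sp) else s.site_id: s.sequence
        for sp in species_order
        for s in sites_by_species[sp]
        if len(s.sequence) >= 50
    }
    if len(seqs) > config.max_tree_leaves:
        keep = sorted(seqs)[: config.max_tree_leaves]
        seqs = {k: seqs[k] for k in keep}
    if len(seqs) >= 3:
        msa = progressive_msa(seqs)
        tree = bootstrap_support(
            msa,
            replicates=config.bootstrap_replicates,
            seed=config.seed,
            collapse=config.bootstrap_collapse,
        )
        tree_newick = tree_to_newick(tree)
        (outdir / "tree.nwk").write_text(tree_newick + "\n")
        logger.info(
            "phylo: %d leaves, %d bootstrap replicates",
            len(seqs),
            config.bootstrap_replicates,
        )

    # stage 5: chromosome walking for rearranged candidates
    walk_dir = outdir / "walk-reports"
    walk_dir.mkdir(exist_ok=True)
    walk_reports = []
    for cluster in matrix.clusters:
        candidates = [
            sp for sp, st in cluster["states"].items() if st == "rearranged_candidate"
        ]
        if not candidates:
            continue
        lead_sp = sorted(cluster["members"])[0]
        lead_id = cluster["members"][lead_sp]
        site = next(
            s for s in sites_by_species[lead_sp] if s.site_id == lead_id
        )
        for target_sp in candidates:
            report = chromosome_walk(
                site,
                assemblies[lead_sp],
                assemblies[target_sp],
                config.walk_preset,
            )
            walk_reports.append(report)
            payload = {
                "locus_id": report.locus_id,
                "target_species": target_sp,
                "window_used": report.window_used,
                "target_chromosome": report.target_chromosome,
                "state": report.state,
                "note": report.note,
                "events": [dataclasses.asdict(e) for e in report.events],
                "residual_unexplained": report.residual_unexplained,
            }
            with open(walk_dir / f"{report.locus_id}_{target_sp}.json", "w") as fh:
                json.dump(payload, fh, indent=1)
    logger.info("walk: %d reports", len(walk_reports))

    _write_summary(
        outdir, config, sites_by_species, tsd_rows, matrix, venn, walk_reports
    )
    return {
        "sites": sites_by_species,
        "matrix": matrix,
        "venn": venn,
        "tree": tree_newick,
        "walks": walk_reports,
    }


def _write_summary(
    outdir, config, sites_by_species, tsd_rows, matrix, venn, walk_reports
) -> None:
    lines = [
        "# mitedyn run summary",
        "",
        f"tool version: {__version__}; seed: {config.seed}",
        "",
        "## Detected insertions (sites.tsv)",
        "",
        "| species | sites | full | short |",
        "|---|---|---|---|",
    ]
    for sp, sites in sites_by_species.items():
        full = sum(1 for s in sites if s.length_class == "full")
        lines.append(f"| {sp} | {len(sites)} | {full} | {len(sites) - full} |")
    with_tsd = sum(1 for _, _, t in tsd_rows if t is not None)
    lines += [
        "",
        f"## Target site duplications (tsd.tsv): {with_tsd}/{len(tsd_rows)} sites",
        "",
        f"## Orthologous clusters (matrix.tsv): {len(matrix.clusters)}",
        "",
        "## Venn regions (venn.tsv)",
        "",
        "| species subset | clusters |",
        "|---|---|",
    ]
    for subset, count in sorted(
        venn.items(), key=lambda kv: (-kv[1], _venn_label(kv[0]))
    ):
        lines.append(f"| {_venn_label(subset)} | {count} |")
    lines += [
        "",
        f"## Chromosome walks (walk-reports/): {len(walk_reports)} reports",
        "",
    ]
    (Path(outdir) / "summary.md").write_text("\n".join(lines))


def simulate_to_dir(
    outdir: str | Path,
    seed: int = 42,
    preset: str = "paper",
    ancestor_length: int = 500_000,
    config: ScenarioConfig | None = None,
) -> None:
    """Write a simulated species set (FASTA + truth + config echo) to a dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is not None:
        assemblies, truth = simulate_species_set(config)
        consensuses = None
        echo = json.loads(json.dumps(dataclasses.asdict(config), default=str))
    elif preset == "paper":
        assemblies, truth, consensuses = paper_scenario(seed, ancestor_length)
        echo = {
            "preset": "paper",
            "seed": seed,
            "ancestor_length": ancestor_length,
        }
    else:
        raise ConfigError(f"unknown preset {preset!r}")
    for species, asm in assemblies.items():
        write_fasta(asm, outdir / f"{species}.fasta")
    truth.to_json(outdir / "truth.json")
    truth.to_bed(outdir / "truth.bed")
    if consensuses:
        with open(outdir / "consensus.fasta", "w") as fh:
            for c in consensuses:
                fh.write(f">{c.family_name}\n{c.sequence}\n")
    with open(outdir / "scenario.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=False, default_flow_style=None)
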