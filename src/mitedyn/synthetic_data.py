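"""Wheat-like multi-genome simulator with planted elements and ground truth.

The species set mirrors the A/B/D history of wheat: two diploids (TU with the
A sub-genome, AT with D), two AB tetraploids (WE, DW) and the ABD hexaploid
(TA).  The three sub-genome ancestors derive from one root sequence at a
deeper divergence (default 5%) than the within-lineage splits (default 2%),
so homeolog confusion in flank mapping is measurable but the true ortholog
always wins.  The background substitution process has no indels, which keeps
every planted coordinate exact; indels enter only through planted elements
and structural events.

Every planting duplicates ``tsd_len`` host bases around the element (a target
site duplication), and each planted feature is logged in a machine-readable
truth table.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core_io import GenomeAssembly
from .kmer import decode, encode
from .te_search import TEConsensus

logger = logging.getLogger(__name__)

#: TSD motif of the Mariam2-like worked example.
MARIAM2_TSD = "GTTACAAAC"

SPECIES_SUBGENOMES = {
    "TU": ("A",),
    "AT": ("D",),
    "WE": ("A", "B"),
    "DW": ("A", "B"),
    "TA": ("A", "B", "D"),
}

#: lineage label -> leaf species inheriting an insertion planted there
LINEAGE_LEAVES = {
    "A": ("TU", "WE", "DW", "TA"),
    "B": ("WE", "DW", "TA"),
    "D": ("AT", "TA"),
    "AB": ("WE", "DW", "TA"),
    "TU": ("TU",),
    "AT": ("AT",),
    "WE": ("WE",),
    "DW": ("DW",),
    "TA": ("TA",),
}

_LINEAGE_CHROMS = {
    "A": ("A1",),
    "B": ("B1",),
    "D": ("D1",),
    "AB": ("A1", "B1"),
    "TU": ("A1",),
    "AT": ("D1",),
    "WE": ("A1", "B1"),
    "DW": ("A1", "B1"),
    "TA": ("A1", "B1", "D1"),
}

EVENT_TYPES = ("deletion", "insertion", "inversion", "duplication")


@dataclass(frozen=True)
class InsertionPlanEntry:
    """How many copies to plant on one lineage branch."""

    lineage: str
    count: int
    length_class: str = "full"  # full | short | mixed
    tsd_len: int = 9
    subfamily: str = "Mariam1"

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGE_LEAVES:
            raise ValueError(f"unknown lineage {self.lineage!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class EventPlanEntry:
    species: str
    event_type: str
    size: int


@dataclass
class ScenarioConfig:
    """Simulation conditions; the seed is mandatory for reproducibility."""

    seed: int
    ancestor_length: int = 500_000
    gc: float = 0.46
    divergence: float = 0.02
    subgenome_divergence: float = 0.05
    copy_mutation_rate: float = 0.01
    insertion_plan: list[InsertionPlanEntry] = field(default_factory=list)
    event_plan: list[EventPlanEntry] = field(default_factory=list)
    short_length_range: tuple[int, int] = (110, 240)
    min_spacing: int = 3000
    edge_margin: int = 6000

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.25:
            raise ValueError("divergence must be within [0, 0.25]")
        if not 0.0 <= self.subgenome_divergence <= 0.25:
            raise ValueError("subgenome_divergence must be within [0, 0.25]")


@dataclass
class TruthTable:
    """Planted insertions and events with exact emitted coordinates."""

    insertions: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)

    def sharing_counts(self) -> dict[frozenset, int]:
        return dict(
            Counter(frozenset(rec["species"]) for rec in self.insertions)
        )

    def to_json(self, path) -> None:
        payload = {
            "insertions": [
                {**rec, "species": {k: v for k, v in rec["species"].items()}}
                for rec in self.insertions
            ],
            "events": self.events,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_bed(self, path) -> None:
        """BED6 rows, one per species occurrence (1 row per planted copy)."""
        with open(path, "w") as fh:
            for rec in self.insertions:
                for species, occ in rec["species"].items():
                    fh.write(
                        f"{occ['chromosome']}\t{occ['start']}\t{occ['end']}\t"
                        f"{species}|{rec['insertion_id']}\t0\t{rec['strand']}\n"
                    )


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.46) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitution-only mutation: each base changes w.p. ``rate``."""
    out = codes.copy()
    if rate <= 0:
        return out
    mask = rng.random(len(out)) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1].astype(np.uint8)


def mariam_like_consensuses(rng: np.random.Generator) -> tuple[TEConsensus, TEConsensus]:
    """Two subfamily consensuses sharing a 39-bp head and a 50-bp tail.

    The first is 300 bp, the second 291 bp; their interiors are unrelated, so
    the pair reproduces the 'similar ends, different internal part'
    structure that defines the two subfamilies.
    """
    head = random_sequence(rng, 39)
    tail = random_sequence(rng, 50)
    body1 = random_sequence(rng, 300 - 39 - 50)
    body2 = random_sequence(rng, 291 - 39 - 50)
    m1 = decode(np.concatenate([head, body1, tail]))
    m2 = decode(np.concatenate([head, body2, tail]))
    return TEConsensus("Mariam1", m1), TEConsensus("Mariam2", m2)


@dataclass
class _PlannedCopy:
    lineage: str
    chromosome: str
    subfamily: str
    length_class: str
    tsd_len: int
    strand: str
    element: np.ndarray  # codes, already strand-oriented for insertion
    root_pos: int = -1
    insertion_id: str = ""
    tsd_motif: str = ""


@dataclass
class _LineageState:
    chroms: dict[str, np.ndarray]
    registry: list  # list of (root_pos, chromosome, added, copy: _PlannedCopy)

    def descend(self, rate: float, rng: np.random.Generator) -> "_LineageState":
        return _LineageState(
            {name: mutate(seq, rate, rng) for name, seq in self.chroms.items()},
            list(self.registry),
        )

    def translate(self, chromosome: str, root_pos: int) -> int:
        shift = sum(
            added
            for rp, chrom, added, _ in self.registry
            if chrom == chromosome and rp < root_pos
        )
        return root_pos + shift

    def plant(self, copy: _PlannedCopy) -> None:
        seq = self.chroms[copy.chromosome]
        p = self.translate(copy.chromosome, copy.root_pos)
        t = copy.tsd_len
        if p - t < 0 or p > len(seq):
            raise ValueError("insertion position out of range")
        motif = decode(seq[p - t : p]) if t else ""
        self.chroms[copy.chromosome] = np.concatenate(
            [seq[:p], copy.element, seq[p - t : p], seq[p:]]
        )
        self.registry.append(
            (copy.root_pos, copy.chromosome, len(copy.element) + t, copy)
        )
        if not copy.tsd_motif:
            # host sequence at the planting branch, before descendant drift
            copy.tsd_motif = motif


def _expand_plan(
    config: ScenarioConfig,
    consensuses: dict[str, TEConsensus],
    rng: np.random.Generator,
) -> list[_PlannedCopy]:
    copies: list[_PlannedCopy] = []
    for entry in config.insertion_plan:
        if entry.subfamily not in consensuses:
            raise ValueError(f"no consensus for subfamily {entry.subfamily!r}")
        base = encode(consensuses[entry.subfamily].sequence)
        for i in range(entry.count):
            if entry.length_class == "mixed":
                length_class = "short" if rng.random() < 0.3 else "full"
            else:
                length_class = entry.length_class
            elem = base.copy()
            if length_class == "short":
                lo, hi = config.short_length_range
                frag_len = int(rng.integers(lo, hi + 1))
                if rng.random() < 0.5:
                    elem = elem[:frag_len]
                else:
                    elem = elem[-frag_len:]
            elem = mutate(elem, config.copy_mutation_rate, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = elem if strand == "+" else _revcomp_codes(elem)
            chrom = str(rng.choice(_LINEAGE_CHROMS[entry.lineage]))
            copies.append(
                _PlannedCopy(
                    lineage=entry.lineage,
                    chromosome=chrom,
                    subfamily=entry.subfamily,
                    length_class=length_class,
                    tsd_len=entry.tsd_len,
                    strand=strand,
                    element=oriented,
                )
            )
    return copies


def _draw_positions(
    copies: list[_PlannedCopy], config: ScenarioConfig, rng: np.random.Generator
) -> None:
    """Assign root-frame positions, globally spaced per chromosome."""
    by_chrom: dict[str, list[_PlannedCopy]] = {}
    for c in copies:
        by_chrom.setdefault(c.chromosome, []).append(c)
    lo = config.edge_margin
    hi = config.ancestor_length - config.edge_margin
    for chrom, group in by_chrom.items():
        taken: list[int] = []
        for c in group:
            for attempt in range(1000):
                pos = int(rng.integers(lo, hi))
                if all(abs(pos - t) >= config.min_spacing for t in taken):
                    break
                logger.debug("position collision on %s, re-drawing", chrom)
            else:
                raise RuntimeError(f"cannot place insertions on {chrom}")
            taken.append(pos)
            c.root_pos = pos
    serial: dict[str, int] = {}
    for c in sorted(copies, key=lambda c: (c.lineage, c.chromosome, c.root_pos)):
        serial[c.lineage] = serial.get(c.lineage, 0) + 1
        c.insertion_id = f"{c.lineage}-{c.chromosome}-{serial[c.lineage]}"


def simulate_species_set(
    config: ScenarioConfig,
    consensuses: tuple[TEConsensus, TEConsensus] | None = None,
) -> tuple[dict[str, GenomeAssembly], TruthTable]:
    """Simulate the five-species wheat-like set with planted elements.

    Deterministic given ``config.seed``.  Returns the species assemblies and
    the truth table of every planted feature with per-species coordinates.
    """
    rng = np.random.default_rng(config.seed)
    if consensuses is None:
        consensuses = mariam_like_consensuses(rng)
    cons_by_name = {c.family_name: c for c in consensuses}
    copies = _expand_plan(config, cons_by_name, rng)
    _draw_positions(copies, config, rng)
    by_lineage: dict[str, list[_PlannedCopy]] = {}
    for c in copies:
        by_lineage.setdefault(c.lineage, []).append(c)

    def plant_all(state: _LineageState, lineage: str) -> None:
        for c in sorted(
            by_lineage.get(lineage, []), key=lambda c: (c.chromosome, c.root_pos)
        ):
            state.plant(c)

    root = random_sequence(rng, config.ancestor_length, config.gc)
    div, sub_div = config.divergence, config.subgenome_divergence
    anc = {
        g: _LineageState({f"{g}1": mutate(root, sub_div, rng)}, [])
        for g in "ABD"
    }
    for g in "ABD":
        plant_all(anc[g], g)
    tu = anc["A"].descend(div, rng)
    plant_all(tu, "TU")
    ab = _LineageState(
        {
            "A1": mutate(anc["A"].chroms["A1"], div, rng),
            "B1": mutate(anc["B"].chroms["B1"], div, rng),
        },
        list(anc["A"].registry) + list(anc["B"].registry),
    )
    plant_all(ab, "AB")
    we = ab.descend(div, rng)
    plant_all(we, "WE")
    dw = ab.descend(div, rng)
    plant_all(dw, "DW")
    at = anc["D"].descend(div, rng)
    plant_all(at, "AT")
    ta = _LineageState(
        {
            "A1": mutate(ab.chroms["A1"], div, rng),
            "B1": mutate(ab.chroms["B1"], div, rng),
            "D1": mutate(anc["D"].chroms["D1"], div, rng),
        },
        list(ab.registry) + list(anc["D"].registry),
    )
    plant_all(ta, "TA")

    leaves = {"TU": tu, "AT": at, "WE": we, "DW": dw, "TA": ta}
    truth = TruthTable()
    occ_by_copy: dict[int, dict[str, dict]] = {id(c): {} for c in copies}
    for species, state in leaves.items():
        for root_pos, chrom, added, c in state.registry:
            p = state.translate(chrom, root_pos)
            occ_by_copy[id(c)][species] = {
                "chromosome": chrom,
                "start": int(p),
                "end": int(p + len(c.element)),
            }
    for c in copies:
        truth.insertions.append(
            {
                "insertion_id": c.insertion_id,
                "lineage": c.lineage,
                "subfamily": c.subfamily,
                "length_class": c.length_class,
                "element_length": int(len(c.element)),
                "tsd_len": int(c.tsd_len),
                "tsd_motif": c.tsd_motif,
                "strand": c.strand,
                "species": occ_by_copy[id(c)],
            }
        )

    assemblies = {
        species: GenomeAssembly(
            species,
            {name: decode(seq) for name, seq in sorted(state.chroms.items())},
            {name: name[0] for name in state.chroms},
        )
        for species, state in leaves.items()
    }
    for i, entry in enumerate(config.event_plan):
        assemblies[entry.species], row = plant_event(
            assemblies[entry.species],
            entry.event_type,
            entry.size,
            seed=int(rng.integers(0, 2**31 - 1)),
            avoid=[
                (occ["chromosome"], occ["start"], occ["end"])
                for rec in truth.insertions
                for sp, occ in rec["species"].items()
                if sp == entry.species
            ],
        )
        _shift_truth(truth, entry.species, row)
        truth.events.append(row)
    return assemblies, truth


def _shift_truth(truth: TruthTable, species: str, event: dict) -> None:
    """Adjust per-species insertion coordinates for a planted event."""
    etype = event["event_type"]
    chrom = event["chromosome"]
    for rec in truth.insertions:
        occ = rec["species"].get(species)
        if occ is None or occ["chromosome"] != chrom:
            continue
        if etype == "deletion" and occ["start"] >= event["end"]:
            occ["start"] -= event["size"]
            occ["end"] -= event["size"]
        elif etype == "insertion" and occ["start"] >= event["start"]:
            occ["start"] += event["size"]
            occ["end"] += event["size"]
        elif etype == "duplication" and occ["start"] >= event["target_start"]:
            occ["start"] += event["size"]
            occ["end"] += event["size"]
        # inversions avoid planted spans, so in-place flips never hit them


def plant_event(
    assembly: GenomeAssembly,
    event_type: str,
    size: int,
    seed: int,
    chromosome: str | None = None,
    avoid: list[tuple[str, int, int]] | None = None,
) -> tuple[GenomeAssembly, dict]:
    """Plant one structural event, returning the new assembly and truth row.

    Deletion removes a span; insertion splices random sequence; inversion
    reverse-complements a span in place; duplication copies a span to a
    distant position.  Spans overlapping ``avoid`` intervals (or a previous
    draw) are rejected and re-drawn.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    rng = np.random.default_rng(seed)
    chrom = chromosome or sorted(assembly.chromosomes)[0]
    seq = assembly.chromosomes[chrom]
    if size >= len(seq) // 4:
        raise ValueError("event size must be below a quarter of the chromosome")
    margin = max(2000, size // 2)
    avoid = [(c, s, e) for c, s, e in (avoid or []) if c == chrom]

    def clashes(a: int, b: int) -> bool:
        return any(a < e + 500 and s - 500 < b for _, s, e in avoid)

    for _ in range(1000):
        start = int(rng.integers(margin, len(seq) - margin - size))
        if not clashes(start, start + size):
            break
    else:
        raise RuntimeError("could not place event")
    end = start + size
    row = {
        "species": assembly.species_id,
        "event_type": event_type,
        "chromosome": chrom,
        "start": start,
        "end": end,
        "size": size,
    }
    if event_type == "deletion":
        new_seq = seq[:start] + seq[end:]
    elif event_type == "insertion":
        novel = decode(random_sequence(rng, size))
        new_seq = seq[:start] + novel + seq[start:]
        row["end"] = start + size
    elif event_type == "inversion":
        from .core_io import revcomp

        new_seq = seq[:start] + revcomp(seq[start:end]) + seq[end:]
    else:  # duplication
        for _ in range(1000):
            target = int(rng.integers(margin, len(seq) - margin))
            if abs(target - start) > size + 2 * margin and not clashes(
                target, target
            ):
                break
        else:
            raise RuntimeError("could not place duplication copy")
        new_seq = seq[:target] + seq[start:end] + seq[target:]
        row["target_start"] = target
        row["target_end"] = target + size
    new_chroms = dict(assembly.chromosomes)
    new_chroms[chrom] = new_seq
    return (
        GenomeAssembly(assembly.species_id, new_chroms, dict(assembly.subgenome_of)),
        row,
    )


#: the printed five-species sharing structure, at desk scale
PAPER_SHARING_PLAN = [
    InsertionPlanEntry("A", 2, "full", 9, "Mariam1"),  # ancient, A lineage
    InsertionPlanEntry("D", 6, "mixed", 9, "Mariam2"),
    InsertionPlanEntry("AB", 10, "mixed", 9, "Mariam1"),
    InsertionPlanEntry("WE", 15, "mixed", 9, "Mariam1"),
    InsertionPlanEntry("DW", 6, "mixed", 9, "Mariam2"),
    InsertionPlanEntry("TA", 6, "mixed", 9, "Mariam1"),
    InsertionPlanEntry("AT", 1, "full", 9, "Mariam2"),
    InsertionPlanEntry("TU", 2, "mixed", 9, "Mariam1"),
]


def paper_scenario(
    seed: int = 42, ancestor_length: int = 500_000
) -> tuple[dict[str, GenomeAssembly], TruthTable, tuple[TEConsensus, TEConsensus]]:
    """The five-genome preset implementing the printed sharing structure.

    2 ancient A-lineage insertions (TU+WE+DW+TA), 6 on the D lineage (AT+TA),
    10 on the AB lineage (WE+DW+TA), 15 WE-unique, 6 DW-unique, 6 TA-unique,
    1 AT-unique, 2 TU-unique.
    """
    config = ScenarioConfig(
        seed=seed,
        ancestor_length=ancestor_length,
        insertion_plan=list(PAPER_SHARING_PLAN),
    )
    # sub-stream seeding keeps the fixture pair independent of the genome draws
    consensuses = mariam_like_consensuses(np.random.default_rng([seed, 1]))
    assemblies, truth = simulate_species_set(config, consensuses)
    return assemblies, truth, consensuses


def expected_sharing_counts(
    plan: list[InsertionPlanEntry] | None = None,
) -> dict[frozenset, int]:
    """Sharing pattern -> planted cluster count implied by a plan."""
    counts: Counter = Counter()
    for entry in plan or PAPER_SHARING_PLAN:
        counts[frozenset(LINEAGE_LEAVES[entry.lineage])] += entry.count
    return dict(counts)
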