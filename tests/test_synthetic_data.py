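"""Simulator determinism, truth-table consistency, and planted events."""

import numpy as np
import pytest

from mitedyn.core_io import revcomp
from mitedyn.kmer import decode, encode
from mitedyn.synthetic_data import (
    EVENT_TYPES,
    InsertionPlanEntry,
    ScenarioConfig,
    expected_sharing_counts,
    mariam_like_consensuses,
    mutate,
    paper_scenario,
    plant_event,
    random_sequence,
    simulate_species_set,
)
from mitedyn.tsd_flank import FlankedLocus, detect_tsd
from mitedyn.te_search import InsertionSite
from mitedyn.core_io import GenomicInterval


def _flat_plan():
    return [
        InsertionPlanEntry("A", 1, "full", 9, "Mariam1"),
        InsertionPlanEntry("D", 1, "full", 9, "Mariam2"),
        InsertionPlanEntry("WE", 2, "mixed", 9, "Mariam1"),
    ]


def _config(seed=3, divergence=0.02, **kw):
    return ScenarioConfig(
        seed=seed,
        ancestor_length=50_000,
        divergence=divergence,
        insertion_plan=_flat_plan(),
        min_spacing=2500,
        **kw,
    )


class TestSimulator:
    def test_identical_seeds_give_identical_outputs(self):
        a1, t1 = simulate_species_set(_config())
        a2, t2 = simulate_species_set(_config())
        for sp in a1:
            assert a1[sp].chromosomes == a2[sp].chromosomes
        assert t1.insertions == t2.insertions

    def test_species_carry_their_subgenomes(self):
        assemblies, _ = simulate_species_set(_config())
        assert set(assemblies) == {"TU", "AT", "WE", "DW", "TA"}
        assert set(assemblies["TU"].chromosomes) == {"A1"}
        assert set(assemblies["AT"].chromosomes) == {"D1"}
        assert set(assemblies["WE"].chromosomes) == {"A1", "B1"}
        assert set(assemblies["TA"].chromosomes) == {"A1", "B1", "D1"}

    def test_zero_insertion_config_matches_configured_divergence(self):
        config = ScenarioConfig(
            seed=5, ancestor_length=50_000, divergence=0.02, insertion_plan=[]
        )
        assemblies, _ = simulate_species_set(config)
        we = encode(assemblies["WE"].chromosomes["A1"])
        dw = encode(assemblies["DW"].chromosomes["A1"])
        observed = float(np.mean(we != dw))
        # two independent 2% branches from the WE/DW ancestor
        expected = 2 * 0.02 * (1 - 0.02 * 4 / 6)
        assert observed == pytest.approx(expected, rel=0.10)

    def test_lineage_planting_is_inherited_by_descendants(self):
        _, truth = simulate_species_set(_config())
        by_lineage = {r["lineage"]: r for r in truth.insertions}
        assert set(by_lineage["A"]["species"]) == {"TU", "WE", "DW", "TA"}
        assert set(by_lineage["D"]["species"]) == {"AT", "TA"}
        for rec in truth.insertions:
            if rec["lineage"] == "WE":
                assert set(rec["species"]) == {"WE"}

    def test_truth_intervals_reproduce_planted_elements(self):
        """Extracting each truth interval from the emitted FASTA gives the
        element (as drifted by descendant substitutions only, here ~2%)."""
        config = _config()
        consensuses = mariam_like_consensuses(np.random.default_rng(7))
        assemblies, truth = simulate_species_set(config, consensuses)
        cons = {c.family_name: c.sequence for c in consensuses}
        for rec in truth.insertions:
            for sp, occ in rec["species"].items():
                seq = assemblies[sp].chromosomes[occ["chromosome"]][
                    occ["start"] : occ["end"]
                ]
                assert len(seq) == rec["element_length"]
                oriented = revcomp(seq) if rec["strand"] == "-" else seq
                ref = cons[rec["subfamily"]]
                if rec["length_class"] == "full":
                    diffs = sum(1 for a, b in zip(oriented, ref) if a != b)
                    assert diffs / len(ref) < 0.15

    def test_planted_junctions_show_the_tsd_without_divergence(self):
        """At zero post-planting divergence every junction shows exactly the
        planted duplication (up to chance extension by the background)."""
        config = ScenarioConfig(
            seed=9,
            ancestor_length=50_000,
            divergence=0.0,
            subgenome_divergence=0.0,
            copy_mutation_rate=0.0,
            insertion_plan=_flat_plan(),
            min_spacing=2500,
        )
        assemblies, truth = simulate_species_set(config)
        for rec in truth.insertions:
            for sp, occ in rec["species"].items():
                chrom = assemblies[sp].chromosomes[occ["chromosome"]]
                site = InsertionSite(
                    "x", sp,
                    GenomicInterval(occ["chromosome"], occ["start"], occ["end"]),
                    1.0, 1.0, rec["length_class"], rec["subfamily"], 1.0, "",
                )
                left = chrom[occ["start"] - 12 : occ["start"]]
                right = chrom[occ["end"] : occ["end"] + 12]
                tsd = detect_tsd(FlankedLocus(site, 12, left, right), max_tsd_len=12)
                assert tsd is not None
                assert tsd.length >= rec["tsd_len"]
                assert tsd.motif.endswith(rec["tsd_motif"]) or tsd.motif == rec["tsd_motif"]

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(seed=1, divergence=0.5)


class TestPaperScenario:
    def test_sharing_plan_matches_printed_structure(self):
        expected = expected_sharing_counts()
        assert expected[frozenset({"WE"})] == 15
        assert expected[frozenset({"AT", "TA"})] == 6
        assert expected[frozenset({"WE", "DW", "TA"})] == 10
        assert expected[frozenset({"TU", "WE", "DW", "TA"})] == 2
        assert sum(expected.values()) == 48

    def test_truth_counts_equal_plan_and_run_is_deterministic(self):
        a1, t1, c1 = paper_scenario(seed=42, ancestor_length=150_000)
        a2, t2, c2 = paper_scenario(seed=42, ancestor_length=150_000)
        assert t1.sharing_counts() == expected_sharing_counts()
        for sp in a1:
            assert a1[sp].chromosomes == a2[sp].chromosomes
        assert [c.sequence for c in c1] == [c.sequence for c in c2]

    def test_consensus_fixture_pair_shares_head_and_tail(self):
        _, _, (m1, m2) = paper_scenario(seed=1, ancestor_length=150_000)
        assert (m1.length, m2.length) == (300, 291)
        assert m1.sequence[:39] == m2.sequence[:39]
        assert m1.sequence[-50:] == m2.sequence[-50:]
        interior_matches = sum(
            a == b for a, b in zip(m1.sequence[39:-50], m2.sequence[39:-50])
        )
        assert interior_matches / 202 < 0.5


class TestPlantEvent:
    @pytest.fixture
    def assembly(self, small_genome):
        return small_genome

    def test_deletion_shortens_by_exact_size(self, assembly):
        new, row = plant_event(assembly, "deletion", 2000, seed=1)
        assert len(new.chromosomes["A1"]) == len(assembly.chromosomes["A1"]) - 2000
        assert row["size"] == 2000

    def test_insertion_lengthens_by_exact_size(self, assembly):
        new, row = plant_event(assembly, "insertion", 1500, seed=2)
        assert len(new.chromosomes["A1"]) == len(assembly.chromosomes["A1"]) + 1500

    def test_inversion_is_in_place_reverse_complement(self, assembly):
        new, row = plant_event(assembly, "inversion", 3000, seed=3)
        old = assembly.chromosomes["A1"]
        got = new.chromosomes["A1"]
        s, e = row["start"], row["end"]
        assert got[s:e] == revcomp(old[s:e])
        assert got[:s] == old[:s] and got[e:] == old[e:]

    def test_duplication_creates_two_identical_spans(self, assembly):
        new, row = plant_event(assembly, "duplication", 1000, seed=4)
        got = new.chromosomes["A1"]
        copy = got[row["target_start"] : row["target_end"]]
        src_start = row["start"] + (
            row["size"] if row["target_start"] <= row["start"] else 0
        )
        assert copy == got[src_start : src_start + row["size"]]

    def test_oversized_event_rejected(self, assembly):
        with pytest.raises(ValueError):
            plant_event(assembly, "deletion", 90_000, seed=5)

    def test_unknown_event_type_rejected(self, assembly):
        with pytest.raises(ValueError):
            plant_event(assembly, "translocation", 100, seed=6)

    def test_event_plan_is_applied_and_logged(self):
        from mitedyn.synthetic_data import EventPlanEntry

        config = _config(event_plan=[EventPlanEntry("WE", "deletion", 2000)])
        assemblies, truth = simulate_species_set(config)
        assert len(truth.events) == 1
        ev = truth.events[0]
        assert ev["species"] == "WE" and ev["event_type"] == "deletion"
        # truth coordinates remain valid after the event shift
        for rec in truth.insertions:
            occ = rec["species"].get("WE")
            if occ is None:
                continue
            seq = assemblies["WE"].chromosomes[occ["chromosome"]]
            assert occ["end"] <= len(seq)
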