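"""Probe design: tiling geometry, filters, set construction and merging."""
import numpy as np
import pytest

import uceforge as uf
from uceforge.bait_design import (DesignParams, ProbeRecord, ProbeSet,
                                  build_master_set, build_temporary_set,
                                  design_probes_for_locus, merge_probe_sets,
                                  read_probe_set, select_final_loci,
                                  subset_by_taxa, write_probe_set)
from uceforge.seqcore import AssemblyRecord, Contig, LocusInterval, revcomp
from uceforge.synth_genomes import evolve_sequence

from conftest import random_seq


def _design(seq, mask=None, **kw):
    mask = np.zeros(len(seq), dtype=bool) if mask is None else mask
    return design_probes_for_locus(seq, mask, "L1", "t1",
                                   DesignParams(**kw))


class TestProbeGeometry:
    def test_two_probes_overlap_midpoint(self, rng):
        probes = _design(random_seq(rng, 400))
        assert len(probes) == 2
        starts = [p.offset for p in probes]
        assert starts[1] - starts[0] == 40  # probe_length / tiling_density
        for s in starts:
            assert s <= 200 < s + 120  # both contain the midpoint

    def test_locus_of_exact_probe_length_collapses_to_one(self, rng):
        probes = _design(random_seq(rng, 120))
        assert len(probes) == 1 and probes[0].offset == 0

    def test_locus_shorter_than_probe_yields_nothing(self, rng):
        assert _design(random_seq(rng, 100)) == []

    def test_repeat_boundary_is_strict(self, rng):
        """26% masked positions drop a probe; exactly 25% is retained."""
        seq = random_seq(rng, 120)
        mask26 = np.zeros(120, dtype=bool)
        mask26[:31] = True          # 31/120 = 25.8%
        assert _design(seq, mask26) == []
        mask25 = np.zeros(120, dtype=bool)
        mask25[:30] = True          # exactly 25%
        assert len(_design(seq, mask25)) == 1

    def test_gc_window_enforced(self):
        low = "AT" * 60            # GC 0
        assert _design(low) == []
        balanced = "ATGC" * 30     # GC 0.5
        assert len(_design(balanced)) == 1


class TestTemporarySet:
    def test_two_probes_per_clean_locus_before_dedupe(self, rng):
        seq = "".join(random_seq(rng, 400) for _ in range(10))
        contig = Contig("c1", seq, np.zeros(len(seq), dtype=bool))
        ref = AssemblyRecord("ref", "genome", [contig])
        loci = [LocusInterval(f"u{i}", "c1", i * 400, (i + 1) * 400)
                for i in range(10)]
        ps = build_temporary_set(loci, ref, DesignParams())
        assert ps.stats["probes_designed"] == 20
        assert len(ps) == 20       # distinct random loci survive dedupe

    def test_duplicate_loci_collapse_under_dedupe(self, rng):
        block = random_seq(rng, 400)
        seq = block + random_seq(rng, 200) + block
        ref = AssemblyRecord("ref", "genome", [
            Contig("c1", seq, np.zeros(len(seq), dtype=bool))])
        loci = [LocusInterval("u1", "c1", 0, 400),
                LocusInterval("u2", "c1", 600, 1000)]
        ps = build_temporary_set(loci, ref, DesignParams())
        assert ps.stats["probes_designed"] == 4
        # the two identical loci cross-link (same-offset copies are identical
        # and staggered copies still overlap 80/120 bp), so the whole family
        # collapses to a single representative
        assert len(ps) == 1

    def test_every_retained_probe_passes_filters(self, small_design):
        for ps in (small_design["temp"], small_design["master"]):
            for p in ps:
                assert 0.30 <= p.gc <= 0.70
                assert p.repeat_frac <= 0.25
                assert len(p.sequence) == 120


class TestSelectFinalLoci:
    def test_all_planted_loci_present_in_all_taxa_retained(self, small_design,
                                                           small_loci):
        assert len(small_design["final"]) == len(small_loci)

    def test_threshold_sweep_monotone(self, small_design, small_loci,
                                      small_panel):
        assemblies, _ = small_panel
        sizes = []
        for threshold in (1, 2, 4, 6):
            params = DesignParams(min_species_for_final=threshold)
            final = select_final_loci(small_design["temp"], small_loci,
                                      list(assemblies.values()), params,
                                      presence=small_design["presence"])
            sizes.append(len(final))
        assert sizes == sorted(sizes, reverse=True)

    def test_sparse_locus_dropped(self, small_design, small_loci, small_panel):
        """With the threshold above the panel size nothing survives."""
        assemblies, _ = small_panel
        params = DesignParams(min_species_for_final=len(assemblies) + 1)
        final = select_final_loci(small_design["temp"], small_loci,
                                  list(assemblies.values()), params,
                                  presence=small_design["presence"])
        assert final == []


class TestMasterSet:
    def test_single_assembly_degenerate_equals_temp_sequences(
            self, small_panel, small_loci):
        assemblies, truth = small_panel
        ref = assemblies["taxon_01"]
        params = DesignParams(min_species_for_final=1)
        temp = build_temporary_set(small_loci, ref, params,
                                   priority=truth.taxa)
        master = build_master_set(small_loci, ref, [ref], params,
                                  priority=truth.taxa)
        assert sorted(p.sequence for p in master) == \
            sorted(p.sequence for p in temp)

    def test_clone_taxa_collapse_per_locus(self, rng):
        """Zero-divergence duplicate taxa contribute nothing new."""
        seq = "".join(random_seq(rng, 500) for _ in range(4))
        mask = np.zeros(len(seq), dtype=bool)
        ref = AssemblyRecord("a", "genome", [Contig("c1", seq, mask)])
        clone = AssemblyRecord("b", "genome", [Contig("c1", seq, mask.copy())])
        loci = [LocusInterval(f"u{i}", "c1", i * 500, (i + 1) * 500)
                for i in range(4)]
        params = DesignParams(min_species_for_final=1)
        master = build_master_set(loci, ref, [ref, clone], params,
                                  priority=["a", "b"])
        assert master.stats["probes_designed"] == 16
        # the staggered clone probes chain into one component per locus
        assert len(master) == 4
        assert all(p.source_taxon == "a" for p in master)

    def test_offset_divergent_copies_keep_multiple_representatives(self, rng):
        """When another taxon's locus copy only aligns over its back half,
        its probes sit beyond 50% coverage from the reference probes and
        survive the master self-screen."""
        core = random_seq(rng, 480)
        ref_seq = random_seq(rng, 300) + core + random_seq(rng, 300)
        # second taxon: front half replaced -> only back 240 bp still present
        other_core = random_seq(rng, 240) + core[240:]
        other_seq = random_seq(rng, 300) + other_core + random_seq(rng, 300)
        ref = AssemblyRecord("a", "genome", [
            Contig("c1", ref_seq, np.zeros(len(ref_seq), dtype=bool))])
        other = AssemblyRecord("b", "genome", [
            Contig("c1", other_seq, np.zeros(len(other_seq), dtype=bool))])
        loci = [LocusInterval("u1", "c1", 300, 780)]
        params = DesignParams(min_species_for_final=1, master_coverage=0.4)
        master = build_master_set(loci, ref, [ref, other], params,
                                  priority=["a", "b"])
        assert set(p.source_taxon for p in master) == {"a", "b"}


class TestSubsetAndMerge:
    def test_subset_by_all_taxa_is_identity(self, small_design):
        master = small_design["master"]
        sub = subset_by_taxa(master, master.source_taxa)
        assert [p.probe_id for p in sub] == [p.probe_id for p in master]

    def test_subset_by_one_taxon(self, small_design):
        master = small_design["master"]
        taxon = master.source_taxa[0]
        sub = subset_by_taxa(master, [taxon])
        assert all(p.source_taxon == taxon for p in sub)
        assert set(sub.target_locus_ids) <= set(master.target_locus_ids)

    def test_unknown_taxon_error_lists_valid_names(self, small_design):
        with pytest.raises(ValueError, match="valid"):
            subset_by_taxa(small_design["master"], ["nope"])

    def test_self_merge_is_identity(self, small_design):
        master = small_design["master"]
        merged = merge_probe_sets(master, master)
        # identical sets collide -> ids are prefixed; sequence content equal
        assert sorted(p.sequence for p in merged) == \
            sorted(p.sequence for p in master)

    def test_disjoint_dissimilar_sets_concatenate(self, rng):
        a = ProbeSet([ProbeRecord(f"a{i}", f"la{i}", "t1", 0,
                                  random_seq(rng, 120), 0.5, 0.0)
                      for i in range(5)])
        b = ProbeSet([ProbeRecord(f"b{i}", f"lb{i}", "t2", 0,
                                  random_seq(rng, 120), 0.5, 0.0)
                      for i in range(5)])
        merged = merge_probe_sets(a, b)
        assert len(merged) == 10

    def test_cross_set_duplicates_reduce_size(self, rng):
        """Shared loci between two sets shrink the merged set below |A|+|B|,
        and the A copy wins."""
        shared = [random_seq(rng, 120) for _ in range(4)]
        a = ProbeSet([ProbeRecord(f"a{i}", f"la{i}", "t1", 0, s, 0.5, 0.0)
                      for i, s in enumerate(shared)])
        b_probes = [ProbeRecord(f"b{i}", f"lb{i}", "t2", 0,
                                evolve_sequence(s, 0.03, i), 0.5, 0.0)
                    for i, s in enumerate(shared)]
        b_probes.append(ProbeRecord("b9", "lb9", "t2", 0,
                                    random_seq(rng, 120), 0.5, 0.0))
        b = ProbeSet(b_probes)
        merged = merge_probe_sets(a, b)
        assert len(merged) == 5    # 4 shared collapse + 1 unique
        assert {p.probe_id[:1] for p in merged
                if p.locus_id.endswith(("la0", "la1", "la2", "la3"))} <= {"a", "A"}


class TestProbeSetIO:
    def test_fasta_manifest_round_trip(self, small_design, tmp_path):
        master = small_design["master"]
        fasta, manifest = tmp_path / "p.fasta", tmp_path / "p.tsv"
        write_probe_set(master, fasta, manifest)
        back = read_probe_set(fasta, manifest)
        assert sorted(p.probe_id for p in back) == \
            sorted(p.probe_id for p in master)
        by_id = {p.probe_id: p for p in master}
        for p in back:
            src = by_id[p.probe_id]
            assert p.sequence == src.sequence
            assert p.locus_id == src.locus_id
            assert p.source_taxon == src.source_taxon
            assert p.offset == src.offset
            assert p.repeat_frac == pytest.approx(src.repeat_frac)
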