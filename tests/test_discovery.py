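"""Seed-and-extend search: indexing, recall, classification, screens."""

import numpy as np
import pytest

from hml9map import discovery, synthetic
from hml9map.io_formats import GenomeAssembly, load_catalog
from hml9map.synthetic import random_sequence, reverse_complement

from conftest import reciprocal_overlap


class TestBuildIndex:
    def test_indexed_position_count(self):
        genome = GenomeAssembly(
            {"c1": random_sequence(51, np.random.default_rng(1))}
        )
        index = discovery.build_index(genome, k=11, step=5)
        assert len(index) == 9  # floor((51-11)/5) + 1

    def test_all_n_chromosome_gives_empty_index(self):
        genome = GenomeAssembly({"c1": "N" * 100})
        assert len(discovery.build_index(genome)) == 0

    def test_planted_copy_kmers_all_indexed(self, reference):
        # brute-force k-mer oracle: every stride-5 window of the planted
        # copy must be retrievable from the index
        rng = np.random.default_rng(2)
        background = random_sequence(30_000, rng)
        pos = 10_000
        seq = (
            background[: pos - 1]
            + reference.sequence
            + background[pos - 1 + len(reference) :]
        )
        genome = GenomeAssembly({"c1": seq})
        index = discovery.build_index(genome)
        k, step = index.k, index.step
        start0 = pos - 1
        # genome stride positions that fall inside the planted copy
        first = ((start0 + step - 1) // step) * step
        for g0 in range(first, start0 + len(reference) - k + 1, step):
            word = seq[g0 : g0 + k]
            assert ("c1", g0 + 1) in index.lookup(word)

    def test_parameter_validation(self):
        genome = GenomeAssembly({"c1": "ACGT" * 10})
        with pytest.raises(ValueError):
            discovery.build_index(genome, k=5)
        with pytest.raises(ValueError):
            discovery.build_index(genome, step=0)


class TestSearch:
    def test_exact_copy_found_with_full_coverage(self, reference):
        rng = np.random.default_rng(3)
        seq = (
            random_sequence(5000, rng)
            + reference.sequence
            + random_sequence(5000, rng)
        )
        genome = GenomeAssembly({"c1": seq})
        index = discovery.build_index(genome)
        chains = discovery.search(reference, index, genome)
        best = max(chains, key=lambda c: c.matches)
        assert best.mismatches == 0
        covered = len(best.aligned_ref_positions)
        assert covered >= 0.99 * len(reference)

    def test_diverged_copy_recovered(self, reference, planted):
        ref, genome, _, truth = planted
        index = discovery.build_index(genome)
        chains = discovery.search(ref, index, genome)
        loci = discovery.merge_chains_to_loci(chains, ref)
        for rec in truth:
            hits = [
                l
                for l in loci
                if l.chrom == rec.chrom
                and reciprocal_overlap((l.start, l.end), (rec.start, rec.end))
                >= 0.9
            ]
            assert len(hits) == 1

    def test_no_long_chains_in_random_genomes(self, reference):
        # empirical false-positive check over 5 seeds
        for seed in range(5):
            rng = np.random.default_rng(seed)
            genome = GenomeAssembly({"c1": random_sequence(200_000, rng)})
            index = discovery.build_index(genome)
            chains = discovery.search(
                reference, index, genome, min_chain_matches=0
            )
            assert max((c.matches for c in chains), default=0) < 100

    def test_strand_symmetry(self, reference):
        rng = np.random.default_rng(8)
        spec = synthetic.PlantSpec(
            "full_provirus", "c1", "+", insert_pos=3000, true_age_my=10.0
        )
        genome0 = GenomeAssembly({"c1": random_sequence(20_000, rng)})
        genome, rec = synthetic.plant_element(
            genome0, reference, spec, seed=rng
        )
        mirrored = GenomeAssembly(
            {"c1": reverse_complement(genome.chromosomes["c1"])}
        )
        loci_fwd = discovery.merge_chains_to_loci(
            discovery.search(
                reference, discovery.build_index(genome), genome
            ),
            reference,
        )
        loci_rev = discovery.merge_chains_to_loci(
            discovery.search(
                reference, discovery.build_index(mirrored), mirrored
            ),
            reference,
        )
        assert len(loci_fwd) == len(loci_rev) == 1
        n = 20_000
        f, r = loci_fwd[0], loci_rev[0]
        assert (r.start, r.end) == (n - f.end + 1, n - f.start + 1)
        assert {f.strand, r.strand} == {"+", "-"}


class TestLociAndClassification:
    def test_classes_match_planted_kinds(self, planted, planted_loci):
        _, _, _, truth = planted
        for rec in truth:
            hits = [
                l
                for l in planted_loci
                if l.chrom == rec.chrom
                and reciprocal_overlap((l.start, l.end), (rec.start, rec.end))
                >= 0.9
            ]
            expected = (
                "solo_LTR" if rec.kind == "solo_LTR" else "provirus"
            )
            assert hits[0].element_class == expected
            assert hits[0].strand == rec.strand

    def test_exact_plant_coverage_near_100(self, planted_loci):
        for locus in planted_loci:
            assert locus.coverage_pct <= 100.5

    def test_deletion_reflected_in_qgap(self, planted, planted_loci):
        # plant3 carries a 1325 bp pol deletion: qgap = 1325/(aligned+1325)
        _, _, _, truth = planted
        rec = [r for r in truth if r.kind == "deleted_provirus"][0]
        locus = [
            l
            for l in planted_loci
            if l.chrom == rec.chrom and l.start == rec.start
        ][0]
        expected = 100.0 * 1325 / (7283 + 1325)
        assert locus.qgap_pct == pytest.approx(expected, abs=1.0)

    def test_opposite_strand_chains_stay_separate(self, reference):
        chain_plus = discovery.AlignmentChain(
            "c1", "+", [(1000, 1500, 1, 501)], 480, 21
        )
        chain_minus = discovery.AlignmentChain(
            "c1", "-", [(1100, 1600, 1, 501)], 480, 21
        )
        loci = discovery.merge_chains_to_loci(
            [chain_plus, chain_minus], reference
        )
        assert len(loci) == 2
        assert {l.strand for l in loci} == {"+", "-"}

    def test_internal_only_fragment_is_provirus(self, reference):
        chain = discovery.AlignmentChain(
            "c1", "+", [(100, 1600, 3500, 5000)], 1400, 101
        )
        assert discovery.classify_locus([chain], reference) == "provirus"

    def test_ltr_only_locus_is_solo(self, reference):
        chain = discovery.AlignmentChain(
            "c1", "+", [(100, 686, 1, 587)], 560, 27
        )
        assert discovery.classify_locus([chain], reference) == "solo_LTR"


class TestNaming:
    def test_band_name_from_midpoint(self, tmp_path):
        from hml9map.io_formats import read_cytobands

        bed = tmp_path / "bands.bed"
        bed.write_text("chr16\t0\t20000000\tp12.3\n")
        bands = read_cytobands(bed)
        locus = discovery.ElementLocus(
            "id1", "chr16", "-", 19393581, 19402152, "provirus", 96.0, 1.0
        )
        assert discovery.name_locus(locus, bands) == "16p12.3"

    def test_fallback_name_without_bands(self):
        locus = discovery.ElementLocus(
            "id1", "chr2", "+", 82022660, 82031279, "provirus", 95.9, 1.1
        )
        assert discovery.name_locus(locus, None) == "chr2:82022660-82031279"

    def test_two_loci_may_share_a_band(self, tmp_path):
        from hml9map.io_formats import read_cytobands

        bed = tmp_path / "bands.bed"
        bed.write_text("chrY\t0\t11000000\tp11.2\n")
        bands = read_cytobands(bed)
        l1 = discovery.ElementLocus(
            "a", "chrY", "-", 9273707, 9279611, "provirus", 60.0, 39.0
        )
        l2 = discovery.ElementLocus(
            "b", "chrY", "-", 8121821, 8126768, "provirus", 55.0, 45.0
        )
        assert discovery.name_locus(l1, bands) == discovery.name_locus(l2, bands)


class TestScreens:
    def test_length_strata_match_catalog(self):
        prov = load_catalog()["proviruses"]
        assert discovery.stratify_lengths(prov.coverage_pct) == (6, 9, 8)

    def test_strata_edge_cases(self):
        assert discovery.stratify_lengths([]) == (0, 0, 0)
        assert discovery.stratify_lengths([100.0] * 4) == (4, 0, 0)
        assert discovery.stratify_lengths([70.0, 40.0, 39.99]) == (0, 2, 1)

    def test_solo_screen_matches_catalog(self):
        tables = load_catalog()
        solo_pcts = dict(
            zip(tables["solo_ltrs"].index, tables["solo_ltrs"].ltr_pct)
        )
        # cytoband names repeat (e.g. three Yp11.2 proviruses): key by row
        prov_pcts = dict(
            zip(tables["proviruses"].number, tables["proviruses"].coverage_pct)
        )
        integ = {
            rec.number: {r: getattr(rec, r) for r in ("gag", "pro", "pol", "env")}
            for rec in tables["integrity"].itertuples()
        }
        res = discovery.screen_for_analysis(solo_pcts, prov_pcts, integ)
        assert len(res.solo_ltrs) == 44
        assert len(res.proviruses) == 5
        assert len(res.regions["env"]) == 13
        assert len(res.regions["gag"]) == 10
        assert len(res.regions["pro"]) == 8
        assert len(res.regions["pol"]) == 11

    def test_impossible_threshold_empties_sets(self):
        res = discovery.screen_for_analysis(
            {"a": 100.0}, {"b": 100.0}, {"b": {"env": 100.0}},
            solo_threshold=101, provirus_threshold=101, region_threshold=101,
        )
        assert res.solo_ltrs == [] and res.proviruses == [] and res.regions == {}
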