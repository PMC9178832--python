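"""GREAT-rule domains vs per-base brute force, associations, exact ORA."""

import itertools
import math

import numpy as np
import pytest

from hml9map import regulatory
from hml9map.io_formats import GeneModel


def make_gene(gene_id, chrom, strand, tss, length=2000):
    if strand == "+":
        start, end = tss, tss + length - 1
    else:
        start, end = tss - length + 1, tss
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, start=start, end=end,
        exons=((start, start + 99), (end - 99, end)),
    )


def brute_force_domains(genes, chrom_length):
    """Per-base oracle: mark basal bases, then walk outward from each basal
    edge until hitting another gene's basal base or the 1 Mb cap."""
    basal_owner = {}
    basals = {}
    for g in genes:
        b = regulatory.basal_interval(g)
        b = (max(1, b[0]), min(chrom_length, b[1]))
        basals[g.gene_id] = b
        for pos in range(b[0], b[1] + 1):
            basal_owner.setdefault(pos, set()).add(g.gene_id)
    covers = {g.gene_id: set(range(*basals[g.gene_id])) for g in genes}
    for g in genes:
        b = basals[g.gene_id]
        covers[g.gene_id] = set(range(b[0], b[1] + 1))
        pos = b[0] - 1
        while pos >= 1 and b[0] - pos <= 1_000_000:
            others = basal_owner.get(pos, set()) - {g.gene_id}
            if others:
                break
            covers[g.gene_id].add(pos)
            pos -= 1
        pos = b[1] + 1
        while pos <= chrom_length and pos - b[1] <= 1_000_000:
            others = basal_owner.get(pos, set()) - {g.gene_id}
            if others:
                break
            covers[g.gene_id].add(pos)
            pos += 1
    return covers


class TestBuildDomains:
    def test_lone_gene_full_extension(self):
        g = make_gene("g", "c1", "+", 2_000_000)
        dom = regulatory.build_domains([g], {"c1": 10_000_000})[0]
        assert dom.basal == (1_995_000, 2_001_000)
        assert dom.extended == (995_000, 3_001_000)

    def test_neighbor_basal_stops_extension(self):
        g1 = make_gene("g1", "c1", "+", 1_000_000)
        g2 = make_gene("g2", "c1", "+", 1_010_000)
        doms = {
            d.gene_id: d
            for d in regulatory.build_domains([g1, g2], {"c1": 5_000_000})
        }
        # gene1 basal ends at 1,001,000; gene2 upstream extension stops there
        assert doms["g2"].extended[0] == 1_001_001
        assert doms["g1"].extended[1] == 1_004_999

    def test_basal_clipped_at_chromosome_start(self):
        g = make_gene("g", "c1", "+", 3_000)
        dom = regulatory.build_domains([g], {"c1": 100_000})[0]
        assert dom.basal[0] == 1

    def test_minus_strand_basal_orientation(self):
        g = make_gene("g", "c1", "-", 50_000)
        dom = regulatory.build_domains([g], {"c1": 200_000})[0]
        assert dom.basal == (49_000, 55_000)

    def test_tss_outside_chromosome_rejected(self):
        g = make_gene("g", "c1", "+", 50_000)
        with pytest.raises(ValueError):
            regulatory.build_domains([g], {"c1": 10_000})

    def test_agrees_with_per_base_brute_force(self):
        rng = np.random.default_rng(4)
        chrom_length = 500_000
        tsss = sorted(rng.choice(np.arange(20_000, 480_000), 6, replace=False))
        genes = [
            make_gene(f"g{i}", "c1", "+" if i % 2 else "-", int(t))
            for i, t in enumerate(tsss)
        ]
        oracle = brute_force_domains(genes, chrom_length)
        doms = regulatory.build_domains(genes, {"c1": chrom_length})
        for d in doms:
            expected = oracle[d.gene_id]
            got = set(range(d.extended[0], d.extended[1] + 1))
            assert got == expected, d.gene_id

    def test_basal_never_truncated(self):
        rng = np.random.default_rng(5)
        tsss = sorted(rng.choice(np.arange(10_000, 190_000), 8, replace=False))
        genes = [
            make_gene(f"g{i}", "c1", "+" if i % 2 else "-", int(t))
            for i, t in enumerate(tsss)
        ]
        for d in regulatory.build_domains(genes, {"c1": 200_000}):
            assert d.extended[0] <= d.basal[0]
            assert d.extended[1] >= d.basal[1]


class TestAssociate:
    def test_midpoint_in_single_domain(self):
        g = make_gene("g", "c1", "+", 100_000)
        doms = regulatory.build_domains([g], {"c1": 5_000_000})
        assocs, counts = regulatory.associate(
            {"e1": ("c1", 150_000, 151_000)}, doms
        )
        assert len(assocs) == 1
        assert counts["e1"] == 1
        assert assocs[0].distance == 50_500

    def test_gene_desert_has_no_association(self):
        g = make_gene("g", "c1", "+", 100_000)
        doms = regulatory.build_domains([g], {"c1": 5_000_000})
        assocs, counts = regulatory.associate(
            {"e1": ("c1", 3_000_000, 3_001_000)}, doms
        )
        assert assocs == [] and counts["e1"] == 0

    def test_matches_exhaustive_domain_lookup(self):
        rng = np.random.default_rng(6)
        chrom_length = 400_000
        tsss = sorted(rng.choice(np.arange(20_000, 380_000), 5, replace=False))
        genes = [
            make_gene(f"g{i}", "c1", "+" if i % 2 else "-", int(t))
            for i, t in enumerate(tsss)
        ]
        doms = regulatory.build_domains(genes, {"c1": chrom_length})
        oracle = brute_force_domains(genes, chrom_length)
        elements = {}
        for i in range(30):
            start = int(rng.integers(1, chrom_length - 600))
            elements[f"e{i}"] = ("c1", start, start + 586)
        assocs, _ = regulatory.associate(elements, doms)
        got = {(a.element_id, a.gene_id) for a in assocs}
        expected = {
            (eid, gid)
            for eid, (_, s, e) in elements.items()
            for gid, cover in oracle.items()
            if (s + e) // 2 in cover
        }
        assert got == expected

    def test_minus_strand_distance_sign(self):
        g = make_gene("g", "c1", "-", 200_000)
        doms = regulatory.build_domains([g], {"c1": 1_000_000})
        assocs, _ = regulatory.associate({"e": ("c1", 150_000, 150_100)}, doms)
        # element upstream... on minus strand, genomic-left is downstream
        assert assocs[0].distance == 200_000 - 150_050


class TestBins:
    def test_boundaries(self):
        distances = [1_000, 10_000, 100_000, 600_000]
        assocs = [
            regulatory.Association("e", "g", d, regulatory.distance_bin(d))
            for d in distances
        ]
        assert regulatory.bin_distances(assocs) == {
            "<5 kb": 1, "5-50 kb": 1, "50-500 kb": 1, ">500 kb": 1
        }

    def test_left_closed_boundaries(self):
        assert regulatory.distance_bin(4_999) == "<5 kb"
        assert regulatory.distance_bin(5_000) == "5-50 kb"
        assert regulatory.distance_bin(-5_000) == "5-50 kb"
        assert regulatory.distance_bin(500_000) == ">500 kb"

    def test_empty(self):
        assert all(v == 0 for v in regulatory.bin_distances([]).values())


def exact_hypergeom_tail(N, K, n, k):
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
    ) / total


class TestOra:
    def test_whole_universe_category_p_is_1(self):
        universe = [f"g{i}" for i in range(20)]
        res = regulatory.ora(
            universe[:5], {"all": set(universe)}, universe
        )
        assert res[0].p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # exact hypergeometric enumeration for all small instances
        rng = np.random.default_rng(7)
        for N in (10, 18, 25):
            universe = [f"g{i}" for i in range(N)]
            for _ in range(5):
                K = int(rng.integers(5, min(N, 12)))
                n = int(rng.integers(2, N // 2 + 1))
                cat = set(rng.choice(universe, K, replace=False))
                genes = list(rng.choice(universe, n, replace=False))
                res = regulatory.ora(
                    genes, {"c": cat}, universe, min_size=1, max_size=N
                )
                k = len(cat & set(genes))
                assert res[0].p_value == pytest.approx(
                    exact_hypergeom_tail(N, K, n, k), rel=1e-9
                )

    def test_small_category_excluded(self):
        universe = [f"g{i}" for i in range(20)]
        res = regulatory.ora(
            universe[:5], {"tiny": set(universe[:4])}, universe
        )
        assert res == []

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(100)]
        cats = {
            f"c{j}": set(rng.choice(universe, 10, replace=False))
            for j in range(15)
        }
        res = regulatory.ora(list(universe[:20]), cats, universe, top=15)
        fdrs = [r.fdr for r in res]
        assert fdrs == sorted(fdrs)
        assert max(fdrs) <= 1.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            regulatory.ora([], {"c": {"a"}}, ["a"])
        with pytest.raises(ValueError):
            regulatory.ora(["a"], {"c": {"a"}}, [])
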