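"""Distances, consensus, clock formulas against the printed ages, NJ."""

import math

import numpy as np
import pytest

from hml9map import dating, synthetic
from hml9map.io_formats import load_catalog


class TestPDistance:
    def test_identical(self):
        assert dating.p_distance("ACGTACGT", "ACGTACGT").D == 0.0

    def test_one_in_four(self):
        res = dating.p_distance("ACGT", "ACGA")
        assert res.D == 0.25
        assert res.sites_compared == 4

    def test_gapped_and_ambiguous_columns_skipped(self):
        res = dating.p_distance("AC-GTN", "ACAGTA")
        assert res.sites_compared == 4
        assert res.D == 0.0

    def test_no_comparable_sites(self):
        with pytest.raises(dating.UndefinedDistanceError):
            dating.p_distance("----", "ACGT")

    def test_simulated_pair_binomial_oracle(self):
        seq = synthetic.random_sequence(1000, np.random.default_rng(1))
        other = synthetic.mutate_sequence(seq, 0.08, seed=2)
        d = dating.p_distance(seq, other).D
        se = math.sqrt(0.08 * 0.92 / 1000)
        assert abs(d - 0.08) < 3 * se


class TestK2P:
    def test_zero_divergence(self):
        assert dating.k2p_distance("ACGT" * 5, "ACGT" * 5).D == 0.0

    def test_closed_form(self):
        # P=0.1, Q=0.05 on a constructed 20-site alignment
        a = "A" * 20
        b = "G" * 2 + "C" * 1 + "A" * 17  # 2 transitions, 1 transversion
        res = dating.k2p_distance(a, b)
        assert res.P == pytest.approx(0.1)
        assert res.Q == pytest.approx(0.05)
        expected = -0.5 * math.log((1 - 2 * 0.1 - 0.05) * math.sqrt(0.9))
        assert res.D == pytest.approx(expected, rel=1e-12)

    def test_correction_exceeds_p_distance(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            seq = synthetic.random_sequence(2000, rng)
            other = synthetic.mutate_sequence(seq, 0.15, seed=seed)
            assert (
                dating.k2p_distance(seq, other).D
                >= dating.p_distance(seq, other).D
            )

    def test_saturation_error(self):
        with pytest.raises(dating.SaturationError):
            dating.k2p_distance("AAAA", "GGGG")


class TestConsensus:
    def test_identical_inputs(self):
        assert dating.build_consensus(["ACGT", "ACGT", "ACGT"]) == "ACGT"

    def test_majority_wins(self):
        assert dating.build_consensus(["A", "A", "G"]) == "A"

    def test_tie_broken_by_reference(self):
        assert dating.build_consensus(["A", "G"], reference="G") == "G"
        assert dating.build_consensus(["A", "G"], reference="C") == "A"

    def test_gap_majority_wins(self):
        assert dating.build_consensus(["-", "-", "A"]) == "-"

    def test_recovers_true_ancestor(self):
        ancestor = synthetic.random_sequence(2000, np.random.default_rng(5))
        children = [
            synthetic.mutate_sequence(ancestor, 0.05, seed=s)
            for s in range(10)
        ]
        cons = dating.build_consensus(children)
        mismatch = synthetic.count_differences(cons, ancestor) / len(ancestor)
        assert mismatch < 0.01

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            dating.build_consensus(["ACGT"])


class TestClockFormulas:
    def test_internal_dating_printed_examples(self):
        # 8q24.3: pol 0.513, env 0.093 -> mean 0.303, age 151.5 my
        mean_d, age = dating.date_internal({"pol": 0.513, "env": 0.093})
        assert mean_d == pytest.approx(0.303)
        assert age == pytest.approx(151.5)
        # 13q31.1: unrounded mean of three regions -> 60.83 my
        mean_d, age = dating.date_internal(
            {"gag": 0.054, "pol": 0.208, "env": 0.103}
        )
        assert mean_d == pytest.approx(0.1216667, abs=1e-6)
        assert round(age, 2) == 60.83

    def test_all_zero_and_all_na(self):
        assert dating.date_internal({"gag": 0.0})[1] == 0.0
        assert dating.date_internal({"gag": None, "env": None}) == (None, None)

    def test_clock_round_trip(self):
        for d in (0.01, 0.1234, 0.3):
            _, age = dating.date_internal({"gag": d})
            assert age * dating.CLOCK_RATE_PCT_PER_MY / 100 == pytest.approx(d)

    def test_ltr_pair_printed_example(self):
        # divergence 0.082 -> 20.5 my at 0.2%/nt/my halved for twin LTRs
        a = "A" * 1000
        b = "G" * 82 + "A" * 918
        d, age = dating.date_ltr_pair(a, b)
        assert d == pytest.approx(0.082)
        assert age == pytest.approx(20.5)

    def test_identical_ltrs_age_zero(self):
        assert dating.date_ltr_pair("ACGT" * 100, "ACGT" * 100)[1] == 0.0

    def test_missing_ltr_gives_na(self):
        assert dating.date_ltr_pair("", "ACGT") == (None, None)

    def test_all_printed_ltr_ages_replay_exactly(self):
        dat = load_catalog()["dating"]
        replayed = []
        for rec in dat.itertuples():
            if rec.d_ltr == rec.d_ltr:  # not NaN
                replayed.append(
                    round(
                        dating.age_from_divergence(rec.d_ltr, paired_ltr=True),
                        2,
                    )
                )
        assert replayed == [
            20.50, 17.50, 20.00, 26.75, 27.50, 35.25, 24.25, 39.25, 48.50
        ]

    def test_parameter_recovery_age_20(self, reference):
        # 50 replicates at true age 20 my: mean estimate within 10%
        rng = np.random.default_rng(77)
        model = synthetic.MutationModel()
        ltr_len = reference.region_length("LTR5")
        ages = []
        for _ in range(50):
            spec = synthetic.PlantSpec(
                "full_provirus", "c", "+", insert_pos=1, true_age_my=20.0
            )
            elem, _ = synthetic.build_element(reference, spec, model, rng)
            _, age = dating.date_ltr_pair(elem[:ltr_len], elem[-ltr_len:])
            ages.append(age)
        assert abs(np.mean(ages) - 20.0) / 20.0 < 0.10


class TestNeighborJoining:
    def test_three_taxa(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        newick = dating.nj_cluster(d, ["a", "b", "c"])
        assert newick.endswith(";")
        assert set("abc") <= set(newick)

    def test_additive_four_taxon_recovery(self):
        # additive matrix for ((a,b),(c,d)): verified by the four-point
        # condition, which prefers the ab|cd split
        d = np.array(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 5],
                [10, 11, 5, 0],
            ],
            dtype=float,
        )
        s_ab_cd = d[0, 1] + d[2, 3]  # 8
        s_ac_bd = d[0, 2] + d[1, 3]  # 20
        s_ad_bc = d[0, 3] + d[1, 2]  # 20
        assert s_ab_cd < s_ac_bd == s_ad_bc
        newick = dating.nj_cluster(d, ["a", "b", "c", "d"])
        parts = dating.newick_bipartitions(newick)
        leaf_sets = {frozenset(p) for p in parts}
        assert frozenset({"a", "b"}) in leaf_sets or frozenset(
            {"c", "d"}
        ) in leaf_sets

    def test_matches_independent_nj_implementation(self):
        # cross-check against scikit-bio on a random additive-ish matrix
        from skbio import DistanceMatrix
        from skbio.tree import nj

        rng = np.random.default_rng(9)
        points = rng.random((6, 4))
        d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(6)]
        ours = dating.nj_cluster(d, labels)
        theirs = nj(DistanceMatrix(d, ids=labels))
        our_parts = {
            frozenset(p)
            for p in dating.newick_bipartitions(ours)
            if 2 <= len(p) <= 4
        }
        their_parts = set()
        for node in theirs.non_tips():
            names = frozenset(t.name for t in node.tips())
            if 2 <= len(names) <= 4:
                their_parts.add(names)
        full = frozenset(labels)
        norm = lambda parts: {
            min(p, full - p, key=sorted) for p in parts
        }
        assert norm(our_parts) <= norm(their_parts) | norm(
            {full - p for p in their_parts}
        )

    def test_two_clades_separate(self):
        # simulated clades: intra 2%, inter 20%
        rng = np.random.default_rng(10)
        anc = synthetic.random_sequence(2000, rng)
        clade1_anc = synthetic.mutate_sequence(anc, 0.10, seed=1)
        clade2_anc = synthetic.mutate_sequence(anc, 0.10, seed=2)
        seqs = [
            synthetic.mutate_sequence(clade1_anc, 0.01, seed=10 + i)
            for i in range(3)
        ] + [
            synthetic.mutate_sequence(clade2_anc, 0.01, seed=20 + i)
            for i in range(3)
        ]
        n = len(seqs)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = dating.p_distance(seqs[i], seqs[j]).D
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        newick = dating.nj_cluster(d, labels)
        parts = {frozenset(p) for p in dating.newick_bipartitions(newick)}
        assert (
            frozenset({"a1", "a2", "a3"}) in parts
            or frozenset({"b1", "b2", "b3"}) in parts
        )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            dating.nj_cluster(np.array([[0, 1], [2, 0]], dtype=float))
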