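import io
import math

import numpy as np
import pytest
from skbio import TreeNode

from batglut import promoter_evolution as pe


def aln_from(seq_map, groups):
    return pe.GroupedAlignment(list(seq_map), list(seq_map.values()), dict(groups))


class TestGroupedAlignment:
    def test_validation(self):
        with pytest.raises(ValueError, match="length"):
            aln_from({"a": "ACGT", "b": "ACG"}, {"a": "G1", "b": "G1"})
        with pytest.raises(ValueError, match="without a group"):
            aln_from({"a": "ACGT", "b": "ACGT"}, {"a": "G1"})
        with pytest.raises(ValueError, match="invalid symbols"):
            aln_from({"a": "ACXT", "b": "ACGT"}, {"a": "G1", "b": "G1"})

    def test_fasta_roundtrip(self, tmp_path, toy_alignment):
        fasta = tmp_path / "aln.fasta"
        toy_alignment.to_fasta(fasta)
        groups_csv = tmp_path / "groups.csv"
        groups_csv.write_text(
            "id,group\n" + "\n".join(f"{i},{toy_alignment.groups[i]}" for i in toy_alignment.ids)
        )
        again = pe.GroupedAlignment.from_fasta(fasta, str(groups_csv))
        assert again.ids == toy_alignment.ids
        assert again.seqs == toy_alignment.seqs
        assert again.groups == toy_alignment.groups


class TestConservationProfile:
    def test_identical_sequences_all_universal(self):
        aln = aln_from({"a": "ACGTA", "b": "ACGTA", "c": "ACGTA"}, {"a": "G1", "b": "G1", "c": "G2"})
        prof = pe.conservation_profile(aln, ["G1", "G2"])
        assert prof.universal_count == 5
        assert prof.levels == {"G1": 100.0, "G2": 100.0}

    def test_toy_counts_by_hand(self, toy_alignment):
        prof = pe.conservation_profile(toy_alignment, ["G1", "G2"])
        assert prof.universal_count == 2
        assert prof.group_counts == {"G1": 1, "G2": 1}
        variable = sum(c == "variable" for c in prof.classes)
        assert variable == 2

    def test_classes_partition_columns(self, toy_alignment):
        prof = pe.conservation_profile(toy_alignment, ["G1", "G2"])
        assert len(prof.classes) == toy_alignment.length
        n_universal = sum(c == "universal" for c in prof.classes)
        assert n_universal == prof.universal_count
        for g in ("G1", "G2"):
            in_group = sum(c.startswith("group:") and g in c.split(":", 1)[1].split(",") for c in prof.classes)
            assert in_group == prof.group_counts[g]

    def test_shared_gap_mode_switch(self):
        aln = aln_from(
            {"a": "A-GT", "b": "A-GT", "c": "ACGT", "d": "ACGA"},
            {"a": "G1", "b": "G1", "c": "G2", "d": "G2"},
        )
        with_gap = pe.conservation_profile(aln, ["G1"], shared_gap_conserves_group=True)
        without = pe.conservation_profile(aln, ["G1"], shared_gap_conserves_group=False)
        assert with_gap.group_counts["G1"] == without.group_counts["G1"] + 1

    def test_n_never_conserves(self):
        aln = aln_from({"a": "NA", "b": "NA", "c": "NA"}, {"a": "G1", "b": "G1", "c": "G1"})
        prof = pe.conservation_profile(aln, ["G1"])
        assert prof.universal_count == 1  # only the A column

    def test_removing_group_member_is_monotone(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(10):
            n, length = 5, 40
            seqs = rng.choice(bases, size=(n, length))
            ids = [f"s{i}" for i in range(n)]
            groups = {sid: "G1" for sid in ids}
            aln = aln_from(dict(zip(ids, ["".join(r) for r in seqs])), groups)
            full = pe.conservation_profile(aln, ["G1"])
            reduced = pe.conservation_profile(aln.subset(ids[:-1]), ["G1"])
            full_cons = full.universal_count + full.group_counts["G1"]
            red_cons = reduced.universal_count + reduced.group_counts["G1"]
            assert red_cons >= full_cons

    def test_empty_group_rejected(self, toy_alignment):
        with pytest.raises(ValueError, match="no members"):
            pe.conservation_profile(toy_alignment, ["G3"])


class TestSharedIndels:
    def test_gapless_alignment(self, toy_alignment):
        assert pe.find_shared_indels(toy_alignment, "G1") == []

    def test_toy_deletion(self):
        aln = aln_from(
            {"a": "ACG---TTA", "b": "ACG---TTA", "c": "ACGCGATTA", "d": "ACGCGCTTA"},
            {"a": "G1", "b": "G1", "c": "G2", "d": "G2"},
        )
        events = pe.find_shared_indels(aln, "G1")
        assert [(e.start, e.length) for e in events] == [(4, 3)]
        assert set(events[0].carriers) == {"a", "b"}

    def test_events_maximal_and_disjoint(self):
        aln = aln_from(
            {"a": "A--G--T", "b": "A--G--T", "c": "ACCGGGT", "d": "ACAGGCT"},
            {"a": "G1", "b": "G1", "c": "G2", "d": "G2"},
        )
        events = pe.find_shared_indels(aln, "G1")
        assert [(e.start, e.length) for e in events] == [(2, 2), (5, 2)]
        # removing the event columns leaves no event at that locus
        keep = [j for j in range(aln.length) if not any(e.start - 1 <= j < e.start - 1 + e.length for e in events)]
        pruned = aln_from(
            {sid: "".join(aln.row(sid)[j] for j in keep) for sid in aln.ids}, aln.groups
        )
        assert pe.find_shared_indels(pruned, "G1") == []

    def test_gap_shared_with_outsiders_not_reported(self):
        aln = aln_from(
            {"a": "A-GT", "b": "A-GT", "c": "A-GT", "d": "ACGT"},
            {"a": "G1", "b": "G1", "c": "G2", "d": "G2"},
        )
        assert pe.find_shared_indels(aln, "G1") == []


class TestSnpClassification:
    def test_table_examples(self):
        # rs5393: susceptible A / normal C; rs5394: susceptible C / normal T
        aln = aln_from(
            {"vampire": "AC", "fruit1": "CG", "fruit2": "-T"},
            {"vampire": "G1", "fruit1": "G2", "fruit2": "G2"},
        )
        rs5393 = pe.SnpSite("rs5393", 1, "A", "C")
        rs5394 = pe.SnpSite("rs5394", 2, "C", "T")
        assert pe.classify_snp_alleles(aln, rs5393) == {
            "vampire": "susceptible", "fruit1": "normal", "fruit2": "gap"}
        assert pe.classify_snp_alleles(aln, rs5394) == {
            "vampire": "susceptible", "fruit1": "other", "fruit2": "normal"}

    def test_column_out_of_range(self):
        aln = aln_from({"a": "AC", "b": "AC"}, {"a": "G1", "b": "G1"})
        with pytest.raises(ValueError, match="outside"):
            pe.classify_snp_alleles(aln, pe.SnpSite("x", 3, "A", "C"))

    def test_allele_validation(self):
        with pytest.raises(ValueError):
            pe.SnpSite("x", 1, "A", "A")
        with pytest.raises(ValueError):
            pe.SnpSite("x", 1, "A", "-")


def chi2_sf_df1(x):
    """Independent chi-square (df=1) survival function via erfc."""
    return math.erfc(math.sqrt(x / 2.0))


class TestTajimaRelativeRate:
    def test_equal_sequences_null(self):
        res = pe.tajima_relative_rate("ACGTAC", "ACGTAC", "ACGTTT")
        assert (res.m1, res.m2) == (0, 0)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_ten_site_triplet_by_enumeration(self):
        out = "ACGTACGTAC"
        b = out
        a = "TCGTACGTAG"  # unique substitutions at sites 1 and 10
        res = pe.tajima_relative_rate(a, b, out)
        assert (res.m1, res.m2) == (2, 0)
        assert res.chi2 == pytest.approx(2.0)
        assert res.p == pytest.approx(chi2_sf_df1(2.0), abs=1e-12)
        assert res.p == pytest.approx(0.1573, abs=5e-4)

    def test_symmetry_under_swap(self):
        a = "TCGAACGTAG"
        b = "ACGTACCTAC"
        o = "ACGTACGTAC"
        r1 = pe.tajima_relative_rate(a, b, o)
        r2 = pe.tajima_relative_rate(b, a, o)
        assert r1.chi2 == r2.chi2 and r1.p == r2.p
        assert (r1.m1, r1.m2) == (r2.m2, r2.m1)

    def test_gap_and_n_columns_excluded(self):
        res = pe.tajima_relative_rate("AC-TN", "ACGTN", "ACCTA")
        assert res.usable_sites == 3  # gap column 3 and N column 5 dropped

    def test_column_order_and_padding_invariance(self, rng):
        a = "TCGAACGTAG"
        b = "ACGTACCTAC"
        o = "ACGTACGTAC"
        base = pe.tajima_relative_rate(a, b, o)
        order = rng.permutation(len(a))
        shuffled = pe.tajima_relative_rate(
            "".join(a[i] for i in order), "".join(b[i] for i in order), "".join(o[i] for i in order)
        )
        padded = pe.tajima_relative_rate(a + "AAAA", b + "AAAA", o + "AAAA")
        assert shuffled.chi2 == base.chi2 and shuffled.p == base.p
        assert padded.chi2 == base.chi2 and padded.p == base.p

    def test_matches_site_enumeration_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a, b, o = ("".join(rng.choice(bases, 60)) for _ in range(3))
            res = pe.tajima_relative_rate(a, b, o)
            m1 = sum(1 for x, y, z in zip(a, b, o) if x != y and y == z)
            m2 = sum(1 for x, y, z in zip(a, b, o) if x != y and x == z)
            assert (res.m1, res.m2) == (m1, m2)
            if m1 + m2:
                chi2 = (m1 - m2) ** 2 / (m1 + m2)
                assert res.p == pytest.approx(chi2_sf_df1(chi2), abs=1e-12)

    def test_no_usable_sites(self):
        with pytest.raises(ValueError, match="usable"):
            pe.tajima_relative_rate("--", "AC", "AC")


class TestNjTree:
    def test_identical_sequences_star(self):
        aln = aln_from(
            {"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"},
            {"a": "G", "b": "G", "c": "G"},
        )
        tree = TreeNode.read(io.StringIO(pe.nj_tree(aln)))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length == pytest.approx(0.0, abs=1e-12)

    def test_additive_distances_recover_topology(self):
        # disjoint mutation sets: 5 unique to each of A/B/C/D pairs plus a
        # 10-site internal branch separating {A,B} from {C,D}
        length = 100
        base = ("ACGT" * 25)
        def mutate(seq, sites, to="T"):
            s = list(seq)
            for j in sites:
                s[j] = "G" if s[j] == to else to
            return "".join(s)
        internal = range(40, 50)
        a = mutate(base, range(0, 2))
        b = mutate(base, range(5, 8))
        cd_base = mutate(base, internal)
        c = mutate(cd_base, range(10, 12))
        d = mutate(cd_base, range(15, 18))
        aln = aln_from({"A": a, "B": b, "C": c, "D": d}, dict.fromkeys("ABCD", "G"))
        tree = TreeNode.read(io.StringIO(pe.nj_tree(aln)))
        clades = [frozenset(t.name for t in n.tips()) for n in tree.non_tips(include_self=False)]
        assert frozenset("AB") in clades or frozenset("CD") in clades

    def test_k2p_single_transition_closed_form(self):
        s1 = "A" * 100
        s2 = "G" + "A" * 99  # one transition
        aln = aln_from({"a": s1, "b": s2, "c": s1}, dict.fromkeys("abc", "G"))
        dm = pe.pairwise_distances(aln, model="k2p")
        expected = -0.5 * math.log(1 - 2 * 0.01) - 0.25 * math.log(1.0)
        assert dm["a", "b"] == pytest.approx(expected, abs=1e-12)
        assert round(dm["a", "b"], 4) == 0.0101

    def test_k2p_saturation_names_pair(self):
        aln = aln_from(
            {"a": "AAAA", "b": "GGGG", "c": "AAAA"}, dict.fromkeys("abc", "G")
        )
        with pytest.raises(ValueError, match="a vs b"):
            pe.pairwise_distances(aln, model="k2p")

    def test_needs_three_sequences(self):
        aln = aln_from({"a": "AC", "b": "AC"}, {"a": "G", "b": "G"})
        with pytest.raises(ValueError, match="three"):
            pe.nj_tree(aln)
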