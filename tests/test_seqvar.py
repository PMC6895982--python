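"""Alignment, variant calling, diagnostic SNPs and the clone filter."""

import numpy as np
import pytest

import homeobias as hb
from homeobias.seqvar import (CloneSet, InputError, PairwiseAlignment,
                              StructureError)


def gene(seq, role="maternal_parent", **kw):
    return hb.GeneSequence(id=f"g_{role}", role=role, seq=seq, **kw)


# ---------------------------------------------------------------------------
# GeneSequence
# ---------------------------------------------------------------------------


class TestGeneSequence:
    def test_rejects_empty_and_non_dna(self):
        with pytest.raises(InputError):
            gene("")
        with pytest.raises(InputError):
            gene("ACGU")

    def test_rejects_bad_exon_structure(self):
        with pytest.raises(StructureError):
            gene("ACGTACGT", exons=((1, 4), (3, 8)))
        with pytest.raises(StructureError):
            gene("ACGTACGT", exons=((1, 10),))

    def test_complete_cds_requires_frame_multiple_of_three(self):
        with pytest.raises(StructureError):
            gene("ACGTACGT", complete_cds=True)
        g = gene("ACGTAC", complete_cds=True)
        assert g.cds == "ACGTAC"

    def test_coordinate_round_trip_with_introns(self):
        g = gene("AAACCCGGGTTT", exons=((1, 3), (7, 12)))
        assert g.cdna == "AAAGGGTTT"
        assert g.genomic_to_cdna(7) == 4
        assert g.genomic_to_cdna(5) is None  # intronic
        for cpos in range(1, g.cdna_length + 1):
            assert g.genomic_to_cdna(g.cdna_to_genomic(cpos)) == cpos
        assert g.region_of(2) == "exon 1"
        assert g.region_of(5) == "intron 1"


# ---------------------------------------------------------------------------
# align_pair
# ---------------------------------------------------------------------------


class TestAlignPair:
    def test_identity(self):
        g = gene("ACGTACGT")
        aln = hb.align_pair(g, g)
        assert aln.rows == ("ACGTACGT", "ACGTACGT")
        assert aln.identity() == 1.0

    def test_single_mismatch_beats_any_gapped_alignment(self):
        # under match +2 / mismatch -3, 7 matches + 1 mismatch scores 11;
        # any alignment using gaps scores at most 12 matches' worth minus
        # two gap runs (>= 7 each), i.e. < 11, so the ungapped alignment
        # is uniquely optimal and the mismatch sits at column 4
        a, b = gene("ACGTACGT"), gene("ACGAACGT", role="paternal_parent")
        aln = hb.align_pair(a, b)
        assert len(aln) == 8
        mismatches = [i for i, (x, y) in enumerate(zip(*aln.rows)) if x != y]
        assert mismatches == [3]

    def test_deterministic_repeat(self):
        rng = np.random.default_rng(5)
        s = "".join(rng.choice(list("ACGT"), size=200))
        t = "".join(rng.choice(list("ACGT"), size=190))
        a, b = gene(s), gene(t, role="paternal_parent")
        r1 = hb.align_pair(a, b)
        r2 = hb.align_pair(a, b)
        assert r1.rows == r2.rows

    def test_rows_recover_inputs(self):
        a, b = gene("ACGTAAACGT"), gene("ACGTCGT", role="paternal_parent")
        aln = hb.align_pair(a, b)
        assert aln.rows[0].replace("-", "") == a.seq
        assert aln.rows[1].replace("-", "") == b.seq


# ---------------------------------------------------------------------------
# call_variants
# ---------------------------------------------------------------------------


def brute_force_counts(row_a, row_b):
    """Independent column scan: SNP columns and maximal gap runs."""
    snps = sum(x != y and "-" not in (x, y) and "N" not in (x, y)
               for x, y in zip(row_a, row_b))
    indels = 0
    in_gap = False
    for x, y in zip(row_a, row_b):
        gap = "-" in (x, y)
        if gap and not in_gap:
            indels += 1
        in_gap = gap
    return snps, indels


class TestCallVariants:
    def test_identical_rows_give_empty_list(self):
        g = gene("ACGTACGT")
        assert hb.call_variants(hb.align_pair(g, g)) == []

    def test_single_gap_column_is_one_indel(self):
        a = gene("ACGT")
        b = gene("ACTGT", role="paternal_parent")
        aln = PairwiseAlignment(a, b, "AC-GT", "ACTGT")
        recs = hb.call_variants(aln)
        assert [r.kind for r in recs] == ["indel"]
        assert recs[0].alleles == ("T", 1)
        assert recs[0].pos_a == 2  # anchored to the last base before the gap

    def test_matches_brute_force_scan_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n, m = rng.integers(10, 61, size=2)
            a = gene("".join(rng.choice(list("ACGT"), size=n)))
            b = gene("".join(rng.choice(list("ACGT"), size=m)),
                     role="paternal_parent")
            aln = hb.align_pair(a, b)
            recs = hb.call_variants(aln)
            got = (sum(r.kind == "SNP" for r in recs),
                   sum(r.kind == "indel" for r in recs))
            assert got == brute_force_counts(*aln.rows)

    def test_symmetry_of_counts_with_alleles_swapped(self):
        rng = np.random.default_rng(13)
        s = "".join(rng.choice(list("ACGT"), size=80))
        t = "".join(rng.choice(list("ACGT"), size=76))
        a, b = gene(s), gene(t, role="paternal_parent")
        fwd = hb.call_variants(hb.align_pair(a, b))
        rev = hb.call_variants(hb.align_pair(b, a))
        fwd_snps = sorted((r.pos_a, r.alleles) for r in fwd if r.kind == "SNP")
        rev_snps = sorted((r.pos_b, (r.alleles[1], r.alleles[0]))
                          for r in rev if r.kind == "SNP")
        assert fwd_snps == rev_snps
        assert (sum(r.kind == "indel" for r in fwd)
                == sum(r.kind == "indel" for r in rev))

    def test_region_partition_is_conserved(self, default_sim):
        aln = hb.align_pair(default_sim.maternal, default_sim.paternal)
        recs = hb.call_variants(aln, default_sim.maternal)
        for kind in ("SNP", "indel"):
            of_kind = [r for r in recs if r.kind == kind]
            exonic = sum(r.region.startswith("exon") for r in of_kind)
            intronic = sum(r.region.startswith("intron") for r in of_kind)
            assert exonic + intronic == len(of_kind)

    def test_recovers_planted_variants_exactly(self, default_sim):
        truth = default_sim.truth
        aln = hb.align_pair(default_sim.maternal, default_sim.paternal)
        recs = hb.call_variants(aln, default_sim.maternal)
        called_snps = {(r.pos_a, r.alleles) for r in recs if r.kind == "SNP"}
        planted = {(s.genomic_pos, (s.maternal_base, s.paternal_base))
                   for s in truth.snps}
        assert called_snps == planted
        called_indels = sorted((r.pos_a, r.alleles[1])
                               for r in recs if r.kind == "indel")
        assert called_indels == sorted((i.anchor_pos, i.length)
                                       for i in truth.indels)


# ---------------------------------------------------------------------------
# coding effect & protein diff
# ---------------------------------------------------------------------------


class TestCodingEffect:
    def pair(self, cds_a, cds_b):
        a = gene(cds_a, complete_cds=True)
        b = gene(cds_b, role="paternal_parent", complete_cds=True)
        aln = hb.align_pair(a, b)
        snps = [v for v in hb.call_variants(aln) if v.kind == "SNP"]
        return a, b, aln, snps

    def test_third_position_degenerate_snp_is_synonymous(self):
        a, b, aln, snps = self.pair("ATGGGATAA", "ATGGGGTAA")  # Gly GGA>GGG
        assert len(snps) == 1
        assert hb.classify_coding_effect(snps[0], aln, a, b) == "synonymous"

    def test_first_position_snp_changes_amino_acid(self):
        a, b, aln, snps = self.pair("ATGGAATAA", "ATGAAATAA")  # Glu>Lys
        assert hb.classify_coding_effect(snps[0], aln, a, b) == "nonsynonymous"

    def test_codon_with_n_is_not_applicable(self):
        a, b, aln, snps = self.pair("ATGGANTAA", "ATGAANTAA")
        assert hb.classify_coding_effect(snps[0], aln, a, b) == "not_applicable"


class TestTranslateAndDiff:
    def test_identical_cds_has_zero_differences(self):
        g = gene("ATGGAAGGATAA", complete_cds=True)
        assert hb.translate_and_diff(g, g) == 0

    def test_two_nonsynonymous_snps_give_two_differences(self):
        a = gene("ATGGAAGGATTACATTAA", complete_cds=True)
        b = gene("ATGAAAGGATTACGTTAA", role="paternal_parent", complete_cds=True)
        assert hb.translate_and_diff(a, b) == 2

    def test_codon_deletion_counts_as_one_difference(self):
        a = gene("ATGGAAGGATTACATTAA", complete_cds=True)
        b = gene("ATGGAATTACATTAA", role="paternal_parent", complete_cds=True)
        assert hb.translate_and_diff(a, b) == 1

    def test_internal_stop_warns_but_returns(self):
        a = gene("ATGTAAGGATAA", complete_cds=True)
        with pytest.warns(UserWarning, match="internal stop"):
            n = hb.translate_and_diff(a, a)
        assert n == 0


# ---------------------------------------------------------------------------
# diagnostic SNPs & homoeolog mutations
# ---------------------------------------------------------------------------


class TestFindDiagnosticSnps:
    def test_identical_parents_give_empty_list(self):
        m = gene("ACGTACGTACGT")
        p = gene("ACGTACGTACGT", role="paternal_parent")
        h = gene("ACGTACGTACGT", role="polyploid_H")
        c = gene("ACGTACGTACGT", role="polyploid_C")
        assert hb.find_diagnostic_snps(m, p, h, c) == []

    def test_planted_sites_recovered_and_retained(self, default_sim):
        s = default_sim
        found = hb.find_diagnostic_snps(s.maternal, s.paternal, s.poly_h, s.poly_c)
        retained = [(d.genomic_pos_maternal, d.cdna_pos)
                    for d in found if d.retained]
        assert retained == sorted(s.truth.diagnostic)

    def test_output_is_subset_of_parental_snps(self, default_sim):
        s = default_sim
        found = hb.find_diagnostic_snps(s.maternal, s.paternal, s.poly_h, s.poly_c)
        parental = {snp.genomic_pos for snp in s.truth.snps}
        assert {d.genomic_pos_maternal for d in found} <= parental

    def test_retained_sites_respect_min_distance(self, default_sim):
        s = default_sim
        found = hb.find_diagnostic_snps(s.maternal, s.paternal, s.poly_h, s.poly_c,
                                        min_distance=5)
        all_cdna = sorted(snp.cdna_pos for snp in s.truth.snps
                          if snp.cdna_pos is not None)
        for d in found:
            nearest = min(abs(d.cdna_pos - c) for c in all_cdna
                          if c != d.cdna_pos)
            assert d.retained == (nearest > 5)


class TestClassifyHomoeologMutations:
    def test_identical_allele_has_no_mutations(self):
        m = gene("ACGTACGTACGT")
        p = gene("ACCTACGTACGT", role="paternal_parent")
        h = gene("ACGTACGTACGT", role="polyploid_H")
        mc = hb.classify_homoeolog_mutations(h, m, p)
        assert mc.total == 0

    def test_planted_split_recovered(self, default_sim):
        s = default_sim
        mc = hb.classify_homoeolog_mutations(s.poly_h, s.maternal, s.paternal)
        assert (mc.n_directional, mc.n_nondirectional) == (12, 8)
        planted = dict(s.truth.h_mutations)
        for mut in mc.mutations:
            assert planted[mut.pos] == mut.label

    def test_counts_partition_all_differences(self, default_sim):
        s = default_sim
        mc = hb.classify_homoeolog_mutations(s.poly_h, s.maternal, s.paternal)
        diffs = sum(x != y for x, y in zip(s.poly_h.seq, s.maternal.seq))
        assert mc.n_directional + mc.n_nondirectional == mc.total == diffs


# ---------------------------------------------------------------------------
# clone-support filter
# ---------------------------------------------------------------------------


X, Y, Z = "AAAA", "CCCC", "GGGG"


class TestAcceptCloneCopies:
    def test_symmetric_clone_sets_accept_both(self):
        sets = [CloneSet(f"pcr{i}", (X,) * 5 + (Y,) * 5) for i in range(3)]
        assert set(hb.accept_clone_copies(sets)) == {X, Y}

    def test_copy_below_threshold_in_any_experiment_is_rejected(self):
        sets = [CloneSet("pcr1", (X,) * 7 + (Y,) * 2 + (Z,)),
                CloneSet("pcr2", (X,) * 6 + (Y,) * 3 + (Z,)),
                CloneSet("pcr3", (X,) * 8 + (Y,) * 2)]
        # Y's support is 0.2 / 0.3 / 0.2 and Z's 0.1 / 0.1 / 0.0
        assert hb.accept_clone_copies(sets) == [X]

    def test_boundary_support_exactly_at_threshold_is_accepted(self):
        sets = [CloneSet("pcr1", (X,) + (Y,) * 3)]
        assert set(hb.accept_clone_copies(sets)) == {X, Y}

    def test_lowering_threshold_never_shrinks_accepted_set(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = rng.integers(0, 6, size=(3, 3))
            counts[:, 0] += 1  # keep every experiment non-empty
            thresholds = [0.5, 0.4, 0.3, 0.2, 0.1]
            previous: set = set()
            for thr in thresholds:
                sets = [CloneSet(f"p{i}",
                                 (X,) * int(c[0]) + (Y,) * int(c[1])
                                 + (Z,) * int(c[2]), threshold=thr)
                        for i, c in enumerate(counts)]
                accepted = set(hb.accept_clone_copies(sets))
                assert previous <= accepted
                previous = accepted
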