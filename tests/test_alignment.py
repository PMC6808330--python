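"""Alignment I/O, masking, concatenation, haplotype collapsing, distances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cyclodelim import (
    Locus,
    MultiLocusAlignment,
    collapse_haplotypes,
    concatenate_loci,
    mask_ambiguities,
    pairwise_distances,
    read_alignment,
    write_alignment,
)
from cyclodelim.exceptions import (
    AlignmentFormatError,
    InputError,
    UndefinedDistanceError,
)


def mla(rows, taxa=None, locus="L"):
    taxa = taxa or tuple(f"t{i+1}" for i in range(len(rows)))
    return MultiLocusAlignment(
        tuple(taxa), tuple(rows), (Locus(locus, 0, len(rows[0])),)
    )


class TestReadWrite:
    def test_reads_aligned_fasta(self, write_fasta):
        path = write_fasta([("t1", "ACGTACGTAC"), ("t2", "ACGTACGTAA"), ("t3", "ACGTACGTAG")])
        aln = read_alignment(path)
        assert aln.n_taxa == 3 and aln.n_columns == 10
        assert aln.taxa == ("t1", "t2", "t3")

    def test_lowercase_is_uppercased(self, write_fasta):
        aln = read_alignment(write_fasta([("t1", "acgt"), ("t2", "acga")]))
        assert aln.seqs == ("ACGT", "ACGA")

    def test_ragged_lengths_rejected(self, write_fasta):
        path = write_fasta([("t1", "ACGTACGTAC"), ("t2", "ACGTACGTA")])
        with pytest.raises(AlignmentFormatError, match="ragged"):
            read_alignment(path)

    def test_duplicate_identifiers_rejected(self, write_fasta):
        path = write_fasta([("t1", "ACGT"), ("t1", "ACGA")])
        with pytest.raises(InputError, match="duplicate"):
            read_alignment(path)

    def test_ambiguity_codes_retained_and_flagged(self, write_fasta):
        aln = read_alignment(write_fasta([("t1", "ACRT"), ("t2", "ACGT")]))
        assert aln.row("t1")[2] == "R"
        assert aln.has_ambiguities
        assert ("t1", 2) in aln.ambiguity_cells()

    def test_roundtrip(self, tmp_path, write_fasta):
        aln = read_alignment(write_fasta([("t1", "ACGT" * 20), ("t2", "ACGA" * 20)]))
        out = tmp_path / "out.fasta"
        write_alignment(aln, out)
        again = read_alignment(out)
        assert again.taxa == aln.taxa and again.seqs == aln.seqs
        # wrapped at 60 columns
        body = out.read_text().splitlines()
        assert max(len(l) for l in body if not l.startswith(">")) == 60


class TestMaskAmbiguities:
    def test_masks_iupac_to_missing(self):
        aln = mask_ambiguities(mla(["ACGA", "RCGA", "ACGA"]))
        assert aln.seqs == ("ACGA", "?CGA", "ACGA")

    def test_identity_without_ambiguities(self):
        a = mla(["ACG-", "AC?T"])
        assert mask_ambiguities(a).seqs == a.seqs

    def test_all_ambiguity_row_fully_masked(self):
        aln = mask_ambiguities(mla(["NRYW", "ACGT"]))
        assert aln.seqs[0] == "????"

    def test_gaps_unchanged(self):
        assert mask_ambiguities(mla(["A-RT"])).seqs[0] == "A-?T"


class TestConcatenate:
    def test_two_loci_concatenated_with_spans(self):
        a = mla(["ACGTA", "ACGTC", "ACGTT"], locus="coi")
        b = mla(["GGGGGGG", "GGGGGGA", "GGGGGGC"], locus="s16")
        cat = concatenate_loci([a, b])
        assert cat.n_columns == 12
        assert [(l.name, l.start, l.end) for l in cat.loci] == [("coi", 0, 5), ("s16", 5, 12)]

    def test_missing_taxon_filled(self):
        a = mla(["ACGTA", "ACGTC"], taxa=("t1", "t2"), locus="coi")
        b = mla(["GGGGGGG"], taxa=("t1",), locus="s16")
        cat = concatenate_loci([a, b], fill_missing=True)
        assert cat.row("t2")[5:] == "???????"

    def test_missing_taxon_error_when_fill_off(self):
        a = mla(["ACGTA", "ACGTC"], taxa=("t1", "t2"), locus="coi")
        b = mla(["GGGGGGG"], taxa=("t1",), locus="s16")
        with pytest.raises(InputError, match="missing"):
            concatenate_loci([a, b], fill_missing=False)

    def test_slicing_recovers_inputs(self):
        a = mla(["ACGTA", "ACGTC"], locus="coi")
        b = mla(["GG-GGGG", "GGGG?GA"], locus="s16")
        cat = concatenate_loci([a, b])
        assert cat.slice_locus("coi").seqs == a.seqs
        assert cat.slice_locus("s16").seqs == b.seqs


class TestCollapseHaplotypes:
    def test_duplicate_pair_collapsed(self):
        aln = mla(["ACGT", "ACGT", "ACGA"])
        collapsed, mapping = collapse_haplotypes(aln)
        assert collapsed.taxa == ("t1", "t3")
        assert mapping == {"t1": ["t1", "t2"], "t3": ["t3"]}

    def test_all_distinct_is_identity(self):
        aln = mla(["ACGT", "ACGA", "ACGC"])
        collapsed, mapping = collapse_haplotypes(aln)
        assert collapsed.seqs == aln.seqs
        assert all(v == [k] for k, v in mapping.items())

    def test_empty_alignment_rejected(self):
        aln = MultiLocusAlignment((), (), ())
        with pytest.raises(InputError):
            collapse_haplotypes(aln)

    @given(st.lists(st.sampled_from(["ACGT", "ACGA", "AC-T", "ACG?"]), min_size=1, max_size=12))
    def test_idempotent_and_mapping_covers_all(self, rows):
        aln = mla(rows)
        collapsed, mapping = collapse_haplotypes(aln)
        assert sum(len(v) for v in mapping.values()) == aln.n_taxa
        again, mapping2 = collapse_haplotypes(collapsed)
        assert again.seqs == collapsed.seqs
        assert all(v == [k] for k, v in mapping2.items())


class TestDistances:
    @pytest.mark.parametrize("model", ["p", "jc69", "k2p"])
    def test_identical_sequences_distance_zero(self, model):
        dm = pairwise_distances(mla(["ACGTACGT", "ACGTACGT"]), model)
        assert dm.d[0, 1] == 0.0

    def test_p_distance_direct_count(self):
        assert pairwise_distances(mla(["ACGT", "ACGA"]), "p").d[0, 1] == 0.25

    def test_pairwise_deletion_excludes_gapped_sites(self):
        # 3 compared sites, no mismatch among them
        assert pairwise_distances(mla(["AC-T", "ACGT"]), "p").d[0, 1] == 0.0

    def test_k2p_closed_form(self):
        # 100 sites: 10 transitions (A->G), 5 transversions (A->C):
        # P=0.1, Q=0.05 => -ln(0.75)/2 - ln(0.9)/4 = 0.17018
        s1 = "A" * 100
        s2 = "G" * 10 + "C" * 5 + "A" * 85
        dm = pairwise_distances(mla([s1, s2]), "k2p")
        assert dm.d[0, 1] == pytest.approx(0.17018, abs=1e-5)

    def test_p_bounded_by_jc69(self):
        aln = mla(["ACGTACGTGGCC", "ACGAACGTGGCA"])
        p = pairwise_distances(aln, "p").d[0, 1]
        jc = pairwise_distances(aln, "jc69").d[0, 1]
        assert 0 < p <= jc

    def test_no_comparable_sites_is_error(self):
        with pytest.raises(UndefinedDistanceError, match="no comparable sites"):
            pairwise_distances(mla(["AC--", "--GT"]), "p")

    def test_saturated_jc69_errors_unless_capped(self):
        aln = mla(["AAAA", "CCCC"])  # p=1 -> log of negative
        with pytest.raises(UndefinedDistanceError, match="saturated"):
            pairwise_distances(aln, "jc69")
        dm = pairwise_distances(aln, "jc69", saturate_cap=5.0)
        assert dm.d[0, 1] == 5.0

    def test_permutation_equivariance(self):
        rows = ["ACGTACGT", "ACGAACGT", "GCGTACTT", "ACGTATGT"]
        aln = mla(rows)
        perm = [2, 0, 3, 1]
        aln_p = mla([rows[i] for i in perm], taxa=tuple(f"t{i+1}" for i in perm))
        dm = pairwise_distances(aln, "k2p")
        dm_p = pairwise_distances(aln_p, "k2p")
        np.testing.assert_allclose(dm_p.reordered(dm.taxa).d, dm.d)

    def test_csv_roundtrip(self, tmp_path):
        dm = pairwise_distances(mla(["ACGT", "ACGA", "GCGT"]), "p")
        dm.to_csv(tmp_path / "d.csv")
        from cyclodelim import DistanceMatrix

        again = DistanceMatrix.from_csv(tmp_path / "d.csv", model="p")
        assert again.taxa == dm.taxa
        np.testing.assert_allclose(again.d, dm.d)
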