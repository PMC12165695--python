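"""ORF calling, CRISPR array detection, locus association, spacer search
and crRNA processing arithmetic."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import given, settings
from hypothesis import strategies as st

from hepnscout.crispr import (
    ArrayParams,
    ProcessingCall,
    associate_arrays_to_genes,
    find_crispr_arrays,
    find_orfs,
    infer_cleavage_offset,
    mature_crrna_length,
    orf_protein,
    read_bed,
    read_gff3,
    spacer_target_search,
    write_bed,
    write_gff3,
)
from hepnscout.hepn import detect_intramolecular_dimer
from hepnscout.synth import ArraySpec, GenomeSpec, OrfSpec, make_chimera, plant_genome


def rec(seq: str, rid: str = "contig") -> SeqRecord:
    return SeqRecord(Seq(seq), id=rid)


class TestFindOrfs:
    def test_constructed_orf_length(self):
        contig = "ATG" + "GCT" * 100 + "TAA"
        (orf,) = find_orfs(rec(contig), min_aa=50)
        assert orf.strand == "+" and orf.aa_length == 101
        assert orf.span == (0, len(contig))

    def test_reverse_complement_mirrors_coordinates(self):
        contig = "TT" + "ATG" + "GCT" * 100 + "TAA" + "CCC"
        fwd = find_orfs(rec(contig), min_aa=50)[0]
        rc = str(Seq(contig).reverse_complement())
        (orf,) = find_orfs(rec(rc), min_aa=50)
        assert orf.strand == "-" and orf.aa_length == fwd.aa_length
        assert orf.span == (len(contig) - fwd.span[1], len(contig) - fwd.span[0])

    def test_no_orfs_in_homopolymer(self):
        assert find_orfs(rec("A" * 2000)) == []

    def test_translation(self):
        contig = "ATG" + "CGT" + "CAC" + "TAA"
        (orf,) = find_orfs(rec(contig), min_aa=1)
        assert orf_protein(rec(contig), orf) == "MRH"


class TestFindArrays:
    def test_single_planted_array_exact(self):
        spec = GenomeSpec(seed=11, length=8000, arrays=[ArraySpec(start=3000)])
        record, truth = plant_genome(spec)
        (found,) = find_crispr_arrays(record)
        want = truth.arrays[0]
        assert found.span == want.span
        assert [r[0] for r in found.repeats] == [r[0] for r in want.repeats]
        assert [s[0] for s in found.spacers] == [s[0] for s in want.spacers]
        assert found.repeat_consensus == want.repeat_consensus

    def test_random_background_clean(self):
        record, _ = plant_genome(GenomeSpec(seed=13, length=10000))
        assert find_crispr_arrays(record) == []

    def test_two_arrays_in_coordinate_order(self):
        spec = GenomeSpec(
            seed=17,
            length=9000,
            arrays=[ArraySpec(start=1000), ArraySpec(start=4500, n_repeats=5)],
        )
        record, truth = plant_genome(spec)
        found = find_crispr_arrays(record)
        assert [a.span for a in found] == [a.span for a in truth.arrays]

    def test_short_contig_empty(self):
        assert find_crispr_arrays(rec("ACGT" * 10)) == []


class TestAssociate:
    def test_planted_array_near_hepn_orf(self):
        base, _ = make_chimera(("HE", "HE"), his_distance=8.0, id="effector")
        protein = "M" + base.sequence
        orf_len = 3 * (len(protein) + 1)
        spec = GenomeSpec(
            seed=23,
            length=8000,
            orfs=[OrfSpec(start=1000, protein=protein)],
            arrays=[ArraySpec(start=1000 + orf_len + 500)],
            scrub_min_aa=50,
        )
        record, truth = plant_genome(spec)
        orfs = find_orfs(record, min_aa=50)
        arrays = find_crispr_arrays(record)
        call = detect_intramolecular_dimer(base)
        (lc,) = associate_arrays_to_genes(arrays, orfs, {orfs[0].id: call})
        assert lc.distance_bp == 500
        assert lc.cas13_candidate

    def test_distant_orf_not_candidate(self):
        base, _ = make_chimera(("HE", "HE"), his_distance=8.0, id="far")
        protein = "M" + base.sequence
        spec = GenomeSpec(
            seed=29,
            length=14000,
            orfs=[OrfSpec(start=100, protein=protein)],
            arrays=[ArraySpec(start=100 + 3 * (len(protein) + 1) + 10000)],
            scrub_min_aa=50,
        )
        record, _ = plant_genome(spec)
        orfs = find_orfs(record, min_aa=50)
        arrays = find_crispr_arrays(record)
        call = detect_intramolecular_dimer(base)
        (lc,) = associate_arrays_to_genes(arrays, orfs, {orfs[0].id: call})
        assert lc.distance_bp == 10000 and not lc.cas13_candidate

    def test_no_orfs_empty(self):
        record, truth = plant_genome(
            GenomeSpec(seed=31, length=8000, arrays=[ArraySpec(start=2000)])
        )
        assert associate_arrays_to_genes(find_crispr_arrays(record), [], {}) == []


class TestSpacerSearch:
    def test_verbatim_spacer_found(self):
        rng = np.random.default_rng(5)
        target = "".join(rng.choice(list("ACGT"), size=500))
        spacer = target[200:230]
        hits = spacer_target_search([rec(spacer, "sp")], [rec(target, "phage")])
        exact = [h for h in hits if h.mismatches == 0 and h.strand == "+"]
        assert len(exact) == 1 and exact[0].position == 200

    def test_mismatch_threshold(self):
        rng = np.random.default_rng(7)
        target = list(rng.choice(list("ACGT"), size=400))
        spacer = "".join(target[100:130])
        mutated = list(spacer)
        mutated[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[3]]
        mutated[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[20]]
        sp = rec("".join(mutated), "sp")
        tg = rec("".join(target), "t")
        two = [h for h in spacer_target_search([sp], [tg], max_mismatch=2) if h.position == 100]
        assert len(two) == 1 and two[0].mismatches == 2
        one = [h for h in spacer_target_search([sp], [tg], max_mismatch=1) if h.position == 100]
        assert one == []

    def test_reverse_strand_hit(self):
        rng = np.random.default_rng(9)
        target = "".join(rng.choice(list("ACGT"), size=300))
        spacer = str(Seq(target[50:80]).reverse_complement())
        hits = spacer_target_search([rec(spacer, "sp")], [rec(target, "t")])
        minus = [h for h in hits if h.strand == "-" and h.mismatches == 0]
        assert len(minus) == 1 and minus[0].position == 50

    def test_equals_brute_force_oracle(self):
        def oracle(spacer, target, max_mm):
            out = set()
            for pat, strand in ((spacer, "+"), (str(Seq(spacer).reverse_complement()), "-")):
                for i in range(len(target) - len(pat) + 1):
                    mm = sum(a != b for a, b in zip(pat, target[i : i + len(pat)]))
                    if mm <= max_mm:
                        out.add((strand, i, mm))
            return out

        rng = np.random.default_rng(11)
        for trial in range(50):
            target = "".join(rng.choice(list("ACGT"), size=120))
            spacer = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 22))))
            got = {
                (h.strand, h.position, h.mismatches)
                for h in spacer_target_search([rec(spacer, "s")], [rec(target, "t")], max_mismatch=3)
            }
            assert got == oracle(spacer, target, 3), f"trial {trial}"

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError):
            spacer_target_search([rec("ACGTACGT", "s")], [rec("ACGT" * 30, "t")])


class TestProcessingArithmetic:
    def test_six_nt_product_cuts_24_upstream(self):
        call = infer_cleavage_offset(30, 6)
        assert call.offset_upstream_of_repeat == 24

    def test_seven_nt_product_cuts_23_upstream(self):
        call = infer_cleavage_offset(30, 7)
        assert call.offset_upstream_of_repeat == 23
        assert call.mature_spacer_len == 23

    def test_full_fragment_cuts_at_junction(self):
        assert infer_cleavage_offset(30, 30).offset_upstream_of_repeat == 0

    def test_mature_guide_length_about_sixty(self):
        assert mature_crrna_length(36, 24) == 60
        assert mature_crrna_length(36, 23) == 59
        assert mature_crrna_length(0, 7) == 7

    def test_mature_crrna_from_processing_call(self):
        assert infer_cleavage_offset(30, 6, repeat_len=36).mature_crrna_len == 60

    def test_errors(self):
        with pytest.raises(ValueError):
            infer_cleavage_offset(30, 31)  # label would sit in the repeat
        with pytest.raises(ValueError):
            mature_crrna_length(-1, 5)

    @settings(max_examples=200, derandomize=True)
    @given(
        spacer=st.integers(min_value=0, max_value=100),
        fragment=st.integers(min_value=0, max_value=100),
        repeat=st.integers(min_value=0, max_value=60),
    )
    def test_length_conservation(self, spacer, fragment, repeat):
        if fragment > spacer:
            with pytest.raises(ValueError):
                infer_cleavage_offset(spacer, fragment, repeat)
        else:
            call = infer_cleavage_offset(spacer, fragment, repeat)
            assert call.offset_upstream_of_repeat + call.fragment_len == call.spacer_len
            assert call.mature_crrna_len == call.mature_spacer_len + repeat


class TestSerialization:
    def test_gff3_round_trip_preserves_intervals(self, tmp_path):
        record, truth = plant_genome(
            GenomeSpec(seed=37, length=8000, arrays=[ArraySpec(start=2500)])
        )
        arrays = find_crispr_arrays(record)
        orfs = find_orfs(record)
        path = tmp_path / "out.gff3"
        write_gff3(arrays, orfs, path)
        feats = read_gff3(path)
        spans = [f[2] for f in feats if f[1] == "repeat_region"]
        assert spans == [arrays[0].span]
        units = [f[2] for f in feats if f[1] == "repeat_unit"]
        assert units == [r[0] for r in arrays[0].repeats]

    def test_bed_round_trip(self, tmp_path):
        rows = [("c1", 10, 46, "sp1"), ("c1", 76, 112, "sp2")]
        path = tmp_path / "sp.bed"
        write_bed(rows, path)
        assert read_bed(path) == rows
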